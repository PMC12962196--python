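"""Z-spectrum normalisation, baseline removal and five-pool Lorentzian fit.

The Z-spectrum at 1.0 uT CW saturation is modelled as a constant semisolid
MT floor plus five Lorentzian saturation pools:

    Z(D) = 1 - c_mt - sum_i A_i (w_i/2)^2 / ((w_i/2)^2 + (D - D0_i)^2)

with pools fixed at 3.5 (amide CEST), 2.0 (amine CEST), 0 (direct water
saturation), -1.6 and -3.5 ppm (relayed NOE).  Processing inverts the
spectrum and anchors the +5 ppm endpoint at zero, which removes the flat
MT contribution; the five-pool decomposition is then fitted to the
baseline-corrected spectrum with the same +5 ppm anchoring applied to the
model, and pool peak amplitudes are the reported CEST / rNOE metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .images import ImageStack
from .protocols import ProtocolError, ZspecProtocol

POOL_NAMES = ("CEST3.5", "CEST2.0", "DS", "NOE1.6", "NOE3.5")
POOL_CENTERS_PPM = {"CEST3.5": 3.5, "CEST2.0": 2.0, "DS": 0.0,
                    "NOE1.6": -1.6, "NOE3.5": -3.5}
# FWHM bounds per pool, ppm
WIDTH_BOUNDS_PPM = {"CEST3.5": (0.5, 4.0), "CEST2.0": (0.3, 3.0),
                    "DS": (0.3, 3.0), "NOE1.6": (0.3, 3.0), "NOE3.5": (1.0, 8.0)}
DS_CENTER_SHIFT_PPM = 0.3  # DS center may float within +-0.3 ppm (B0 proxy)


@dataclass
class LorentzianPool:
    """One saturation pool: peak amplitude, FWHM and center offset (ppm)."""

    name: str
    amplitude: float
    width_ppm: float
    center_ppm: float | None = None

    def __post_init__(self) -> None:
        if self.center_ppm is None:
            self.center_ppm = POOL_CENTERS_PPM[self.name]
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")
        if self.width_ppm <= 0:
            raise ValueError(f"{self.name}: width must be positive")


def default_pool_table() -> list[LorentzianPool]:
    """Initialisation pool table for the fitter (healthy-tissue-like values)."""
    return [
        LorentzianPool("CEST3.5", 0.05, 1.5),
        LorentzianPool("CEST2.0", 0.04, 1.0),
        LorentzianPool("DS", 0.85, 1.2),
        LorentzianPool("NOE1.6", 0.04, 1.0),
        LorentzianPool("NOE3.5", 0.12, 3.5),
    ]


def lorentzian(offsets_ppm: np.ndarray, amplitude: float, width_ppm: float,
               center_ppm: float) -> np.ndarray:
    hw2 = (0.5 * width_ppm) ** 2
    return amplitude * hw2 / (hw2 + (np.asarray(offsets_ppm, float) - center_ppm) ** 2)


def pools_sum(offsets_ppm, pools) -> np.ndarray:
    out = np.zeros_like(np.asarray(offsets_ppm, dtype=float))
    for p in pools:
        out += lorentzian(offsets_ppm, p.amplitude, p.width_ppm, p.center_ppm)
    return out


def zspectrum_forward(pools, c_mt: float, protocol: ZspecProtocol) -> np.ndarray:
    """Noiseless Z-spectrum samples on the protocol's offset grid."""
    z = 1.0 - c_mt - pools_sum(protocol.offsets_ppm, pools)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("nonphysical pool table: Z outside [0, 1]")
    return z


def normalize_zspectrum(stack: ImageStack | np.ndarray, protocol: ZspecProtocol,
                        mode: str = "interp") -> tuple[np.ndarray, np.ndarray]:
    """Z = S/S0 per voxel, with S0 from the two bracketing reference scans.

    ``mode='interp'`` linearly interpolates S0 in acquisition order between
    the first and last (reference) volumes, correcting slow signal drift;
    ``mode='mean'`` uses their average.  Returns ``(z, clip_mask)`` where
    ``clip_mask`` reports voxels/offsets with Z > 1.05 (reported, not
    silently clipped).  Voxels with a nonpositive reference are masked NaN.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if data.shape[-1] != protocol.n_volumes:
        raise ProtocolError(
            f"stack has {data.shape[-1]} volumes; protocol expects "
            f"{protocol.n_volumes} (offsets + 2 references)"
        )
    ref0, ref1 = data[..., 0], data[..., -1]
    sat = data[..., 1:-1]
    n = protocol.n_offsets
    if mode == "interp":
        frac = (np.arange(1, n + 1)) / (n + 1)  # acquisition-order position
        s0 = ref0[..., None] * (1 - frac) + ref1[..., None] * frac
    elif mode == "mean":
        s0 = (0.5 * (ref0 + ref1))[..., None] * np.ones(n)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    bad = (ref0 <= 0) | (ref1 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = sat / s0
    z[bad] = np.nan
    clip = z > 1.05
    return z, clip


def invert_and_debase(z: np.ndarray, protocol: ZspecProtocol) -> np.ndarray:
    """Inverted, baseline-corrected spectrum Y(D) = (1-Z(D)) - (1-Z(+5 ppm)).

    The constant semisolid-MT contribution cancels; Y is exactly zero at
    the +5 ppm endpoint.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != protocol.n_offsets:
        raise ProtocolError("spectrum length does not match the offset grid")
    anchor_idx = int(np.argmax(protocol.offsets_ppm))
    if not np.isclose(protocol.offsets_ppm[anchor_idx], 5.0):
        raise ProtocolError("offset grid is missing the +5 ppm anchor sample")
    inv = 1.0 - z
    return inv - inv[..., anchor_idx:anchor_idx + 1]


@dataclass
class ZspectrumFit:
    """Five-pool decomposition of one baseline-corrected spectrum."""

    pools: list[LorentzianPool]
    residual_norm: float
    converged: bool

    def amplitude(self, name: str) -> float:
        for p in self.pools:
            if p.name == name:
                return p.amplitude
        raise KeyError(name)

    def as_dict(self) -> dict[str, float]:
        return {p.name: p.amplitude for p in self.pools}


def _pack(pools, ds_shift: float) -> np.ndarray:
    amps = [p.amplitude for p in pools]
    widths = [p.width_ppm for p in pools]
    return np.array(amps + widths + [ds_shift])


def _model(x: np.ndarray, offsets: np.ndarray, anchor_idx: int,
           names=POOL_NAMES) -> np.ndarray:
    amps, widths, ds_shift = x[:5], x[5:10], x[10]
    total = np.zeros_like(offsets)
    for name, a, w in zip(names, amps, widths):
        c = POOL_CENTERS_PPM[name] + (ds_shift if name == "DS" else 0.0)
        total += lorentzian(offsets, a, w, c)
    return total - total[anchor_idx]  # same +5 ppm anchoring as the data


def fit_five_pool(y: np.ndarray, protocol: ZspecProtocol,
                  init_pools: list[LorentzianPool] | None = None) -> ZspectrumFit:
    """Bounded nonlinear least squares for the five-pool decomposition.

    Free parameters: five amplitudes in [0, 1], five FWHMs within the
    pool-specific bounds, and the DS center shift within +-0.3 ppm.
    Initialisation comes from the default pool table; the optimiser is
    deterministic so identical inputs give bit-identical fits.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (protocol.n_offsets,):
        raise ProtocolError("expected one spectrum on the protocol offset grid")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite samples")
    offsets = protocol.offsets_ppm
    anchor_idx = int(np.argmax(offsets))

    pools0 = init_pools if init_pools is not None else default_pool_table()
    pools0 = sorted(pools0, key=lambda p: POOL_NAMES.index(p.name))
    x0 = _pack(pools0, 0.0)
    lo = np.array([0.0] * 5 + [WIDTH_BOUNDS_PPM[n][0] for n in POOL_NAMES]
                  + [-DS_CENTER_SHIFT_PPM])
    hi = np.array([1.0] * 5 + [WIDTH_BOUNDS_PPM[n][1] for n in POOL_NAMES]
                  + [DS_CENTER_SHIFT_PPM])
    x0 = np.clip(x0, lo, hi)

    res = least_squares(lambda x: _model(x, offsets, anchor_idx) - y, x0,
                        bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    pools = []
    for i, name in enumerate(POOL_NAMES):
        center = POOL_CENTERS_PPM[name] + (res.x[10] if name == "DS" else 0.0)
        pools.append(LorentzianPool(name, float(res.x[i]), float(res.x[5 + i]), center))
    return ZspectrumFit(pools=pools,
                        residual_norm=float(np.sqrt(2.0 * res.cost)),
                        converged=bool(res.success))


def fit_roi_spectra(z: np.ndarray, labels: np.ndarray, protocol: ZspecProtocol,
                    codes=None) -> dict[int, ZspectrumFit]:
    """ROI-mode fitting: average Z over each ROI's voxels, then decompose.

    ``z`` has shape ``spatial + (n_offsets,)`` and ``labels`` the matching
    spatial shape; NaN voxels are excluded from the ROI means.
    """
    labels = np.asarray(labels)
    if codes is None:
        codes = [c for c in np.unique(labels) if c != 0]
    fits: dict[int, ZspectrumFit] = {}
    for code in codes:
        sel = z[labels == code]
        mean_z = np.nanmean(sel, axis=0)
        y = invert_and_debase(mean_z, protocol)
        fits[int(code)] = fit_five_pool(y, protocol)
    return fits
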