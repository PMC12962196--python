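"""Two-pool steady-state magnetization-transfer model and PSR fitting.

The pulsed saturation protocol is mapped to an equivalent continuous-wave
amplitude (CW power equivalent, average-power matching over the TR) and the
signal is modelled as the steady state of the coupled two-pool longitudinal
Bloch equations:

    S(D, w1) = scale * [R_a (R_b + k_ba + R_rfb) + k_ba R_b PSR]
               / [(R_a + k_ba PSR + R_rfa)(R_b + k_ba + R_rfb) - k_ba^2 PSR]

with the bound-pool saturation rate R_rfb = pi w1^2 g_SL(D, T2b) using the
super-Lorentzian lineshape, and the free-pool direct-saturation rate in the
Lorentzian-wing approximation R_rfa = (w1 / 2 pi D)^2 / T2a.  The bound/free
pool size ratio PSR is the quantity of interest; R_a and R_b are fixed at
1 s^-1 (no independent T1 observation in the protocol), T2a enters only
through the composite 1/(R_a T2a).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .images import ImageStack
from .protocols import ProtocolError, QmtProtocol

_U_SING = 1.0 / np.sqrt(3.0)  # orientation singularity of the lineshape
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(128)
# 128-point panels on [0, u*] and [u*, 1]: node clustering at the panel
# edges resolves the narrow integrand feature at the singular point
_GL_U = np.concatenate([0.5 * _U_SING * (_GL_NODES + 1.0),
                        _U_SING + 0.5 * (1.0 - _U_SING) * (_GL_NODES + 1.0)])
_GL_W = np.concatenate([0.5 * _U_SING * _GL_WEIGHTS,
                        0.5 * (1.0 - _U_SING) * _GL_WEIGHTS])


def superlorentzian_lineshape(offset_hz, t2b_s) -> np.ndarray:
    """Super-Lorentzian absorption lineshape g(offset, T2b), in seconds.

    g = int_0^1 sqrt(2/pi) T2b/|3u^2-1| exp(-2 (2 pi offset T2b / (3u^2-1))^2) du
    by fixed 256-point Gauss-Legendre quadrature split at the orientation
    singularity u = 1/sqrt(3), where the integrand vanishes
    super-exponentially for any nonzero offset.  Accurate to better than
    1e-4 relative over the protocol's 1-100 kHz, 5-50 us range.  Even in
    the offset: g(-D) = g(D).
    """
    t2b = float(t2b_s)
    if t2b <= 0:
        raise ValueError(f"T2b must be positive, got {t2b}")
    offset = np.abs(np.asarray(offset_hz, dtype=float))
    denom = 3.0 * _GL_U ** 2 - 1.0
    x = 2.0 * np.pi * offset[..., None] * t2b / denom
    integrand = np.sqrt(2.0 / np.pi) * (t2b / np.abs(denom)) * np.exp(-2.0 * x ** 2)
    return integrand @ _GL_W


def _pulse_shape_moments(shape: str, n_grid: int = 4096) -> tuple[float, float]:
    """Normalized first/second moments (p1, p2) of the unit-peak pulse shape."""
    if shape == "rect":
        return 1.0, 1.0
    if shape == "gaussian":
        # unit-peak Gaussian truncated where the envelope reaches 1% of peak
        t = np.linspace(-0.5, 0.5, n_grid)
        sigma = 0.5 / np.sqrt(2.0 * np.log(100.0))
        s = np.exp(-t ** 2 / (2.0 * sigma ** 2))
        p1 = np.trapezoid(s, t)
        p2 = np.trapezoid(s ** 2, t)
        return float(p1), float(p2)
    raise ValueError(f"unknown pulse shape {shape!r}")


def cw_power_equivalent(theta_sat_deg: float, pulse_width_ms: float, tr_ms: float,
                        shape: str = "gaussian") -> float:
    """CW power-equivalent saturation amplitude w1_cwpe in rad/s.

    Peak amplitude from the flip angle (theta = w1_peak * p1 * pw), then
    average-power matching over the repetition time:
    w1_cwpe = w1_peak * sqrt(p2 * pw / TR).
    """
    if theta_sat_deg <= 0:
        raise ValueError("saturation flip angle must be positive")
    p1, p2 = _pulse_shape_moments(shape)
    pw = pulse_width_ms * 1e-3
    tr = tr_ms * 1e-3
    w1_peak = np.deg2rad(theta_sat_deg) / (p1 * pw)
    return float(w1_peak * np.sqrt(p2 * pw / tr))


@dataclass
class QmtParameters:
    """Two-pool model parameters; ``inv_ra_t2a`` is the composite 1/(R_a T2a)."""

    psr: float
    k_ba: float = 20.0            # s^-1, bound -> free exchange
    t2b_us: float = 12.0          # bound-pool T2, microseconds
    inv_ra_t2a: float = 20.0      # 1/(R_a * T2a), unitless
    scale: float = 1.0
    r_a: float = 1.0              # s^-1, fixed
    r_b: float = 1.0              # s^-1, fixed

    def __post_init__(self) -> None:
        if not 0 <= self.psr < 1:
            raise ValueError(f"PSR must be in [0, 1), got {self.psr}")
        for name in ("k_ba", "t2b_us", "inv_ra_t2a", "scale", "r_a", "r_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def ramani_signal(params: QmtParameters, protocol: QmtProtocol) -> np.ndarray:
    """Predicted normalized signal per protocol volume (power varying slowest)."""
    powers, offsets = protocol.grid()
    w1 = np.array([
        cw_power_equivalent(p, protocol.pulse_width_ms, protocol.tr_ms,
                            protocol.pulse_shape)
        for p in protocol.flip_angles_deg
    ])
    w1_per_vol = w1[np.searchsorted(protocol.flip_angles_deg, powers)]
    return _ramani_eval(
        np.array([params.psr, params.k_ba, params.t2b_us, params.inv_ra_t2a,
                  params.scale]),
        w1_per_vol, offsets, params.r_a, params.r_b,
    )


def _ramani_eval(x: np.ndarray, w1: np.ndarray, offsets: np.ndarray,
                 r_a: float, r_b: float) -> np.ndarray:
    psr, k_ba, t2b_us, inv_ra_t2a, scale = x
    g = superlorentzian_lineshape(offsets, t2b_us * 1e-6)
    r_rfb = np.pi * w1 ** 2 * g
    inv_t2a = inv_ra_t2a * r_a
    r_rfa = (w1 / (2.0 * np.pi * offsets)) ** 2 * inv_t2a
    bound = r_b + k_ba + r_rfb
    num = r_a * bound + k_ba * r_b * psr
    den = (r_a + k_ba * psr + r_rfa) * bound - k_ba ** 2 * psr
    return scale * num / den


@dataclass
class PsrFit:
    """Voxelwise PSR fit with nuisance parameters and diagnostics."""

    psr: np.ndarray
    k_ba: np.ndarray
    t2b_us: np.ndarray
    inv_ra_t2a: np.ndarray
    scale: np.ndarray
    residual_norm: np.ndarray
    converged: np.ndarray
    mask: np.ndarray


_BOUNDS_LO = np.array([0.0, 1.0, 5.0, 1.0, 0.3])
_BOUNDS_HI = np.array([0.5, 100.0, 50.0, 100.0, 3.0])
_STARTS = np.array([
    [0.05, 10.0, 8.0, 15.0, 1.0],
    [0.15, 20.0, 12.0, 25.0, 1.0],
    [0.30, 40.0, 20.0, 40.0, 1.0],
])


def fit_psr(stack: ImageStack | np.ndarray, protocol: QmtProtocol,
            mask: np.ndarray | None = None, r_a: float = 1.0, r_b: float = 1.0,
            n_starts: int = 3) -> PsrFit:
    """Per-voxel bounded nonlinear least squares for the two-pool model.

    Each voxel's time series is normalized by the far-offset lowest-power
    volume (the protocol's quasi-unsaturated reference), then fitted over
    {PSR, k_ba, T2b, 1/(R_a T2a), scale} from ``n_starts`` starting points,
    keeping the lowest-residual solution.  Non-converged voxels are flagged
    and their PSR set to NaN.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if data.shape[-1] != protocol.n_volumes:
        raise ProtocolError(
            f"stack has {data.shape[-1]} volumes; protocol expects {protocol.n_volumes}"
        )
    spatial = data.shape[:-1]
    flat = data.reshape(-1, data.shape[-1])
    fit_mask = flat[:, protocol.reference_index] > 0
    if mask is not None:
        fit_mask &= np.asarray(mask, bool).reshape(-1)

    powers, offsets = protocol.grid()
    w1_levels = np.array([
        cw_power_equivalent(p, protocol.pulse_width_ms, protocol.tr_ms,
                            protocol.pulse_shape)
        for p in protocol.flip_angles_deg
    ])
    w1 = w1_levels[np.searchsorted(protocol.flip_angles_deg, powers)]

    n = flat.shape[0]
    out = {k: np.full(n, np.nan) for k in
           ("psr", "k_ba", "t2b_us", "inv_ra_t2a", "scale", "residual_norm")}
    converged = np.zeros(n, dtype=bool)

    starts = _STARTS[:n_starts]
    for idx in np.nonzero(fit_mask)[0]:
        y = flat[idx] / flat[idx, protocol.reference_index]
        best = None
        for x0 in starts:
            try:
                res = least_squares(
                    lambda x: _ramani_eval(x, w1, offsets, r_a, r_b) - y,
                    x0, bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            continue
        converged[idx] = True
        for key, val in zip(("psr", "k_ba", "t2b_us", "inv_ra_t2a", "scale"), best.x):
            out[key][idx] = val
        out["residual_norm"][idx] = np.sqrt(2.0 * best.cost)

    return PsrFit(
        psr=out["psr"].reshape(spatial),
        k_ba=out["k_ba"].reshape(spatial),
        t2b_us=out["t2b_us"].reshape(spatial),
        inv_ra_t2a=out["inv_ra_t2a"].reshape(spatial),
        scale=out["scale"].reshape(spatial),
        residual_norm=out["residual_norm"].reshape(spatial),
        converged=converged.reshape(spatial),
        mask=fit_mask.reshape(spatial),
    )
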