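"""Acquisition protocol descriptions for the three quantitative modalities.

Each protocol is an immutable-ish dataclass carrying exactly the pulse /
offset / gradient information that both the forward simulators and the
fitters consume, plus TSV round-trip helpers so protocols can ride along
with image stacks as sidecar tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .directions import DIRECTIONS_30

GAMMA_HZ_PER_T = 42.577478518e6  # proton gyromagnetic ratio / 2pi
PPM_TO_HZ = 400.0  # 9.4 T proton resonance: 1 ppm = 400 Hz


class ProtocolError(ValueError):
    """Raised when a protocol violates its structural invariants."""


@dataclass
class DwiProtocol:
    """Single-shell diffusion protocol: b-values and unit gradient directions.

    ``b_values`` in s/mm^2, one entry per volume; zero entries are the
    non-diffusion-weighted (b0) volumes and their direction rows are ignored.
    """

    b_values: np.ndarray
    gradient_directions: np.ndarray

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.gradient_directions = np.asarray(self.gradient_directions, dtype=float)
        if self.gradient_directions.shape != (self.b_values.size, 3):
            raise ProtocolError(
                "gradient_directions must be (n_volumes, 3); got "
                f"{self.gradient_directions.shape} for {self.b_values.size} b-values"
            )
        dw = self.b_values > 0
        if not np.any(self.b_values == 0):
            raise ProtocolError("protocol needs at least one b=0 volume")
        if dw.sum() < 6:
            raise ProtocolError("at least 6 diffusion-weighted directions required")
        norms = np.linalg.norm(self.gradient_directions[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ProtocolError("nonzero-b gradient directions must be unit vectors")

    @property
    def n_volumes(self) -> int:
        return int(self.b_values.size)

    @classmethod
    def default(cls, b: float = 1000.0) -> "DwiProtocol":
        """b=1000 s/mm^2 shell, 30 equally-spaced directions plus one b0."""
        bvals = np.concatenate([[0.0], np.full(len(DIRECTIONS_30), b)])
        dirs = np.vstack([[0.0, 0.0, 0.0], DIRECTIONS_30])
        return cls(bvals, dirs)

    # FSL-style sidecars ----------------------------------------------------
    def write_bval_bvec(self, bval_path, bvec_path) -> None:
        np.savetxt(bval_path, self.b_values[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.gradient_directions.T, fmt="%.15f")

    @classmethod
    def from_bval_bvec(cls, bval_path, bvec_path) -> "DwiProtocol":
        bvals = np.atleast_1d(np.loadtxt(bval_path)).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals, bvecs)


@dataclass
class QmtProtocol:
    """Pulsed magnetization-transfer protocol: saturation powers x offsets.

    One acquired volume per (flip angle, offset) pair, powers varying
    slowest.  Offsets in Hz; the largest offset of the lowest power serves
    as the normalisation reference by default.
    """

    flip_angles_deg: np.ndarray = field(
        default_factory=lambda: np.array([220.0, 820.0])
    )
    offsets_hz: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e3, 100e3, 10)
    )
    pulse_width_ms: float = 10.0
    tr_ms: float = 24.0
    excitation_flip_deg: float = 7.0
    pulse_shape: str = "gaussian"

    def __post_init__(self) -> None:
        self.flip_angles_deg = np.asarray(self.flip_angles_deg, dtype=float)
        self.offsets_hz = np.asarray(self.offsets_hz, dtype=float)
        if self.flip_angles_deg.size < 2 or len(set(self.flip_angles_deg)) < 2:
            raise ProtocolError("need at least 2 distinct saturation powers")
        if self.offsets_hz.size < 4:
            raise ProtocolError("need at least 4 offsets")
        if np.any(self.offsets_hz <= 0) or np.any(np.diff(self.offsets_hz) <= 0):
            raise ProtocolError("offsets must be strictly positive and increasing")
        if self.pulse_shape not in ("gaussian", "rect"):
            raise ProtocolError(f"unknown pulse shape {self.pulse_shape!r}")

    @property
    def n_volumes(self) -> int:
        return int(self.flip_angles_deg.size * self.offsets_hz.size)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-volume (flip_deg, offset_hz) arrays, power varying slowest."""
        p, o = np.meshgrid(self.flip_angles_deg, self.offsets_hz, indexing="ij")
        return p.ravel(), o.ravel()

    @property
    def reference_index(self) -> int:
        """Volume index of the far-offset lowest-power (quasi-unsaturated) scan."""
        powers, offsets = self.grid()
        low = powers == self.flip_angles_deg.min()
        return int(np.nonzero(low & (offsets == offsets.max()))[0][0])

    def to_table(self) -> pd.DataFrame:
        powers, offsets = self.grid()
        return pd.DataFrame({"power_deg": powers, "offset_hz": offsets})

    @classmethod
    def from_table(cls, table: pd.DataFrame, **kwargs) -> "QmtProtocol":
        flips = np.unique(table["power_deg"].to_numpy())
        offsets = np.unique(table["offset_hz"].to_numpy())
        proto = cls(flip_angles_deg=np.sort(flips), offsets_hz=np.sort(offsets), **kwargs)
        if proto.n_volumes != len(table):
            raise ProtocolError("protocol table is not a full power x offset grid")
        return proto


@dataclass
class ZspecProtocol:
    """CEST Z-spectrum protocol: CW saturation, uniform ppm offset grid.

    Offsets run -5..+5 ppm in 0.2 ppm steps (51 samples); two reference
    scans at 100 kHz bracket the acquisition (indices 0 and last).
    """

    offsets_ppm: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(-5.0, 5.0 + 1e-9, 0.2), 10)
    )
    sat_duration_s: float = 5.0
    sat_amplitude_ut: float = 1.0
    hz_per_ppm: float = PPM_TO_HZ
    reference_offset_hz: float = 100e3

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        steps = np.diff(self.offsets_ppm)
        if not np.allclose(steps, steps[0]):
            raise ProtocolError("offset grid must be uniform")
        if not np.allclose(self.offsets_ppm, -self.offsets_ppm[::-1]):
            raise ProtocolError("offset grid must be symmetric about 0")

    @property
    def n_offsets(self) -> int:
        return int(self.offsets_ppm.size)

    @property
    def n_volumes(self) -> int:
        """Saturation offsets plus the two bracketing reference scans."""
        return self.n_offsets + 2

    def to_table(self) -> pd.DataFrame:
        offs = np.concatenate(
            [[self.reference_offset_hz], self.offsets_ppm * self.hz_per_ppm,
             [self.reference_offset_hz]]
        )
        is_ref = np.zeros(offs.size, dtype=int)
        is_ref[[0, -1]] = 1
        return pd.DataFrame({"offset_hz": offs, "is_reference": is_ref})

    @classmethod
    def from_table(cls, table: pd.DataFrame, hz_per_ppm: float = PPM_TO_HZ,
                   **kwargs) -> "ZspecProtocol":
        ref = table["is_reference"].to_numpy().astype(bool)
        if ref.sum() != 2 or not (ref[0] and ref[-1]):
            raise ProtocolError("expected exactly two bracketing reference scans")
        offs = table.loc[~ref, "offset_hz"].to_numpy() / hz_per_ppm
        return cls(offsets_ppm=offs, hz_per_ppm=hz_per_ppm,
                   reference_offset_hz=float(table.loc[ref, "offset_hz"].iloc[0]),
                   **kwargs)
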