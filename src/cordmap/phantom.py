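"""Synthetic spinal-cord phantom cohorts.

Generates the study design the statistics run on: a cohort of subjects,
each with two lesioned cervical segments imaged pre- and post-lesion, a
unilateral dorsal-nerve-root lesion, 14 side-resolved ROIs on an axial
label map, per-ROI ground-truth tissue parameters with between-subject
variation, and noisy DWI / MT-weighted / Z-spectrum image stacks produced
by the forward models of the dti, qmt and zspec modules under Rician
magnitude noise.

Geometry is schematic, not anatomical: an elliptical cord cross-section
with a butterfly grey-matter region (ventral and dorsal horns), white
matter split into ventral / lateral / dorsal pathways, dorsal root entry
zone (DREZ) strips at the dorsolateral margin, and dorsal nerve root (DNR)
bundles outside the cord boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dti, qmt, zspec
from .images import ImageStack
from .protocols import DwiProtocol, QmtProtocol, ZspecProtocol

ROI_NAMES = ("VH", "DH", "LP", "VP", "DP", "DREZ", "DNR")
SIDES = ("left", "right")

#: parameters subject to between-subject variation and lesion effects
SAMPLED_PARAMS = (
    "lambda1", "lambda2", "lambda3",
    "psr", "k_ba", "t2b_us", "inv_ra_t2a",
    "A_CEST3.5", "A_CEST2.0", "A_DS", "A_NOE1.6", "A_NOE3.5",
    "c_mt", "s0",
)

#: validity ranges used to truncate sampled draws
_PARAM_RANGES = {
    "psr": (1e-4, 0.999),
    "A_CEST3.5": (0.0, 1.0), "A_CEST2.0": (0.0, 1.0), "A_DS": (0.0, 1.0),
    "A_NOE1.6": (0.0, 1.0), "A_NOE3.5": (0.0, 1.0),
    "c_mt": (0.0, 0.5),
}

#: Lorentzian FWHMs (ppm) — fixed tissue properties, not sampled
POOL_WIDTHS_PPM = {"CEST3.5": 1.5, "CEST2.0": 1.0, "DS": 1.2,
                   "NOE1.6": 1.0, "NOE3.5": 3.5}


class ConfigurationError(ValueError):
    """Invalid cohort / effect configuration."""


class SizingError(ValueError):
    """Grid too small to place all ROIs."""


# ---------------------------------------------------------------------------
# label scheme and geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiLabelScheme:
    """Integer code -> (ROI name, side); 0 is background/CSF."""

    labels: dict[int, tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for code, (name, side) in self.labels.items():
            if code <= 0:
                raise ConfigurationError("ROI codes must be positive (0 is background)")
            if name not in ROI_NAMES or side not in SIDES:
                raise ConfigurationError(f"unknown ROI {(name, side)}")
            seen.add((name, side))
        expected = {(n, s) for n in ROI_NAMES for s in SIDES}
        if seen != expected:
            raise ConfigurationError(
                "scheme must contain each of the 14 side-resolved ROIs exactly once"
            )

    def code_of(self, name: str, side: str) -> int:
        for code, pair in self.labels.items():
            if pair == (name, side):
                return code
        raise KeyError((name, side))

    def to_json_dict(self) -> dict:
        return {str(c): {"name": n, "side": s} for c, (n, s) in self.labels.items()}

    @classmethod
    def default(cls) -> "RoiLabelScheme":
        labels = {}
        code = 1
        for name in ROI_NAMES:
            for side in SIDES:
                labels[code] = (name, side)
                code += 1
        return cls(labels)


def build_label_map(grid_size: tuple[int, int],
                    scheme: RoiLabelScheme | None = None) -> np.ndarray:
    """Schematic axial label image on an (nx, ny) grid.

    Left is negative x; dorsal is positive y.  Raises :class:`SizingError`
    below 48x48, the smallest grid on which every ROI keeps >= 20 voxels.
    """
    nx, ny = grid_size
    if min(nx, ny) < 48:
        raise SizingError(f"grid {grid_size} too small; need at least 48x48")
    scheme = scheme or RoiLabelScheme.default()
    s = min(nx, ny) / 64.0  # geometry scale relative to the 64x64 reference

    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    xx, yy = np.meshgrid(x, y, indexing="ij")

    a, b = 20.0 * s, 16.0 * s                      # cord ellipse semi-axes
    r_ell = np.sqrt((xx / a) ** 2 + (yy / b) ** 2)
    cord = r_ell <= 1.0
    theta = np.degrees(np.arctan2(np.abs(xx), yy))  # angle from dorsal (+y) axis

    labels = np.zeros((nx, ny), dtype=int)

    def put(mask, name, side):
        labels[mask] = scheme.code_of(name, side)

    left, right = xx < 0, xx >= 0
    # white matter partition: dorsal / ventral wedges, lateral remainder
    for side, half in (("left", left), ("right", right)):
        put(cord & half, "LP", side)
        put(cord & half & (theta >= 125.0), "VP", side)
        put(cord & half & (theta <= 25.0), "DP", side)
        # DREZ: dorsolateral shell strip
        put(cord & half & (r_ell >= 0.78) & (theta > 25.0) & (theta <= 65.0),
            "DREZ", side)
    # grey-matter butterfly: ventral and dorsal horns
    for sgn, side in ((-1.0, "left"), (1.0, "right")):
        vh = (xx - sgn * 7.0 * s) ** 2 + (yy + 6.0 * s) ** 2 <= (4.2 * s) ** 2
        dh = (xx - sgn * 5.0 * s) ** 2 + (yy - 6.0 * s) ** 2 <= (4.0 * s) ** 2
        put(vh & cord, "VH", side)
        put(dh & cord, "DH", side)
        # dorsal nerve root bundle outside the cord
        dnr = (xx - sgn * 19.0 * s) ** 2 + (yy - 15.0 * s) ** 2 <= (3.8 * s) ** 2
        put(dnr & ~cord, "DNR", side)

    counts = {pair: int((labels == code).sum()) for code, pair in scheme.labels.items()}
    small = {k: v for k, v in counts.items() if v < 20}
    if small:
        raise SizingError(f"grid {grid_size} leaves ROIs under 20 voxels: {small}")
    return labels


# ---------------------------------------------------------------------------
# cohort design, tissue parameters, lesion effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Study layout: subjects x segments x {pre, post}, unilateral lesion."""

    n_subjects: int = 4
    segments_per_subject: int = 2
    conditions: tuple[str, ...] = ("pre", "post")
    lesion_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.segments_per_subject < 1:
            raise ConfigurationError("need at least one subject and one segment")
        if self.lesion_side not in SIDES:
            raise ConfigurationError(f"lesion_side must be one of {SIDES}")
        if tuple(self.conditions) != ("pre", "post"):
            raise ConfigurationError("conditions must be ('pre', 'post')")

    @property
    def n_injured_segments(self) -> int:
        return self.n_subjects * self.segments_per_subject

    def keys(self):
        for subject in range(1, self.n_subjects + 1):
            for segment in range(1, self.segments_per_subject + 1):
                for condition in self.conditions:
                    yield subject, segment, condition


def default_class_means() -> dict[str, dict[str, float]]:
    """Per-ROI ground-truth parameter means (9.4 T healthy-tissue-like).

    Diffusivities in um^2/ms; a single Z-spectrum pool table is shared by
    all tissue classes, with contrast carried by diffusion and PSR.
    """
    pools = {"A_CEST3.5": 0.05, "A_CEST2.0": 0.04, "A_DS": 0.85,
             "A_NOE1.6": 0.04, "A_NOE3.5": 0.12, "c_mt": 0.08}
    common = {"k_ba": 20.0, "t2b_us": 12.0, "inv_ra_t2a": 20.0, "s0": 100.0, **pools}
    wm = {"lambda1": 1.7, "lambda2": 0.3, "lambda3": 0.3, "psr": 0.17, **common}
    gm = {"lambda1": 1.0, "lambda2": 0.7, "lambda3": 0.7, "psr": 0.10, **common}
    dnr = {"lambda1": 1.5, "lambda2": 0.35, "lambda3": 0.35, "psr": 0.15, **common}
    return {
        "VH": dict(gm), "DH": dict(gm),
        "LP": dict(wm), "VP": dict(wm), "DP": dict(wm), "DREZ": dict(wm),
        "DNR": dict(dnr),
    }


@dataclass(frozen=True)
class LesionEffectTable:
    """Multiplicative lesion-side, post-lesion parameter factors per ROI."""

    factors: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for roi, params in self.factors.items():
            if roi not in ROI_NAMES:
                raise ConfigurationError(f"unknown ROI in effect table: {roi!r}")
            for pname, f in params.items():
                if pname not in SAMPLED_PARAMS:
                    raise ConfigurationError(
                        f"unknown parameter in effect table: {roi}.{pname!r}"
                    )
                if not f > 0:
                    raise ConfigurationError(f"effect factor must be > 0: {roi}.{pname}")

    def factor(self, roi: str, param: str) -> float:
        return self.factors.get(roi, {}).get(param, 1.0)

    @classmethod
    def null(cls) -> "LesionEffectTable":
        return cls({})

    @classmethod
    def default(cls) -> "LesionEffectTable":
        """Shipped lesion effects one week after dorsal-root section.

        PSR and rNOE(-1.6) multipliers encode the reported percent
        decreases (35.4% / 13.1% in DNR / DREZ for PSR; 85.8% / 72.5% for
        rNOE(-1.6)).  The remaining factors are directional only: signs
        follow the described group differences (FA down in DNR and DREZ,
        CEST(3.5) up, rNOE(-3.5) down in DNR), magnitudes are choices of
        this phantom.
        """
        return cls({
            "DNR": {
                "psr": 1.0 - 0.354,
                "A_NOE1.6": 1.0 - 0.858,
                "A_NOE3.5": 0.60,
                "A_CEST3.5": 1.50,
                "lambda1": 0.90,
                "lambda2": 1.30,
                "lambda3": 1.30,
            },
            "DREZ": {
                "psr": 1.0 - 0.131,
                "A_NOE1.6": 1.0 - 0.725,
                "A_CEST3.5": 1.40,
                "lambda2": 1.20,
                "lambda3": 1.20,
            },
        })


_POOL_PARAMS = ("A_CEST3.5", "A_CEST2.0", "A_DS", "A_NOE1.6", "A_NOE3.5", "c_mt")
_ZCHECK_PPM = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.1), 10)


def _pools_physical(draw: dict[str, float], margin: float = 0.005) -> bool:
    """True when the drawn pool table keeps Z(D) >= margin everywhere.

    The DS amplitude sits close to the on-resonance floor (Z(0) ~ 0.04 at
    the class means), so independent draws must be jointly rejected when
    they overshoot it.
    """
    total = np.full_like(_ZCHECK_PPM, draw["c_mt"])
    for name in zspec.POOL_NAMES:
        total += zspec.lorentzian(_ZCHECK_PPM, draw[f"A_{name}"],
                                  POOL_WIDTHS_PPM[name], zspec.POOL_CENTERS_PPM[name])
    return bool(total.max() <= 1.0 - margin)


def _truncated_normal(rng: np.random.Generator, mean: float, cv: float,
                      lo: float, hi: float) -> float:
    if cv == 0:
        return float(np.clip(mean, lo, hi))
    sd = cv * mean
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def sample_cohort_parameters(
    design: CohortDesign,
    class_means: dict[str, dict[str, float]] | None = None,
    between_subject_cv: float = 0.05,
    effects: LesionEffectTable | None = None,
    rng: np.random.Generator | None = None,
    shared_base: bool = True,
) -> dict[tuple[int, int, str], dict[tuple[str, str], dict[str, float]]]:
    """Ground-truth parameter tables keyed (subject, segment, condition).

    Each (subject, segment, side, ROI) gets one base draw from a normal
    distribution centred on the class mean with the given coefficient of
    variation, truncated to the parameter's valid range; pre- and
    post-lesion conditions share that base draw (longitudinal design,
    ``shared_base=True``) or are drawn independently (cross-sectional,
    ``shared_base=False``), and post-lesion lesion-side ROIs are
    multiplied by the effect factors.  Eigenvalues are re-sorted after
    drawing so lambda1 >= lambda2 >= lambda3.
    """
    if not 0 <= between_subject_cv <= 0.2:
        raise ConfigurationError("between_subject_cv must be in [0, 0.2]")
    class_means = class_means if class_means is not None else default_class_means()
    effects = effects if effects is not None else LesionEffectTable.null()
    rng = rng if rng is not None else np.random.default_rng(design.seed)

    def draw_table() -> dict[tuple[str, str], dict[str, float]]:
        table: dict[tuple[str, str], dict[str, float]] = {}
        for name in ROI_NAMES:
            means = class_means[name]
            for side in SIDES:
                draw = {}
                for pname in SAMPLED_PARAMS:
                    lo, hi = _PARAM_RANGES.get(pname, (1e-12, np.inf))
                    draw[pname] = _truncated_normal(
                        rng, means[pname], between_subject_cv, lo, hi)
                # joint physical validity of the Z-spectrum pool block
                for _ in range(200):
                    if _pools_physical(draw):
                        break
                    for pname in _POOL_PARAMS:
                        lo, hi = _PARAM_RANGES.get(pname, (1e-12, np.inf))
                        draw[pname] = _truncated_normal(
                            rng, means[pname], between_subject_cv, lo, hi)
                else:
                    draw.update({p: means[p] for p in _POOL_PARAMS})
                lams = sorted(
                    (draw["lambda1"], draw["lambda2"], draw["lambda3"]),
                    reverse=True)
                draw["lambda1"], draw["lambda2"], draw["lambda3"] = lams
                table[(name, side)] = draw
        return table

    cohort: dict = {}
    for subject in range(1, design.n_subjects + 1):
        for segment in range(1, design.segments_per_subject + 1):
            base = draw_table() if shared_base else None
            for condition in design.conditions:
                src = base if shared_base else draw_table()
                table = {}
                for (name, side), draw in src.items():
                    params = dict(draw)
                    if condition == "post" and side == design.lesion_side:
                        for pname in SAMPLED_PARAMS:
                            params[pname] *= effects.factor(name, pname)
                    table[(name, side)] = params
                cohort[(subject, segment, condition)] = table
    return cohort


# ---------------------------------------------------------------------------
# noise and forward simulation
# ---------------------------------------------------------------------------

def add_rician_noise(signal: np.ndarray, sigma: float,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Rician magnitude noise: v -> sqrt((v + n1)^2 + n2^2), n_i ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


@dataclass(frozen=True)
class NoiseLevels:
    """Per-modality noise SDs expressed as SNR relative to the nominal S0."""

    snr_dwi: float = 40.0
    snr_qmt: float = 50.0
    snr_zspec: float = 60.0

    def sigmas(self, s0: float) -> dict[str, float]:
        def sig(snr):
            if snr <= 0:
                raise ConfigurationError("SNR must be positive (use noiseless=True)")
            return s0 / snr
        return {"dwi": sig(self.snr_dwi), "qmt": sig(self.snr_qmt),
                "zspec": sig(self.snr_zspec)}


def _principal_axis(name: str, side: str) -> np.ndarray:
    if name == "DNR":
        # in-plane oblique, pointing from the root bundle toward the cord
        v = np.array([0.785 if side == "left" else -0.785, -0.620, 0.0])
        return v / np.linalg.norm(v)
    return np.array([0.0, 0.0, 1.0])  # head-foot, through-slice


@dataclass
class Bundle:
    """All simulated data for one (subject, segment, condition)."""

    subject: int
    segment: int
    condition: str
    dwi: ImageStack
    qmt: ImageStack
    zspec: ImageStack
    labels: np.ndarray
    scheme: RoiLabelScheme
    truth: dict[tuple[str, str], dict[str, float]]


def _pool_table_from_params(params: dict[str, float]) -> list[zspec.LorentzianPool]:
    return [zspec.LorentzianPool(name, params[f"A_{name}"], POOL_WIDTHS_PPM[name])
            for name in zspec.POOL_NAMES]


def simulate_cohort(
    design: CohortDesign,
    dwi_protocol: DwiProtocol | None = None,
    qmt_protocol: QmtProtocol | None = None,
    zspec_protocol: ZspecProtocol | None = None,
    noise: NoiseLevels | None = None,
    noiseless: bool = False,
    grid_size: tuple[int, int] = (48, 48),
    class_means: dict | None = None,
    between_subject_cv: float = 0.05,
    effects: LesionEffectTable | None = None,
    scheme: RoiLabelScheme | None = None,
) -> dict[tuple[int, int, str], Bundle]:
    """Simulate the full cohort: one single-slice bundle per key.

    All bundles share geometry (same label map), so stages are pre-aligned.
    Ground truth is retained on each bundle for recovery testing.  The
    design seed fully determines parameter draws and noise.
    """
    dwi_protocol = dwi_protocol or DwiProtocol.default()
    qmt_protocol = qmt_protocol or QmtProtocol()
    zspec_protocol = zspec_protocol or ZspecProtocol()
    noise = noise or NoiseLevels()
    scheme = scheme or RoiLabelScheme.default()
    effects = effects if effects is not None else LesionEffectTable.default()
    class_means = class_means if class_means is not None else default_class_means()

    labels = build_label_map(grid_size, scheme)
    rng = np.random.default_rng(design.seed)
    cohort_params = sample_cohort_parameters(
        design, class_means, between_subject_cv, effects, rng=rng)

    s0_nominal = float(np.mean([class_means[n]["s0"] for n in ROI_NAMES]))
    sigmas = noise.sigmas(s0_nominal) if not noiseless else \
        {"dwi": 0.0, "qmt": 0.0, "zspec": 0.0}

    bundles: dict[tuple[int, int, str], Bundle] = {}
    for key in design.keys():
        truth = cohort_params[key]
        shape2d = labels.shape

        dwi_img = np.zeros(shape2d + (1, dwi_protocol.n_volumes))
        qmt_img = np.zeros(shape2d + (1, qmt_protocol.n_volumes))
        z_img = np.zeros(shape2d + (1, zspec_protocol.n_volumes))

        for code, (name, side) in scheme.labels.items():
            vox = labels == code
            if not vox.any():
                continue
            p = truth[(name, side)]
            tensor = dti.tensor_from_eigensystem(
                (p["lambda1"], p["lambda2"], p["lambda3"]),
                _principal_axis(name, side))
            dwi_sig = dti.predict_dwi_signal(tensor, p["s0"], dwi_protocol)
            qmt_par = qmt.QmtParameters(
                psr=p["psr"], k_ba=p["k_ba"], t2b_us=p["t2b_us"],
                inv_ra_t2a=p["inv_ra_t2a"], scale=1.0)
            qmt_sig = p["s0"] * qmt.ramani_signal(qmt_par, qmt_protocol)
            zsp = zspec.zspectrum_forward(
                _pool_table_from_params(p), p["c_mt"], zspec_protocol)
            z_sig = p["s0"] * np.concatenate([[1.0], zsp, [1.0]])

            dwi_img[vox, 0, :] = dwi_sig
            qmt_img[vox, 0, :] = qmt_sig
            z_img[vox, 0, :] = z_sig

        bundles[key] = Bundle(
            subject=key[0], segment=key[1], condition=key[2],
            dwi=ImageStack(add_rician_noise(dwi_img, sigmas["dwi"], rng=rng)),
            qmt=ImageStack(add_rician_noise(qmt_img, sigmas["qmt"], rng=rng)),
            zspec=ImageStack(add_rician_noise(z_img, sigmas["zspec"], rng=rng)),
            labels=labels, scheme=scheme, truth=truth,
        )
    return bundles


METRIC_NAMES = ("FA", "AD", "RD", "PSR", "CEST3.5", "CEST2.0", "NOE1.6", "NOE3.5")


def true_metrics(params: dict[str, float]) -> dict[str, float]:
    """Map ground-truth tissue parameters to the eight reported metrics."""
    lam = np.array([params["lambda1"], params["lambda2"], params["lambda3"]])
    m = dti.tensor_metrics(lam)
    return {
        "FA": float(m["FA"]), "AD": float(m["AD"]), "RD": float(m["RD"]),
        "PSR": params["psr"],
        "CEST3.5": params["A_CEST3.5"], "CEST2.0": params["A_CEST2.0"],
        "NOE1.6": params["A_NOE1.6"], "NOE3.5": params["A_NOE3.5"],
    }
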