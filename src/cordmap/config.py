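"""Pipeline configuration: schema-validated YAML/JSON with full defaults.

An empty document resolves to the study defaults (acquisition constants,
cohort layout, shipped lesion effects).  Unknown keys are rejected with a
close-match suggestion.
"""

from __future__ import annotations

import difflib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .phantom import LesionEffectTable, NoiseLevels, CohortDesign


class ConfigError(ValueError):
    """Configuration document violates the schema."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortBlock(_Strict):
    n_subjects: int = Field(4, ge=1)
    segments_per_subject: int = Field(2, ge=1)
    lesion_side: str = "left"
    grid_size: tuple[int, int] = (48, 48)
    between_subject_cv: float = Field(0.05, ge=0.0, le=0.2)


class DwiBlock(_Strict):
    b_value: float = Field(1000.0, gt=0)


class QmtBlock(_Strict):
    flip_angles_deg: list[float] = Field(default_factory=lambda: [220.0, 820.0])
    pulse_width_ms: float = Field(10.0, gt=0)
    tr_ms: float = Field(24.0, gt=0)
    excitation_flip_deg: float = Field(7.0, gt=0)
    n_offsets: int = Field(10, ge=4)
    offset_min_hz: float = Field(1e3, gt=0)
    offset_max_hz: float = Field(100e3, gt=0)


class ZspecBlock(_Strict):
    offset_max_ppm: float = Field(5.0, gt=0)
    offset_step_ppm: float = Field(0.2, gt=0)
    sat_duration_s: float = Field(5.0, gt=0)
    sat_amplitude_ut: float = Field(1.0, gt=0)
    hz_per_ppm: float = Field(400.0, gt=0)


class ProtocolsBlock(_Strict):
    dwi: DwiBlock = Field(default_factory=DwiBlock)
    qmt: QmtBlock = Field(default_factory=QmtBlock)
    zspec: ZspecBlock = Field(default_factory=ZspecBlock)


class NoiseBlock(_Strict):
    snr_dwi: float = Field(40.0, gt=0)
    snr_qmt: float = Field(50.0, gt=0)
    snr_zspec: float = Field(60.0, gt=0)
    noiseless: bool = False


class StatsBlock(_Strict):
    pre_matching: str = "matched"
    correlation_method: str = "pearson"
    alpha: float = Field(0.05, gt=0, lt=1)
    benjamini_hochberg: bool = False

    @model_validator(mode="after")
    def _check_choices(self):
        if self.pre_matching not in ("matched", "averaged"):
            raise ValueError("stats.pre_matching must be 'matched' or 'averaged'")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("stats.correlation_method must be 'pearson' or 'spearman'")
        return self


class FitBlock(_Strict):
    qmt_mode: str = "voxel"
    zspec_mode: str = "roi"

    @model_validator(mode="after")
    def _check_choices(self):
        for field in ("qmt_mode", "zspec_mode"):
            if getattr(self, field) not in ("voxel", "roi"):
                raise ValueError(f"fit.{field} must be 'voxel' or 'roi'")
        return self


def _default_effects() -> dict:
    return {roi: dict(p) for roi, p in LesionEffectTable.default().factors.items()}


class PipelineConfig(_Strict):
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    protocols: ProtocolsBlock = Field(default_factory=ProtocolsBlock)
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    lesion_effects: dict[str, dict[str, float]] = Field(default_factory=_default_effects)
    stats: StatsBlock = Field(default_factory=StatsBlock)
    fit: FitBlock = Field(default_factory=FitBlock)
    seed: int = 0

    # ---- factory helpers ----
    def design(self, seed: int | None = None) -> CohortDesign:
        return CohortDesign(
            n_subjects=self.cohort.n_subjects,
            segments_per_subject=self.cohort.segments_per_subject,
            lesion_side=self.cohort.lesion_side,
            seed=self.seed if seed is None else seed,
        )

    def effects(self) -> LesionEffectTable:
        return LesionEffectTable(self.lesion_effects)

    def noise_levels(self) -> NoiseLevels:
        return NoiseLevels(snr_dwi=self.noise.snr_dwi, snr_qmt=self.noise.snr_qmt,
                           snr_zspec=self.noise.snr_zspec)

    def protocols_tuple(self):
        from .protocols import DwiProtocol, QmtProtocol, ZspecProtocol
        import numpy as np
        dwi = DwiProtocol.default(b=self.protocols.dwi.b_value)
        q = self.protocols.qmt
        qmt = QmtProtocol(
            flip_angles_deg=np.asarray(q.flip_angles_deg),
            offsets_hz=np.geomspace(q.offset_min_hz, q.offset_max_hz, q.n_offsets),
            pulse_width_ms=q.pulse_width_ms, tr_ms=q.tr_ms,
            excitation_flip_deg=q.excitation_flip_deg)
        z = self.protocols.zspec
        zsp = ZspecProtocol(
            offsets_ppm=np.round(np.arange(-z.offset_max_ppm,
                                           z.offset_max_ppm + 1e-9,
                                           z.offset_step_ppm), 10),
            sat_duration_s=z.sat_duration_s, sat_amplitude_ut=z.sat_amplitude_ut,
            hz_per_ppm=z.hz_per_ppm)
        return dwi, qmt, zsp


def _all_field_names(model: type[BaseModel]) -> set[str]:
    names = set(model.model_fields)
    for f in model.model_fields.values():
        ann = f.annotation
        if isinstance(ann, type) and issubclass(ann, BaseModel):
            names |= _all_field_names(ann)
    return names


def validate_config(document=None) -> PipelineConfig:
    """Parse and validate a config document (dict, YAML/JSON text, or path).

    ``None`` or an empty document yields the all-defaults configuration.
    Schema violations raise :class:`ConfigError` naming the offending key,
    with a suggestion when it looks like a misspelling.
    """
    if document is None:
        data = {}
    elif isinstance(document, dict):
        data = document
    else:
        doc = Path(document)
        text = doc.read_text() if doc.exists() else str(document)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config document must be a mapping")
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        known = _all_field_names(PipelineConfig)
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            msg = f"{loc}: {err['msg']}"
            if err["type"] == "extra_forbidden":
                bad = str(err["loc"][-1])
                close = difflib.get_close_matches(bad, known, n=1)
                if close:
                    msg += f" (did you mean {close[0]!r}?)"
            msgs.append(msg)
        raise ConfigError("invalid configuration: " + "; ".join(msgs)) from exc


def resolved_config_json(config: PipelineConfig, seed: int | None = None) -> str:
    """Provenance record: resolved config + seed + package version."""
    from . import __version__
    payload = {"config": config.model_dump(), "seed": config.seed if seed is None
               else seed, "version": __version__}
    return json.dumps(payload, indent=2, default=list)
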