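"""Pipeline configuration.

Every clinically meaningful threshold in the pipeline lives here as data —
DLCN point values and band cut-offs, rarity/conservation filter thresholds,
ACMG frequency cut-offs, MLPA dosage-quotient thresholds — so that each can
be overridden from a YAML file without touching code.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .models import ClinvarAssertion, DlcnBand


class GroupAggregation(str, enum.Enum):
    max = "max"  # standard DLCN reading: best criterion per group scores
    sum = "sum"  # sensitivity-analysis mode


class LdlBandPoints(BaseModel):
    """LDL-C (mmol/L) lower bound -> points; bands evaluated highest first."""

    min_ldl: float
    points: int = Field(ge=0)


class DlcnPoints(BaseModel):
    family: dict[str, int] = Field(
        default_factory=lambda: {
            "premature_cvd": 1,
            "ldl_above_p95": 1,
            "xanthoma_or_arcus": 2,
            "child_ldl_above_p95": 2,
        }
    )
    clinical: dict[str, int] = Field(
        default_factory=lambda: {
            "premature_cad": 2,
            "premature_cerebral_or_peripheral": 1,
        }
    )
    physical: dict[str, int] = Field(
        default_factory=lambda: {
            "tendon_xanthomata": 6,
            "arcus_cornealis_before_45": 4,
        }
    )
    ldl_bands: list[LdlBandPoints] = Field(
        default_factory=lambda: [
            LdlBandPoints(min_ldl=8.5, points=8),
            LdlBandPoints(min_ldl=6.5, points=5),
            LdlBandPoints(min_ldl=5.0, points=3),
            LdlBandPoints(min_ldl=4.0, points=1),
        ]
    )
    dna_functional_mutation: int = 8


class DlcnBands(BaseModel):
    """Inclusive integer score ranges per band; ``definite`` is open above.

    The three named bands must tile the score axis from ``possible[0]``
    upward with no gap or overlap; everything below is "unlikely".
    """

    possible: tuple[int, int] = (3, 5)
    probable: tuple[int, int] = (6, 8)
    definite_min: int = 9

    @model_validator(mode="after")
    def _contiguous(self) -> "DlcnBands":
        lo_p, hi_p = self.possible
        lo_pr, hi_pr = self.probable
        if not (lo_p <= hi_p and lo_pr <= hi_pr):
            raise ValueError("band ranges must be non-empty")
        if lo_pr != hi_p + 1:
            raise ValueError(
                f"bands must tile the score axis: possible ends at {hi_p}, "
                f"probable starts at {lo_pr}"
            )
        if self.definite_min != hi_pr + 1:
            raise ValueError(
                f"bands must tile the score axis: probable ends at {hi_pr}, "
                f"definite starts at {self.definite_min}"
            )
        return self

    def classify(self, total: int) -> DlcnBand:
        if total >= self.definite_min:
            return DlcnBand.definite
        if total >= self.probable[0]:
            return DlcnBand.probable
        if total >= self.possible[0]:
            return DlcnBand.possible
        return DlcnBand.unlikely


class PercentileCell(BaseModel):
    sex: str  # "F" or "M"
    age_min: int
    age_max: int
    p95_ldl: float  # mmol/L


class FilterConfig(BaseModel):
    rare_af_threshold: float = Field(default=0.005, ge=0, le=1)
    conservation_percentile_threshold: float = Field(default=0.7, ge=0, le=1)
    predictor_damaging_fraction: float = Field(default=0.5, ge=0, le=1)
    excluded_assertions: set[ClinvarAssertion] = Field(
        default_factory=lambda: {
            ClinvarAssertion.benign,
            ClinvarAssertion.likely_benign,
        }
    )


class AcmgConfig(BaseModel):
    ba1_af_threshold: float = Field(default=0.05, ge=0, le=1)
    pm2_af_threshold: float = Field(default=0.0001, ge=0, le=1)


class MlpaConfig(BaseModel):
    deletion_threshold: float = Field(default=0.7, gt=0)
    duplication_threshold: float = Field(default=1.3, gt=0)
    homozygous_deletion_threshold: float = Field(default=0.25, gt=0)
    transcript: str = "NM_000527.4"

    @model_validator(mode="after")
    def _ordered(self) -> "MlpaConfig":
        if not (
            self.homozygous_deletion_threshold
            < self.deletion_threshold
            < self.duplication_threshold
        ):
            raise ValueError("dosage thresholds must be ordered hom-del < del < dup")
        return self


class Config(BaseModel):
    dlcn_points: DlcnPoints = Field(default_factory=DlcnPoints)
    dlcn_bands: DlcnBands = Field(default_factory=DlcnBands)
    dlcn_group_aggregation: GroupAggregation = GroupAggregation.max
    friedewald_max_tg: float = 4.5  # mmol/L; formula invalid above
    friedewald_direct_ldl_threshold: float = 4.5  # mmol/L; flag for direct assay
    percentile_table: list[PercentileCell] = Field(default_factory=list)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    acmg: AcmgConfig = Field(default_factory=AcmgConfig)
    mlpa: MlpaConfig = Field(default_factory=MlpaConfig)
    seed: int = 0


def _data_path(name: str) -> Path:
    return Path(str(resources.files("fhdx").joinpath("data", name)))


def default_config() -> Config:
    """Packaged defaults, including the synthetic (non-clinical) age/sex
    95th-percentile LDL-C table."""
    return load_config(_data_path("default_config.yaml"))


def load_config(path: Union[str, Path]) -> Config:
    """Read a YAML config; absent keys fall back to packaged defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    if "dlcn_bands" in raw and isinstance(raw["dlcn_bands"], dict):
        raw["dlcn_bands"] = _normalise_bands(raw["dlcn_bands"])
    return Config.model_validate(raw)


def _normalise_bands(bands: dict) -> dict:
    """Accept either the internal shape or the range shape
    ``{possible: [3, 5], probable: [6, 8], definite: [9, null]}``."""
    if "definite" in bands:
        out = dict(bands)
        definite = out.pop("definite")
        if isinstance(definite, (list, tuple)):
            out["definite_min"] = definite[0]
        else:
            out["definite_min"] = definite
        return out
    return bands
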