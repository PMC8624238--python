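"""Dutch Lipid Clinic Network (DLCN) scoring.

The DLCN score is the sum over five criterion groups — family history,
personal clinical history, physical examination, LDL-C level, DNA test —
of a per-group subscore.  Within a group the standard reading takes the
MAXIMUM of the points of the satisfied criteria (a patient with both
tendon xanthomata and premature arcus scores 6, not 10); a configuration
flag switches to summation for sensitivity analysis.  The total is banded
into unlikely (<3), possible (3-5), probable (6-8) and definite (>8) FH.

LDL-C may be estimated from total cholesterol, HDL-C and triglycerides by
the Friedewald relation (mmol/L form, divisor 2.2); above 4.5 mmol/L a
direct assay is indicated, which is reported here as a flag on the
estimate rather than a rejection.
"""

from __future__ import annotations

from typing import Optional

from .config import Config, DlcnBands, GroupAggregation, PercentileCell
from .models import DlcnBand, DlcnCriteriaInput, DlcnResult, DnaMutation, Sex


class FriedewaldError(ValueError):
    pass


def compute_friedewald_ldl(
    tc: float, hdl: float, tg: float, config: Optional[Config] = None
) -> tuple[float, bool]:
    """LDL-C = TC - HDL-C - TG/2.2 (all mmol/L).

    Returns the estimate and a flag indicating that a direct measurement
    is required (estimate above the configured threshold, default 4.5).
    Raises for non-physiological results and for triglycerides above the
    formula's validity bound (default 4.5 mmol/L ~ 400 mg/dL).
    """
    if min(tc, hdl, tg) <= 0:
        raise FriedewaldError("tc, hdl and tg must all be positive")
    cfg = config or Config()
    if tg > cfg.friedewald_max_tg:
        raise FriedewaldError(
            f"Friedewald invalid at high TG ({tg} > {cfg.friedewald_max_tg} mmol/L)"
        )
    ldl = tc - hdl - tg / 2.2
    if ldl <= 0:
        raise FriedewaldError(
            f"non-physiological Friedewald result (ldl = {ldl:.3f} mmol/L)"
        )
    return ldl, ldl > cfg.friedewald_direct_ldl_threshold


class PercentileTableError(ValueError):
    pass


def exceeds_95th_percentile(
    sex: Sex, age: int, ldl: float, table: list[PercentileCell]
) -> bool:
    """True iff ``ldl`` strictly exceeds the age/sex-specific 95th
    percentile ("exceed" is read strictly; a tie does not qualify)."""
    for cell in table:
        if cell.sex == sex.value and cell.age_min <= age <= cell.age_max:
            return ldl > cell.p95_ldl
    raise PercentileTableError(
        f"percentile table has no cell for sex={sex.value}, age={age}"
    )


def _ldl_points(ldl: Optional[float], config: Config) -> int:
    if ldl is None:
        return 0
    for band in sorted(config.dlcn_points.ldl_bands, key=lambda b: -b.min_ldl):
        if ldl >= band.min_ldl:
            return band.points
    return 0


def score_dlcn(criteria: DlcnCriteriaInput, config: Optional[Config] = None) -> DlcnResult:
    cfg = config or Config()
    pts = cfg.dlcn_points

    family = {
        pts.family["premature_cvd"]: criteria.family_premature_cvd,
        pts.family["ldl_above_p95"]: criteria.family_ldl_above_p95,
        pts.family["xanthoma_or_arcus"]: criteria.family_xanthoma_or_arcus,
        pts.family["child_ldl_above_p95"]: criteria.family_child_ldl_above_p95,
    }
    clinical = {
        pts.clinical["premature_cad"]: criteria.personal_premature_cad,
        pts.clinical["premature_cerebral_or_peripheral"]:
            criteria.personal_premature_cerebral_or_peripheral,
    }
    physical = {
        pts.physical["tendon_xanthomata"]: criteria.tendon_xanthomata,
        pts.physical["arcus_cornealis_before_45"]: criteria.arcus_cornealis_before_45,
    }

    def group_score(points_to_flag: dict[int, bool]) -> int:
        hit = [p for p, flag in points_to_flag.items() if flag]
        if not hit:
            return 0
        return sum(hit) if cfg.dlcn_group_aggregation == GroupAggregation.sum else max(hit)

    subscores = {
        "family": group_score(family),
        "clinical": group_score(clinical),
        "physical": group_score(physical),
        "ldl": _ldl_points(criteria.ldl_mmol_per_l, cfg),
        "dna": pts.dna_functional_mutation
        if criteria.dna_functional_mutation == DnaMutation.yes
        else 0,
    }
    total = sum(subscores.values())
    return DlcnResult(
        group_subscores=subscores, total=total, band=classify_band(total, cfg.dlcn_bands)
    )


def classify_band(total: int, bands: Optional[DlcnBands] = None) -> DlcnBand:
    """Map a total score to its diagnostic band (>8 definite, 6-8 probable,
    3-5 possible, <3 unlikely with the default cut-offs)."""
    if total < 0:
        raise ValueError("DLCN total cannot be negative")
    return (bands or DlcnBands()).classify(total)
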