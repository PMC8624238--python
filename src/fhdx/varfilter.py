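"""Rare-variant annotation filtering.

A three-step cascade over annotated variant records:

1. rarity — drop any record whose highest allele frequency across the
   configured population databases reaches the "rare" threshold (default
   0.005); a variant absent from every database counts as frequency 0
   (a novel variant passes);
2. clinical assertion — drop records asserted benign or likely benign;
3. in-silico tagging — annotate survivors with a predictor-consensus
   verdict.  Predictors act as a supplementary signal only: a record is
   never removed on predictor evidence alone.

Conservation is handled as a percentile rule: a variant counts as
conserved when its conservation score beats at least the configured
fraction (default 0.7) of a reference score distribution, ties counted
half (midrank).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import FilterConfig
from .models import AnnotationRecord, ClinvarAssertion, PredictorCall


class Consensus(str, enum.Enum):
    damaging = "damaging"
    benign_leaning = "benign_leaning"
    indeterminate = "indeterminate"


STEP_RARITY = "rarity"
STEP_ASSERTION = "assertion"
RETAINED = "retained"


@dataclass
class FilterReport:
    input_count: int
    step_counts: list[tuple[str, int]]  # (step name, surviving count after step)
    surviving: list[AnnotationRecord]
    audit: dict[tuple[str, int, str, str], str] = field(default_factory=dict)
    consensus: dict[tuple[str, int, str, str], Consensus] = field(default_factory=dict)


def conservation_percentile(score: float, reference_scores: Sequence[float]) -> float:
    """Midrank percentile of ``score`` in ``reference_scores``: the fraction
    of reference scores strictly below it, ties contributing one half."""
    if len(reference_scores) == 0:
        raise ValueError("reference score set must be non-empty")
    less = sum(1 for r in reference_scores if r < score)
    equal = sum(1 for r in reference_scores if r == score)
    return (less + 0.5 * equal) / len(reference_scores)


def _is_conserved(
    record: AnnotationRecord,
    config: FilterConfig,
    reference_scores: Optional[dict[str, Sequence[float]]] = None,
) -> bool:
    """At least one conservation tool above the percentile threshold.
    Scores are taken as percentile fractions directly unless a per-tool
    reference distribution is supplied."""
    for tool, score in record.conservation_scores.items():
        if reference_scores is not None and tool in reference_scores:
            pct = conservation_percentile(score, reference_scores[tool])
        else:
            pct = score
        if pct > config.conservation_percentile_threshold:
            return True
    return False


def predictor_consensus(
    record: AnnotationRecord,
    config: Optional[FilterConfig] = None,
    reference_scores: Optional[dict[str, Sequence[float]]] = None,
) -> Consensus:
    cfg = config or FilterConfig()
    calls = [c for c in record.predictor_calls.values() if c != PredictorCall.unknown]
    if not calls:
        return Consensus.indeterminate
    frac = sum(1 for c in calls if c == PredictorCall.damaging) / len(calls)
    if frac >= cfg.predictor_damaging_fraction and _is_conserved(
        record, cfg, reference_scores
    ):
        return Consensus.damaging
    if frac <= 1 - cfg.predictor_damaging_fraction:
        return Consensus.benign_leaning
    return Consensus.indeterminate


def apply_filter_cascade(
    records: Sequence[AnnotationRecord],
    config: Optional[FilterConfig] = None,
    reference_scores: Optional[dict[str, Sequence[float]]] = None,
) -> FilterReport:
    cfg = config or FilterConfig()
    audit: dict[tuple[str, int, str, str], str] = {}

    after_rarity = []
    for rec in records:
        max_af = rec.max_af or 0.0
        if max_af >= cfg.rare_af_threshold:
            audit[rec.allele_key()] = STEP_RARITY
        else:
            after_rarity.append(rec)

    after_assertion = []
    for rec in after_rarity:
        if rec.clinvar_assertion in cfg.excluded_assertions:
            audit[rec.allele_key()] = STEP_ASSERTION
        else:
            after_assertion.append(rec)

    consensus = {}
    for rec in after_assertion:
        consensus[rec.allele_key()] = predictor_consensus(rec, cfg, reference_scores)
        audit[rec.allele_key()] = RETAINED

    return FilterReport(
        input_count=len(records),
        step_counts=[
            (STEP_RARITY, len(after_rarity)),
            (STEP_ASSERTION, len(after_assertion)),
        ],
        surviving=after_assertion,
        audit=audit,
        consensus=consensus,
    )


def prioritize_candidates(
    report: FilterReport, known_table: Sequence[AnnotationRecord]
) -> list[AnnotationRecord]:
    """Order survivors for review.

    Tier 1: asserted pathogenic / likely pathogenic in ClinVar.
    Tier 2: a pathogenic entry is known at the same genomic position
            (same or different alternate allele).
    Tier 3: novel with a damaging predictor consensus.
    Tier 4: everything else.  Stable within tier by (chrom, pos).
    """
    known_pathogenic_sites = {
        rec.site_key()
        for rec in known_table
        if rec.clinvar_assertion
        in (ClinvarAssertion.pathogenic, ClinvarAssertion.likely_pathogenic)
    }

    def tier(rec: AnnotationRecord) -> int:
        if rec.clinvar_assertion in (
            ClinvarAssertion.pathogenic,
            ClinvarAssertion.likely_pathogenic,
        ):
            return 1
        if rec.site_key() in known_pathogenic_sites:
            return 2
        if report.consensus.get(rec.allele_key()) == Consensus.damaging:
            return 3
        return 4

    def chrom_sort_key(chrom: str):
        return (0, int(chrom)) if chrom.isdigit() else (1, chrom)

    return sorted(
        report.surviving, key=lambda r: (tier(r), chrom_sort_key(r.chrom), r.pos)
    )
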