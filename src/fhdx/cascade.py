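"""Cascade screening and cohort detection-yield summaries.

Cascade genetic screening tests the first-degree relatives of each newly
identified mutation carrier, wave by wave: wave 1 holds the untested
first-degree relatives of the proband; whenever a tested individual comes
back positive, their own untested first-degree relatives join the next
wave.  The cohort summary aggregates detection yields the way clinical
FH studies report them — per-gene percentages among variant-positive
probands, yield among probands' children, and yields within each DLCN
diagnostic band — with percentages rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np

from .models import (
    DlcnBand,
    GeneticResult,
    GeneticStatus,
    Pedigree,
    Relation,
    Role,
    Subject,
)

MAJOR_GENES = ("LDLR", "APOB")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), matching how
    clinical percentages are conventionally printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> Optional[float]:
    """100*num/den rounded half-up to 1 decimal; None when undefined."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, 1)


@dataclass
class GeneYield:
    count: int
    percent: Optional[float]


@dataclass
class BandBreakdown:
    n: int
    n_positive: int
    by_gene: dict[str, GeneYield]
    n_negative: int
    negative_percent: Optional[float]


@dataclass
class CohortSummary:
    n_subjects: int
    n_probands: int
    n_variant_positive_subjects: int
    subject_level_percent: Optional[float]
    n_variant_positive_probands: int
    per_gene_probands: dict[str, GeneYield]       # every gene observed
    gene_split_probands: dict[str, GeneYield]     # LDLR / APOB / other
    children_n: int
    children_positive: int
    children_percent: Optional[float]
    undefined_denominators: list[str] = field(default_factory=list)


def _is_positive(subject: Subject) -> bool:
    g = subject.genetic_result
    return g is not None and g.status == GeneticStatus.positive


def summarize_cohort(subjects: Sequence[Subject]) -> CohortSummary:
    n = len(subjects)
    probands = [s for s in subjects if s.role == Role.proband]
    positives = [s for s in subjects if _is_positive(s)]
    positive_probands = [s for s in probands if _is_positive(s)]
    children = [s for s in subjects if s.relation_to_proband == Relation.child]
    positive_children = [c for c in children if _is_positive(c)]

    per_gene: dict[str, int] = {}
    for s in positive_probands:
        per_gene[s.genetic_result.gene] = per_gene.get(s.genetic_result.gene, 0) + 1

    npp = len(positive_probands)
    per_gene_yield = {g: GeneYield(c, percent(c, npp)) for g, c in sorted(per_gene.items())}

    split_counts = {g: per_gene.get(g, 0) for g in MAJOR_GENES}
    split_counts["other"] = npp - sum(split_counts.values())
    gene_split = {g: GeneYield(c, percent(c, npp)) for g, c in split_counts.items()}

    undefined = []
    if n == 0:
        undefined.append("subjects")
    if npp == 0:
        undefined.append("variant_positive_probands")
    if not children:
        undefined.append("children")

    return CohortSummary(
        n_subjects=n,
        n_probands=len(probands),
        n_variant_positive_subjects=len(positives),
        subject_level_percent=percent(len(positives), n),
        n_variant_positive_probands=npp,
        per_gene_probands=per_gene_yield,
        gene_split_probands=gene_split,
        children_n=len(children),
        children_positive=len(positive_children),
        children_percent=percent(len(positive_children), len(children)),
        undefined_denominators=undefined,
    )


def crosstab_dlcn_by_result(
    subjects_with_bands: Sequence[tuple[Subject, Optional[DlcnBand]]],
) -> tuple[dict[DlcnBand, BandBreakdown], int]:
    """Band x genetic-outcome cross-tabulation.

    Returns the per-band breakdown (counts and within-band percentages
    per gene, plus the variant-negative remainder) and the number of
    subjects excluded for lacking a band.
    """
    excluded = sum(1 for _, band in subjects_with_bands if band is None)
    table: dict[DlcnBand, BandBreakdown] = {}
    for band in DlcnBand:
        members = [s for s, b in subjects_with_bands if b == band]
        if not members:
            continue
        n = len(members)
        pos = [s for s in members if _is_positive(s)]
        genes: dict[str, int] = {}
        for s in pos:
            genes[s.genetic_result.gene] = genes.get(s.genetic_result.gene, 0) + 1
        n_neg = n - len(pos)
        table[band] = BandBreakdown(
            n=n,
            n_positive=len(pos),
            by_gene={g: GeneYield(c, percent(c, n)) for g, c in sorted(genes.items())},
            n_negative=n_neg,
            negative_percent=percent(n_neg, n),
        )
    return table, excluded


@dataclass
class CascadePlan:
    proband_id: str
    variant_ids: list[str]
    waves: list[list[str]]


def propose_cascade(
    pedigree: Pedigree,
    proband_id: str,
    results: Optional[Mapping[str, GeneticResult]] = None,
) -> CascadePlan:
    """Wave-structured testing plan.

    Wave 1: untested first-degree relatives of the proband.  Each known
    positive individual contributes their untested first-degree relatives
    to the wave after the one in which they were reached (the proband is
    wave 0).  Waves are disjoint and exclude the proband.
    """
    if proband_id not in pedigree.members_by_id:
        raise ValueError(f"proband {proband_id!r} not in pedigree {pedigree.family_id!r}")
    res = dict(results or {})
    proband_result = res.get(proband_id)
    variant_ids = list(proband_result.variant_ids) if proband_result else []

    def is_positive(iid: str) -> bool:
        r = res.get(iid)
        return r is not None and r.status == GeneticStatus.positive

    tested = {iid for iid, r in res.items() if r.status != GeneticStatus.untested}
    proposed: set[str] = set()
    waves: list[list[str]] = []
    frontier = [proband_id]  # positive individuals reached at the previous wave
    visited_positives = {proband_id}
    while frontier:
        wave: list[str] = []
        next_frontier: list[str] = []
        for pid in frontier:
            for rel in pedigree.first_degree_relatives(pid):
                if rel == proband_id or rel in proposed:
                    continue
                if rel not in tested:
                    wave.append(rel)
                    proposed.add(rel)
                elif is_positive(rel) and rel not in visited_positives:
                    next_frontier.append(rel)
                    visited_positives.add(rel)
        if wave:
            waves.append(wave)
        frontier = next_frontier
    return CascadePlan(proband_id=proband_id, variant_ids=variant_ids, waves=waves)


def simulate_transmission(
    pedigree: Pedigree,
    founder_carriers: Mapping[str, bool],
    seed: int,
) -> dict[str, bool]:
    """Autosomal-dominant transmission of a single heterozygous variant.

    Founders carry per ``founder_carriers`` (absent founders are
    non-carriers).  Every carrier parent transmits the allele to each
    child independently with probability 1/2; a child is a carrier when
    it receives the allele from at least one parent (so one het parent
    gives 1/2, two het parents 3/4).  Deterministic for a fixed seed.
    """
    founders = set(pedigree.founders())
    for iid in founder_carriers:
        if iid not in pedigree.members_by_id:
            raise ValueError(f"unknown individual {iid!r} in founder carrier map")
        if iid not in founders:
            raise ValueError(f"{iid!r} is not a founder; only founder status may be set")

    rng = np.random.default_rng(seed)
    status: dict[str, bool] = {f: bool(founder_carriers.get(f, False)) for f in founders}
    pending = [m for m in pedigree.individuals if m.individual_id not in status]
    # parents precede children in the dependency order; iterate until settled
    while pending:
        progressed = False
        remaining = []
        for m in pending:
            parents = pedigree.parents_of(m.individual_id)
            if all(p in status for p in parents):
                transmitted = any(
                    status[p] and rng.random() < 0.5 for p in parents
                )
                status[m.individual_id] = transmitted
                progressed = True
            else:
                remaining.append(m)
        if not progressed:  # unreachable given pedigree acyclicity
            raise RuntimeError("could not order pedigree for simulation")
        pending = remaining
    return status
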