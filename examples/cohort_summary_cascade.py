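"""Summarize detection yields for the reference cohort and plan cascade
screening for one family.

The deterministic reference cohort has 80 subjects (60 probands, 20
first-degree relatives).  The summary reports how many carry a clinically
significant variant, split by gene and by DLCN diagnostic band; the
cascade planner lists which relatives to test next.
"""

from fhdx import (
    build_paper_fixture,
    crosstab_dlcn_by_result,
    propose_cascade,
    score_dlcn,
    summarize_cohort,
)
from fhdx.config import default_config

subjects, pedigrees, _ = build_paper_fixture()
summary = summarize_cohort(subjects)
print(f"subjects: {summary.n_subjects}, variant-positive: "
      f"{summary.n_variant_positive_subjects} ({summary.subject_level_percent}%)")
for gene, y in summary.gene_split_probands.items():
    print(f"  {gene:<6} {y.count:>2} positive probands ({y.percent}%)")
print(f"children of probands: {summary.children_positive}/{summary.children_n} "
      f"positive ({summary.children_percent}%)")

cfg = default_config()
table, _ = crosstab_dlcn_by_result(
    [(s, score_dlcn(s.dlcn_input, cfg).band) for s in subjects]
)
for band, b in table.items():
    print(f"band {band.value:<9} n={b.n:>2}: {b.n_positive} positive, "
          f"{b.n_negative} negative ({b.negative_percent}%)")
# Yield is concentrated in the 'definite' band — the rationale for
# sequencing every phenotypic FH patient but expecting most confirmations
# among high scorers.

ped = next(p for p in pedigrees if len(p.individuals) > 2)
proband = ped.individuals[0].individual_id
plan = propose_cascade(ped, proband)
print(f"\ncascade plan for {proband} (family {ped.family_id}): waves={plan.waves}")
# Wave 1 lists untested first-degree relatives; later waves would follow
# each new positive result.
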