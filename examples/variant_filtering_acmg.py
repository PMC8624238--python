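"""Filter an annotated variant table and classify survivors with ACMG rules.

Generates an annotation table containing the packaged rare FH variant
panel plus common polymorphisms and benign decoys, runs the rarity /
assertion / predictor cascade, ranks the survivors, then auto-assigns
computable ACMG codes and classifies each.
"""

from fhdx import (
    EvidenceSet,
    apply_filter_cascade,
    auto_evidence,
    classify_acmg,
    gen_annotation_table,
    load_variant_panel,
    prioritize_candidates,
)

records = gen_annotation_table(seed=0)
report = apply_filter_cascade(records)
print(f"input records: {report.input_count}")
for step, surviving in report.step_counts:
    print(f"  after {step:<9} step: {surviving} remain")
# The 20 rare panel variants survive; all common (AF >= 0.5%) and
# benign/likely-benign records are dropped.

known = load_variant_panel()
ranked = prioritize_candidates(report, known)
print("\ntop candidates (ClinVar-asserted first, then known sites, then novel):")
for rec in ranked[:5]:
    ev = auto_evidence(rec, known)
    cls = classify_acmg(EvidenceSet.from_codes(ev.codes))
    print(f"  {rec.variant_id:<12} {rec.gene:<7} {rec.hgvs_c:<12} "
          f"codes={sorted(ev.codes)} -> {cls.classification.value}")
# Auto-assignment covers only the mechanical codes (PM2, PP3, PS1/PM5,
# BA1, PVS1); a full classification adds manually curated evidence.
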