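# fhdx — molecular diagnosis of familial hypercholesterolemia

`fhdx` is a Python toolkit for the analysis side of familial
hypercholesterolemia (FH) molecular diagnostics. FH is an autosomal-dominant
disorder of LDL clearance: carriers of a pathogenic variant in *LDLR*,
*APOB* or related lipid-metabolism genes have lifelong elevated LDL
cholesterol and a sharply increased risk of premature coronary disease.
A diagnostic workflow combines a clinical score, targeted sequencing of a
lipid-gene panel, dosage analysis for larger deletions, and cascade testing
of relatives. `fhdx` implements each analysis stage as a library module
with a thin CLI, aimed at methodologists and lab bioinformaticians who want
a transparent, testable reimplementation of this pipeline:

* **DLCN scoring** (`fhdx.dlcn`) — the Dutch Lipid Clinic Network score:
  per-group subscores (family history, clinical history, physical exam,
  LDL-C, DNA), `total = Σ_g max_{c∈g} points(c)`, banded as unlikely (<3),
  possible (3–5), probable (6–8), definite (>8). Includes the Friedewald
  estimate LDL-C = TC − HDL-C − TG/2.2 (mmol/L).
* **Rare-variant filtering** (`fhdx.varfilter`) — a rarity step
  (popmax-style allele frequency < 0.005 by default), exclusion of
  benign/likely-benign assertions, and in-silico predictor/conservation
  tagging that never removes a record on its own; with per-record audit
  trail and candidate prioritization.
* **ACMG/AMP classification** (`fhdx.acmg`) — the 2015 evidence-combining
  rules as a data table over evidence counts (PVS/PS/PM/PP vs BA/BS/BP),
  plus auto-assignment of the mechanically computable codes (BA1, PM2,
  PP3/BP4, PS1/PM5, PVS1).
* **MLPA dosage calling** (`fhdx.mlpa`) — reference-probe and
  control-sample normalization to dosage quotients (DQ ≈ 1 for two copies,
  ≈ 0.5 for a heterozygous deletion), per-exon event calling with
  contiguous-event merging, and HGVS naming of whole-exon deletions.
* **Cascade screening & summaries** (`fhdx.cascade`) — wave-structured
  testing plans over pedigrees, Mendelian transmission simulation, and
  cohort detection-yield summaries (per-gene splits, children's yield,
  DLCN-band cross-tabulations).
* **Synthetic data** (`fhdx.synth`) — a calibrated random-cohort generator,
  an annotation-table generator with embedded rare-variant panel and
  filter decoys, an MLPA run simulator, and a deterministic 80-subject
  reference cohort used throughout the tests.

## Worked example

```python
from fhdx import DlcnCriteriaInput, score_dlcn
from fhdx.models import DnaMutation

result = score_dlcn(DlcnCriteriaInput(
    tendon_xanthomata=True, personal_premature_cad=True,
    ldl_mmol_per_l=7.0, dna_functional_mutation=DnaMutation.yes,
))
print(result.group_subscores, result.total, result.band.value)
```

prints

```
{'family': 0, 'clinical': 2, 'physical': 6, 'ldl': 5, 'dna': 8} 21 definite
```

— xanthomata score 6, premature coronary disease 2, an LDL-C of 7.0 mmol/L
falls in the 6.5–8.4 band (5 points), and the confirmed mutation adds 8;
a total of 21 is far above the definite threshold (>8).

Running the cohort pipeline end to end on the packaged reference cohort:

```bash
fhdx fixture --out cohort/
fhdx summarize --subjects cohort/subjects.tsv --out summary.json
```

`summary.json` reports a 47.5% subject-level detection yield (38/80), a
73.1 / 11.5 / 15.4% split of positive probands across *LDLR* / *APOB* /
other lipid genes, 85.7% yield among probands' children, and DLCN bands
of 34 definite / 5 probable / 41 possible subjects with 76.5% *LDLR* and
8.8% *APOB* positives in the definite band. See `examples/` for scripts
covering each capability (DLCN scoring, filtering + ACMG, MLPA calling,
summaries and cascade planning).

The other subcommands mirror the library modules: `fhdx validate`,
`fhdx score-dlcn`, `fhdx filter-variants`, `fhdx classify-acmg`,
`fhdx mlpa-call`, `fhdx cascade`, `fhdx simulate`.

## Data notes

Packaged data live in `src/fhdx/data/`: the rare FH variant panel
(20 records across *LDLR*, *APOB*, *ABCG5*, *APOC3*, *LPL*, *SREBF1*,
with gnomAD frequencies and ClinVar assertions), a partial LDLR
(NM_000527.4) exon-boundary table, the ACMG combining-rule table, and the
default configuration. The 95th-percentile LDL-C table in the default
config is synthetic and non-clinical; replace it with population reference
data for any real use. This package is a research tool, not a medical
device.
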