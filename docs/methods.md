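# Methods

This note records the models and procedures `fhdx` implements, the
defaults that matter, what the synthetic data emulate, and the design
choices made where more than one reasonable option existed.

## DLCN scoring

The Dutch Lipid Clinic Network score sums five group subscores: family
history (premature cardiovascular disease in a first-degree relative, 1;
relative with LDL-C above the age/sex 95th percentile, 1; relative with
tendon xanthomata and/or arcus cornealis, 2; child under 18 with LDL-C
above the 95th percentile, 2), clinical history (premature coronary
disease, 2; premature cerebral or peripheral vascular disease, 1),
physical examination (tendon xanthomata, 6; arcus cornealis before age
45, 4), LDL-C level (≥8.5 mmol/L, 8; 6.5–8.4, 5; 5.0–6.4, 3; 4.0–4.9, 1)
and DNA evidence (functional mutation, 8). Within a group the subscore is
the **maximum** over satisfied criteria — the standard reading, under
which two physical signs still score 6, not 10; a configuration flag
(`dlcn_group_aggregation: sum`) enables summation for sensitivity
analysis. Bands: unlikely <3, possible 3–5, probable 6–8, definite >8.
Band cut-offs are validated to tile the score axis without gaps or
overlap. An untested DNA criterion scores 0, so pre-genetic and
post-genetic scores are both computable from the same structure.

Friedewald estimation uses the mmol/L form, LDL-C = TC − HDL-C − TG/2.2,
refused above TG 4.5 mmol/L (the formula's validity bound) or when the
result is non-positive. Estimates above 4.5 mmol/L are flagged as
requiring a direct assay rather than rejected — software cannot perform
the measurement, only indicate it. The 95th-percentile comparison is
strict (a tie does not count as "exceeding" the percentile). The packaged
percentile table is synthetic (plausible mmol/L values) because no
population reference table is distributed with the package; it is
config-replaceable and marked non-clinical.

## Rare-variant filter cascade

Records are annotated alternate alleles (one per record; multi-allelic
sites must be split upstream), GRCh38, 1-based. Three ordered steps:

1. **Rarity.** A record is dropped when its *maximum* allele frequency
   across the configured population sources reaches the threshold
   (default 0.005). The maximum (popmax-like) is conservative against
   population-specific common alleles. A variant observed in no source
   counts as frequency 0 and passes — required so that genuinely novel
   variants survive.
2. **Clinical assertion.** Records asserted benign or likely benign are
   dropped (set config-overridable).
3. **In-silico tagging.** Survivors are tagged with a predictor
   consensus: *damaging* when the damaging fraction of reporting
   predictors is ≥ 0.5 **and** at least one conservation measure beats
   the 0.7 percentile threshold; *benign-leaning* when the damaging
   fraction is ≤ 0.5; otherwise *indeterminate* (also when no predictor
   reports). Predictors are a supplementary signal and never remove a
   record by themselves.

Conservation uses a midrank percentile: the fraction of a reference score
distribution strictly below the variant's score, ties counted half.
Scores already expressed as percentile fractions (e.g. phastCons) can be
used directly; raw scores (e.g. GERP) are ranked against an explicit
reference distribution supplied by the caller — the package does not fix
which reference set ("other variants") is appropriate, since that choice
is dataset-specific.

Every record's fate (step of removal, or retained + consensus) is kept in
an audit map, so the report partitions its input exactly. Candidate
prioritization orders survivors: (1) ClinVar pathogenic/likely
pathogenic, (2) records at a genomic position where a pathogenic allele
is already described — including a *different* substitution at that
position, which is how a novel change at a known site outranks a
first-ever variant, (3) novel with damaging consensus, (4) remainder;
stable within tier by position.

## ACMG/AMP classification

The 2015 combining rules are shipped as a YAML data table of minimum
category counts (e.g. pathogenic ⊇ {1 PVS + 1 PS}, {2 PS}, …; likely
pathogenic ⊇ {1 PS + 1 PM}, {3 PM}, …; benign ⊇ {BA1}, {2 BS}; likely
benign ⊇ {1 BS + 1 BP}, {2 BP}). Classes are evaluated strongest first
within each side, which makes upper bounds in rules like "1 strong + 1–2
moderate" unnecessary. Evidence satisfying both a pathogenic-side and a
benign-side rule yields uncertain significance with rationale
"conflicting"; satisfying neither yields "insufficient". Classification
depends only on the per-category count vector, a property the test suite
exploits by enumerating the full bounded grid (7,680 vectors) against an
independently hand-coded decision procedure.

Auto-assignment is deliberately limited to mechanically computable codes:
BA1 (max AF > 0.05), PM2 (absent everywhere or max AF < 1e-4), PP3/BP4
(from the filter module's predictor consensus), PS1 (same amino-acid
change as a known pathogenic entry), PM5 (different missense at a residue
with a known pathogenic missense; suppressed when PS1 fires, since one
observation should contribute one code), and PVS1 only from an explicit
null-variant flag on the record — the package does not itself decide
whether a splice-region change outside the canonical ±1/2 dinucleotides
is a null variant; that judgment stays with the user. No strength
modulation (up/downgrading of codes) is implemented.

## MLPA dosage analysis

Dosage quotients are computed in two steps: each target-probe peak is
divided by the mean of the reference-probe peaks of its sample
(cancelling per-sample scale exactly), then by the median of that ratio
across control samples (median for robustness to one aberrant control;
the intra-sample statistic is the mean, matching common kit practice).
By construction every probe's control-median DQ is exactly 1. Calls use
DQ < 0.7 for deletion, > 1.3 for duplication (expected heterozygous
ratios 0.5/1.5), and < 0.25 flags a homozygous deletion; adjacent probes
in exon order with the same aberrant state merge into one event.
Whole-exon deletions of exons a..b are named
`c.(x+1_y-1)_(z+1_w-1)del` with x = cDNA end of exon a−1, y = x+1,
z = cDNA end of exon b, w = z+1, against NM_000527.4; the packaged
LDLR boundary table is partial (exons 1, 10, 14, 15) and user-extensible.
Note that some published ratio-chart captions describe a heterozygous
deletion as "ratio ~1.5"; this package follows the dosage convention in
which a deletion *reduces* the ratio (points fall below the normal band),
consistent with how such charts plot deleted probes below the lower
control curve.

## Cascade screening and summaries

A cascade plan is wave-structured: wave 1 holds the proband's untested
first-degree relatives (parents, siblings — defined as sharing ≥1
recorded parent — and children); each already-known positive relative
contributes their own untested first-degree relatives to the wave after
the one at which they were reached. Waves are disjoint and the proband is
excluded. Transmission simulation is single-locus autosomal dominant:
each carrier parent transmits independently with probability 1/2, so one
heterozygous parent gives a carrier probability of 1/2 and two give 3/4;
carrier status may be set on founders only.

Summary percentages are rounded half-up to one decimal, matching how
such yields are conventionally printed. Denominators: subject-level yield
over all subjects; per-gene splits over variant-positive *probands*
(compound heterozygotes count once); children's yield over probands'
children. Zero denominators report "undefined", never 0. The DLCN-band
cross-tabulation reports within-band gene splits and the variant-negative
remainder, excluding (and counting) subjects without a band.

## Synthetic data

The random generator (`gen_cohort`) emulates the statistical structure of
a targeted-sequencing FH cohort: total cholesterol truncated normal with
target mean 8.6 and sd 3.4 mmol/L (bounds 1–30), triglycerides log-normal
with moment-matched mean 1.8 / sd 1.4 (right-skewed, as real TG
distributions are), HDL-C truncated normal 1.4 ± 0.4. Truncated draws are
re-centred by the analytic truncation shift so the *marginal* target mean
is preserved. Probands are variant-positive at rate 26/60 with genes and
variants drawn from the packaged panel spectrum (weighted by carrier
counts); ~2/26 of positives are compound heterozygous; children receive
the variant with Mendelian probability 1/2. Carriers' total cholesterol
is shifted by +3.0 mmol/L per carrier "dose" (doubled for compound
heterozygotes — homozygous-type disease is clinically much more severe)
applied as a mean-preserving contrast, so genotype–phenotype correlation
exists without moving the cohort-level targets. All randomness flows from
one seed; outputs are byte-identical across reruns.

What the generator does **not** emulate: linkage and haplotype structure,
age/sex-specific lipid trends, treatment effects on measured lipids,
assay noise, pedigree complexity beyond nuclear families, and variant
discovery from reads. Passing tests therefore demonstrate correctness of
the *analysis* stages under the stated statistical model, not performance
on real sequencing data.

The deterministic reference cohort (`build_paper_fixture`) is
constructed, not sampled: 80 subjects (60 probands, 14 children, 6 other
first-degree relatives) with DLCN criteria engineered to band as
34 definite / 5 probable / 41 possible, and variant assignments giving
26 positive probands (19 *LDLR* — two of them compound heterozygous —
3 *APOB*, 4 in other lipid genes), 12 of 14 positive children, and a
definite band of 26 *LDLR* + 3 *APOB* + 5 negative. It encodes 38
subject-level positives (47.5% of 80); individual lipid values and ages
in the fixture are placeholders and are not summarized anywhere.

The MLPA simulator applies a per-probe copy ratio times multiplicative
log-normal noise, plus a per-sample global scale factor (sd 0.1 on the
log scale) that normalization must cancel; the scale factor is omitted in
noise-free runs so that dosage quotients reproduce copy ratios exactly in
floating point. Performance checks use 200 test samples, 8 controls and
30 heterozygous deletion events at noise sd 0.05 — at these settings a
probe at DQ 1 sits ~6 standard deviations from the deletion threshold, so
near-perfect event-level sensitivity and specificity are the expected
regime, and the suite requires ≥ 0.99.

## Numerical and degenerate-input choices

* Percent rounding uses decimal half-up (Python's `round` is
  banker's rounding and would print 14.75 → 14.7/14.8 inconsistently).
* `conservation_percentile` of an empty reference set, a pedigree with a
  parentage cycle or unknown parent id, an MLPA sample with all reference
  peaks zero, a probe with zero control median, a deletion span lacking a
  boundary entry, and a transmission simulation seeded on a non-founder
  all raise immediately with the offending entity named.
* Filter and summary operations are order-invariant in their inputs;
  the cascade is idempotent on its survivor set.
* PED sex coding is 1 = male / 2 = female, phenotype 0/−9 = missing;
  missing table values are written "NA" and read from any of "", "NA",
  ".". All tables are tab-separated UTF-8 with '.' decimals.

## Known limitations

* The ACMG engine implements the generic 2015 combinations only — no
  gene-specific (e.g. FH VCEP) specifications and no Bayesian point
  system.
* Auto-assigned evidence is a small subset of the code set; classes
  produced from auto-evidence alone are conservative (often VUS).
* The filter cascade assumes annotation (frequencies, predictor calls,
  assertions) is already attached; it performs no live database queries
  and no splice-effect prediction.
* MLPA analysis starts from peak intensities; capillary-electrophoresis
  signal processing and probe design are out of scope.
* Pedigree utilities assume small clinical pedigrees; no inbreeding
  handling, genotype phasing or penetrance modelling.
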