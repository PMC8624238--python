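"""Synthetic cohort, annotation-table and MLPA-run generation.

Two kinds of artifacts come out of this module:

* random cohorts (``gen_cohort``) whose statistical structure emulates a
  targeted-sequencing FH study: lipid profiles drawn from truncated
  normal / log-normal distributions calibrated to the cohort moments
  (total cholesterol 8.6 +/- 3.4 mmol/L, triglycerides mean 1.8 sd 1.4,
  HDL-C 1.4 +/- 0.4), a rare-variant spectrum over six lipid genes,
  autosomal-dominant transmission to relatives, and a configurable
  carrier effect on total cholesterol applied as a mean-preserving
  within-cohort contrast;

* a fully deterministic reference cohort (``build_paper_fixture``)
  whose aggregate counts equal the published study's printed totals
  (80 subjects = 60 probands + 20 relatives; DLCN bands 34/5/41;
  26 variant-positive probands split 19 LDLR / 3 APOB / 4 other;
  12 of 14 children positive; definite band 26 LDLR + 3 APOB +
  5 negative).  Individual-level phenotypes in the fixture are synthetic
  reconstructions — only the aggregates are meaningful.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as fio
from .models import (
    AnnotationRecord,
    ClinvarAssertion,
    DlcnCriteriaInput,
    GeneticResult,
    GeneticStatus,
    LdlMethod,
    LipidPanel,
    Pedigree,
    PedigreeMember,
    PredictorCall,
    Relation,
    Role,
    Sex,
    Subject,
    Zygosity,
)
from .mlpa import PROMOTER, MlpaRun, Probe, SampleRole, Target


class LipidDistribution(BaseModel):
    mean: float
    sd: float = Field(ge=0)
    lower: float
    upper: float

    @model_validator(mode="after")
    def _bounds(self) -> "LipidDistribution":
        if not self.lower < self.upper:
            raise ValueError("truncation bounds must satisfy lower < upper")
        return self


class VariantSpectrumEntry(BaseModel):
    gene: str
    variant_id: str
    weight: float = Field(gt=0)


def _default_spectrum() -> list[VariantSpectrumEntry]:
    weights = fio.load_panel_weights()
    return [
        VariantSpectrumEntry(gene=rec.gene, variant_id=rec.variant_id, weight=w)
        for rec, w in (
            (r, weights[r.variant_id]) for r in fio.load_variant_panel()
        )
    ]


class SimulationParams(BaseModel):
    """Generator conditions, defaulting to the study's reported structure."""

    n_probands: int = Field(default=60, ge=0)
    tc: LipidDistribution = LipidDistribution(mean=8.6, sd=3.4, lower=1.0, upper=30.0)
    tg: LipidDistribution = LipidDistribution(mean=1.8, sd=1.4, lower=0.2, upper=20.0)
    hdl: LipidDistribution = LipidDistribution(mean=1.4, sd=0.4, lower=0.3, upper=3.5)
    proband_positive_rate: float = Field(default=26 / 60, ge=0, le=1)
    compound_het_fraction: float = Field(default=2 / 26, ge=0, le=1)
    fraction_on_therapy: float = Field(default=0.41, ge=0, le=1)
    xanthoma_rate: float = Field(default=0.42, ge=0, le=1)
    premature_cad_rate: float = Field(default=0.20, ge=0, le=1)
    mean_children_per_proband: float = Field(default=14 / 60, ge=0)
    other_relative_rate: float = Field(default=6 / 60, ge=0, le=1)
    carrier_tc_shift: float = 3.0  # mmol/L, doubled for compound heterozygotes
    spectrum: list[VariantSpectrumEntry] = Field(default_factory=_default_spectrum)
    n_common_background: int = Field(default=30, ge=0)
    n_benign_decoys: int = Field(default=10, ge=0)
    mlpa_event_rate: float = Field(default=0.05, ge=0, le=1)
    mlpa_noise_sd: float = Field(default=0.05, ge=0)
    seed: int = 0


def _truncnorm(rng: np.random.Generator, dist: LipidDistribution, n: int) -> np.ndarray:
    """Truncated-normal draws re-centred so the sample target is the
    stated mean despite truncation (the truncation-induced mean shift is
    subtracted analytically)."""
    if dist.sd == 0:
        return np.full(n, dist.mean)
    a = (dist.lower - dist.mean) / dist.sd
    b = (dist.upper - dist.mean) / dist.sd
    phi = lambda x: math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)
    Phi = lambda x: 0.5 * (1 + math.erf(x / math.sqrt(2)))
    z = Phi(b) - Phi(a)
    if z <= 0:
        raise ValueError("unreachable truncation bounds")
    delta = dist.sd * (phi(a) - phi(b)) / z  # E[truncated] - mean
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(dist.mean, dist.sd, size=max(n - filled, 16))
        keep = draw[(draw >= dist.lower) & (draw <= dist.upper)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out - delta


def _lognormal_matched(
    rng: np.random.Generator, dist: LipidDistribution, n: int
) -> np.ndarray:
    """Log-normal draws whose (untruncated) mean and sd equal the targets;
    right-skew mirrors real triglyceride distributions."""
    sigma2 = math.log(1 + (dist.sd / dist.mean) ** 2)
    mu = math.log(dist.mean) - sigma2 / 2
    draw = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    return np.clip(draw, dist.lower, dist.upper)


def _spectrum_probabilities(spectrum: Sequence[VariantSpectrumEntry]) -> np.ndarray:
    w = np.array([e.weight for e in spectrum], dtype=float)
    return w / w.sum()


def gen_cohort(
    params: Optional[SimulationParams] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> tuple[list[Subject], list[Pedigree], list[AnnotationRecord]]:
    """Generate a random cohort; optionally write subjects.tsv,
    families.ped and annotations.tsv under ``out_dir``.

    Deterministic (byte-identical files) for a fixed ``params.seed``.
    """
    p = params or SimulationParams()
    rng = np.random.default_rng(p.seed)
    n_pro = p.n_probands

    # carrier structure first, so the lipid contrast can be mean-preserving
    positive = rng.random(n_pro) < p.proband_positive_rate
    spectrum_p = _spectrum_probabilities(p.spectrum) if p.spectrum else None
    variant_idx = rng.integers(0, max(len(p.spectrum), 1), size=n_pro) if not p.spectrum \
        else rng.choice(len(p.spectrum), size=n_pro, p=spectrum_p)
    compound = positive & (rng.random(n_pro) < p.compound_het_fraction)

    n_children = rng.poisson(p.mean_children_per_proband, size=n_pro)
    has_other = rng.random(n_pro) < p.other_relative_rate

    subjects: list[Subject] = []
    pedigrees: list[Pedigree] = []
    dose: list[float] = []  # carrier dose per subject (0 / 1 / 2)
    rows: list[dict] = []

    def spectrum_entry(i: int) -> VariantSpectrumEntry:
        return p.spectrum[int(variant_idx[i])]

    for i in range(n_pro):
        pid = f"P{i + 1:04d}"
        fam = f"FAM{i + 1:04d}"
        sex = Sex.F if i % 2 == 0 else Sex.M
        members = [PedigreeMember(individual_id=pid, sex=sex, affected=True)]
        if positive[i]:
            entry = spectrum_entry(i)
            ids = [entry.variant_id]
            zyg = Zygosity.het
            if compound[i]:
                alt = p.spectrum[(int(variant_idx[i]) + 1) % len(p.spectrum)]
                ids = [entry.variant_id, alt.variant_id]
                zyg = Zygosity.compound_het
            genetic = GeneticResult(
                status=GeneticStatus.positive, gene=entry.gene,
                variant_ids=ids, zygosity=zyg,
            )
            dose.append(2.0 if compound[i] else 1.0)
        else:
            genetic = GeneticResult(status=GeneticStatus.negative)
            dose.append(0.0)
        rows.append({
            "id": pid, "fam": fam, "role": Role.proband,
            "relation": Relation.self, "sex": sex,
            "age": int(rng.integers(20, 74)), "genetic": genetic,
            "on_therapy": bool(rng.random() < p.fraction_on_therapy),
        })

        for c in range(int(n_children[i])):
            cid = f"{pid}C{c + 1}"
            carrier = bool(positive[i]) and bool(rng.random() < 0.5)
            if carrier:
                entry = spectrum_entry(i)
                genetic_c = GeneticResult(
                    status=GeneticStatus.positive, gene=entry.gene,
                    variant_ids=[entry.variant_id], zygosity=Zygosity.het,
                )
            else:
                genetic_c = GeneticResult(status=GeneticStatus.negative)
            dose.append(1.0 if carrier else 0.0)
            csex = Sex.F if rng.random() < 0.5 else Sex.M
            rows.append({
                "id": cid, "fam": fam, "role": Role.relative,
                "relation": Relation.child, "sex": csex,
                "age": int(rng.integers(5, 18)), "genetic": genetic_c,
                "on_therapy": False,
            })
            members.append(PedigreeMember(
                individual_id=cid,
                father_id=pid if sex == Sex.M else None,
                mother_id=pid if sex == Sex.F else None,
                sex=csex, affected=carrier,
            ))
        if has_other[i]:
            rid = f"{pid}R1"
            rsex = Sex.F if rng.random() < 0.5 else Sex.M
            dose.append(0.0)
            rows.append({
                "id": rid, "fam": fam, "role": Role.relative,
                "relation": Relation.sibling, "sex": rsex,
                "age": int(rng.integers(20, 74)),
                "genetic": GeneticResult(status=GeneticStatus.negative),
                "on_therapy": False,
            })
            members.append(PedigreeMember(individual_id=rid, sex=rsex, affected=False))
        pedigrees.append(Pedigree(family_id=fam, individuals=members))

    n = len(rows)
    dose_arr = np.array(dose)
    tc = _truncnorm(rng, p.tc, n)
    tg = _lognormal_matched(rng, p.tg, n)
    hdl = _truncnorm(rng, p.hdl, n)
    # mean-preserving carrier contrast on total cholesterol
    if n:
        tc = tc + p.carrier_tc_shift * (dose_arr - dose_arr.mean())
        tc = np.clip(tc, 0.5, None)

    for i, row in enumerate(rows):
        ldl_est = tc[i] - hdl[i] - tg[i] / 2.2
        ldl = float(ldl_est) if 0 < ldl_est else None
        lipid = LipidPanel(
            tc=float(tc[i]), tg=float(tg[i]), hdl=float(hdl[i]),
            ldl=ldl,
            ldl_method=LdlMethod.friedewald if ldl is not None else LdlMethod.missing,
        )
        dlcn = DlcnCriteriaInput(
            tendon_xanthomata=bool(rng.random() < p.xanthoma_rate),
            personal_premature_cad=bool(rng.random() < p.premature_cad_rate),
            ldl_mmol_per_l=ldl,
        )
        subjects.append(Subject(
            subject_id=row["id"], family_id=row["fam"], role=row["role"],
            relation_to_proband=row["relation"], sex=row["sex"], age=row["age"],
            lipid=lipid, on_lipid_lowering=row["on_therapy"],
            dlcn_input=dlcn, genetic_result=row["genetic"],
        ))

    annotations = gen_annotation_table(
        spectrum=p.spectrum,
        n_common_background=p.n_common_background,
        n_benign_decoys=p.n_benign_decoys,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_subject_table(subjects, out / "subjects.tsv")
        fio.write_pedigree(pedigrees, out / "families.ped")
        fio.write_annotation_table(annotations, out / "annotations.tsv")
    return subjects, pedigrees, annotations


# ------------------------------------------------------------- annotations


def gen_annotation_table(
    spectrum: Optional[Sequence[VariantSpectrumEntry]] = None,
    n_common_background: int = 30,
    n_benign_decoys: int = 10,
    seed: int = 0,
    include_panel: bool = True,
) -> list[AnnotationRecord]:
    """Annotation table: the packaged rare-variant panel verbatim, plus
    common background polymorphisms (AF 0.01-0.5) and rare benign /
    likely-benign decoys that the filter cascade must remove."""
    rng = np.random.default_rng(seed)
    records: list[AnnotationRecord] = []
    if include_panel:
        panel = fio.load_variant_panel()
        if spectrum is not None:
            wanted = {e.variant_id for e in spectrum}
            panel = [r for r in panel if r.variant_id in wanted] or panel
        for rec in panel:
            enriched = rec.model_copy(update={
                "predictor_calls": {
                    "sift": PredictorCall.damaging,
                    "polyphen2": PredictorCall.damaging,
                    "provean": PredictorCall.damaging,
                    "mutation_taster": PredictorCall.damaging,
                },
                "conservation_scores": {"phastcons": 0.95, "gerp": 0.9},
            })
            records.append(enriched)

    used = {r.allele_key() for r in records}
    bases = ["A", "C", "G", "T"]

    def fresh_site() -> tuple[str, int, str, str]:
        while True:
            chrom = str(rng.integers(1, 23))
            pos = int(rng.integers(1_000_000, 200_000_000))
            ref, alt = rng.choice(bases, size=2, replace=False)
            key = (chrom, pos, str(ref), str(alt))
            if key not in used:
                used.add(key)
                return key

    for k in range(n_common_background):
        chrom, pos, ref, alt = fresh_site()
        records.append(AnnotationRecord(
            variant_id=f"bg{k + 1:03d}", chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene="BACKGROUND", hgvs_c="",
            af_by_source={"gnomad": float(np.round(rng.uniform(0.01, 0.5), 6))},
            clinvar_assertion=ClinvarAssertion.not_reported,
            predictor_calls={"sift": PredictorCall.tolerated},
        ))
    for k in range(n_benign_decoys):
        chrom, pos, ref, alt = fresh_site()
        records.append(AnnotationRecord(
            variant_id=f"decoy{k + 1:03d}", chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene="DECOY", hgvs_c="",
            af_by_source={"gnomad": float(np.round(rng.uniform(1e-4, 1e-3), 7))},
            clinvar_assertion=ClinvarAssertion.benign
            if k % 2 == 0 else ClinvarAssertion.likely_benign,
        ))

    keys = [r.allele_key() for r in records]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (chrom, pos, alt) in generated annotation table")
    return records


# -------------------------------------------------------------------- MLPA

LDLR_TARGETS: list[Target] = [PROMOTER] + list(range(1, 19))


def default_probe_set(n_reference: int = 8) -> list[Probe]:
    probes = [
        Probe(probe_id=f"LDLR_{'prom' if t == PROMOTER else f'ex{t:02d}'}", target=t)
        for t in LDLR_TARGETS
    ]
    probes += [
        Probe(probe_id=f"REF_{j + 1:02d}", target=None, is_reference=True)
        for j in range(n_reference)
    ]
    return probes


MlpaEvent = tuple[str, tuple[Target, Target], float]  # sample, (first, last), ratio


def gen_mlpa_run(
    n_samples: int,
    events: Sequence[MlpaEvent] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
    n_controls: int = 8,
    probes: Optional[list[Probe]] = None,
) -> MlpaRun:
    """Simulate probe peaks: per-probe baseline x copy ratio x log-normal
    noise, plus (when noisy) a per-sample global scale that the dosage
    normalization must cancel.  Zero noise reproduces copy ratios
    exactly."""
    rng = np.random.default_rng(seed)
    probe_list = probes or default_probe_set()
    test_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    control_ids = [f"CTRL{i + 1:02d}" for i in range(n_controls)]
    sample_ids = test_ids + control_ids
    known = set(test_ids)
    for sample, _, ratio in events:
        if sample not in known:
            raise ValueError(f"event references unknown test sample {sample!r}")
        if ratio <= 0:
            raise ValueError("copy ratio must be positive")

    order: list[Target] = [p.target for p in probe_list if not p.is_reference]

    def span_targets(span: tuple[Target, Target]) -> set[Target]:
        i, j = order.index(span[0]), order.index(span[1])
        if i > j:
            i, j = j, i
        return set(order[i : j + 1])

    ratio = pd.DataFrame(1.0, index=sample_ids, columns=[p.probe_id for p in probe_list])
    for sample, span, r in events:
        hit = span_targets(span)
        for p in probe_list:
            if not p.is_reference and p.target in hit:
                ratio.loc[sample, p.probe_id] = r

    baseline = np.array([800.0 + 35.0 * k for k in range(len(probe_list))])
    peaks = ratio * baseline[np.newaxis, :]
    if noise_sd > 0:
        noise = np.exp(rng.normal(0.0, noise_sd, size=peaks.shape))
        scale = np.exp(rng.normal(0.0, 0.1, size=(len(sample_ids), 1)))
        peaks = peaks * noise * scale

    roles = {s: SampleRole.test for s in test_ids}
    roles.update({s: SampleRole.control for s in control_ids})
    return MlpaRun(sample_roles=roles, probes=probe_list, peaks=peaks)


# ------------------------------------------------------ deterministic fixture


def _fixture_dlcn(band: str) -> DlcnCriteriaInput:
    """Criteria engineered to land in a given diagnostic band without the
    DNA criterion (pre-genetic scoring)."""
    if band == "definite":    # physical 6 + LDL 5 = 11
        return DlcnCriteriaInput(tendon_xanthomata=True, ldl_mmol_per_l=7.0)
    if band == "probable":    # clinical 2 + LDL 5 = 7
        return DlcnCriteriaInput(personal_premature_cad=True, ldl_mmol_per_l=7.0)
    if band == "possible":    # LDL 3
        return DlcnCriteriaInput(ldl_mmol_per_l=5.5)
    raise ValueError(band)


def _fixture_subject(
    sid: str, fam: str, role: Role, relation: Relation, sex: Sex, age: int,
    band: str, genetic: GeneticResult, on_therapy: bool = False,
) -> Subject:
    d = _fixture_dlcn(band)
    ldl = d.ldl_mmol_per_l
    lipid = LipidPanel(tc=ldl + 2.3, tg=1.8, hdl=1.4, ldl=ldl, ldl_method=LdlMethod.direct)
    return Subject(
        subject_id=sid, family_id=fam, role=role, relation_to_proband=relation,
        sex=sex, age=age, lipid=lipid, on_lipid_lowering=on_therapy,
        dlcn_input=d, genetic_result=genetic,
    )


# LDLR variants assigned to the 19 LDLR-positive probands: the first two
# are the compound heterozygotes, the rest cycle through the panel.
_LDLR_SINGLE = [
    "rs121908038", "rs121908038", "rs121908038", "rs137853964", "rs28942078",
    "rs28942078", "rs539080792", "rs570942190", "rs755757866", "rs755757866",
    "rs761954844", "rs879254566", "rs879254721", "rs879254721", "rs879254980",
    "rs879255191", "rs121908038",
]
_OTHER_GENES = [("LPL", "rs118204077"), ("APOC3", "rs138326449"),
                ("ABCG5", "rs145164937"), ("SREBF1", "rs115855236")]


def build_paper_fixture(
    out_dir: Optional[Union[str, Path]] = None,
) -> tuple[list[Subject], list[Pedigree], list[AnnotationRecord]]:
    """Deterministic reference cohort reproducing the published aggregate
    counts (see module docstring).  No randomness: re-running produces
    byte-identical files."""
    subjects: list[Subject] = []
    pedigrees: list[Pedigree] = []

    def pos(gene: str, ids: list[str], zyg: Zygosity = Zygosity.het) -> GeneticResult:
        return GeneticResult(status=GeneticStatus.positive, gene=gene,
                             variant_ids=ids, zygosity=zyg)

    NEG = GeneticResult(status=GeneticStatus.negative)

    # --- probands ---------------------------------------------------------
    proband_specs: list[tuple[str, GeneticResult]] = []
    proband_specs.append(("definite", pos("LDLR", ["rs875989907", "rs879254769"],
                                          Zygosity.compound_het)))
    proband_specs.append(("definite", pos("LDLR", ["rs875989894", "novel"],
                                          Zygosity.compound_het)))
    for k, vid in enumerate(_LDLR_SINGLE):           # probands 3..19
        band = "definite" if k < 14 else ("probable" if k < 16 else "possible")
        proband_specs.append((band, pos("LDLR", [vid])))
    for _ in range(3):                               # probands 20..22
        proband_specs.append(("definite", pos("APOB", ["rs5742904"])))
    for gene, vid in _OTHER_GENES:                   # probands 23..26
        proband_specs.append(("possible", pos(gene, [vid])))
    for k in range(34):                              # probands 27..60, negative
        band = "definite" if k < 5 else ("probable" if k < 8 else "possible")
        proband_specs.append((band, NEG))
    assert len(proband_specs) == 60

    for i, (band, genetic) in enumerate(proband_specs):
        pid = f"P{i + 1:03d}"
        fam = f"FAM{i + 1:03d}"
        sex = Sex.F if i % 2 == 0 else Sex.M
        subjects.append(_fixture_subject(
            pid, fam, Role.proband, Relation.self, sex, 30 + (i % 40), band,
            genetic, on_therapy=(i < 25),
        ))
        pedigrees.append(Pedigree(
            family_id=fam,
            individuals=[PedigreeMember(individual_id=pid, sex=sex, affected=True)],
        ))

    ped_by_fam = {p.family_id: p for p in pedigrees}

    def add_child(parent_index: int, cid: str, band: str, genetic: GeneticResult) -> None:
        parent = subjects[parent_index]
        fam = parent.family_id
        sex = Sex.M if int(cid[1:3]) % 2 else Sex.F
        subjects.append(_fixture_subject(
            cid, fam, Role.relative, Relation.child, sex, 8 + parent_index % 10,
            band, genetic,
        ))
        ped_by_fam[fam].individuals.append(PedigreeMember(
            individual_id=cid,
            father_id=parent.subject_id if parent.sex == Sex.M else None,
            mother_id=parent.subject_id if parent.sex == Sex.F else None,
            sex=sex,
            affected=genetic.status == GeneticStatus.positive,
        ))

    # --- children: 10 LDLR+, 1 APOB+, 1 SREBF1+, 2 negative ---------------
    for c in range(10):
        parent = subjects[c + 2]  # LDLR single-variant probands P003..P012
        add_child(c + 2, f"C{c + 1:02d}", "definite",
                  pos("LDLR", list(parent.genetic_result.variant_ids)))
    add_child(19, "C11", "possible", pos("APOB", ["rs5742904"]))      # P020
    add_child(25, "C12", "possible", pos("SREBF1", ["rs115855236"]))  # P026
    add_child(26, "C13", "possible", NEG)                             # P027
    add_child(27, "C14", "possible", NEG)                             # P028

    # --- six other first-degree relatives, all variant-negative -----------
    other_rel = [(12, Relation.sibling), (13, Relation.sibling), (14, Relation.sibling),
                 (15, Relation.parent), (16, Relation.parent), (17, Relation.sibling)]
    for j, (pi, relation) in enumerate(other_rel):
        parent = subjects[pi]
        rid = f"R{j + 1:02d}"
        sex = Sex.F if j % 2 else Sex.M
        age = 68 if relation == Relation.parent else 45
        subjects.append(_fixture_subject(
            rid, parent.family_id, Role.relative, relation, sex, age, "possible", NEG,
        ))
        member = PedigreeMember(individual_id=rid, sex=sex, affected=False)
        ped = ped_by_fam[parent.family_id]
        if relation == Relation.parent:
            ped.individuals.append(member)
            target = ped.members_by_id[parent.subject_id]
            if sex == Sex.M:
                target.father_id = rid
            else:
                target.mother_id = rid
        else:  # sibling: link both through a shared (untyped) founder father
            founder = PedigreeMember(individual_id=f"F{j + 1:02d}", sex=Sex.M)
            ped.individuals.extend([founder, member])
            ped.members_by_id[parent.subject_id].father_id = founder.individual_id
            member.father_id = founder.individual_id

    pedigrees = [
        Pedigree(family_id=p.family_id, individuals=p.individuals) for p in pedigrees
    ]  # re-validate after in-place edits

    annotations = fio.load_variant_panel()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_subject_table(subjects, out / "subjects.tsv")
        fio.write_pedigree(pedigrees, out / "families.ped")
        fio.write_annotation_table(annotations, out / "annotations.tsv")
    return subjects, pedigrees, annotations
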