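"""Readers and writers for the pipeline's tabular formats.

Canonical dialect: tab-separated, UTF-8, '.' decimal.  Missing optional
values are written as "NA"; on input, "", "NA" and "." are equivalent.
Pedigrees use the de facto 6-column PED convention (family, individual,
father, mother, sex, phenotype; sex 1=male/2=female, 0=unknown;
phenotype 0/-9=missing, 1=unaffected, 2=affected).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd
from pydantic import ValidationError

from .config import _data_path
from .models import (
    AnnotationRecord,
    ClinvarAssertion,
    DlcnCriteriaInput,
    DnaMutation,
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

_NA = {"", "NA", "."}

SUBJECT_COLUMNS = [
    "subject_id", "family_id", "role", "relation_to_proband", "sex", "age",
    "tc", "tg", "hdl", "ldl", "ldl_method", "on_lipid_lowering",
    "family_premature_cvd", "family_ldl_above_p95", "family_xanthoma_or_arcus",
    "family_child_ldl_above_p95", "personal_premature_cad",
    "personal_premature_cerebral_or_peripheral", "tendon_xanthomata",
    "arcus_cornealis_before_45", "dlcn_ldl", "dna_functional_mutation",
    "genetic_status", "gene", "variant_ids", "zygosity",
]

ANNOTATION_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "gene", "hgvs_c", "hgvs_p",
    "af_by_source", "predictor_calls", "conservation_scores",
    "clinvar_assertion", "hgmd_id", "zygosity", "is_null_variant",
]


class FormatError(ValueError):
    """Structural problem with an input file (missing column, bad header)."""


class RowValidationError(ValueError):
    def __init__(self, path: Union[str, Path], row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"{path}: row {row_index}: {message}")


def _opt(value: str) -> Optional[str]:
    return None if value in _NA else value


def _opt_float(value: str) -> Optional[float]:
    s = _opt(value)
    return None if s is None else float(s)


def _bool(value: str) -> bool:
    if value in {"1", "true", "True"}:
        return True
    if value in {"0", "false", "False"} | _NA:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _read_tsv(path: Union[str, Path], required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return df


# ---------------------------------------------------------------- subjects


def _subject_from_row(row: pd.Series) -> Subject:
    lipid = LipidPanel(
        tc=float(row["tc"]),
        tg=float(row["tg"]),
        hdl=float(row["hdl"]),
        ldl=_opt_float(row["ldl"]),
        ldl_method=LdlMethod(row["ldl_method"]) if _opt(row["ldl_method"]) else LdlMethod.missing,
    )
    dlcn = DlcnCriteriaInput(
        family_premature_cvd=_bool(row["family_premature_cvd"]),
        family_ldl_above_p95=_bool(row["family_ldl_above_p95"]),
        family_xanthoma_or_arcus=_bool(row["family_xanthoma_or_arcus"]),
        family_child_ldl_above_p95=_bool(row["family_child_ldl_above_p95"]),
        personal_premature_cad=_bool(row["personal_premature_cad"]),
        personal_premature_cerebral_or_peripheral=_bool(
            row["personal_premature_cerebral_or_peripheral"]
        ),
        tendon_xanthomata=_bool(row["tendon_xanthomata"]),
        arcus_cornealis_before_45=_bool(row["arcus_cornealis_before_45"]),
        ldl_mmol_per_l=_opt_float(row["dlcn_ldl"]),
        dna_functional_mutation=DnaMutation(row["dna_functional_mutation"])
        if _opt(row["dna_functional_mutation"])
        else DnaMutation.untested,
    )
    status = _opt(row["genetic_status"])
    genetic = GeneticResult(
        status=GeneticStatus(status) if status else GeneticStatus.untested,
        gene=_opt(row["gene"]),
        variant_ids=[v for v in row["variant_ids"].split(",") if v and v not in _NA],
        zygosity=Zygosity(row["zygosity"]) if _opt(row["zygosity"]) else None,
    )
    return Subject(
        subject_id=row["subject_id"],
        family_id=row["family_id"],
        role=Role(row["role"]),
        relation_to_proband=Relation(row["relation_to_proband"]),
        sex=Sex(row["sex"]),
        age=int(row["age"]),
        lipid=lipid,
        on_lipid_lowering=_bool(row["on_lipid_lowering"]),
        dlcn_input=dlcn,
        genetic_result=genetic,
    )


def read_subject_table(path: Union[str, Path]) -> list[Subject]:
    """Parse a subject TSV; raises at the first malformed row (with its index)."""
    df = _read_tsv(path, SUBJECT_COLUMNS)
    subjects: list[Subject] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        try:
            subj = _subject_from_row(row)
        except (ValueError, ValidationError) as exc:
            raise RowValidationError(path, int(i), str(exc)) from exc
        if subj.subject_id in seen:
            raise RowValidationError(path, int(i), f"duplicate subject_id {subj.subject_id!r}")
        seen.add(subj.subject_id)
        subjects.append(subj)
    return subjects


def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        d = s.dlcn_input or DlcnCriteriaInput()
        g = s.genetic_result or GeneticResult()
        rows.append({
            "subject_id": s.subject_id,
            "family_id": s.family_id,
            "role": s.role.value,
            "relation_to_proband": s.relation_to_proband.value,
            "sex": s.sex.value,
            "age": s.age,
            "tc": s.lipid.tc,
            "tg": s.lipid.tg,
            "hdl": s.lipid.hdl,
            "ldl": "NA" if s.lipid.ldl is None else s.lipid.ldl,
            "ldl_method": s.lipid.ldl_method.value,
            "on_lipid_lowering": int(s.on_lipid_lowering),
            "family_premature_cvd": int(d.family_premature_cvd),
            "family_ldl_above_p95": int(d.family_ldl_above_p95),
            "family_xanthoma_or_arcus": int(d.family_xanthoma_or_arcus),
            "family_child_ldl_above_p95": int(d.family_child_ldl_above_p95),
            "personal_premature_cad": int(d.personal_premature_cad),
            "personal_premature_cerebral_or_peripheral": int(
                d.personal_premature_cerebral_or_peripheral
            ),
            "tendon_xanthomata": int(d.tendon_xanthomata),
            "arcus_cornealis_before_45": int(d.arcus_cornealis_before_45),
            "dlcn_ldl": "NA" if d.ldl_mmol_per_l is None else d.ldl_mmol_per_l,
            "dna_functional_mutation": d.dna_functional_mutation.value,
            "genetic_status": g.status.value,
            "gene": g.gene or "NA",
            "variant_ids": ",".join(g.variant_ids) or "NA",
            "zygosity": g.zygosity.value if g.zygosity else "NA",
        })
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def write_subject_table(subjects: list[Subject], path: Union[str, Path]) -> None:
    subjects_to_frame(subjects).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- pedigrees


def read_pedigree(path: Union[str, Path]) -> list[Pedigree]:
    """Read a 6-column PED file; returns one Pedigree per family id."""
    families: dict[str, list[PedigreeMember]] = {}
    order: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 PED columns, got {len(fields)}")
            fam, iid, father, mother, sex, pheno = fields
            if iid in (father, mother):
                raise RowValidationError(path, lineno, f"individual {iid!r} is its own parent")
            member = PedigreeMember(
                individual_id=iid,
                father_id=None if father in {"0"} | _NA else father,
                mother_id=None if mother in {"0"} | _NA else mother,
                sex={"1": Sex.M, "2": Sex.F}.get(sex),
                affected={"2": True, "1": False}.get(pheno),
            )
            if fam not in families:
                families[fam] = []
                order.append(fam)
            families[fam].append(member)
    return [Pedigree(family_id=fam, individuals=families[fam]) for fam in order]


def write_pedigree(pedigrees: list[Pedigree], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ped in pedigrees:
            for m in ped.individuals:
                sex = {Sex.M: "1", Sex.F: "2", None: "0"}[m.sex]
                pheno = {True: "2", False: "1", None: "0"}[m.affected]
                fh.write(
                    f"{ped.family_id}\t{m.individual_id}\t{m.father_id or '0'}\t"
                    f"{m.mother_id or '0'}\t{sex}\t{pheno}\n"
                )


# ---------------------------------------------------------------- annotations


def _parse_map(text: str, cast) -> dict:
    """Parse "key:value;key:value" map cells."""
    s = _opt(text)
    if s is None:
        return {}
    out = {}
    for item in s.split(";"):
        k, _, v = item.partition(":")
        out[k] = cast(v)
    return out


def read_annotation_table(path: Union[str, Path]) -> list[AnnotationRecord]:
    """Flat-TSV annotated variant table (one alt allele per row)."""
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(AnnotationRecord(
                variant_id=row["variant_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                hgvs_c=_opt(row["hgvs_c"]) or "",
                hgvs_p=_opt(row["hgvs_p"]),
                af_by_source=_parse_map(row["af_by_source"], float),
                predictor_calls=_parse_map(row["predictor_calls"], str),
                conservation_scores=_parse_map(row["conservation_scores"], float),
                clinvar_assertion=ClinvarAssertion(row["clinvar_assertion"]),
                hgmd_id=_opt(row["hgmd_id"]),
                zygosity=Zygosity(row["zygosity"]),
                is_null_variant=_bool(row["is_null_variant"]),
            ))
        except (ValueError, ValidationError) as exc:
            raise RowValidationError(path, int(i), str(exc)) from exc
    return records


def annotations_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "variant_id": r.variant_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "hgvs_c": r.hgvs_c or "NA",
            "hgvs_p": r.hgvs_p or "NA",
            "af_by_source": ";".join(f"{k}:{v}" for k, v in r.af_by_source.items()) or "NA",
            "predictor_calls": ";".join(
                f"{k}:{v.value}" for k, v in r.predictor_calls.items()
            ) or "NA",
            "conservation_scores": ";".join(
                f"{k}:{v}" for k, v in r.conservation_scores.items()
            ) or "NA",
            "clinvar_assertion": r.clinvar_assertion.value,
            "hgmd_id": r.hgmd_id or "NA",
            "zygosity": r.zygosity.value,
            "is_null_variant": int(r.is_null_variant),
        })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation_table(records: list[AnnotationRecord], path: Union[str, Path]) -> None:
    annotations_to_frame(records).to_csv(path, sep="\t", index=False)


def read_annotation_vcf(path: Union[str, Path]) -> list[AnnotationRecord]:
    """Annotated variants from a VCF (v4.2, one alt allele per record).

    Annotations are carried in INFO keys: ``GENE``, ``HGVSC``, ``HGVSP``,
    ``CLNSIG`` (this module's assertion vocabulary), ``HGMD``, ``NULLVAR``
    (flag), ``AF_<source>`` (per-database allele frequency),
    ``PRED_<tool>`` (D = damaging, T = tolerated) and ``CONS_<tool>``
    (conservation score).  The record id holds the dbSNP id or "novel".
    """
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"{path}: multi-allelic record at {v.CHROM}:{v.POS}; split upstream"
            )
        info = dict(v.INFO)
        af, preds, cons = {}, {}, {}
        for key, value in info.items():
            if key.startswith("AF_"):
                af[key[3:].lower()] = float(value)
            elif key.startswith("PRED_"):
                preds[key[5:].lower()] = (
                    PredictorCall.damaging if value == "D"
                    else PredictorCall.tolerated if value == "T"
                    else PredictorCall.unknown
                )
            elif key.startswith("CONS_"):
                cons[key[5:].lower()] = float(value)
        records.append(AnnotationRecord(
            variant_id=v.ID or "novel",
            chrom=v.CHROM.removeprefix("chr"),
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0],
            gene=info.get("GENE", ""),
            hgvs_c=info.get("HGVSC", ""),
            hgvs_p=info.get("HGVSP"),
            af_by_source=af,
            predictor_calls=preds,
            conservation_scores=cons,
            clinvar_assertion=ClinvarAssertion(info.get("CLNSIG", "not_reported")),
            hgmd_id=info.get("HGMD"),
            zygosity=Zygosity(info.get("ZYG", "het")),
            is_null_variant=bool(info.get("NULLVAR", False)),
        ))
    vcf.close()
    return records


# ------------------------------------------------------------ packaged data


def load_variant_panel() -> list[AnnotationRecord]:
    """The packaged panel of rare FH-associated variants (LDLR, APOB, ABCG5,
    APOC3, LPL, SREBF1) with gnomAD frequencies and ClinVar assertions."""
    df = pd.read_csv(_data_path("fh_variant_panel.tsv"), sep="\t", dtype=str,
                     keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        af = _opt_float(row["gnomad_af"])
        records.append(AnnotationRecord(
            variant_id=row["variant_id"],
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            hgvs_c=row["hgvs_c"],
            hgvs_p=_opt(row["hgvs_p"]),
            af_by_source={} if af is None else {"gnomad": af},
            clinvar_assertion=ClinvarAssertion(row["clinvar_assertion"]),
            hgmd_id=_opt(row["hgmd_id"]),
            is_null_variant=_bool(row["is_null_variant"]),
        ))
    return records


def load_panel_weights() -> dict[str, int]:
    """variant_id -> number of carrier probands in the packaged spectrum."""
    df = pd.read_csv(_data_path("fh_variant_panel.tsv"), sep="\t", dtype=str,
                     keep_default_na=False)
    return dict(zip(df["variant_id"], df["n_carrier_probands"].astype(int)))


def load_ldlr_exon_boundaries() -> dict[int, int]:
    """Partial LDLR (NM_000527.4) exon -> cDNA end-coordinate map."""
    df = pd.read_csv(_data_path("ldlr_exons.tsv"), sep="\t")
    return dict(zip(df["exon"].astype(int), df["cdna_end"].astype(int)))
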