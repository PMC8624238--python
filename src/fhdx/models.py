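"""Domain types shared across the diagnostic pipeline.

Familial hypercholesterolemia (FH) diagnostics combine a clinical score
(Dutch Lipid Clinic Network, DLCN), lipid chemistry, annotated rare-variant
tables from targeted sequencing, MLPA exon-dosage data and pedigree-driven
cascade screening.  The types here are the common currency between those
stages: validation happens at construction so downstream code can assume
well-formed inputs.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class Role(str, enum.Enum):
    proband = "proband"
    relative = "relative"


class Relation(str, enum.Enum):
    self = "self"
    child = "child"
    parent = "parent"
    sibling = "sibling"
    other = "other"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class LdlMethod(str, enum.Enum):
    friedewald = "friedewald"
    direct = "direct"
    missing = "missing"


class GeneticStatus(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    untested = "untested"


class Zygosity(str, enum.Enum):
    het = "het"
    hom = "hom"
    compound_het = "compound_het"


class ClinvarAssertion(str, enum.Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    conflicting = "conflicting"
    uncertain = "uncertain"
    likely_benign = "likely_benign"
    benign = "benign"
    not_reported = "not_reported"


class PredictorCall(str, enum.Enum):
    damaging = "damaging"
    tolerated = "tolerated"
    unknown = "unknown"


class DlcnBand(str, enum.Enum):
    unlikely = "unlikely"
    possible = "possible"
    probable = "probable"
    definite = "definite"


class DnaMutation(str, enum.Enum):
    yes = "yes"
    no = "no"
    untested = "untested"


class LipidPanel(BaseModel):
    """Fasting lipid profile in mmol/L (tc = total cholesterol, tg =
    triglycerides, hdl/ldl = HDL-/LDL-cholesterol)."""

    tc: float = Field(gt=0)
    tg: float = Field(gt=0)
    hdl: float = Field(gt=0)
    ldl: Optional[float] = Field(default=None, gt=0)
    ldl_method: LdlMethod = LdlMethod.missing

    @model_validator(mode="after")
    def _ldl_below_tc(self) -> "LipidPanel":
        if self.ldl is not None and self.ldl >= self.tc:
            raise ValueError(f"ldl ({self.ldl}) must be < tc ({self.tc})")
        return self


class GeneticResult(BaseModel):
    status: GeneticStatus = GeneticStatus.untested
    gene: Optional[str] = None
    variant_ids: list[str] = Field(default_factory=list)
    zygosity: Optional[Zygosity] = None

    @model_validator(mode="after")
    def _consistency(self) -> "GeneticResult":
        if self.status == GeneticStatus.positive and not self.gene:
            raise ValueError("positive genetic result requires a gene")
        if self.zygosity == Zygosity.compound_het and len(self.variant_ids) < 2:
            raise ValueError("compound heterozygote requires >= 2 variant ids")
        return self


class DlcnCriteriaInput(BaseModel):
    """Raw yes/no DLCN criteria plus the (pre-treatment) LDL-C level.

    Family criteria refer to first-degree relatives; "premature" means
    <55 y in men / <60 y in women, as in the DLCN definition.
    """

    family_premature_cvd: bool = False
    family_ldl_above_p95: bool = False
    family_xanthoma_or_arcus: bool = False
    family_child_ldl_above_p95: bool = False
    personal_premature_cad: bool = False
    personal_premature_cerebral_or_peripheral: bool = False
    tendon_xanthomata: bool = False
    arcus_cornealis_before_45: bool = False
    ldl_mmol_per_l: Optional[float] = Field(default=None, ge=0)
    dna_functional_mutation: DnaMutation = DnaMutation.untested


class DlcnResult(BaseModel):
    group_subscores: dict[str, int]
    total: int = Field(ge=0)
    band: DlcnBand

    @model_validator(mode="after")
    def _total_is_sum(self) -> "DlcnResult":
        if self.total != sum(self.group_subscores.values()):
            raise ValueError("total must equal the sum of group subscores")
        return self


class Subject(BaseModel):
    subject_id: str
    family_id: str
    role: Role
    relation_to_proband: Relation
    sex: Sex
    age: int = Field(ge=0, le=120)
    lipid: LipidPanel
    on_lipid_lowering: bool = False
    dlcn_input: Optional[DlcnCriteriaInput] = None
    genetic_result: Optional[GeneticResult] = None

    @model_validator(mode="after")
    def _proband_is_self(self) -> "Subject":
        if self.role == Role.proband and self.relation_to_proband != Relation.self:
            raise ValueError("a proband's relation_to_proband must be 'self'")
        return self


class PedigreeMember(BaseModel):
    individual_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Optional[Sex] = None
    affected: Optional[bool] = None


class Pedigree(BaseModel):
    """One family as a parent-link graph.  Founders have no recorded
    parents.  Acyclicity (nobody is their own ancestor) is enforced."""

    family_id: str
    individuals: list[PedigreeMember]

    @model_validator(mode="after")
    def _validate_links(self) -> "Pedigree":
        ids = {m.individual_id for m in self.individuals}
        if len(ids) != len(self.individuals):
            raise ValueError("duplicate individual id in pedigree")
        for m in self.individuals:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise ValueError(
                        f"unknown parent id {pid!r} for individual {m.individual_id!r}"
                    )
        # explicit DFS ancestor walk: nobody may reach themselves
        parents = {
            m.individual_id: [p for p in (m.father_id, m.mother_id) if p is not None]
            for m in self.individuals
        }
        for start in ids:
            stack, seen = list(parents[start]), set()
            while stack:
                cur = stack.pop()
                if cur == start:
                    raise ValueError(f"cyclic parentage involving {start!r}")
                if cur in seen:
                    continue
                seen.add(cur)
                stack.extend(parents[cur])
        return self

    @property
    def members_by_id(self) -> dict[str, PedigreeMember]:
        return {m.individual_id: m for m in self.individuals}

    def founders(self) -> list[str]:
        return [
            m.individual_id
            for m in self.individuals
            if m.father_id is None and m.mother_id is None
        ]

    def children_of(self, individual_id: str) -> list[str]:
        return [
            m.individual_id
            for m in self.individuals
            if individual_id in (m.father_id, m.mother_id)
        ]

    def parents_of(self, individual_id: str) -> list[str]:
        m = self.members_by_id[individual_id]
        return [p for p in (m.father_id, m.mother_id) if p is not None]

    def siblings_of(self, individual_id: str) -> list[str]:
        """Individuals sharing >= 1 recorded parent (full and half sibs alike)."""
        mine = set(self.parents_of(individual_id))
        if not mine:
            return []
        return [
            m.individual_id
            for m in self.individuals
            if m.individual_id != individual_id
            and mine & {p for p in (m.father_id, m.mother_id) if p is not None}
        ]

    def first_degree_relatives(self, individual_id: str) -> list[str]:
        rel = (
            self.parents_of(individual_id)
            + self.siblings_of(individual_id)
            + self.children_of(individual_id)
        )
        out: list[str] = []
        for r in rel:  # preserve order, drop duplicates
            if r not in out:
                out.append(r)
        return out


class AnnotationRecord(BaseModel):
    """One annotated alternate allele (multi-allelics split upstream).

    Coordinates are GRCh38, 1-based.  ``af_by_source`` maps a population
    database name to the allele frequency observed there; a source in which
    the variant was not observed is simply absent from the map.
    """

    variant_id: str
    chrom: str
    pos: int = Field(gt=0)
    ref: str = Field(min_length=1)
    alt: str = Field(min_length=1)
    gene: str
    hgvs_c: str = ""
    hgvs_p: Optional[str] = None
    af_by_source: dict[str, float] = Field(default_factory=dict)
    predictor_calls: dict[str, PredictorCall] = Field(default_factory=dict)
    conservation_scores: dict[str, float] = Field(default_factory=dict)
    clinvar_assertion: ClinvarAssertion = ClinvarAssertion.not_reported
    hgmd_id: Optional[str] = None
    zygosity: Zygosity = Zygosity.het
    is_null_variant: bool = False

    @field_validator("af_by_source")
    @classmethod
    def _af_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for src, af in v.items():
            if not (0.0 <= af <= 1.0) or math.isnan(af):
                raise ValueError(f"allele frequency for {src!r} outside [0,1]: {af}")
        return v

    @property
    def max_af(self) -> Optional[float]:
        """Highest frequency across sources (popmax-like); None if unobserved."""
        return max(self.af_by_source.values()) if self.af_by_source else None

    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def allele_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)
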