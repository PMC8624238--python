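"""ACMG/AMP 2015 variant classification as a deterministic rule engine.

Evidence items are coded by strength category — PVS (very strong), PS
(strong), PM (moderate), PP (supporting) on the pathogenic side; BA
(stand-alone), BS (strong), BP (supporting) on the benign side — and
combined by fixed rules into one of five classes.  The combining table is
shipped as data (``data/acmg_rules.yaml``): each rule is a conjunction of
minimum category counts, classes are evaluated strongest first, and the
final class depends only on the per-category count vector.  Evidence
reaching both sides, or neither, yields uncertain significance.

Only mechanically computable codes are auto-assigned from an annotation
record (frequency codes BA1/PM2, in-silico codes PP3/BP4, same-residue
codes PS1/PM5, and PVS1 from an explicit null-variant flag); everything
requiring clinical judgment must be supplied by the user.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .config import AcmgConfig, FilterConfig
from .models import AnnotationRecord, ClinvarAssertion
from .varfilter import Consensus, predictor_consensus

CATEGORIES = ("pvs", "ps", "pm", "pp", "ba", "bs", "bp")
_PATHOGENIC_CATEGORIES = ("pvs", "ps", "pm", "pp")
_BENIGN_CATEGORIES = ("ba", "bs", "bp")

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)\d*$")


class AcmgClassification(str, enum.Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    uncertain_significance = "uncertain_significance"
    likely_benign = "likely_benign"
    benign = "benign"


@dataclass(frozen=True)
class EvidenceSet:
    """Active ACMG codes plus the per-category count vector they imply."""

    codes: frozenset[str]

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "EvidenceSet":
        norm = frozenset(c.upper() for c in codes)
        for c in norm:
            if not _CODE_RE.match(c):
                raise ValueError(f"unrecognised ACMG code {c!r}")
        return cls(codes=norm)

    @property
    def counts(self) -> dict[str, int]:
        counts = {cat: 0 for cat in CATEGORIES}
        for code in self.codes:
            for cat in ("PVS", "BA", "BS", "BP", "PS", "PM", "PP"):
                if code.startswith(cat):
                    counts[cat.lower()] += 1
                    break
        return counts


@dataclass
class AcmgClass:
    classification: AcmgClassification
    rationale: str


class RuleTableError(ValueError):
    pass


RuleTable = dict[str, list[dict[str, int]]]


def load_rule_table(path: Optional[Union[str, Path]] = None) -> RuleTable:
    """Load the combining-rule table (the packaged 2015 table by default)."""
    p = Path(path) if path else Path(
        str(resources.files("fhdx").joinpath("data", "acmg_rules.yaml"))
    )
    with open(p, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    expected = {"pathogenic", "likely_pathogenic", "benign", "likely_benign"}
    if not isinstance(raw, dict) or set(raw) != expected:
        raise RuleTableError(f"rule table must define exactly the classes {sorted(expected)}")
    for cls_name, rules in raw.items():
        side = _PATHOGENIC_CATEGORIES if "pathogenic" in cls_name else _BENIGN_CATEGORIES
        if not isinstance(rules, list) or not rules:
            raise RuleTableError(f"class {cls_name!r} needs a non-empty rule list")
        for rule in rules:
            if not rule or any(cat not in side for cat in rule):
                raise RuleTableError(f"rule {rule!r} under {cls_name!r} uses invalid categories")
            if any(not isinstance(v, int) or v < 1 for v in rule.values()):
                raise RuleTableError(f"rule {rule!r} counts must be positive integers")
    return raw


def _satisfies(counts: dict[str, int], rule: dict[str, int]) -> bool:
    return all(counts.get(cat, 0) >= n for cat, n in rule.items())


def _rule_name(cls_name: str, rule: dict[str, int]) -> str:
    parts = "+".join(f"{n}{cat.upper()}" for cat, n in rule.items())
    return f"{cls_name}[{parts}]"


def classify_acmg(
    evidence: EvidenceSet, rules: Optional[RuleTable] = None
) -> AcmgClass:
    table = rules if rules is not None else load_rule_table()
    counts = evidence.counts

    def first_match(class_names: Sequence[str]) -> Optional[tuple[str, dict[str, int]]]:
        for cls_name in class_names:
            for rule in table[cls_name]:
                if _satisfies(counts, rule):
                    return cls_name, rule
        return None

    path_hit = first_match(["pathogenic", "likely_pathogenic"])
    benign_hit = first_match(["benign", "likely_benign"])

    if path_hit and benign_hit:
        return AcmgClass(AcmgClassification.uncertain_significance, "conflicting")
    if path_hit is None and benign_hit is None:
        return AcmgClass(AcmgClassification.uncertain_significance, "insufficient")
    cls_name, rule = path_hit or benign_hit  # type: ignore[misc]
    return AcmgClass(AcmgClassification(cls_name), _rule_name(cls_name, rule))


_MISSENSE_RE = re.compile(r"^p\.([A-Za-z]{3})(\d+)([A-Za-z]{3})$")


def _residue(hgvs_p: Optional[str]) -> Optional[tuple[int, str, str]]:
    """(position, ref aa, alt aa) from a p.Xxx123Yyy missense description."""
    if not hgvs_p:
        return None
    m = _MISSENSE_RE.match(hgvs_p)
    if not m or m.group(3) in ("Ter",):
        return None
    return int(m.group(2)), m.group(1), m.group(3)


def auto_evidence(
    record: AnnotationRecord,
    known_table: Sequence[AnnotationRecord],
    config: Optional[AcmgConfig] = None,
    filter_config: Optional[FilterConfig] = None,
) -> EvidenceSet:
    """Assign the mechanically computable ACMG codes for one record.

    BA1   max population frequency above the stand-alone benign threshold;
    PM2   absent from, or ultra-rare in, every population source;
    PP3 / BP4   predictor consensus damaging / benign-leaning;
    PS1   same amino-acid change as a known pathogenic entry;
    PM5   different missense at a residue with a known pathogenic missense
          (suppressed when PS1 fires: one observation, one code);
    PVS1  explicit null-variant flag on the record.
    """
    cfg = config or AcmgConfig()
    codes: set[str] = set()

    max_af = record.max_af
    if max_af is not None and max_af > cfg.ba1_af_threshold:
        codes.add("BA1")
    if max_af is None or max_af < cfg.pm2_af_threshold:
        codes.add("PM2")

    verdict = predictor_consensus(record, filter_config)
    if verdict == Consensus.damaging:
        codes.add("PP3")
    elif verdict == Consensus.benign_leaning:
        codes.add("BP4")

    if record.is_null_variant:
        codes.add("PVS1")

    mine = _residue(record.hgvs_p)
    for known in known_table:
        if known.clinvar_assertion not in (
            ClinvarAssertion.pathogenic,
            ClinvarAssertion.likely_pathogenic,
        ):
            continue
        if known.gene != record.gene:
            continue
        if known.allele_key() == record.allele_key():
            continue  # the record itself is not evidence about itself
        theirs = _residue(known.hgvs_p)
        if record.hgvs_p and known.hgvs_p == record.hgvs_p:
            codes.add("PS1")
        elif mine and theirs and mine[0] == theirs[0] and mine[2] != theirs[2]:
            codes.add("PM5")
    if "PS1" in codes:
        codes.discard("PM5")

    return EvidenceSet.from_codes(codes)
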