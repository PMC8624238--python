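"""Rarity / assertion / predictor filter cascade and candidate ordering."""

import numpy as np
import pytest

from fhdx.config import FilterConfig
from fhdx.models import AnnotationRecord, ClinvarAssertion, PredictorCall
from fhdx.varfilter import (
    Consensus,
    apply_filter_cascade,
    conservation_percentile,
    predictor_consensus,
    prioritize_candidates,
)


def rec(variant_id="v", chrom="1", pos=100, ref="A", alt="G", **over):
    base = dict(variant_id=variant_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene="LDLR")
    base.update(over)
    return AnnotationRecord(**base)


class TestConservationPercentile:
    def test_above_all_references(self):
        refs = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        assert conservation_percentile(0.9, refs) == 1.0

    def test_all_ties_give_midrank_half(self):
        assert conservation_percentile(0.5, [0.5] * 6) == 0.5

    def test_below_all_references(self):
        assert conservation_percentile(0.3, [0.4, 0.5, 0.6, 0.7, 0.8]) == 0.0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            conservation_percentile(0.5, [])

    def test_non_decreasing_in_score(self):
        rng = np.random.default_rng(5)
        refs = list(rng.uniform(0, 1, size=40))
        scores = np.sort(rng.uniform(0, 1, size=50))
        pcts = [conservation_percentile(float(s), refs) for s in scores]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))


class TestPredictorConsensus:
    def test_unanimous_damaging_and_conserved(self):
        r = rec(
            predictor_calls={f"t{i}": PredictorCall.damaging for i in range(4)},
            conservation_scores={"phastcons": 0.9},
        )
        assert predictor_consensus(r) == Consensus.damaging

    def test_no_calls_is_indeterminate(self):
        assert predictor_consensus(rec()) == Consensus.indeterminate

    def test_minority_damaging_leans_benign(self):
        calls = {"t0": PredictorCall.damaging}
        calls.update({f"t{i}": PredictorCall.tolerated for i in range(1, 4)})
        assert predictor_consensus(rec(predictor_calls=calls)) == Consensus.benign_leaning

    def test_damaging_requires_conservation_support(self):
        r = rec(predictor_calls={f"t{i}": PredictorCall.damaging for i in range(4)})
        assert predictor_consensus(r) == Consensus.indeterminate

    def test_reference_distribution_route(self):
        r = rec(
            predictor_calls={"t0": PredictorCall.damaging},
            conservation_scores={"gerp": 5.1},
        )
        refs = {"gerp": [0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 4.5, 4.8, 5.0, 6.0]}
        # 5.1 beats 9/10 reference scores -> conserved at the 0.7 threshold
        assert predictor_consensus(r, reference_scores=refs) == Consensus.damaging


class TestFilterCascade:
    def test_rare_gnomad_variant_passes_rarity(self):
        r = rec(variant_id="rs145164937", gene="ABCG5",
                af_by_source={"gnomad": 0.002223})
        report = apply_filter_cascade([r])
        assert report.surviving == [r]

    def test_common_variant_dropped_at_rarity(self):
        r = rec(af_by_source={"gnomad": 0.02})
        report = apply_filter_cascade([r])
        assert report.surviving == []
        assert report.audit[r.allele_key()] == "rarity"

    def test_benign_assertion_dropped_with_audit(self):
        r = rec(clinvar_assertion=ClinvarAssertion.benign)
        report = apply_filter_cascade([r])
        assert report.surviving == []
        assert report.audit[r.allele_key()] == "assertion"

    def test_empty_input(self):
        report = apply_filter_cascade([])
        assert report.input_count == 0
        assert report.step_counts == [("rarity", 0), ("assertion", 0)]

    def test_absent_frequency_counts_as_novel(self):
        report = apply_filter_cascade([rec(variant_id="novel")])
        assert len(report.surviving) == 1

    def _random_records(self, rng, n):
        out = []
        for i in range(n):
            af = {}
            for src in ("gnomad", "gme", "abraom"):
                if rng.random() < 0.6:
                    af[src] = float(rng.uniform(0, 0.02))
            out.append(rec(
                variant_id=f"v{i}", pos=100 + i,
                af_by_source=af,
                clinvar_assertion=list(ClinvarAssertion)[
                    int(rng.integers(0, len(ClinvarAssertion)))
                ],
            ))
        return out

    def test_matches_per_record_oracle(self):
        """Survivors equal a brute-force re-evaluation of the rarity and
        assertion predicates record by record."""
        rng = np.random.default_rng(11)
        cfg = FilterConfig()
        for _ in range(20):
            records = self._random_records(rng, int(rng.integers(0, 21)))
            report = apply_filter_cascade(records, cfg)
            oracle = [
                r for r in records
                if max(r.af_by_source.values(), default=0.0) < cfg.rare_af_threshold
                and r.clinvar_assertion
                not in (ClinvarAssertion.benign, ClinvarAssertion.likely_benign)
            ]
            assert report.surviving == oracle

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(13)
        records = self._random_records(rng, 20)
        report = apply_filter_cascade(records)
        again = apply_filter_cascade(report.surviving)
        assert again.surviving == report.surviving
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert {r.allele_key() for r in apply_filter_cascade(shuffled).surviving} == {
            r.allele_key() for r in report.surviving
        }

    def test_audit_partitions_input(self):
        rng = np.random.default_rng(19)
        records = self._random_records(rng, 20)
        report = apply_filter_cascade(records)
        assert len(report.audit) == report.input_count
        dropped = sum(1 for v in report.audit.values() if v != "retained")
        assert dropped + len(report.surviving) == report.input_count


class TestPrioritize:
    def test_clinvar_pathogenic_before_novel_damaging(self):
        novel = rec(
            variant_id="novel", pos=200,
            predictor_calls={"t": PredictorCall.damaging},
            conservation_scores={"c": 0.9},
        )
        asserted = rec(variant_id="rs1", pos=100,
                       clinvar_assertion=ClinvarAssertion.pathogenic)
        report = apply_filter_cascade([novel, asserted])
        ordered = prioritize_candidates(report, [])
        assert [r.variant_id for r in ordered] == ["rs1", "novel"]

    def test_known_site_outranks_novel_missense(self):
        # different substitution at a site with a described pathogenic allele
        # ranks above a first-time variant with damaging consensus
        site_match = rec(variant_id="c266", chrom="19", pos=11213415,
                         ref="G", alt="C", hgvs_p="p.Cys89Ser")
        novel = rec(
            variant_id="novel", chrom="19", pos=11222252, ref="T", alt="G",
            hgvs_p="p.Tyr375Asp",
            predictor_calls={"t": PredictorCall.damaging},
            conservation_scores={"c": 0.9},
        )
        known = [rec(variant_id="rs875989894", chrom="19", pos=11213415,
                     ref="G", alt="A", hgvs_p="p.Cys89Tyr",
                     clinvar_assertion=ClinvarAssertion.pathogenic)]
        report = apply_filter_cascade([novel, site_match])
        ordered = prioritize_candidates(report, known)
        assert [r.variant_id for r in ordered] == ["c266", "novel"]

    def test_empty_survivors(self):
        assert prioritize_candidates(apply_filter_cascade([]), []) == []
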