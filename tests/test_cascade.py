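"""Cascade planning, cohort summaries and Mendelian transmission."""

import numpy as np
import pytest
from scipy import stats

from fhdx.cascade import (
    crosstab_dlcn_by_result,
    percent,
    propose_cascade,
    round_half_up,
    simulate_transmission,
    summarize_cohort,
)
from fhdx.models import (
    DlcnBand,
    GeneticResult,
    GeneticStatus,
    Pedigree,
    PedigreeMember,
    Sex,
)
from tests.test_io import make_subject

POS_LDLR = GeneticResult(status=GeneticStatus.positive, gene="LDLR", variant_ids=["rs1"])
NEG = GeneticResult(status=GeneticStatus.negative)


def family_pedigree() -> Pedigree:
    """Proband with two children, a sibling (shared founder father) and the
    sibling's child."""
    return Pedigree(
        family_id="FAM",
        individuals=[
            PedigreeMember(individual_id="GF", sex=Sex.M),
            PedigreeMember(individual_id="PRO", father_id="GF", sex=Sex.F),
            PedigreeMember(individual_id="K1", mother_id="PRO", sex=Sex.M),
            PedigreeMember(individual_id="K2", mother_id="PRO", sex=Sex.F),
            PedigreeMember(individual_id="SIB", father_id="GF", sex=Sex.M),
            PedigreeMember(individual_id="NEP", father_id="SIB", sex=Sex.M),
        ],
    )


class TestProposeCascade:
    def test_first_wave_is_untested_first_degree_relatives(self):
        plan = propose_cascade(family_pedigree(), "PRO", {"PRO": POS_LDLR})
        assert set(plan.waves[0]) == {"GF", "K1", "K2", "SIB"}

    def test_positive_sibling_pulls_in_nephew(self):
        plan = propose_cascade(
            family_pedigree(), "PRO", {"PRO": POS_LDLR, "SIB": POS_LDLR}
        )
        assert set(plan.waves[0]) == {"GF", "K1", "K2"}
        assert plan.waves[1] == ["NEP"]

    def test_no_relatives_no_waves(self):
        ped = Pedigree(family_id="F", individuals=[PedigreeMember(individual_id="X")])
        plan = propose_cascade(ped, "X", {})
        assert plan.waves == []

    def test_unknown_proband_rejected(self):
        with pytest.raises(ValueError, match="not in pedigree"):
            propose_cascade(family_pedigree(), "NOBODY", {})

    def test_waves_disjoint_and_reachable(self):
        """Property: waves never repeat an individual, and everyone proposed
        is one parent/child/sibling edge from a positive individual
        (graph-reachability oracle)."""
        ped = family_pedigree()
        results = {"PRO": POS_LDLR, "SIB": POS_LDLR, "K1": NEG}
        plan = propose_cascade(ped, "PRO", results)
        flat = [i for wave in plan.waves for i in wave]
        assert len(flat) == len(set(flat))
        assert "PRO" not in flat
        positives = {"PRO", "SIB"}
        for individual in flat:
            assert any(
                individual in ped.first_degree_relatives(p) for p in positives
            )


class TestSummarize:
    def _cohort(self, gene_counts, n_probands=60, children=(), n_extra_relatives=0):
        subjects = []
        i = 0
        genes = [g for g, c in gene_counts.items() for _ in range(c)]
        for k in range(n_probands):
            genetic = (
                GeneticResult(status=GeneticStatus.positive, gene=genes[k],
                              variant_ids=[f"rs{k}"])
                if k < len(genes) else NEG
            )
            subjects.append(make_subject(i, genetic_result=genetic))
            i += 1
        for status in children:
            subjects.append(make_subject(
                i, role="relative", relation_to_proband="child",
                genetic_result=GeneticResult(
                    status=GeneticStatus.positive, gene="LDLR", variant_ids=["rs9"])
                if status else NEG,
            ))
            i += 1
        for _ in range(n_extra_relatives):
            subjects.append(make_subject(
                i, role="relative", relation_to_proband="sibling", genetic_result=NEG))
            i += 1
        return subjects

    def test_per_gene_split_among_positive_probands(self):
        cohort = self._cohort({"LDLR": 19, "APOB": 3, "LPL": 1, "SREBF1": 1,
                               "APOC3": 1, "ABCG5": 1})
        s = summarize_cohort(cohort)
        assert s.n_variant_positive_probands == 26
        assert s.gene_split_probands["LDLR"].percent == 73.1
        assert s.gene_split_probands["APOB"].percent == 11.5
        assert s.gene_split_probands["other"].percent == 15.4

    def test_children_yield(self):
        cohort = self._cohort({"LDLR": 5}, children=[True] * 12 + [False] * 2)
        s = summarize_cohort(cohort)
        assert s.children_n == 14 and s.children_positive == 12
        assert s.children_percent == 85.7

    def test_zero_positive_cohort_has_undefined_percentages(self):
        s = summarize_cohort(self._cohort({}))
        assert s.n_variant_positive_subjects == 0
        assert s.gene_split_probands["LDLR"].percent is None
        assert "variant_positive_probands" in s.undefined_denominators

    def test_percentages_match_oracle(self):
        """Recomputing every reported percentage with a one-line oracle
        agrees to 0.1, and gene counts sum to the positive total."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            counts = {g: int(rng.integers(1, 10))
                      for g in ("LDLR", "APOB", "LPL", "PCSK9")}
            cohort = self._cohort(counts, n_probands=40)
            s = summarize_cohort(cohort)
            npos = sum(counts.values())
            assert s.n_variant_positive_probands == npos
            assert sum(y.count for y in s.per_gene_probands.values()) == npos
            for g, y in s.per_gene_probands.items():
                assert y.percent == pytest.approx(
                    round(100 * counts[g] / npos, 1), abs=0.1)


class TestCrosstab:
    def test_definite_band_breakdown(self):
        subjects = []
        i = 0
        for gene, n in (("LDLR", 26), ("APOB", 3)):
            for _ in range(n):
                subjects.append((make_subject(i, genetic_result=GeneticResult(
                    status=GeneticStatus.positive, gene=gene, variant_ids=["x"])),
                    DlcnBand.definite))
                i += 1
        for _ in range(5):
            subjects.append((make_subject(i, genetic_result=NEG), DlcnBand.definite))
            i += 1
        table, excluded = crosstab_dlcn_by_result(subjects)
        b = table[DlcnBand.definite]
        assert b.n == 34
        assert b.by_gene["LDLR"].percent == 76.5
        assert b.by_gene["APOB"].percent == 8.8
        assert b.negative_percent == 14.7
        assert excluded == 0

    def test_band_missing_subjects_counted_as_excluded(self):
        pairs = [(make_subject(0, genetic_result=NEG), None),
                 (make_subject(1, genetic_result=NEG), DlcnBand.probable)]
        table, excluded = crosstab_dlcn_by_result(pairs)
        assert excluded == 1
        assert table[DlcnBand.probable].n == 1

    def test_empty_cohort_gives_empty_table(self):
        table, excluded = crosstab_dlcn_by_result([])
        assert table == {} and excluded == 0


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (73.07, 73.1), (11.53, 11.5), (15.38, 15.4), (85.71, 85.7),
        (14.705, 14.7), (76.47, 76.5), (2.45, 2.5), (2.55, 2.6),
    ])
    def test_half_up_to_one_decimal(self, value, expected):
        assert round_half_up(value, 1) == expected

    def test_zero_denominator_is_undefined_not_zero(self):
        assert percent(0, 0) is None


class TestTransmission:
    def _fan_pedigree(self, n_children, two_parents=False):
        members = [PedigreeMember(individual_id="PA", sex=Sex.M),
                   PedigreeMember(individual_id="MA", sex=Sex.F)]
        for k in range(n_children):
            members.append(PedigreeMember(
                individual_id=f"C{k}", father_id="PA", mother_id="MA"))
        return Pedigree(family_id="F", individuals=members)

    def test_single_het_parent_transmits_half(self):
        n = 10_000
        ped = self._fan_pedigree(n)
        status = simulate_transmission(ped, {"PA": True}, seed=5)
        frac = sum(status[f"C{k}"] for k in range(n)) / n
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_no_carrier_founders_all_negative(self):
        ped = self._fan_pedigree(50)
        status = simulate_transmission(ped, {}, seed=1)
        assert not any(status.values())

    def test_two_het_parents_give_three_quarters(self):
        n = 10_000
        ped = self._fan_pedigree(n)
        status = simulate_transmission(ped, {"PA": True, "MA": True}, seed=9)
        carriers = sum(status[f"C{k}"] for k in range(n))
        # exact binomial test against p = 3/4 at alpha = 0.001
        p = stats.binomtest(carriers, n, 0.75).pvalue
        assert p > 0.001

    def test_non_founder_carrier_input_rejected(self):
        ped = self._fan_pedigree(2)
        with pytest.raises(ValueError, match="founder"):
            simulate_transmission(ped, {"C0": True}, seed=0)

    def test_deterministic_under_seed(self):
        ped = self._fan_pedigree(100)
        a = simulate_transmission(ped, {"PA": True}, seed=3)
        assert a == simulate_transmission(ped, {"PA": True}, seed=3)

    def test_mendelian_fraction_binomial_consistent(self):
        """Carrier fraction is consistent with Binomial(n, 1/2) at
        alpha = 0.001 for a fixed seed."""
        n = 10_000
        ped = self._fan_pedigree(n)
        status = simulate_transmission(ped, {"MA": True}, seed=12)
        carriers = sum(status[f"C{k}"] for k in range(n))
        assert stats.binomtest(carriers, n, 0.5).pvalue > 0.001
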