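import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import parasym as ps
from parasym.patterns import _runs_pmf, expected_exactly_one

from . import _oracles
from .conftest import POWER_TREE


class TestClustering:
    def test_enriched_domain_matches_hypergeometric_oracle(self):
        res = ps.clustering_test(
            "p", "copy1", {"dom": (10, 2), "rest": (3, 8)}
        )
        target = [r for r in res if r.domain_name == "dom"][0]
        # one-sided enrichment p by explicit tail enumeration
        a, b, c, d = 10, 2, 3, 8
        r1, c1, n = a + b, a + c, a + b + c + d
        oracle = sum(
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
            for x in range(a, min(r1, c1) + 1)
        )
        assert target.p_value == pytest.approx(oracle)
        assert target.clustered

    def test_empty_domain_not_clustered(self):
        res = ps.clustering_test("p", "copy1", {"a": (0, 0), "b": (5, 5)})
        empty = [r for r in res if r.domain_name == "a"][0]
        assert empty.p_value == pytest.approx(1.0)
        assert not empty.clustered

    def test_single_domain_rejected(self):
        with pytest.raises(ps.ParasymError, match=">= 2 domains"):
            ps.clustering_test("p", "copy1", {"only": (3, 3)})

    def test_fast_domain_detected_in_simulation(self):
        # one domain at 5x the background omega, equal-branch star where
        # parsimony ancestors are reliable
        layout = (("fast", 1, 250), ("slow", 251, 750))
        hits = 0
        for i in range(20):
            scen = ps.SimulationScenario(
                n_codons=750, seed=700 + i,
                t_by_branch={b: 0.45 for b in ("copy1", "copy2", "outgroup")},
                omega_by_branch={b: 0.2 for b in ("copy1", "copy2", "outgroup")},
                domain_layout=layout,
                omega_overrides={("fast", "copy1"): 1.0},
            )
            trio, _ = ps.simulate_trio(scen)
            counts = {}
            for name, start, end in layout:
                bc = ps.branch_counts(trio, columns=np.arange(start - 1, end))
                counts[name] = (
                    round(bc["copy1"].N), round(bc["copy1"].S)
                )
            res = ps.clustering_test("p", "copy1", counts)
            hits += [r for r in res if r.domain_name == "fast"][0].clustered
        assert hits >= 16

    def test_null_clustering_p_values_conservative(self):
        # uniform omega: pooled p-values stochastically >= uniform
        ps_all = []
        for i in range(12):
            scen = ps.SimulationScenario(
                n_codons=400, seed=800 + i, t_by_branch=POWER_TREE,
                omega_by_branch={b: 0.5 for b in ("copy1", "copy2", "outgroup")},
            )
            trio, _ = ps.simulate_trio(scen)
            counts = {}
            for name, lo, hi in (("a", 1, 200), ("b", 201, 400)):
                bc = ps.branch_counts(trio, columns=np.arange(lo - 1, hi))
                counts[name] = (round(bc["copy1"].N), round(bc["copy1"].S))
            ps_all += [r.p_value for r in ps.clustering_test("p", "copy1", counts)]
        assert np.mean(ps_all) >= 0.45


class TestAssortment:
    def test_exhaustive_expectation_three_proteins(self):
        # 3 proteins x 2 domains, 3 asymmetric: C(6,3)=20 assignments
        assert expected_exactly_one([2, 2, 2], 3) == pytest.approx(1.8)

    def test_expectation_matches_enumeration_oracle(self):
        # brute force over all C(8,3) assignments for domain counts [3,2,3]
        import itertools

        counts = [3, 2, 3]
        k = 3
        slots = [i for i, c in enumerate(counts) for _ in range(c)]
        total = 0
        acc = 0
        for combo in itertools.combinations(range(len(slots)), k):
            per = [0] * len(counts)
            for s in combo:
                per[slots[s]] += 1
            acc += sum(1 for v in per if v == 1)
            total += 1
        assert expected_exactly_one(counts, k) == pytest.approx(acc / total)

    def test_zero_asymmetric_domains(self):
        out = ps.assortment_analysis([[False, False], [False, False]])
        assert out["expected_exactly_one"] == 0.0
        assert math.isnan(out["ratio"])

    def test_seed_determinism(self):
        flags = [[True, False], [True, True, False], [False, False]]
        a = ps.assortment_analysis(flags, n_perms=500, seed=4)
        b = ps.assortment_analysis(flags, n_perms=500, seed=4)
        assert a == b

    def test_permutation_close_to_enumeration(self):
        flags = [[True, False], [True, False, True], [False, False, False]]
        out = ps.assortment_analysis(flags, n_perms=4000, seed=1)
        assert out["expected_exactly_one"] == pytest.approx(
            expected_exactly_one([2, 3, 3], 3)
        )


class TestConcordance:
    def test_all_same_copy_concordant(self):
        assert ps.faster_copy_concordance([["copy1", "copy1", "copy1"]]) == 1.0

    def test_split_copies_discordant(self):
        assert ps.faster_copy_concordance([["copy1", "copy2"]]) == 0.0

    def test_single_domain_pairs_ignored(self):
        frac = ps.faster_copy_concordance([["copy1"], ["copy2", "copy2"]])
        assert frac == 1.0

    def test_no_eligible_pairs_rejected(self):
        with pytest.raises(ps.ParasymError):
            ps.faster_copy_concordance([["copy1"]])


class _FakeDsa:
    def __init__(self, name, sig):
        self.domain_name = name
        self.significant = sig


class TestFamilyFrequency:
    def test_hypergeometric_tails(self):
        results = [_FakeDsa("homeo", False)] * 19
        results += [_FakeDsa("other", True)] * 353 + [_FakeDsa("other", False)] * (
            1113 - 19 - 353
        )
        out = {f.domain_name: f for f in ps.family_asymmetry_frequency(results)}
        homeo = out["homeo"]
        assert homeo.n_tested == 19 and homeo.n_asymmetric == 0
        assert homeo.p_under == pytest.approx(
            stats.hypergeom.cdf(0, 1113, 353, 19)
        )

    def test_family_at_pool_fraction_unremarkable(self):
        results = [_FakeDsa("f", True)] * 2 + [_FakeDsa("f", False)] * 8
        results += [_FakeDsa("g", True)] * 20 + [_FakeDsa("g", False)] * 80
        out = {f.domain_name: f for f in ps.family_asymmetry_frequency(results)}
        assert out["f"].p_over > 0.2 and out["f"].p_under > 0.2

    def test_saturated_family_overrepresented(self):
        results = [_FakeDsa("hot", True)] * 5
        results += [_FakeDsa("bg", True)] * 5 + [_FakeDsa("bg", False)] * 90
        out = {f.domain_name: f for f in ps.family_asymmetry_frequency(results)}
        assert out["hot"].p_over < 0.001


class TestRunsTest:
    def test_two_runs_example(self):
        runs, p = ps.interleaving_runs_test(list("111222"))
        assert runs == 2
        assert p == pytest.approx(0.1)

    def test_maximal_interleaving(self):
        runs, p = ps.interleaving_runs_test(list("121212"))
        assert runs == 6
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 2), (5, 5)])
    def test_pmf_matches_enumeration_oracle(self, n1, n2):
        pmf = _runs_pmf(n1, n2)
        oracle = _oracles.runs_distribution_oracle(n1, n2)
        assert set(pmf) == set(oracle)
        for r, frac in oracle.items():
            assert pmf[r] == pytest.approx(float(frac))

    def test_single_label_kind_rejected(self):
        with pytest.raises(ps.ParasymError):
            ps.interleaving_runs_test(list("1111"))

    def test_normal_approximation_reasonable(self):
        labels = list("1" * 15 + "2" * 15)
        runs, p = ps.interleaving_runs_test(labels)
        assert runs == 2
        assert p < 1e-6


class TestStouffer:
    def test_two_gene_closed_form(self):
        p1, p2 = 0.03, 0.2
        z1, z2 = stats.norm.isf(p1), stats.norm.isf(p2)
        expected = stats.norm.sf((z1 + z2) / math.sqrt(2))
        assert ps.stouffer_combine([p1, p2]) == pytest.approx(expected)

    def test_single_p_identity(self):
        assert ps.stouffer_combine([0.07]) == pytest.approx(0.07)
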