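import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import parasym as ps
from parasym.asymmetry import (
    faster_copy_from_table,
    region_columns,
    round_half_away,
)

from . import _oracles
from .conftest import POWER_TREE, make_trio


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 0, 0, 1), 1.0),
            ((2, 0, 0, 2), 1 / 3),
            ((10, 5, 10, 5), 1.0),
        ],
    )
    def test_enumeration_examples(self, table, expected):
        assert ps.fisher_exact_2x2(*table) == pytest.approx(expected)

    def test_empty_table_warns_p_one(self):
        with pytest.warns(UserWarning, match="empty"):
            assert ps.fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ps.ParasymError):
            ps.fisher_exact_2x2(-1, 0, 0, 1)
        with pytest.raises(ps.ParasymError):
            ps.fisher_exact_2x2(1.5, 0, 0, 1)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8),
           st.integers(0, 8))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert ps.fisher_exact_2x2(a, b, c, d) == pytest.approx(
            _oracles.fisher_exact_oracle(a, b, c, d)
        )

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(0, 10))
    def test_row_swap_invariance_and_faster_flip(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert ps.fisher_exact_2x2(a, b, c, d) == pytest.approx(
            ps.fisher_exact_2x2(c, d, a, b)
        )
        flip = {"copy1": "copy2", "copy2": "copy1", "tie": "tie"}
        assert faster_copy_from_table(c, d, a, b) == flip[
            faster_copy_from_table(a, b, c, d)
        ]


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(12.4, 12), (3.5, 4), (10.1, 10), (9.8, 10), (0.0, 0)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


def _stat(N, S):
    return ps.BranchStat(N, S, 100.0, 50.0, 0.1, 0.5)


def _bc(n1, s1, n2, s2):
    return ps.BranchCounts(
        "x",
        {"copy1": _stat(n1, s1), "copy2": _stat(n2, s2),
         "outgroup": _stat(1, 1)},
        100,
    )


class TestBuildTable:
    def test_wpa_rounding_example(self):
        bc = _bc(12.4, 10.1, 3.2, 9.8)
        assert ps.build_table(bc, level="WPA") == (12, 10, 3, 10)

    def test_dsa_uses_whole_protein_synonymous_background(self):
        whole = _bc(50, 40, 30, 45)
        region = _bc(10, 1, 2, 1)
        assert ps.build_table(whole, "DSA", region) == (10, 40, 2, 45)

    def test_region_background_switch(self):
        whole = _bc(50, 40, 30, 45)
        region = _bc(10, 1, 2, 1)
        assert ps.build_table(whole, "CDA", region, background="region") == (
            10, 1, 2, 1
        )

    def test_domain_spanning_protein_equals_wpa(self, null_trio):
        arch = ps.DomainArchitecture(
            "p", (("ALL", 1, null_trio.n_columns),)
        )
        whole = ps.branch_counts(null_trio)
        cols = region_columns(arch, null_trio.n_columns, "DSA", "ALL")
        region = ps.branch_counts(null_trio, columns=cols)
        assert ps.build_table(whole, "DSA", region) == ps.build_table(
            whole, level="WPA"
        )

    def test_empty_region_rejected(self):
        arch = ps.DomainArchitecture("p", (("A", 1, 10),))
        with pytest.raises(ps.ParasymError, match="empty region"):
            region_columns(arch, 10, "LINKER")


class TestBhFdr:
    def test_step_up_with_monotonization(self):
        assert ps.bh_fdr([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])

    def test_single_p_unchanged(self):
        assert ps.bh_fdr([0.2]) == [pytest.approx(0.2)]

    def test_equal_ps_unchanged(self):
        assert ps.bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_empty(self):
        assert ps.bh_fdr([]) == []

    def test_q_at_least_p(self, rng):
        p = rng.random(30)
        q = ps.bh_fdr(list(p))
        assert np.all(np.asarray(q) >= p - 1e-12)


class TestTestAsymmetry:
    def test_strong_pair_among_nulls_flagged(self):
        pairs = []
        for i in range(8):
            scen = ps.SimulationScenario(n_codons=1000, seed=300 + i,
                                         t_by_branch=POWER_TREE)
            trio, _ = ps.simulate_trio(scen, pair_id=f"null{i}")
            pairs.append((trio, None))
        scen = ps.SimulationScenario(
            n_codons=1000, seed=999, t_by_branch=POWER_TREE,
            omega_by_branch={"copy1": 1.5, "copy2": 0.2, "outgroup": 0.5},
        )
        trio, _ = ps.simulate_trio(scen, pair_id="hot")
        pairs.append((trio, None))
        results = ps.test_asymmetry(pairs, "WPA", fdr=0.10)
        hot = [r for r in results if r.pair_id == "hot"][0]
        assert hot.significant and hot.faster_copy == "copy1"

    def test_opposite_domain_asymmetry_found_by_dsa_not_cda(self):
        layout = (("domA", 1, 200), ("domB", 301, 500))
        scen = ps.SimulationScenario(
            n_codons=500, seed=1,
            t_by_branch={"copy1": 0.45, "copy2": 0.45, "outgroup": 0.9},
            omega_by_branch={b: 0.1 for b in ("copy1", "copy2", "outgroup")},
            domain_layout=layout,
            omega_overrides={("domA", "copy1"): 2.0, ("domB", "copy2"): 2.0},
        )
        trio, _ = ps.simulate_trio(scen, pair_id="opp")
        arch = ps.DomainArchitecture("opp", layout)
        dsa = ps.test_asymmetry([(trio, arch)], "DSA", fdr=0.10)
        cda = ps.test_asymmetry([(trio, arch)], "CDA", fdr=0.10)
        assert dsa[0].significant and dsa[1].significant
        assert {dsa[0].faster_copy, dsa[1].faster_copy} == {"copy1", "copy2"}
        assert not cda[0].significant

    def test_copy_swap_flips_faster_keeps_p(self, asymmetric_trio):
        t = asymmetric_trio
        swapped = ps.CodonTrioAlignment(t.pair_id, t.seq_copy2, t.seq_copy1,
                                        t.seq_outgroup)
        r1 = ps.test_asymmetry([(t, None)], "WPA")[0]
        r2 = ps.test_asymmetry([(swapped, None)], "WPA")[0]
        assert r1.p_value == pytest.approx(r2.p_value)
        assert {r1.faster_copy, r2.faster_copy} == {"copy1", "copy2"}


class TestBootstrap:
    def test_identical_sequences_zero_support(self):
        trio = make_trio("ATGTTTGGGCCC" * 5, "ATGTTTGGGCCC" * 5,
                         "ATGTTTGGGCCC" * 5)
        assert ps.bootstrap_support(trio, n_reps=20, seed=0) == 0.0

    def test_seed_determinism(self, asymmetric_trio):
        a = ps.bootstrap_support(asymmetric_trio, n_reps=30, seed=7)
        b = ps.bootstrap_support(asymmetric_trio, n_reps=30, seed=7)
        assert a == b

    def test_strong_asymmetric_pair_high_support(self, asymmetric_trio):
        assert ps.bootstrap_support(asymmetric_trio, n_reps=100, seed=1) >= 0.8


class TestSampledWpaControl:
    def test_full_length_equals_wpa(self, asymmetric_trio):
        bc = ps.branch_counts(asymmetric_trio)
        p_wpa = ps.fisher_exact_2x2(*ps.build_table(bc, level="WPA"))
        frac = ps.sampled_wpa_control(
            asymmetric_trio, asymmetric_trio.n_columns, n_reps=10, seed=3
        )
        assert frac == (1.0 if p_wpa <= 0.05 else 0.0)

    def test_seed_determinism(self, asymmetric_trio):
        a = ps.sampled_wpa_control(asymmetric_trio, 200, n_reps=20, seed=5)
        b = ps.sampled_wpa_control(asymmetric_trio, 200, n_reps=20, seed=5)
        assert a == b

    def test_power_declines_with_shorter_subsets(self, asymmetric_trio):
        long_frac = ps.sampled_wpa_control(asymmetric_trio, 800, n_reps=40, seed=2)
        short_frac = ps.sampled_wpa_control(asymmetric_trio, 60, n_reps=40, seed=2)
        assert short_frac <= long_frac

    def test_invalid_length_rejected(self, asymmetric_trio):
        with pytest.raises(ps.ParasymError):
            ps.sampled_wpa_control(asymmetric_trio, 0, n_reps=5, seed=1)
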