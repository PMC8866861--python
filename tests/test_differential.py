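import itertools

import numpy as np
import pandas as pd
import pytest

from stressdecomp.design import DEFAULT_DESIGN
from stressdecomp.differential import (
    Decomposition,
    DifferentialResult,
    bh_adjust,
    call_arm,
    decompose,
    exact_mw_matrix,
    fc_filter,
    mann_whitney,
)
from stressdecomp.errors import DataValidationError
from stressdecomp.pipeline import normalize
from stressdecomp.preprocess import FoldChangeTable, fold_changes
from stressdecomp.synthetic import TruthSpec, generate_expression


def brute_force_mw(a, b):
    """Independent oracle: enumerate every labeling, score by pairwise counts.

    The statistic is U of the first group computed directly as
    #(a_i > b_j) + 0.5 * #(a_i == b_j) -- no ranks involved. Two-sided
    p doubles the smaller of the two inclusive tails.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n, n_a = len(pooled), len(a)

    def u_of(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(a, b)
    dist = []
    for idx in itertools.combinations(range(n), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        dist.append(u_of(ga, gb))
    dist = np.array(dist)
    p_low = np.mean(dist <= u_obs)
    p_high = np.mean(dist >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))


class TestMannWhitney:
    def test_all_ties_p_one(self):
        u, p = mann_whitney([5, 5, 5], [5] * 12)
        assert p == 1.0
        assert u == pytest.approx(3 * 12 / 2)

    def test_spec_example_extreme_separation(self):
        # a=(1,2,3) below every b value: 455 labelings, two-sided p = 2/455
        u, p = mann_whitney([1, 2, 3], list(range(4, 16)))
        assert u == 0.0
        assert p == pytest.approx(2 / 455, abs=1e-15)

    def test_exact_equals_brute_force_small(self, rng):
        for _ in range(100):
            n_a = int(rng.integers(1, 6))
            n_b = int(rng.integers(1, 12 - n_a + 1))
            if rng.random() < 0.5:
                pool = rng.normal(size=n_a + n_b)
            else:
                pool = rng.integers(0, 4, size=n_a + n_b).astype(float)
            a, b = pool[:n_a], pool[n_a:]
            u_ref, p_ref = brute_force_mw(a, b)
            u, p = mann_whitney(a, b, mode="exact")
            assert u == pytest.approx(u_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-15)

    def test_empty_group_rejected(self):
        with pytest.raises(DataValidationError):
            mann_whitney([], [1.0])

    def test_auto_switches_to_approx(self):
        a = list(range(11))
        b = list(range(6, 17))
        _, p_exact = mann_whitney(a, b, mode="exact", exact_limit=22)
        _, p_auto = mann_whitney(a, b, mode="auto")  # 30 samples -> approx
        assert p_auto != p_exact
        assert 0 < p_auto <= 1

    def test_matrix_path_matches_scalar(self, rng):
        values = rng.normal(size=(25, 15))
        values[5, :] = 1.0  # constant row
        idx_a, idx_b = np.arange(3), np.arange(3, 15)
        u_vec, p_vec = exact_mw_matrix(values, idx_a, idx_b)
        for i in range(25):
            u, p = mann_whitney(values[i, :3], values[i, 3:], mode="exact")
            assert u_vec[i] == pytest.approx(u)
            assert p_vec[i] == pytest.approx(p, abs=1e-15)


class TestBHAdjust:
    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_computed_step_up(self):
        # p=(.01,.02,.03,.04), m=4: m*p/i = (.04,.04,.04,.04)
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_test_identity(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        p[:20] = rng.uniform(0, 0.01, size=20)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-14)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            bh_adjust([0.5, 1.5])


@pytest.fixture(scope="module")
def planted_run():
    spec = TruthSpec(
        proportions={"salt_up": 0.1, "salt_down": 0.1, "osmotic_up": 0.1, "osmotic_down": 0.1},
        effect=2.0,
        noise_sd=0.25,
    )
    es, truth = generate_expression(200, spec, seed=7)
    fc = fold_changes(es)
    norm = normalize(es)
    res_n = call_arm(norm, "NaCl", fc=fc, use_adjusted=False)
    res_s = call_arm(norm, "sorbitol", fc=fc, use_adjusted=False)
    return es, truth, fc, norm, res_n, res_s


class TestCallArm:
    def test_planted_salt_gene_called_up_in_nacl_only(self, planted_run):
        _, truth, _, _, res_n, res_s = planted_run
        salt_up = truth.genes_of("salt_up")
        frac_sig = np.mean([g in res_n.directed("up") for g in salt_up])
        assert frac_sig > 0.9
        frac_sorb = np.mean([g in res_s.significant for g in salt_up])
        assert frac_sorb < 0.1

    def test_constant_gene_p_one_direction_none(self, default_design):
        # a gene constant across samples z-scores to all-zero and must come
        # out with p = 1 and no direction
        spec = TruthSpec(noise_sd=0.3)
        es, _ = generate_expression(10, spec, seed=3)
        gene = es.genes[0]
        norm = normalize(es)
        norm.values[0, :] = 0.0
        res = call_arm(norm, "NaCl")
        assert res.table.loc[gene, "p"] == 1.0
        assert res.table.loc[gene, "direction"] == "none"

    def test_direction_none_iff_not_significant(self, planted_run):
        _, _, _, _, res_n, _ = planted_run
        tab = res_n.table
        assert ((tab["direction"] == "none") == ~tab["significant"]).all()

    def test_max_abs_fc_column_present(self, planted_run):
        _, _, fc, _, res_n, _ = planted_run
        expected = fc.arm_max_abs("NaCl")
        np.testing.assert_allclose(res_n.table["max_abs_log2fc"], expected)

    def test_missing_arm_rejected(self, planted_run):
        _, _, _, norm, _, _ = planted_run
        with pytest.raises(DataValidationError):
            call_arm(norm, "mannitol")


def _fake_result(arm, calls):
    """calls: gene -> direction or None."""
    genes = sorted(calls)
    table = pd.DataFrame(
        {
            "U": 0.0,
            "p": [0.001 if calls[g] else 0.5 for g in genes],
            "padj": [0.001 if calls[g] else 0.5 for g in genes],
            "significant": [calls[g] is not None for g in genes],
            "direction": [calls[g] or "none" for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return DifferentialResult(arm=arm, table=table, alpha=0.01, use_adjusted=True)


class TestDecompose:
    def test_set_algebra(self):
        res_a = _fake_result("NaCl", {"g1": "up", "g2": "down", "g3": None})
        res_b = _fake_result("sorbitol", {"g1": None, "g2": "down", "g3": "up"})
        dec = decompose(res_a, res_b)
        assert dec.salt_specific == {"g1"}
        assert dec.salt_specific_up == {"g1"}
        assert dec.osmotic == {"g2"}
        assert dec.osmotic_down == {"g2"}
        assert dec.sorbitol_only == {"g3"}
        assert dec.discordant == set()

    def test_identical_lists_empty_salt_specific(self):
        calls = {"g1": "up", "g2": "down"}
        dec = decompose(_fake_result("NaCl", calls), _fake_result("sorbitol", calls))
        assert dec.salt_specific == set()
        assert dec.osmotic == {"g1", "g2"}

    def test_discordant_follows_nacl_direction(self):
        res_a = _fake_result("NaCl", {"g1": "up"})
        res_b = _fake_result("sorbitol", {"g1": "down"})
        dec = decompose(res_a, res_b)
        assert dec.osmotic_up == {"g1"}
        assert dec.discordant == {"g1"}

    def test_partition_properties(self, planted_run):
        _, _, _, _, res_n, res_s = planted_run
        dec = decompose(res_n, res_s)
        a, b = res_n.significant, res_s.significant
        assert dec.salt_specific | dec.osmotic == a
        assert dec.salt_specific & dec.osmotic == set()
        assert dec.sorbitol_only == b - a
        assert len(dec.salt_specific) + len(dec.osmotic) == len(a)

    def test_mismatched_universe_rejected(self):
        res_a = _fake_result("NaCl", {"g1": "up"})
        res_b = _fake_result("sorbitol", {"g2": "up"})
        with pytest.raises(DataValidationError):
            decompose(res_a, res_b)

    def test_recovery_on_strong_effects(self):
        # balanced up/down planting: unbalanced planting at large effects
        # visibly distorts null genes through the shared quantile-normalization
        # reference, so recovery is only exact with the final two-fold filter
        spec = TruthSpec(
            proportions={
                "salt_up": 0.05, "salt_down": 0.05, "osmotic_up": 0.05, "osmotic_down": 0.05
            },
            effect=3.0,
            noise_sd=0.25,
        )
        es, truth = generate_expression(100, spec, seed=1)
        fc = fold_changes(es)
        norm = normalize(es)
        dec = decompose(
            call_arm(norm, "NaCl", fc=fc, use_adjusted=False),
            call_arm(norm, "sorbitol", fc=fc, use_adjusted=False),
        )
        dec = fc_filter(dec, fc)
        salt = dec.go_input["salt_specific_up"] | dec.go_input["salt_specific_down"]
        osmotic = dec.go_input["osmotic_up"] | dec.go_input["osmotic_down"]
        assert salt == truth.salt_specific
        assert osmotic == truth.osmotic


class TestFcFilter:
    def _dec(self, salt=(), osmotic=(), universe=()):
        return Decomposition(
            salt_specific_up=set(salt),
            salt_specific_down=set(),
            osmotic_up=set(osmotic),
            osmotic_down=set(),
            sorbitol_only=set(),
            discordant=set(),
            universe=list(universe),
        )

    def _fc(self, table):
        frame = pd.DataFrame(table).T
        frame.columns = ["NaCl-50", "NaCl-75", "sorbitol-100", "sorbitol-150"]
        return FoldChangeTable(
            log2fc=frame,
            arms={"NaCl": ["NaCl-50", "NaCl-75"], "sorbitol": ["sorbitol-100", "sorbitol-150"]},
        )

    def test_kept_at_1_1(self):
        fc = self._fc({"g1": [1.1, 0.5, 0.0, 0.0]})
        dec = fc_filter(self._dec(salt={"g1"}, universe=["g1"]), fc)
        assert dec.go_input["salt_specific_up"] == {"g1"}

    def test_below_threshold_removed(self):
        fc = self._fc({"g1": [0.9, -0.99, 0.5, 0.2]})
        dec = fc_filter(self._dec(salt={"g1"}, universe=["g1"]), fc)
        assert dec.go_input["salt_specific_up"] == set()

    def test_osmotic_passes_via_either_arm(self):
        fc = self._fc({"g1": [0.2, 0.3, 1.5, 0.1]})
        dec = fc_filter(self._dec(osmotic={"g1"}, universe=["g1"]), fc)
        assert dec.go_input["osmotic_up"] == {"g1"}

    def test_salt_gene_needs_nacl_arm(self):
        # large sorbitol fold change must not rescue a salt-specific gene
        fc = self._fc({"g1": [0.2, 0.3, 3.0, 0.1]})
        dec = fc_filter(self._dec(salt={"g1"}, universe=["g1"]), fc)
        assert dec.go_input["salt_specific_up"] == set()

    def test_threshold_guard(self):
        fc = self._fc({"g1": [1.1, 0.5, 0.0, 0.0]})
        with pytest.raises(DataValidationError):
            fc_filter(self._dec(salt={"g1"}, universe=["g1"]), fc, threshold=1.0)

    def test_subsets_of_parents(self, planted_run):
        _, _, fc, _, res_n, res_s = planted_run
        dec = fc_filter(decompose(res_n, res_s), fc)
        for name, genes in dec.go_input.items():
            assert genes <= getattr(dec, name)
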