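"""Brownian-motion simulation and the simulation-based phylogenetic ANOVA."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from csrpipe.origins import (
    balance_sensitivity,
    bonferroni,
    f_oneway_statistic,
    group_summary,
    phylo_anova,
    prepare_variables,
    run_comparison,
    simulate_bm,
)
from csrpipe.phylo import yule_tree


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


def star_tree(n, length=1.0, prefix="t"):
    s = "(" + ",".join(f"{prefix}{i}:{length}" for i in range(n)) + ");"
    return newick(s)


class TestSimulateBM:
    def test_two_cherry_moments_match_shared_path_lengths(self):
        tree = newick("(a:1,b:1);")
        vals, labels = simulate_bm(tree, sigma2=1.0, seed=5, size=10000)
        df = dict(zip(labels, vals.T))
        assert np.var(df["a"]) == pytest.approx(1.0, abs=0.05)
        assert np.var(df["b"]) == pytest.approx(1.0, abs=0.05)
        assert np.cov(df["a"], df["b"])[0, 1] == pytest.approx(0.0, abs=0.05)

    def test_shared_ancestry_induces_covariance(self):
        tree = newick("((a:1,b:1):2,c:3);")
        vals, labels = simulate_bm(tree, sigma2=2.0, seed=5, size=20000)
        df = dict(zip(labels, vals.T))
        # var = sigma2 * root-to-tip depth; cov(a,b) = sigma2 * shared path
        assert np.var(df["a"]) == pytest.approx(6.0, rel=0.05)
        assert np.cov(df["a"], df["b"])[0, 1] == pytest.approx(4.0, rel=0.08)
        assert abs(np.cov(df["a"], df["c"])[0, 1]) < 0.15

    def test_ultrametric_tip_variance_is_rate_times_depth(self):
        tree = yule_tree(12, [f"s{i}" for i in range(12)], seed=3)
        vals, _ = simulate_bm(tree, sigma2=3.0, seed=9, size=30000)
        # unit depth after rescaling: every tip variance = sigma2
        assert np.allclose(vals.var(axis=0), 3.0, rtol=0.06)

    def test_zero_length_pendants_are_identical(self):
        tree = newick("((a:0,b:0):1,c:1);")
        vals, labels = simulate_bm(tree, sigma2=1.0, seed=1, size=50)
        d = dict(zip(labels, vals.T))
        assert np.array_equal(d["a"], d["b"])

    def test_single_replicate_returns_mapping(self):
        tree = newick("(a:1,b:1);")
        out = simulate_bm(tree, 1.0, seed=0)
        assert set(out) == {"a", "b"}

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_bm(newick("(a:1,b:1);"), 0.0, seed=0)


class TestPhyloANOVA:
    def _data(self, n_a=6, n_b=6, shift=0.0, seed=0):
        tree = star_tree(n_a + n_b)
        rng = np.random.default_rng(seed)
        values = {f"t{i}": rng.normal(shift if i < n_a else 0.0, 1.0)
                  for i in range(n_a + n_b)}
        groups = {f"t{i}": ("alien" if i < n_a else "native") for i in range(n_a + n_b)}
        return values, groups, tree

    def test_scale_and_shift_invariance(self):
        values, groups, tree = self._data(shift=1.0)
        r1 = phylo_anova(values, groups, tree, n_sim=500, seed=42)
        r2 = phylo_anova({k: 10 * v + 3 for k, v in values.items()}, groups, tree,
                         n_sim=500, seed=42)
        assert r1.f_obs == pytest.approx(r2.f_obs)
        assert r1.p_sim == r2.p_sim

    def test_p_floor_is_one_over_nsim_plus_one(self):
        values, groups, tree = self._data(shift=50.0)
        res = phylo_anova(values, groups, tree, n_sim=199, seed=1)
        assert res.p_sim == pytest.approx(1 / 200)

    def test_small_groups_rejected(self):
        values, groups, tree = self._data()
        groups = dict(groups)
        lone = [k for k, g in groups.items() if g == "alien"]
        for k in lone[1:]:
            groups[k] = "native"
        with pytest.raises(ValueError, match="two groups"):
            phylo_anova(values, groups, tree, n_sim=99, seed=0)

    def test_star_tree_matches_iid_monte_carlo_oracle(self):
        """On a star phylogeny BM tips are iid: the phylogenetic p and a
        plain Monte-Carlo ANOVA p must agree within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        for rep in range(5):
            n = 24
            tree = star_tree(n)
            values = {f"t{i}": rng.normal(0.4 if i < 8 else 0.0, 1.0) for i in range(n)}
            groups = {f"t{i}": ("alien" if i < 8 else "native") for i in range(n)}
            res = phylo_anova(values, groups, tree, n_sim=4000, seed=100 + rep)
            codes = np.array([groups[f"t{i}"] for i in range(n)])
            obs = np.array([values[f"t{i}"] for i in range(n)])
            f_obs = f_oneway_statistic(obs[None, :], codes)[0]
            sims = rng.standard_normal((4000, n))
            f_sim = f_oneway_statistic(sims, codes)
            p_mc = (np.count_nonzero(f_sim >= f_obs) + 1) / 4001
            assert abs(res.p_sim - p_mc) < 0.05

    def test_power_under_large_shift(self):
        """Star tree, 60+20 tips, 2-SD group shift: rejection ≥ 90%."""
        tree = star_tree(80)
        groups = {f"t{i}": ("alien" if i < 20 else "native") for i in range(80)}
        rng = np.random.default_rng(11)
        rejections = 0
        for rep in range(100):
            values = {f"t{i}": rng.normal(2.0 if i < 20 else 0.0, 1.0)
                      for i in range(80)}
            res = phylo_anova(values, groups, tree, n_sim=199, seed=int(rng.integers(2**31)))
            rejections += res.p_sim <= 0.05
        assert rejections >= 90


class TestVariablePreparation:
    def test_log_rules(self):
        profiles = pd.DataFrame({
            "species_id": ["a", "b"], "la_mm2": [100.0, 1000.0],
            "ldmc_pct": [30.0, 40.0], "sla_mm2_mg": [10.0, 20.0]})
        scores = pd.DataFrame({
            "species_id": ["a", "b"], "c": [55.0, 20.0],
            "s": [45.0, 60.0], "r": [0.0, 20.0]})
        v = prepare_variables(profiles, scores)
        assert v["R"]["a"] == pytest.approx(0.0)  # ln(0 + 1)
        assert v["LA"]["a"] == pytest.approx(np.log(100))  # 4.60517...
        assert v["C"]["a"] == 55.0  # untransformed pass-through
        assert v["LDMC"]["b"] == 40.0
        assert v["SLA"]["b"] == pytest.approx(np.log(20))


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [
        (0.01, 3, 0.03),
        (0.5, 3, 1.0),
        (0.2, 1, 0.2),
    ])
    def test_adjustment(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 2)
        with pytest.raises(ValueError):
            bonferroni(0.2, 0)


class TestBalanceSensitivity:
    def test_balanced_input_repeats_full_analysis(self):
        tree = star_tree(8)
        rng = np.random.default_rng(0)
        values = {f"t{i}": rng.normal() for i in range(8)}
        groups = {f"t{i}": ("alien" if i < 4 else "native") for i in range(8)}
        ps = balance_sensitivity(values, groups, tree, n_resamples=5, seed=3, n_sim=199)
        assert len(set(ps)) == 1

    def test_zero_resamples_is_empty(self):
        tree = star_tree(6)
        values = {f"t{i}": float(i) for i in range(6)}
        groups = {f"t{i}": ("alien" if i < 3 else "native") for i in range(6)}
        assert balance_sensitivity(values, groups, tree, 0, seed=0).size == 0

    def test_null_data_resampled_p_overlaps_full_p(self):
        tree = star_tree(30)
        rng = np.random.default_rng(5)
        values = {f"t{i}": rng.normal() for i in range(30)}
        groups = {f"t{i}": ("alien" if i < 6 else "native") for i in range(30)}
        full = phylo_anova(values, groups, tree, n_sim=999, seed=1).p_sim
        ps = balance_sensitivity(values, groups, tree, n_resamples=20, seed=2, n_sim=499)
        assert ps.min() - 0.05 <= full <= ps.max() + 0.05


class TestGroupSummary:
    def test_single_member_group(self):
        scores = pd.DataFrame({"species_id": ["a", "b", "c"],
                               "c": [40.0, 60.0, 20.0],
                               "s": [60.0, 40.0, 50.0],
                               "r": [0.0, 0.0, 30.0]})
        med = group_summary(scores, {"a": "native", "b": "native", "c": "alien"})
        assert (med["alien"].c, med["alien"].s, med["alien"].r) == (20.0, 50.0, 30.0)

    def test_symmetric_pair_gives_midpoint(self):
        scores = pd.DataFrame({"species_id": ["a", "b"],
                               "c": [40.0, 60.0], "s": [60.0, 40.0], "r": [0.0, 0.0]})
        med = group_summary(scores, {"a": "native", "b": "native"})
        assert (med["native"].c, med["native"].s) == (50.0, 50.0)

    def test_matches_sort_median_oracle_before_reclosure(self, rng):
        n = 9
        raw = rng.dirichlet(np.ones(3), size=n) * 100
        scores = pd.DataFrame({"species_id": [f"s{i}" for i in range(n)],
                               "c": raw[:, 0], "s": raw[:, 1], "r": raw[:, 2]})
        med = group_summary(scores, {f"s{i}": "native" for i in range(n)})
        expect = np.median(raw, axis=0)
        expect = 100 * expect / expect.sum()
        assert (med["native"].c, med["native"].s, med["native"].r) == pytest.approx(
            tuple(expect))


def test_run_comparison_excludes_non_tree_species(default_dataset):
    """Species absent from the phylogeny are dropped from the ANOVA only."""
    from csrpipe.csr import score_table
    from csrpipe.phylo import prune_to, tip_labels
    from csrpipe.traits import aggregate_to_species

    ds = default_dataset
    profiles = aggregate_to_species(ds.leaf_table, ds.origins)
    scores = score_table(profiles)
    tips = tip_labels(ds.tree)
    # drop three native species from the tree (like excluding tree ferns)
    natives = [t for t in tips if ds.origins[t] == "native"]
    pruned = prune_to(ds.tree, set(tips) - set(natives[:3]))
    res = run_comparison(profiles, scores, pruned, ds.origins, n_sim=199, seed=5)
    assert set(res["variable"]) == {"C", "S", "R", "LA", "LDMC", "SLA"}
    assert (res["p_adjusted"] >= res["p_sim"] - 1e-12).all()
    assert ((res["p_sim"] >= 1 / 200) & (res["p_sim"] <= 1.0)).all()
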