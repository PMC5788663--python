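import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as scistats

from clonetrace import regnet, simulate
from clonetrace.regnet import CisWindow, PWM


def random_pwm(rng, name="TF", length=8, concentration=0.3):
    counts = rng.gamma(concentration, size=(4, length)) * 100
    return PWM.from_counts(name, counts, pseudocount=0.5)


def brute_force_affinity(pwm, window):
    """Naive per-position, per-strand scorer (independent oracle)."""
    seq = window.sequence.upper()
    mask = (window.accessible_mask if window.accessible_mask is not None
            else np.ones(len(seq), dtype=bool))
    L = pwm.length
    total = 0.0
    for mat in (pwm.matrix, pwm.reverse_complement().matrix):
        for i in range(len(seq) - L + 1):
            if not mask[i:i + L].all():
                continue
            lr = 1.0
            for j, base in enumerate(seq[i:i + L]):
                idx = "ACGT".find(base)
                lr *= mat[idx, j] / 0.25 if idx >= 0 else 1.0
            total += lr
    return total


class TestPwm:
    def test_normalization_and_shape(self):
        counts = np.array([[8, 0, 2, 1], [1, 9, 2, 1], [1, 0, 4, 1], [0, 1, 2, 7]],
                          dtype=float)
        pwm = PWM.from_counts("X", counts)
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0)
        assert pwm.length == 4
        with pytest.raises(ValueError):
            PWM.from_counts("bad", counts[:3])

    def test_reverse_complement_involution(self):
        pwm = random_pwm(np.random.default_rng(0))
        assert np.allclose(pwm.reverse_complement().reverse_complement().matrix,
                           pwm.matrix)

    def test_jaspar_round_trip(self, tmp_path):
        text = (">MA0001.1 TESTTF\n"
                "A  [ 4  19  0  0  0 ]\n"
                "C  [16   0 20  0  0 ]\n"
                "G  [ 0   1  0 20  0 ]\n"
                "T  [ 0   0  0  0 20 ]\n")
        p = tmp_path / "m.jaspar"
        p.write_text(text)
        pwms = regnet.read_jaspar(p)
        assert len(pwms) == 1 and pwms[0].length == 5
        assert np.allclose(pwms[0].matrix.sum(axis=0), 1.0)


class TestPromoterAffinity:
    def test_consensus_bounds_single_site_score(self):
        pwm = random_pwm(np.random.default_rng(1), length=6)
        consensus = "".join("ACGT"[i] for i in pwm.matrix.argmax(axis=0))
        site_lr = float(np.prod(pwm.matrix.max(axis=0) / 0.25))
        affinity = regnet.promoter_affinity(pwm, CisWindow("g", consensus))
        assert affinity >= site_lr

    def test_all_masked_is_zero(self):
        pwm = random_pwm(np.random.default_rng(2))
        w = CisWindow("g", "ACGTACGTACGT", accessible_mask=np.zeros(12, dtype=bool))
        assert regnet.promoter_affinity(pwm, w) == 0.0

    def test_short_sequence_warns_and_returns_zero(self):
        pwm = random_pwm(np.random.default_rng(3), length=8)
        with pytest.warns(UserWarning):
            assert regnet.promoter_affinity(pwm, CisWindow("g", "ACGT")) == 0.0

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(4)
        pwm = random_pwm(rng, length=7)
        for i in range(50):
            seq = "".join(rng.choice(list("ACGTN"), size=200,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            mask = rng.random(200) > 0.2
            w = CisWindow("g", seq, accessible_mask=mask)
            assert regnet.promoter_affinity(pwm, w) == pytest.approx(
                brute_force_affinity(pwm, w), rel=1e-9)

    def test_additive_over_disjoint_segments(self):
        rng = np.random.default_rng(5)
        pwm = random_pwm(rng, length=6)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        mask_a = np.zeros(120, dtype=bool)
        mask_b = np.zeros(120, dtype=bool)
        mask_a[:50] = True
        mask_b[60:] = True  # gap > motif length: no site spans both segments
        both = mask_a | mask_b
        fa = regnet.promoter_affinity(pwm, CisWindow("g", seq, accessible_mask=mask_a))
        fb = regnet.promoter_affinity(pwm, CisWindow("g", seq, accessible_mask=mask_b))
        fab = regnet.promoter_affinity(pwm, CisWindow("g", seq, accessible_mask=both))
        assert fab == pytest.approx(fa + fb, rel=1e-12)


class TestTfActivity:
    def test_exact_linear_expression(self):
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(6)
        aff = pd.DataFrame([rng.uniform(0, 3, 40)], index=["TF"], columns=genes)
        expr = pd.DataFrame(
            {s: 2.0 * aff.loc["TF"] + 5.0 for s in ["s1", "s2", "s3"]}, index=genes)
        act = regnet.infer_tf_activity(expr, aff)
        assert np.allclose(act.values.loc["TF"], 2.0)

    def test_gene_permutation_invariance(self):
        reg = simulate.simulate_regulatory_data(n_genes=300, n_tfs=2, targets_per_tf=40,
                                                n_mirnas=1, targets_per_mirna=100, seed=7)
        act = regnet.infer_tf_activity(reg.expression, reg.affinities)
        perm = np.random.default_rng(0).permutation(reg.expression.index)
        act_p = regnet.infer_tf_activity(reg.expression.loc[perm],
                                         reg.affinities[perm])
        assert np.allclose(act.values, act_p.values)

    def test_zero_variance_affinity_dropped(self):
        genes = [f"g{i}" for i in range(10)]
        aff = pd.DataFrame([[1.0] * 10, list(range(10))], index=["flat", "ok"],
                           columns=genes)
        expr = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 4)),
                            index=genes, columns=list("abcd"))
        with pytest.warns(UserWarning):
            act = regnet.infer_tf_activity(expr, aff)
        assert act.regulators == ["ok"]

    def test_recovery_under_noise(self):
        reg = simulate.simulate_regulatory_data(seed=8)
        act = regnet.infer_tf_activity(reg.expression, reg.affinities)
        for tf in reg.tf_activities.index:
            r = np.corrcoef(act.values.loc[tf], reg.tf_activities.loc[tf])[0, 1]
            assert r >= 0.9


class TestWindowSelection:
    def test_planted_window_selected(self):
        reg = simulate.simulate_regulatory_data(n_genes=600, n_tfs=2, targets_per_tf=60,
                                                n_mirnas=1, targets_per_mirna=100, seed=3)
        by_k = simulate.windowed_affinities(reg, true_window_kb=5, seed=3)
        out = regnet.select_window(reg.expression, by_k)
        assert (out["window_kb"] == 5).all()
        assert out["selected"].all()

    def test_tie_break_prefers_smaller_window(self):
        reg = simulate.simulate_regulatory_data(n_genes=400, n_tfs=1, targets_per_tf=50,
                                                n_mirnas=1, targets_per_mirna=100, seed=4)
        same = {k: reg.affinities for k in range(1, 11)}
        out = regnet.select_window(reg.expression, same)
        assert out.loc["TF0", "window_kb"] == 1

    def test_pure_noise_unselected(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(400)]
        expr = pd.DataFrame(rng.normal(size=(400, 15)), index=genes,
                            columns=[f"s{j}" for j in range(15)])
        by_k = {k: pd.DataFrame(np.abs(rng.normal(size=(1, 400))), index=["TF0"],
                                columns=genes) for k in range(1, 11)}
        out = regnet.select_window(expr, by_k)
        assert not out.loc["TF0", "selected"]

    def test_too_few_genes(self):
        expr = pd.DataFrame(np.ones((5, 4)), index=list("abcde"), columns=list("wxyz"))
        with pytest.raises(ValueError):
            regnet.select_window(expr, {1: expr.T})


class TestTfTargets:
    def test_planted_targets_recovered(self):
        reg = simulate.simulate_regulatory_data(seed=9)
        act = regnet.infer_tf_activity(reg.expression, reg.affinities)
        tgt = regnet.tf_targets(reg.affinities.loc["TF0"], act.values.loc["TF0"],
                                reg.expression)
        truth = reg.tf_targets["TF0"]
        jaccard = len(tgt & truth) / len(tgt | truth)
        assert jaccard >= 0.7

    def test_zero_signal_tf_yields_few_targets(self):
        reg = simulate.simulate_regulatory_data(seed=10)
        rng = np.random.default_rng(10)
        null_aff = pd.Series(rng.uniform(0, 1, len(reg.expression.index)),
                             index=reg.expression.index)
        null_act = pd.Series(rng.normal(size=len(reg.expression.columns)),
                             index=reg.expression.columns)
        tgt = regnet.tf_targets(null_aff, null_act, reg.expression)
        # BH at 5% over 2000 genes: false discoveries intersected with the
        # top decile stay a small handful
        assert len(tgt) <= 0.05 * len(reg.expression.index)

    def test_degenerate_thresholds_return_all_genes(self):
        reg = simulate.simulate_regulatory_data(n_genes=200, n_tfs=1, targets_per_tf=30,
                                                n_mirnas=1, targets_per_mirna=100, seed=11)
        act = regnet.infer_tf_activity(reg.expression, reg.affinities)
        tgt = regnet.tf_targets(reg.affinities.loc["TF0"], act.values.loc["TF0"],
                                reg.expression, affinity_quantile=0.0, fdr=1.0)
        assert tgt == set(reg.expression.index)


class TestMirnaActivity:
    def test_small_target_sets_filtered(self):
        genes = [f"g{i}" for i in range(300)]
        expr = pd.DataFrame(np.zeros((300, 3)), index=genes, columns=list("abc"))
        sets = {"small": set(genes[:99]), "big": set(genes[:100])}
        act = regnet.infer_mirna_activity(expr, sets)
        assert act.regulators == ["big"]
        assert act.metadata["target_set_size"]["big"] == 100

    def test_noiseless_repressor_activity_exact(self):
        genes = [f"g{i}" for i in range(400)]
        targets = set(genes[:150])
        indicator = np.array([g in targets for g in genes], dtype=float)
        expr = pd.DataFrame({"s1": 5.0 - indicator, "s2": 5.0 - indicator}, index=genes)
        act = regnet.infer_mirna_activity(expr, {"mir": targets})
        assert np.allclose(act.values.loc["mir"], -1.0)

    def test_noisy_repressors_mostly_negative(self):
        reg = simulate.simulate_regulatory_data(seed=12)
        act = regnet.infer_mirna_activity(reg.expression, reg.mirna_target_sets)
        neg_frac = (act.values.to_numpy() < 0).mean()
        assert neg_frac >= 0.95

    def test_no_survivor_warns(self):
        genes = [f"g{i}" for i in range(50)]
        expr = pd.DataFrame(np.zeros((50, 2)), index=genes, columns=list("ab"))
        with pytest.warns(UserWarning):
            act = regnet.infer_mirna_activity(expr, {"m": set(genes[:10])})
        assert act.values.empty


class TestKeyDrivers:
    def star_network(self):
        g = nx.DiGraph()
        leaves = [f"L{i:02d}" for i in range(20)]
        g.add_edges_from(("hub", leaf) for leaf in leaves)
        return g, leaves

    def test_star_hub_ranks_first_with_closed_form_p(self):
        g, leaves = self.star_network()
        signature = leaves[:10]
        ranked = regnet.key_driver_analysis(g, signature, neighborhood_depth=2)
        top = ranked.iloc[0]
        assert top.driver == "hub" and top.n_downstream == 20
        expected = scistats.hypergeom.sf(10 - 1, 21, 10, 20)
        assert top.enrichment_p == pytest.approx(expected, rel=1e-9)
        assert top.adjusted_p == pytest.approx(min(1.0, expected * len(ranked)))

    def test_no_incoming_paths_ranked_by_downstream_size(self):
        g = nx.DiGraph()
        g.add_nodes_from(["s1", "s2"])
        g.add_edges_from([("s1", "x1"), ("s1", "x2"), ("s2", "x1")])
        ranked = regnet.key_driver_analysis(g, ["s1", "s2"], neighborhood_depth=1)
        assert (ranked["enrichment_p"] == 1.0).all()
        assert list(ranked["n_downstream"]) == sorted(ranked["n_downstream"],
                                                      reverse=True)

    def test_depth_nesting(self):
        g, leaves = self.star_network()
        g.add_edge("upstream", "hub")
        r1 = regnet.key_driver_analysis(g, leaves[:5], neighborhood_depth=1)
        r2 = regnet.key_driver_analysis(g, leaves[:5], neighborhood_depth=2)
        assert set(r1["driver"]) <= set(r2["driver"])

    def test_missing_signature_genes(self):
        g, leaves = self.star_network()
        with pytest.warns(UserWarning):
            ranked = regnet.key_driver_analysis(g, leaves[:3] + ["ghost"], 2)
        assert "ghost" not in set(ranked["driver"])
        with pytest.raises(ValueError):
            regnet.key_driver_analysis(g, ["ghost"], 2)
        with pytest.raises(ValueError):
            regnet.key_driver_analysis(g, [], 2)

    def test_planted_driver_detected(self):
        g, drivers, modules = simulate.simulate_driver_network(seed=0)
        ranked = regnet.key_driver_analysis(g, modules["module1"], 2)
        assert ranked.iloc[0].driver == "D1"


class TestGenesetEnrichment:
    def test_identity_sets(self):
        u = {f"g{i}" for i in range(10)}
        assert regnet.geneset_enrichment(u, u, u) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_universe_20(self):
        rng = np.random.default_rng(13)
        universe = [f"g{i}" for i in range(20)]
        for _ in range(25):
            q = set(rng.choice(universe, size=rng.integers(1, 15), replace=False))
            a = set(rng.choice(universe, size=rng.integers(1, 15), replace=False))
            k = len(q & a)
            # oracle: enumerate the hypergeometric tail with binomial coefficients
            expected = sum(
                math.comb(len(a), j) * math.comb(20 - len(a), len(q) - j)
                for j in range(k, min(len(q), len(a)) + 1)
            ) / math.comb(20, len(q))
            assert regnet.geneset_enrichment(q, a, universe) == pytest.approx(
                expected, rel=1e-9)

    def test_disjoint_large_sets_near_one(self):
        universe = [f"g{i}" for i in range(100)]
        q, a = set(universe[:40]), set(universe[50:90])
        assert regnet.geneset_enrichment(q, a, universe) > 0.999

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            regnet.geneset_enrichment({"a"}, {"a"}, set())


class TestNetworkIo:
    def test_edge_list_round_trip(self, tmp_path):
        g, _, _ = simulate.simulate_driver_network(seed=1)
        p = tmp_path / "net.tsv"
        regnet.write_edge_list(g, p)
        back = regnet.read_edge_list(p)
        assert set(back.edges) == set(g.edges)

    def test_gene_sets_round_trip(self, tmp_path):
        sets = {"m1": {"a", "b", "c"}, "m2": {"d"}}
        p = tmp_path / "s.gmt"
        regnet.write_gene_sets(sets, p)
        assert regnet.read_gene_sets(p) == sets
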