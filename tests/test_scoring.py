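"""Module score and ssGSEA against hand computations and brute-force oracles.

The oracles here are deliberately naive reimplementations (per-cell Python
loops, explicit running sums) kept independent of the vectorized package
code they check.
"""

import numpy as np
import pytest
from scipy.stats import rankdata

from senindex import (GeneSet, ModuleScoreParams, SsgseaParams, module_score,
                      score_panel, ssgsea_score, ssgsea_score_sets)

from conftest import make_norm


def brute_force_ssgsea(expr_row, in_set, alpha):
    """One cell, straight from the definition: average-tie ranks, walk the
    descending-expression list (gene index breaks ties), accumulate
    weighted in-set vs uniform out-of-set ECDFs."""
    g = len(expr_row)
    ranks = rankdata(expr_row)
    order = sorted(range(g), key=lambda j: (-expr_row[j], j))
    denom = sum(ranks[j] ** alpha for j in order if in_set[j])
    n_out = sum(1 for j in order if not in_set[j])
    ecdf_in = ecdf_out = 0.0
    total = 0.0
    for j in order:
        if in_set[j]:
            ecdf_in += ranks[j] ** alpha / denom
        else:
            ecdf_out += 1.0 / n_out
        total += ecdf_in - ecdf_out
    return total


def brute_force_module_score(values, gene_names, sig_genes, n_bins):
    """Binned-control module score with exhaustive control pools (the
    deterministic regime where every non-signature bin-mate is a control)."""
    n_cells, n_genes = values.shape
    means = values.mean(axis=0)
    order = sorted(range(n_genes), key=lambda j: (means[j], j))
    bins = {}
    splits = np.array_split(order, min(n_bins, n_genes))
    for b, idx in enumerate(splits):
        for j in idx:
            bins[j] = b
    sig_idx = [gene_names.index(g) for g in sig_genes]
    ctrl = []
    for j in sig_idx:
        pool = [k for k in range(n_genes) if bins[k] == bins[j] and k not in sig_idx]
        ctrl.extend(pool)
    out = np.empty(n_cells)
    for c in range(n_cells):
        out[c] = (np.mean([values[c, j] for j in sig_idx])
                  - np.mean([values[c, k] for k in ctrl]))
    return out


class TestModuleScore:
    def test_identical_expression_scores_zero(self):
        nm = make_norm(np.full((4, 12), 3.0))
        s = module_score(nm, GeneSet("s", ["g1", "g2"]),
                         ModuleScoreParams(n_bins=1, n_ctrl_per_gene=5, seed=0))
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_additive_shift_recovered(self):
        # signature genes equal their bin-mates plus a constant in every cell
        rng = np.random.default_rng(5)
        base = rng.random((6, 1))
        x = np.tile(base, (1, 10))
        x[:, :2] += 0.7  # signature genes g1, g2
        nm = make_norm(x)
        s = module_score(nm, GeneSet("s", ["g1", "g2"]),
                         ModuleScoreParams(n_bins=1, n_ctrl_per_gene=10 ** 4, seed=0))
        np.testing.assert_allclose(s, 0.7, atol=1e-12)

    def test_brute_force_oracle_full_complement(self):
        rng = np.random.default_rng(7)
        x = rng.random((10, 20))
        nm = make_norm(x)
        sig = ["g3", "g11", "g17"]
        got = module_score(nm, GeneSet("s", sig),
                           ModuleScoreParams(n_bins=1, n_ctrl_per_gene=10 ** 4, seed=0))
        names = [f"g{j + 1}" for j in range(20)]
        want = x[:, [2, 10, 16]].mean(axis=1) - np.delete(x, [2, 10, 16], axis=1).mean(axis=1)
        np.testing.assert_allclose(got, want, atol=1e-12)
    def test_brute_force_oracle_multibin(self):
        # multi-bin deterministic regime against the naive reimplementation
        rng = np.random.default_rng(8)
        x = rng.random((12, 60))
        nm = make_norm(x)
        names = [f"g{j + 1}" for j in range(60)]
        sig = ["g3", "g27", "g58"]
        got5 = module_score(nm, GeneSet("s", sig),
                            ModuleScoreParams(n_bins=5, n_ctrl_per_gene=10 ** 4, seed=0))
        want5 = brute_force_module_score(x, names, sig, n_bins=5)
        np.testing.assert_allclose(got5, want5, atol=1e-9)

    def test_null_signatures_center_on_zero(self):
        # random single-gene signatures drawn from one bin score ~0 on average
        rng = np.random.default_rng(11)
        x = rng.random((15, 60))
        nm = make_norm(x)
        p = ModuleScoreParams(n_bins=1, n_ctrl_per_gene=10 ** 4, seed=0)
        scores = []
        for j in rng.choice(60, size=40, replace=False):
            s = module_score(nm, GeneSet("s", [f"g{j + 1}"]), p)
            scores.append(s.mean())
        scores = np.asarray(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) <= 3 * se

    def test_signature_covering_panel_rejected(self):
        nm = make_norm(np.random.default_rng(0).random((3, 4)))
        with pytest.raises(ValueError, match="control"):
            module_score(nm, GeneSet("all", ["g1", "g2", "g3", "g4"]))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        x = rng.random((30, 50))
        nm = make_norm(x)
        p = ModuleScoreParams(n_bins=5, n_ctrl_per_gene=3, seed=42)
        a = module_score(nm, GeneSet("s", ["g5", "g25"]), p)
        b = module_score(nm, GeneSet("s", ["g5", "g25"]), p)
        np.testing.assert_array_equal(a, b)


class TestSsgseaScore:
    def test_hand_computed_running_sum(self):
        # one cell, 4 genes ranked g1>g2>g3>g4, set={g1}, alpha=0:
        # (1-0) + (1-1/3) + (1-2/3) + (1-1) = 2.0
        nm = make_norm([[4.0, 3.0, 2.0, 1.0]])
        s = ssgsea_score(nm, GeneSet("s", ["g1"]),
                         SsgseaParams(weight_exponent=0.0, normalize_across_cells=False))
        assert s[0] == pytest.approx(2.0, abs=1e-12)

    def test_identical_cells_identical_scores(self):
        x = np.tile([[0.3, 1.2, 0.0, 2.2, 0.7]], (3, 1))
        s = ssgsea_score(make_norm(x), GeneSet("s", ["g2", "g4"]))
        assert s[0] == s[1] == s[2]

    def test_single_gene_set_monotone_in_rank(self):
        # the higher the gene ranks, the higher the score
        scores = []
        for pos in range(5):
            x = np.arange(5, 0, -1.0)[None, :]  # g1 highest ... g5 lowest
            nm = make_norm(x)
            s = ssgsea_score(nm, GeneSet("s", [f"g{pos + 1}"]),
                             SsgseaParams(normalize_across_cells=False))
            scores.append(s[0])
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.random((6, 25))
        gs = GeneSet("s", ["g2", "g9", "g20"])
        p = SsgseaParams(normalize_across_cells=False)
        a = ssgsea_score(make_norm(x), gs, p)
        b = ssgsea_score(make_norm(np.exp(3 * x)), gs, p)
        np.testing.assert_allclose(a, b, atol=1e-9)

    @pytest.mark.parametrize("alpha,tied", [(0.25, False), (0.0, False), (0.75, True)])
    def test_brute_force_oracle(self, alpha, tied):
        rng = np.random.default_rng(int(alpha * 100))
        x = rng.random((20, 30))
        if tied:
            x = np.round(x, 1)  # force rank ties
        in_set = np.zeros(30, dtype=bool)
        in_set[[1, 7, 13, 22, 28]] = True
        genes = [f"g{j + 1}" for j in range(30)]
        gs = GeneSet("s", [g for g, m in zip(genes, in_set) if m])
        got = ssgsea_score(make_norm(x), gs,
                           SsgseaParams(weight_exponent=alpha,
                                        normalize_across_cells=False))
        want = np.array([brute_force_ssgsea(x[c], in_set, alpha) for c in range(20)])
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_full_panel_set_rejected(self):
        nm = make_norm(np.random.default_rng(0).random((2, 3)))
        with pytest.raises(ValueError):
            ssgsea_score(nm, GeneSet("s", ["g1", "g2", "g3"]))

    def test_range_normalization_spans_unit(self):
        rng = np.random.default_rng(9)
        nm = make_norm(rng.random((30, 20)))
        s = ssgsea_score(nm, GeneSet("s", ["g4", "g12"]),
                         SsgseaParams(normalize_across_cells=True))
        assert s.max() - s.min() == pytest.approx(1.0, abs=1e-12)


class TestScorePanel:
    def test_columns_per_signature(self):
        nm = make_norm(np.random.default_rng(2).random((8, 30)))
        reg = {"a": GeneSet("a", ["g1", "g2"]), "b": GeneSet("b", ["g5", "g9"])}
        t = score_panel(nm, reg)
        assert list(t.columns) == ["a", "b"] and len(t) == 8

    def test_empty_registry_warns(self, caplog):
        nm = make_norm(np.random.default_rng(2).random((4, 10)))
        with caplog.at_level("WARNING"):
            t = score_panel(nm, {})
        assert t.empty and t.shape[0] == 4 or len(t.columns) == 0

    def test_bitwise_reproducible(self):
        nm = make_norm(np.random.default_rng(2).random((8, 30)))
        reg = {"a": GeneSet("a", ["g1", "g2"])}
        sets = [GeneSet("cc", [f"g{j}" for j in range(10, 20)])]
        t1 = score_panel(nm, reg, sets, ModuleScoreParams(seed=3))
        t2 = score_panel(nm, reg, sets, ModuleScoreParams(seed=3))
        assert (t1.to_numpy() == t2.to_numpy()).all()

    def test_multiset_global_normalization(self):
        rng = np.random.default_rng(4)
        nm = make_norm(rng.random((25, 30)))
        sets = [GeneSet("a", ["g1", "g4"]), GeneSet("b", ["g9", "g20", "g22"])]
        df = ssgsea_score_sets(nm, sets, SsgseaParams(normalize_across_cells=True))
        arr = df.to_numpy()
        assert arr.max() - arr.min() == pytest.approx(1.0, abs=1e-12)
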