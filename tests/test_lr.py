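import numpy as np
import pandas as pd
import pytest

from nichecompare.datatypes import AnalysisConfig
from nichecompare.lr import (
    interaction_counts,
    lr_permutation_test,
    lr_score,
    lr_z_screen,
)


def expr_with_clusters(values_by_cluster, n_per_cluster=20):
    """values_by_cluster: {cluster: {gene: constant value}} -> (expr, genes, clusters)."""
    genes = sorted({g for d in values_by_cluster.values() for g in d})
    cols, clusters = [], []
    for lab, d in sorted(values_by_cluster.items()):
        for _ in range(n_per_cluster):
            cols.append([d.get(g, 0.0) for g in genes])
            clusters.append(lab)
    return np.array(cols).T, genes, np.array(clusters)


PAIR = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})


class TestScore:
    def test_product_of_means(self):
        expr, genes, clusters = expr_with_clusters(
            {"A": {"L": 2.0, "R": 1.0}, "B": {"L": 1.0, "R": 3.0}}
        )
        res = lr_score(expr, genes, clusters, PAIR)
        row = res[(res.cell_type_a == "A") & (res.cell_type_b == "B")].iloc[0]
        assert row["score"] == 6.0

    def test_ratio_gate_excludes_sparse_ligand(self):
        # ligand detected in 9% of A's cells (9 of 100)
        rng = np.random.default_rng(0)
        expr, genes, clusters = expr_with_clusters(
            {"A": {"L": 0.0, "R": 1.0}, "B": {"L": 1.0, "R": 1.0}}, n_per_cluster=100
        )
        li = genes.index("L")
        a_cols = np.flatnonzero(clusters == "A")
        expr[li, a_cols[:9]] = 5.0
        res = lr_score(expr, genes, clusters, PAIR)
        assert res[(res.cell_type_a == "A")].empty

    def test_unexpressed_ligand_absent_not_zero(self):
        expr, genes, clusters = expr_with_clusters(
            {"A": {"L": 0.0, "R": 1.0}, "B": {"L": 0.0, "R": 1.0}}
        )
        res = lr_score(expr, genes, clusters, PAIR)
        assert res.empty  # gate precedes scoring: no zero-score rows

    def test_missing_gene_skipped(self):
        expr, genes, clusters = expr_with_clusters({"A": {"L": 1.0}, "B": {"L": 1.0}})
        pair = pd.DataFrame({"ligand": ["L"], "receptor": ["NOTPRESENT"]})
        assert lr_score(expr, genes, clusters, pair).empty

    def test_small_cluster_skipped(self):
        expr, genes, clusters = expr_with_clusters(
            {"A": {"L": 1.0, "R": 1.0}, "B": {"L": 1.0, "R": 1.0}}, n_per_cluster=30
        )
        clusters[:5] = "tiny"
        res = lr_score(expr[:, 5:], genes, clusters[5:], PAIR)  # keep sizes valid
        assert set(res.cell_type_a) <= {"A", "B"}

    def test_score_scaling_equivariance(self):
        expr, genes, clusters = expr_with_clusters(
            {"A": {"L": 2.0, "R": 1.0}, "B": {"L": 1.0, "R": 3.0}}
        )
        s1 = lr_score(expr, genes, clusters, PAIR)
        s2 = lr_score(3.0 * expr, genes, clusters, PAIR)
        assert np.allclose(s2["score"], 9.0 * s1["score"])

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(1)
        expr, genes, clusters = expr_with_clusters(
            {"A": {"L": 2.0, "R": 1.0}, "B": {"L": 1.0, "R": 3.0}}
        )
        expr += rng.exponential(0.5, expr.shape)
        perm = rng.permutation(expr.shape[1])
        s1 = lr_score(expr, genes, clusters, PAIR)
        s2 = lr_score(expr[:, perm], genes, clusters[perm], PAIR)
        pd.testing.assert_frame_equal(s1, s2)


class TestPermutation:
    def test_add_one_p_floor(self):
        """Observed score above every permuted score -> p = 1/(B+1)."""
        rng = np.random.default_rng(2)
        n = 40
        expr = rng.exponential(0.2, (2, 2 * n))
        clusters = np.array(["A"] * n + ["B"] * n)
        # make the observed configuration extreme
        expr[0, :n] += 50.0
        expr[1, n:] += 50.0
        cfg = AnalysisConfig(lr_n_perm=1000, seed=0)
        cand = lr_score(expr, ["L", "R"], clusters, PAIR, cfg)
        res = lr_permutation_test(expr, ["L", "R"], clusters, cand, cfg)
        row = res[(res.cell_type_a == "A") & (res.cell_type_b == "B")].iloc[0]
        assert np.isclose(row["p"], 1.0 / 1001.0)
        assert row["passes_perm"]

    def test_empty_candidates(self):
        res = lr_permutation_test(
            np.ones((1, 10)), ["g"], np.array(["A"] * 10),
            pd.DataFrame(columns=["ligand", "receptor", "cell_type_a",
                                  "cell_type_b", "score"]),
        )
        assert res.empty and "p" in res.columns

    def test_permutation_p_valid_under_null(self):
        """P(p <= alpha) <= alpha + 2/(B+1) for exchangeable labels."""
        rng = np.random.default_rng(3)
        n_genes, n_cells = 80, 600
        expr = rng.lognormal(0, 1, (n_genes, n_cells))
        genes = [f"g{i}" for i in range(n_genes)]
        clusters = rng.choice(["A", "B", "C"], n_cells)
        pairs = pd.DataFrame(
            {"ligand": genes[:40], "receptor": genes[40:80]}
        )
        cfg = AnalysisConfig(lr_n_perm=400, seed=4)
        cand = lr_score(expr, genes, clusters, pairs, cfg)
        res = lr_permutation_test(expr, genes, clusters, cand, cfg)
        for alpha in (0.01, 0.05, 0.1):
            # binomial slack on top of the permutation bound at this n
            n = len(res)
            tol = 2 / (cfg.lr_n_perm + 1) + 2 * np.sqrt(alpha * (1 - alpha) / n)
            assert (res["p"] <= alpha).mean() <= alpha + tol


class TestZScreen:
    def screen(self, ligand_z, receptor_z, p=0.01):
        lr_res = pd.DataFrame(
            {
                "ligand": ["L"], "receptor": ["R"],
                "cell_type_a": ["A"], "cell_type_b": ["B"],
                "score": [1.0], "p": [p], "passes_perm": [p <= 0.05],
            }
        )
        markers = pd.DataFrame(
            {
                "gene": ["L", "R"], "cluster": ["A", "B"],
                "z": [ligand_z, receptor_z],
            }
        )
        return lr_z_screen(lr_res, markers).iloc[0]

    def test_boundaries_are_strict(self):
        assert not self.screen(4.0, 1.0)["passes_z"]  # ligand z must exceed 4
        assert not self.screen(6.0, 0.0)["passes_z"]  # receptor z must exceed 0
        assert self.screen(4.001, 0.001)["passes_z"]

    def test_reported_requires_both_screens(self):
        row = self.screen(6.0, 1.0, p=0.01)
        assert row["reported"]
        assert not self.screen(6.0, 1.0, p=0.2)["reported"]

    def test_missing_marker_entry_fails_screens(self):
        lr_res = pd.DataFrame(
            {
                "ligand": ["L"], "receptor": ["R"],
                "cell_type_a": ["A"], "cell_type_b": ["B"],
                "score": [1.0], "p": [0.01], "passes_perm": [True],
            }
        )
        empty_markers = pd.DataFrame({"gene": [], "cluster": [], "z": []})
        row = lr_z_screen(lr_res, empty_markers).iloc[0]
        assert row["ligand_z"] == 0.0 and not row["passes_z"]

    def test_reported_set_shrinks_as_thresholds_tighten(self):
        rng = np.random.default_rng(5)
        n = 50
        lr_res = pd.DataFrame(
            {
                "ligand": [f"L{i}" for i in range(n)],
                "receptor": [f"R{i}" for i in range(n)],
                "cell_type_a": "A", "cell_type_b": "B",
                "score": rng.exponential(1, n),
                "p": rng.uniform(0, 0.2, n),
            }
        )
        markers = pd.DataFrame(
            {
                "gene": [f"L{i}" for i in range(n)] + [f"R{i}" for i in range(n)],
                "cluster": ["A"] * n + ["B"] * n,
                "z": rng.normal(4, 2, 2 * n),
            }
        )
        sets = []
        for lig_z, p_th in [(3.0, 0.1), (4.0, 0.05), (5.0, 0.01)]:
            cfg = AnalysisConfig(lr_ligand_z=lig_z, lr_p=p_th)
            r = lr_res.copy()
            r["passes_perm"] = r["p"] <= cfg.lr_p
            out = lr_z_screen(r, markers, cfg)
            sets.append(set(out.loc[out["reported"], "ligand"]))
        assert sets[2] <= sets[1] <= sets[0]


def test_interaction_counts_summarizes_reported():
    df = pd.DataFrame(
        {
            "cell_type_a": ["A", "A", "B"],
            "cell_type_b": ["B", "B", "A"],
            "reported": [True, True, False],
        }
    )
    counts = interaction_counts(df)
    assert counts.iloc[0]["n_interactions"] == 2 and len(counts) == 1
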