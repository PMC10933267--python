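"""Network analytics: correlation clustering against a brute-force Ward
oracle, overlap/hub/novelty set arithmetic, Fisher exact enrichment
against an exhaustive hypergeometric enumeration, and expression
cross-referencing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from etchnet.network import (build_matrix, correlation_cluster,
                             expression_crossref, fisher_vs_reference,
                             method_overlap, novelty_annotation,
                             prey_sharing, top_hubs)


def brute_force_ward(X):
    """Naive agglomerative Ward: at each step merge the pair of clusters
    with the smallest variance-increase distance
    sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            A, B = X[clusters[a]], X[clusters[b]]
            d = np.sqrt(2 * len(A) * len(B) / (len(A) + len(B))) \
                * np.linalg.norm(A.mean(0) - B.mean(0))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return heights


class TestCorrelationCluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
            index=["b1", "b2", "b3"], columns=["p1", "p2", "p3"])
        result = correlation_cluster(matrix)
        assert result.correlation.loc["b1", "b2"] == pytest.approx(1.0)
        assert result.linkage[0, 2] == pytest.approx(0.0)
        assert {int(result.linkage[0, 0]), int(result.linkage[0, 1])} == {0, 1}

    def test_exact_anticorrelation(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                              index=["b1", "b2"], columns=list("pqr"))
        result = correlation_cluster(matrix)
        assert result.correlation.loc["b1", "b2"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_linkage_heights_match_brute_force_ward(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 4)) * 3
        matrix = pd.DataFrame(np.abs(X),
                              index=[f"b{i}" for i in range(6)],
                              columns=[f"p{j}" for j in range(4)])
        result = correlation_cluster(matrix)
        expected = brute_force_ward(matrix.to_numpy())
        assert result.linkage[:, 2] == pytest.approx(expected, rel=1e-9)

    def test_constant_row_excluded_with_warning(self):
        matrix = pd.DataFrame([[1, 2, 3], [5, 5, 5], [4, 1, 2]],
                              index=["b1", "flat", "b3"],
                              columns=list("pqr"), dtype=float)
        with pytest.warns(UserWarning):
            result = correlation_cluster(matrix)
        assert result.excluded == ["flat"]
        assert "flat" not in result.labels
        assert np.isnan(result.correlation.loc["flat", "b1"])

    def test_correlation_matrix_invariants(self, small_screen):
        from etchnet.scoring import score_all_baits
        _, runs, _ = small_screen
        scored = score_all_baits(runs)
        matrix = build_matrix(scored[scored["bfdr"] < 0.01])
        result = correlation_cluster(matrix)
        corr = result.correlation.to_numpy()
        assert np.allclose(corr, corr.T, equal_nan=True)
        assert np.allclose(np.diag(corr), 1.0)
        finite = corr[np.isfinite(corr)]
        assert ((finite >= -1 - 1e-12) & (finite <= 1 + 1e-12)).all()

    def test_newick_contains_all_labels(self):
        matrix = pd.DataFrame(np.arange(12.0).reshape(4, 3) ** 2,
                              index=list("abcd"), columns=list("xyz"))
        result = correlation_cluster(matrix)
        for label in "abcd":
            assert label in result.newick
        assert result.newick.endswith(";")

    def test_single_bait_rejected(self):
        with pytest.raises(ValueError):
            correlation_cluster(pd.DataFrame([[1.0, 2.0]], index=["b"]))


class TestSetArithmetic:
    def test_method_overlap_example(self):
        counts = method_overlap({"b": {"A", "B", "C"}},
                                {"b": {"B", "C", "D"}})
        assert counts == {"only_bioid": 1, "both": 2, "only_apms": 1}

    def test_identical_sets(self):
        counts = method_overlap({"b": {"A", "B"}}, {"b2": {"A", "B"}})
        assert counts == {"only_bioid": 0, "both": 2, "only_apms": 0}

    def test_counts_sum_to_union(self):
        bio = {"b1": {"A", "B"}, "b2": {"C"}}
        ap = {"b1": {"B", "D"}, "b2": {"E"}}
        counts = method_overlap(bio, ap)
        union = {"A", "B", "C", "D", "E"}
        assert sum(counts.values()) == len(union)

    def test_prey_sharing_counts(self):
        sets = {f"b{i}": {"X", f"u{i}"} for i in range(3)}
        sets["b3"] = {"u3"}
        sets["b4"] = {"u4"}
        sharing = prey_sharing(sets)
        by_prey = sharing.set_index("prey_id")["n_baits"]
        assert by_prey["X"] == 3
        assert by_prey["u0"] == 1
        assert list(top_hubs(sharing)["prey_id"]) == ["X"]

    def test_prey_in_every_set(self):
        sets = {f"b{i}": {"HUB"} for i in range(7)}
        sharing = prey_sharing(sets)
        assert sharing.iloc[0]["n_baits"] == 7

    def test_novelty_annotation(self):
        hci_sets = {"b1": {f"p{i}" for i in range(10)}}
        known = [("b1", "p0"), ("b1", "p1"), ("b1", "p2"),
                 ("b2", "p3")]  # wrong bait: does not count
        out = novelty_annotation(hci_sets, known)
        assert out.iloc[0]["known"] == 3
        assert out.iloc[0]["novel"] == 7

    def test_empty_known_list_all_novel(self):
        out = novelty_annotation({"b": {"x", "y"}}, [])
        assert out.iloc[0]["novel"] == 2 and out.iloc[0]["known"] == 0

    def test_known_equal_to_hcis_zero_novel(self):
        out = novelty_annotation({"b": {"x", "y"}},
                                 [("b", "x"), ("b", "y")])
        assert out.iloc[0]["novel"] == 0


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration: sum of probabilities of all
    tables (with the observed margins) no more likely than the observed."""
    n1, k = a + b, a + c
    N = a + b + c + d
    rv = hypergeom(N, n1, k)
    lo, hi = max(0, k - (c + d)), min(k, n1)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(x) for x in range(lo, hi + 1)
                     if rv.pmf(x) <= p_obs * (1 + 1e-7)))


class TestFisher:
    def test_example_table(self):
        study = {f"s{i}": {"P"} if i < 8 else set() for i in range(10)}
        ref = {f"r{i}": {"P"} if i < 1 else set() for i in range(10)}
        out = fisher_vs_reference(study, ref, prey_universe={"P"})
        row = out.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (8, 2, 1, 9)
        assert row.p == pytest.approx(0.005477, abs=5e-7)
        assert row.direction == "over"

    def test_equal_proportions_p_one(self):
        study = {f"s{i}": {"P"} if i < 5 else set() for i in range(10)}
        ref = {f"r{i}": {"P"} if i < 5 else set() for i in range(10)}
        out = fisher_vs_reference(study, ref, prey_universe={"P"})
        assert out.iloc[0]["p"] == pytest.approx(1.0)
        assert out.iloc[0]["direction"] == "equal"

    def test_matches_enumeration_oracle_to_1e10(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n_study = int(rng.integers(2, 16))
            n_ref = int(rng.integers(2, 16))
            a = int(rng.integers(0, n_study + 1))
            c = int(rng.integers(0, n_ref + 1))
            study = {f"s{i}": {"P"} if i < a else set()
                     for i in range(n_study)}
            ref = {f"r{i}": {"P"} if i < c else set()
                   for i in range(n_ref)}
            out = fisher_vs_reference(study, ref, prey_universe={"P"})
            expected = fisher_two_sided_oracle(a, n_study - a, c, n_ref - c)
            assert out.iloc[0]["p"] == pytest.approx(expected, abs=1e-10)

    def test_bh_adjustment_properties(self):
        rng = np.random.default_rng(6)
        n_study, n_ref = 12, 12
        study = {f"s{i}": set() for i in range(n_study)}
        ref = {f"r{i}": set() for i in range(n_ref)}
        for p in range(30):
            prey = f"P{p:02d}"
            for i in rng.choice(n_study, size=int(rng.integers(0, 13)),
                                replace=False):
                study[f"s{i}"].add(prey)
            for i in rng.choice(n_ref, size=int(rng.integers(0, 13)),
                                replace=False):
                ref[f"r{i}"].add(prey)
        out = fisher_vs_reference(study, ref)
        assert (out["q"] >= out["p"] - 1e-12).all()
        ranked = out.sort_values("p")
        assert (np.diff(ranked["q"]) >= -1e-12).all()

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            fisher_vs_reference({"s": {"P"}}, {})


class TestExpressionCrossref:
    @pytest.fixture()
    def expression(self):
        rows = []
        rpkm = {"p1": 0.0, "p2": 1.0, "p3": 5.0, "p4": 0.2, "p5": 2.0}
        for gene, value in rpkm.items():
            for stage in ("zygote", "2cell", "4cell", "8cell", "morula"):
                rows.append((gene, stage, value if stage == "8cell"
                             else value * 0.1))
        return pd.DataFrame(rows, columns=["gene_id", "stage", "rpkm"])

    WINDOW = ["zygote", "2cell", "4cell", "8cell", "morula"]

    def test_zero_rpkm_excluded(self, expression):
        out = expression_crossref(["p1"], expression, self.WINDOW)
        assert out["count"] == 0

    def test_exactly_one_excluded_under_strict_threshold(self, expression):
        out = expression_crossref(["p2"], expression, self.WINDOW)
        assert out["count"] == 0
        out = expression_crossref(["p2"], expression, self.WINDOW,
                                  inclusive=True)
        assert out["count"] == 1

    def test_three_of_five_above_threshold(self, expression):
        out = expression_crossref(["p1", "p2", "p3", "p4", "p5"],
                                  expression, self.WINDOW)
        # hand scan: only p3 (5.0) and p5 (2.0) exceed RPKM 1 strictly
        assert out["count"] == 2
        assert out["retained"] == ["p3", "p5"]

    def test_missing_prey_counted_not_expressed(self, expression):
        out = expression_crossref(["p3", "UNKNOWN"], expression, self.WINDOW)
        assert out["count"] == 1 and out["missing"] == ["UNKNOWN"]

    def test_uncovered_stage_raises(self, expression):
        with pytest.raises(ValueError):
            expression_crossref(["p3"], expression, ["oocyte", "zygote"])
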