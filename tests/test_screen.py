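"""Correlation screen, clustering and over-representation tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from discgrowth import (
    ExpressionMatrix,
    ScreenResult,
    classify_genes,
    cluster_genes,
    correlate_with_growth_rate,
    enrich,
    max_normalize,
    summarise_replicates,
)


def pearson_reference(x, y):
    """Straightforward sum-formula Pearson r, independent of the screen path."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(a * a for a in x), sum(b * b for b in y), sum(
        a * b for a, b in zip(x, y))
    denom = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return (n * sxy - sx * sy) / denom


def matrix_from_profiles(profiles: np.ndarray, reps: int = 1) -> ExpressionMatrix:
    tps = [80, 88, 96, 104, 112, 116, 118][: profiles.shape[1]]
    cols, vals = [], []
    for j, tp in enumerate(tps):
        for r in range(reps):
            cols.append(f"{tp}_rep{r + 1}")
            vals.append(profiles[:, j])
    idx = pd.Index([f"g{i}" for i in range(profiles.shape[0])], name="gene")
    return ExpressionMatrix(pd.DataFrame(np.column_stack(vals), index=idx, columns=cols))


class TestSummariseReplicates:
    def test_mean_of_two_replicates(self):
        df = pd.DataFrame({"80_rep1": [2.0], "80_rep2": [4.0], "88_rep1": [5.0]},
                          index=pd.Index(["g1"], name="gene"))
        out = summarise_replicates(ExpressionMatrix(df))
        assert out.loc["g1", 80.0] == 3.0
        assert out.loc["g1", 88.0] == 5.0

    def test_single_replicate_passes_through(self):
        m = matrix_from_profiles(np.array([[1.0, 2.0, 3.0]]), reps=1)
        out = summarise_replicates(m)
        np.testing.assert_allclose(out.to_numpy()[0], [1, 2, 3])

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        m = matrix_from_profiles(rng.uniform(1, 10, size=(20, 7)), reps=3)
        out = summarise_replicates(m)
        for tp in m.timepoints:
            cols = m.replicate_columns(tp)
            expected = m.data[cols].to_numpy().mean(axis=1)
            np.testing.assert_allclose(out[tp].to_numpy(), expected)


class TestCorrelate:
    def test_positive_affine_gives_r_one(self):
        rate = np.array([9, 7, 5, 4, 3, 2.5, 2.0]) / 100
        prof = matrix_from_profiles((2 * rate + 5)[None, :])
        res = correlate_with_growth_rate(summarise_replicates(prof), rate)
        assert res.r.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_negative_profile_gives_r_minus_one(self):
        rate = np.array([9, 7, 5, 4, 3, 2.5, 2.0]) / 100
        prof = matrix_from_profiles((1 - rate)[None, :])
        res = correlate_with_growth_rate(summarise_replicates(prof), rate)
        assert res.r.iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_sum_formula_on_random_vectors(self):
        rng = np.random.default_rng(12)
        profiles = rng.uniform(0.1, 10, size=(1000, 7))
        rate = rng.uniform(0.01, 0.1, size=7)
        res = correlate_with_growth_rate(
            pd.DataFrame(profiles, index=[f"g{i}" for i in range(1000)]), rate)
        expected = [pearson_reference(row, rate) for row in profiles]
        np.testing.assert_allclose(res.r.to_numpy(), expected, atol=1e-12)

    def test_constant_profile_flagged_undefined_not_nan_propagated(self):
        rate = np.linspace(0.09, 0.02, 7)
        profiles = pd.DataFrame([[3.0] * 7, list(rate)], index=["flat", "ok"])
        res = classify_genes(correlate_with_growth_rate(profiles, rate))
        assert math.isnan(res.table.loc["flat", "r"])
        assert res.table.loc["flat", "class"] == "undefined"
        assert res.table.loc["ok", "class"] == "positive"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rate length"):
            correlate_with_growth_rate(pd.DataFrame([[1.0, 2.0, 3.0]]), [0.1, 0.2])


class TestClassify:
    def test_boundary_r_is_unselected(self):
        res = classify_genes(ScreenResult(pd.DataFrame({"r": [0.8, -0.8]}, index=["a", "b"])))
        assert list(res.table["class"]) == ["unselected", "unselected"]

    def test_threshold_rule(self):
        res = classify_genes(ScreenResult(pd.DataFrame({"r": [-0.9, 0.95, 0.1]},
                                                       index=["a", "b", "c"])))
        assert list(res.table["class"]) == ["negative", "positive", "unselected"]

    def test_classes_partition_genes(self):
        rng = np.random.default_rng(3)
        r = np.concatenate([rng.uniform(-1, 1, 50), [np.nan, 0.8, -0.8]])
        res = classify_genes(ScreenResult(pd.DataFrame({"r": r})))
        counts = res.table["class"].value_counts()
        assert counts.sum() == len(r)
        assert set(counts.index) <= {"positive", "negative", "unselected", "undefined"}

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_genes(ScreenResult(pd.DataFrame({"r": [0.5]})), threshold=1.2)


class TestMaxNormalize:
    def test_divides_rows_by_their_max(self):
        out = max_normalize(pd.DataFrame([[1.0, 2.0, 4.0]], index=["g"]))
        np.testing.assert_allclose(out.to_numpy()[0], [0.25, 0.5, 1.0])

    def test_idempotent(self):
        m = pd.DataFrame(np.random.default_rng(1).uniform(0.5, 9, (10, 7)))
        np.testing.assert_allclose(max_normalize(max_normalize(m)), max_normalize(m))

    def test_constant_row_becomes_ones(self):
        out = max_normalize(pd.DataFrame([[3.0, 3.0, 3.0]], index=["g"]))
        np.testing.assert_array_equal(out.to_numpy()[0], [1, 1, 1])

    def test_all_zero_rows_rejected_by_name(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["bad", "good"])
        with pytest.raises(ValueError, match="bad"):
            max_normalize(m)


def ward_d2_oracle(x: np.ndarray):
    """Brute-force Lance-Williams agglomeration in the ward.D2 flavour.

    Squared Euclidean distances enter the Ward update; reported heights
    are their square roots.  Ties resolved by the smallest pair.
    """
    n = x.shape[0]
    d2 = {}  # squared inter-cluster distances
    for i, j in itertools.combinations(range(n), 2):
        d2[(i, j)] = float(((x[i] - x[j]) ** 2).sum())
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(math.sqrt(best))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            nk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            val = ((ni + nk) * dik + (nj + nk) * djk - nk * best) / (ni + nj + nk)
            d2[tuple(sorted((new, k)))] = val
        active -= {i, j}
        for key in [kk for kk in d2 if kk[0] in (i, j) or kk[1] in (i, j)]:
            del d2[key]
        active.add(new)
        sizes[new] = ni + nj
    return np.asarray(heights)


class TestClusterGenes:
    def test_identical_rows_merge_first_at_height_zero(self):
        m = pd.DataFrame([[0.5, 1.0], [0.5, 1.0], [0.1, 0.9]], index=["a", "b", "c"])
        heat = cluster_genes(m)
        i, j, h = heat.merges[0]
        assert {i, j} == {0, 1}
        assert h == 0.0

    def test_merge_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            x = rng.uniform(0, 1, size=(5, 7))
            heat = cluster_genes(pd.DataFrame(x))
            np.testing.assert_allclose(heat.merge_heights, ward_d2_oracle(x), rtol=1e-10)

    def test_merge_heights_nondecreasing_and_final_is_max(self):
        x = np.random.default_rng(8).uniform(0, 1, size=(12, 7))
        h = cluster_genes(pd.DataFrame(x)).merge_heights
        assert np.all(np.diff(h) >= -1e-12)
        assert h[-1] == h.max()

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, size=(8, 7))
        perm = rng.permutation(8)
        h1 = cluster_genes(pd.DataFrame(x)).merge_heights
        h2 = cluster_genes(pd.DataFrame(x[perm])).merge_heights
        np.testing.assert_allclose(np.sort(h1), np.sort(h2), rtol=1e-10)


def hypergeom_tail_enumeration(n_universe, n_set, n_list, overlap):
    """P(X >= overlap) by exhaustive summation of the hypergeometric pmf."""
    def comb(n, k):
        return math.comb(n, k)

    total = comb(n_universe, n_list)
    p = 0.0
    for k in range(overlap, min(n_set, n_list) + 1):
        p += comb(n_set, k) * comb(n_universe - n_set, n_list - k) / total
    return p


class TestEnrich:
    UNIVERSE = [f"g{i}" for i in range(20)]

    def test_matches_exhaustive_enumeration(self):
        gset = self.UNIVERSE[:5]
        selected = self.UNIVERSE[1:9]  # overlap = 4 (g1..g4)
        out = enrich(selected, self.UNIVERSE, {"s": gset})
        assert out.loc["s", "overlap"] == 4
        assert out.loc["s", "p"] == pytest.approx(
            hypergeom_tail_enumeration(20, 5, 8, 4), rel=1e-12)

    def test_list_equals_universe_gives_p_one(self):
        out = enrich(self.UNIVERSE, self.UNIVERSE, {"s": self.UNIVERSE[:5]})
        assert out.loc["s", "overlap"] == 5
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        out = enrich(self.UNIVERSE[:3], self.UNIVERSE, {"s": self.UNIVERSE[10:15]})
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_p_monotone_nonincreasing_in_overlap(self):
        ps = [hypergeom_tail_enumeration(20, 6, 8, k) for k in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        # and the implementation agrees along the way
        for k in range(1, 6):
            selected = self.UNIVERSE[:k] + self.UNIVERSE[10 : 10 + 8 - k]
            out = enrich(selected, self.UNIVERSE, {"s": self.UNIVERSE[:6]})
            assert out.loc["s", "p"] == pytest.approx(ps[k], rel=1e-12)

    def test_ease_mode_decrements_overlap(self):
        selected = self.UNIVERSE[:4] + self.UNIVERSE[10:14]
        plain = enrich(selected, self.UNIVERSE, {"s": self.UNIVERSE[:5]})
        eased = enrich(selected, self.UNIVERSE, {"s": self.UNIVERSE[:5]}, ease=True)
        assert eased.loc["s", "p"] == pytest.approx(
            hypergeom_tail_enumeration(20, 5, 8, 3), rel=1e-12)
        assert eased.loc["s", "p"] > plain.loc["s", "p"]
        single = enrich(self.UNIVERSE[:1], self.UNIVERSE, {"s": self.UNIVERSE[:5]}, ease=True)
        assert single.loc["s", "p"] == 1.0

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="not in universe"):
            enrich(["zz"], self.UNIVERSE, {"s": self.UNIVERSE[:5]})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            enrich([], [], {"s": ["g1"]})
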