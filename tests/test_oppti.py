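import itertools
import math

import numpy as np
import pandas as pd
import pytest

from protarget.io_model import AbundanceMatrix
from protarget.oppti import (
    MAD_SCALE,
    NeighborMap,
    OpptiParams,
    build_neighbor_map,
    call_overexpression,
    dysregulation,
    enrichment_pvalues,
    infer_background,
    marker_standardize,
    permutation_null,
    run_oppti,
)
from protarget.preprocess import mad_normalize
from protarget.simulate import SimParams, generate_cohort
from tests.conftest import correlated_vector


def zmat(values, markers=None):
    arr = np.asarray(values, dtype=float)
    markers = markers or [f"m{i}" for i in range(arr.shape[0])]
    cols = [f"s{j}" for j in range(arr.shape[1])]
    return AbundanceMatrix(
        pd.DataFrame(arr, index=markers, columns=cols), scale_tag="marker_zscore"
    )


def brute_force_null(scores, threshold):
    """Oracle: enumerate every combination of within-sample permutations."""
    scores = np.asarray(scores, dtype=float)
    n_markers, n_samples = scores.shape
    col_perms = []
    for j in range(n_samples):
        idx = np.flatnonzero(~np.isnan(scores[:, j]))
        col_perms.append([
            (idx, np.array(p)) for p in itertools.permutations(scores[idx, j])
        ])
    pool = []
    for combo in itertools.product(*col_perms):
        work = scores.copy()
        for j, (idx, vals) in enumerate(combo):
            work[idx, j] = vals
        with np.errstate(invalid="ignore"):
            pool.extend(np.nansum(work > threshold, axis=1).astype(int))
    return np.array(pool)


class TestMarkerStandardize:
    def test_hand_arithmetic(self):
        m = AbundanceMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"], columns=["s1", "s2", "s3"]),
            scale_tag="mad_normalized",
        )
        z = marker_standardize(m)
        np.testing.assert_allclose(
            z.data.to_numpy().ravel(), [-1 / MAD_SCALE, 0.0, 1 / MAD_SCALE], atol=1e-9
        )
        assert z.data.iloc[0, 0] == pytest.approx(-0.6745, abs=1e-4)

    def test_symmetric(self):
        m = AbundanceMatrix(
            pd.DataFrame([[-3.0, -1.0, 0.0, 1.0, 3.0]], index=["A"],
                         columns=list("abcde"))
        )
        z = marker_standardize(m).data.to_numpy().ravel()
        np.testing.assert_allclose(z, -z[::-1], atol=1e-12)

    def test_constant_marker_dropped(self):
        m = AbundanceMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["A", "B"],
                         columns=["s1", "s2", "s3"])
        )
        z = marker_standardize(m)
        assert z.marker_ids == ["B"]


class TestBuildNeighborMap:
    def test_duplicate_marker_is_top_neighbor(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        m = zmat([base, base, rng.normal(size=50)], ["A", "Adup", "C"])
        nb = build_neighbor_map(m, OpptiParams(k=1, min_overlap=5))
        assert nb.neighbors["A"] == ["Adup"]
        assert nb.weights["A"][0] == pytest.approx(1.0)

    def test_constructed_correlations(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        b = correlated_vector(rng, a, 0.9)
        c = correlated_vector(rng, a, 0.5)
        d = correlated_vector(rng, a, -0.8)
        m = zmat([a, b, c, d], ["A", "B", "C", "D"])
        nb = build_neighbor_map(m, OpptiParams(k=2, min_overlap=5))
        assert nb.neighbors["A"] == ["B", "C"]
        np.testing.assert_allclose(nb.weights["A"], [0.9 / 1.4, 0.5 / 1.4], atol=1e-6)

    def test_k_clipped_to_available(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=60)
        rows = [correlated_vector(rng, base, r) for r in (0.9, 0.8, 0.7, 0.6, 0.5)]
        m = zmat(rows)
        nb = build_neighbor_map(m, OpptiParams(k=10, min_overlap=5))
        assert len(nb.neighbors["m0"]) == 4  # all positive-correlated others

    def test_no_positive_correlate_excluded(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=100)
        b = correlated_vector(rng, a, -0.9)
        c = correlated_vector(rng, a, 0.7)
        m = zmat([a, b, c], ["A", "B", "C"])
        nb = build_neighbor_map(m, OpptiParams(k=2, min_overlap=5))
        # B anticorrelates with A; whether it is excluded depends on corr(B, C)
        assert "A" in nb.neighbors
        assert "B" not in nb.neighbors["A"]

    def test_too_few_markers(self):
        m = zmat([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="2 markers"):
            build_neighbor_map(m, OpptiParams(k=1, min_overlap=2))

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        m = zmat(rng.normal(size=(20, 40)))
        nb = build_neighbor_map(m, OpptiParams(k=5, min_overlap=10))
        for marker, w in nb.weights.items():
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()
            assert marker not in nb.neighbors[marker]


class TestInferBackground:
    def test_identical_neighbor(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        m = zmat([base, base], ["A", "B"])
        nb = build_neighbor_map(m, OpptiParams(k=1, min_overlap=5))
        inferred = infer_background(m, nb)
        np.testing.assert_allclose(inferred.loc["A"].to_numpy(), base, atol=1e-12)

    def test_weighted_mean_arithmetic(self):
        m = zmat([[0.0], [2.0], [-2.0]], ["A", "N1", "N2"])
        nb = NeighborMap(
            neighbors={"A": ["N1", "N2"]},
            weights={"A": np.array([0.75, 0.25])},
        )
        inferred = infer_background(m, nb)
        assert inferred.loc["A", "s0"] == pytest.approx(1.0)

    def test_all_neighbors_missing(self):
        m = zmat([[0.0, 1.0], [np.nan, 2.0], [np.nan, -2.0]], ["A", "N1", "N2"])
        nb = NeighborMap(
            neighbors={"A": ["N1", "N2"]},
            weights={"A": np.array([0.75, 0.25])},
        )
        inferred = infer_background(m, nb)
        assert np.isnan(inferred.loc["A", "s0"])

    def test_renormalizes_over_observed(self):
        m = zmat([[0.0], [np.nan], [4.0]], ["A", "N1", "N2"])
        nb = NeighborMap(
            neighbors={"A": ["N1", "N2"]},
            weights={"A": np.array([0.75, 0.25])},
        )
        inferred = infer_background(m, nb)
        assert inferred.loc["A", "s0"] == pytest.approx(4.0)


class TestDysregulation:
    def test_marker_equal_to_neighbor_zero_before_restandardization(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        m = zmat([base, base], ["A", "B"])
        nb = build_neighbor_map(m, OpptiParams(k=1, min_overlap=5))
        inferred = infer_background(m, nb)
        raw = m.data.to_numpy() - inferred.to_numpy()
        np.testing.assert_allclose(raw[0], 0.0, atol=1e-12)
        # restandardization then flags the marker untestable (MAD 0)
        d = dysregulation(m, inferred)
        assert d.loc["A"].isna().all()

    def test_planted_outlier_is_max(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=40)
        sig = base.copy()
        sig[7] += 5.0
        m = zmat([sig, base], ["A", "B"])
        nb = NeighborMap(neighbors={"A": ["B"]}, weights={"A": np.array([1.0])})
        inferred = infer_background(m, nb)
        # deviations are 0 except the planted cell; perturb slightly for MAD > 0
        m2 = zmat([sig + rng.normal(scale=0.01, size=40), base], ["A", "B"])
        d = dysregulation(m2, infer_background(m2, nb))
        assert d.loc["A"].idxmax() == d.columns[7]

    def test_median_near_zero_after_restandardization(self):
        rng = np.random.default_rng(2)
        m = zmat(rng.normal(size=(5, 50)))
        nb = build_neighbor_map(m, OpptiParams(k=2, min_overlap=10))
        d = dysregulation(m, infer_background(m, nb))
        meds = d.median(axis=1).dropna()
        np.testing.assert_allclose(meds.to_numpy(), 0.0, atol=1e-9)


class TestCallOverexpression:
    def test_boundary_not_called(self):
        d = pd.DataFrame([[2.0, 2.1, np.nan]], index=["A"], columns=list("abc"))
        calls = call_overexpression(d, 2.0)
        assert not calls.loc["A", "a"]  # exactly T -> not called
        assert calls.loc["A", "b"]
        assert not calls.loc["A", "c"]  # missing never called

    def test_single_planted_outlier(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(rng.normal(scale=0.5, size=(4, 10)))
        d.iloc[2, 3] = 5.0
        calls = call_overexpression(d, 2.0)
        assert calls.to_numpy().sum() == 1
        assert calls.iloc[2, 3]

    def test_all_equal_no_calls(self):
        d = pd.DataFrame(np.ones((3, 4)))
        assert not call_overexpression(d, 2.0).to_numpy().any()


class TestPermutationNull:
    def test_column_constant_counts_unchanged(self):
        d = pd.DataFrame(
            np.tile(np.array([[3.0, 0.0, 3.0]]), (4, 1)),
            index=list("ABCD"), columns=list("abc"),
        )
        null = permutation_null(d, 2.0, n_perm=20, seed=0)
        observed = (d > 2.0).sum(axis=1).to_numpy()
        assert set(null.counts) == set(observed)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(2, 3))
        scores[0, 0] = 3.0
        d = pd.DataFrame(scores, index=["A", "B"], columns=list("abc"))
        null = permutation_null(d, 2.0, exhaustive=True)
        oracle = brute_force_null(scores, 2.0)
        assert sorted(null.counts) == sorted(oracle)
        assert null.n_perm == 2**3

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        d = pd.DataFrame(rng.normal(size=(10, 8)))
        a = permutation_null(d, 2.0, n_perm=15, seed=42)
        b = permutation_null(d, 2.0, n_perm=15, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_missing_entries_stay_in_place(self):
        d = pd.DataFrame(
            [[3.0, np.nan], [0.0, np.nan], [1.0, 5.0]],
            index=list("ABC"), columns=list("ab"),
        )
        null = permutation_null(d, 2.0, n_perm=10, seed=1)
        # column b has one observed value; total calls per iteration constant
        total_observed = int((d > 2.0).sum().sum())
        per_iter = null.counts.reshape(10, 3).sum(axis=1)
        assert (per_iter == total_observed).all()

    def test_single_marker_rejected(self):
        d = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=list("ab"))
        with pytest.raises(ValueError, match="2 markers"):
            permutation_null(d, 2.0)

    def test_invalid_nperm(self):
        with pytest.raises(ValueError):
            OpptiParams(n_perm=0)


class TestEnrichmentPvalues:
    def test_observed_zero_gives_one(self):
        from protarget.oppti import PermutationNull

        null = PermutationNull(counts=np.array([0, 1, 2, 0]), n_perm=2, seed=0)
        p = enrichment_pvalues(np.array([0]), null)
        assert p[0] == pytest.approx(1.0)

    def test_exceeding_maximum(self):
        from protarget.oppti import PermutationNull

        null = PermutationNull(counts=np.array([0, 1, 2, 3]), n_perm=2, seed=0)
        p = enrichment_pvalues(np.array([10]), null)
        assert p[0] == pytest.approx(1.0 / 5.0)

    def test_planted_marker_significant(self):
        rng = np.random.default_rng(7)
        n_samples = 100
        scores = rng.normal(size=(201, n_samples))
        hit = rng.random(n_samples) < 0.15
        scores[0, hit] += 4.0
        d = pd.DataFrame(scores)
        null = permutation_null(d, 2.0, n_perm=100, seed=0)
        observed = (d > 2.0).sum(axis=1).to_numpy()
        p = enrichment_pvalues(observed, null)
        assert p[0] < 0.01


class TestRunOppti:
    def test_pro_arithmetic(self):
        # a marker called in 20 of 159 quantified samples -> PRO = 0.1258
        assert 20 / 159 == pytest.approx(0.1258, abs=5e-5)
        rng = np.random.default_rng(8)
        p = SimParams(n_markers=40, n_subjects=30, missing_rate=0.1)
        tumor, _, _, _ = generate_cohort(p, 11)
        res = run_oppti(mad_normalize(tumor),
                        OpptiParams(k=5, min_overlap=10, n_perm=20, seed=0))
        t = res.table.dropna(subset=["pro"])
        np.testing.assert_allclose(
            t["pro"].to_numpy(), (t["n_called"] / t["n_quantified"]).to_numpy()
        )

    def test_determinism(self):
        p = SimParams(n_markers=30, n_subjects=25, n_outlier_markers=3)
        tumor, _, _, _ = generate_cohort(p, 2)
        params = OpptiParams(k=5, min_overlap=10, n_perm=25, seed=9)
        a = run_oppti(mad_normalize(tumor), params)
        b = run_oppti(mad_normalize(tumor), params)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_calls_depend_only_on_own_scores(self):
        # permuting OTHER markers' scores does not change marker A's calls
        rng = np.random.default_rng(9)
        d = pd.DataFrame(rng.normal(size=(6, 12)))
        calls_before = call_overexpression(d, 2.0).iloc[0]
        shuffled = d.copy()
        for j in range(shuffled.shape[1]):
            other = shuffled.iloc[1:, j].to_numpy()
            shuffled.iloc[1:, j] = rng.permutation(other)
        calls_after = call_overexpression(shuffled, 2.0).iloc[0]
        pd.testing.assert_series_equal(calls_before, calls_after)

    def test_dropped_markers_reported_with_missing_stats(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=30)
        rows = {
            "A": base + rng.normal(scale=0.2, size=30),
            "B": base + rng.normal(scale=0.2, size=30),
            "CONST": np.ones(30),
        }
        m = AbundanceMatrix(pd.DataFrame(rows).T)
        m.data.columns = [f"s{j}" for j in range(30)]
        res = run_oppti(m, OpptiParams(k=2, min_overlap=10, n_perm=10, seed=0))
        row = res.table.set_index("marker").loc["CONST"]
        assert np.isnan(row["perm_p"])
        assert set(res.table["marker"]) == {"A", "B", "CONST"}
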