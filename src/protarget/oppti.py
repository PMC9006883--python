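"""Outlier-overexpression detection on a tumor cohort.

Each marker's expected abundance in a tumor sample is inferred from its most
strongly co-expressed markers (weighted k-nearest neighbors on Pearson
correlation, positive correlates only).  The deviation of the observed value
from this background — the dysregulation score — is robustly restandardized
per marker; samples exceeding a cutoff are overexpression calls.  Marker-level
enrichment of calls is tested against a null built by permuting dysregulation
scores within every sample across markers, pooling null call counts over all
iterations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from protarget.diffexp import bh_fdr
from protarget.io_model import AbundanceMatrix

#: Gaussian consistency constant so MAD estimates the SD under normality
MAD_SCALE = 1.4826


@dataclass
class OpptiParams:
    """Tuning parameters for the outlier-overexpression detector.

    ``min_overlap=None`` resolves at run time to max(30, 25% of samples),
    clipped to the sample count.  ``exhaustive=True`` replaces Monte Carlo
    permutations with full enumeration of within-sample rearrangements
    (feasible only for tiny matrices).
    """

    k: int = 10
    min_overlap: int | None = None
    threshold_T: float = 2.0
    n_perm: int = 100
    seed: int = 0
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if not self.threshold_T > 0:
            raise ValueError(f"threshold_T must be positive, got {self.threshold_T}")

    def resolve_min_overlap(self, n_samples: int) -> int:
        if self.min_overlap is not None:
            return self.min_overlap
        return min(n_samples, max(30, math.ceil(0.25 * n_samples)))


@dataclass
class NeighborMap:
    """Per-marker co-expressed neighbors with normalized nonnegative weights."""

    neighbors: dict[str, list[str]]
    weights: dict[str, np.ndarray]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for marker, nbs in self.neighbors.items():
            w = self.weights[marker]
            if marker in nbs:
                raise ValueError(f"marker {marker!r} is its own neighbor")
            if len(nbs) < 1:
                raise ValueError(f"marker {marker!r} has no neighbors")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"weights for {marker!r} must be >= 0 and sum to 1")


@dataclass
class PermutationNull:
    """Pooled null per-marker overexpression counts across permutation iterations."""

    counts: np.ndarray  # flattened pool, one count per (iteration, marker)
    n_perm: int
    seed: int | None


@dataclass
class OpptiResult:
    """Per-marker overexpression summary plus per-cell scores and calls."""

    table: pd.DataFrame  # marker, pro, perm_p, fdr, n_called, n_quantified
    dysregulation: pd.DataFrame
    calls: pd.DataFrame
    params: OpptiParams


# ---------------------------------------------------------------------------


def marker_standardize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Robust per-marker z-scores: (x - median) / (1.4826 * MAD), across samples.

    Markers with zero MAD are dropped.
    """
    values = m.data.to_numpy(copy=True)
    med = np.nanmedian(values, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(values - med), axis=1, keepdims=True)
    keep = (mad[:, 0] > 0) & ~np.isnan(mad[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - med) / (MAD_SCALE * mad)
    out = pd.DataFrame(z[keep], index=m.data.index[keep], columns=m.data.columns)
    return AbundanceMatrix(out, scale_tag="marker_zscore")


def build_neighbor_map(z: AbundanceMatrix, params: OpptiParams) -> NeighborMap:
    """Top-k positively correlated markers per marker, correlation-weighted.

    Pearson correlations are pairwise-complete and require at least
    ``min_overlap`` shared samples.  Markers with no positive correlate are
    excluded from testing and listed in ``excluded``.  When fewer than k
    other markers exist, all positive correlates are used.
    """
    n_markers, n_samples = z.shape
    if n_markers < 2:
        raise ValueError(f"need at least 2 markers, got {n_markers}")
    min_overlap = params.resolve_min_overlap(n_samples)
    # markers are rows; corr() works column-wise, hence the transpose
    corr = z.data.T.corr(min_periods=min_overlap)
    cmat = corr.to_numpy(copy=True)
    np.fill_diagonal(cmat, np.nan)
    markers = list(z.data.index)
    neighbors: dict[str, list[str]] = {}
    weights: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for i, marker in enumerate(markers):
        row = cmat[i]
        pos = np.where(np.nan_to_num(row, nan=-1.0) > 0)[0]
        if len(pos) == 0:
            excluded.append(marker)
            continue
        top = pos[np.argsort(row[pos], kind="mergesort")[::-1][: params.k]]
        w = row[top]
        neighbors[marker] = [markers[j] for j in top]
        weights[marker] = w / w.sum()
    return NeighborMap(neighbors=neighbors, weights=weights, excluded=excluded)


def infer_background(z: AbundanceMatrix, nb: NeighborMap) -> pd.DataFrame:
    """Weighted mean of neighbor z-scores, weights renormalized over observed
    neighbors; missing where no neighbor is observed."""
    data = z.data
    idx = {m: i for i, m in enumerate(data.index)}
    values = data.to_numpy()
    out = np.full(values.shape, np.nan)
    for marker, nbs in nb.neighbors.items():
        i = idx[marker]
        rows = values[[idx[n] for n in nbs]]  # (k, n_samples)
        w = nb.weights[marker][:, None]
        obs = ~np.isnan(rows)
        wsum = np.where(obs, w, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            est = np.nansum(rows * w, axis=0) / wsum
        out[i] = np.where(wsum > 0, est, np.nan)
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def dysregulation(z: AbundanceMatrix, inferred: pd.DataFrame) -> pd.DataFrame:
    """Observed-minus-inferred deviations, robustly restandardized per marker.

    Markers whose deviation MAD is zero (or with no scores at all) come back
    as all-missing rows, flagging them untestable.
    """
    import warnings as _warnings

    d = z.data.to_numpy() - inferred.to_numpy()
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="All-NaN slice")
        med = np.nanmedian(d, axis=1, keepdims=True)
        mad = np.nanmedian(np.abs(d - med), axis=1, keepdims=True)
    ok = np.isfinite(mad[:, 0]) & (mad[:, 0] > 0)
    out = np.full(d.shape, np.nan)
    out[ok] = (d[ok] - med[ok]) / (MAD_SCALE * mad[ok])
    return pd.DataFrame(out, index=z.data.index, columns=z.data.columns)


def call_overexpression(d: pd.DataFrame, threshold_T: float) -> pd.DataFrame:
    """Boolean calls: score strictly greater than the cutoff; missing never called."""
    return d.gt(threshold_T) & d.notna()


# ---------------------------------------------------------------------------
# permutation null


def _exceedance_counts(scores: np.ndarray, threshold: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nansum(scores > threshold, axis=1).astype(int)


def permutation_null(
    d: pd.DataFrame,
    threshold_T: float,
    n_perm: int = 100,
    seed: int | None = 0,
    exhaustive: bool = False,
    max_exhaustive: int = 200_000,
) -> PermutationNull:
    """Null per-marker call counts from within-sample score permutations.

    Each iteration independently permutes the observed scores of every sample
    across markers (missing entries stay in place) and recounts per-marker
    exceedances of the cutoff; counts from all iterations are pooled into one
    empirical null.  ``exhaustive=True`` enumerates every combination of
    within-sample rearrangements instead (error if the space exceeds
    ``max_exhaustive``).
    """
    scores = d.to_numpy()
    n_markers, n_samples = scores.shape
    if n_markers < 2:
        raise ValueError("permutation null needs at least 2 markers")
    obs_idx = [np.flatnonzero(~np.isnan(scores[:, j])) for j in range(n_samples)]

    if exhaustive:
        per_col = [
            list(itertools.permutations(scores[idx, j], len(idx)))
            for j, idx in enumerate(obs_idx)
        ]
        total = math.prod(len(p) for p in per_col)
        if total > max_exhaustive:
            raise ValueError(
                f"exhaustive enumeration would need {total} arrangements "
                f"(limit {max_exhaustive})"
            )
        pool = []
        work = scores.copy()
        for combo in itertools.product(*per_col):
            for j, (idx, vals) in enumerate(zip(obs_idx, combo)):
                work[idx, j] = vals
            pool.append(_exceedance_counts(work, threshold_T))
        counts = np.concatenate(pool)
        return PermutationNull(counts=counts, n_perm=total, seed=None)

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.empty((n_perm, n_markers), dtype=int)
    work = scores.copy()
    for it in range(n_perm):
        for j, idx in enumerate(obs_idx):
            if len(idx) > 1:
                work[idx, j] = scores[rng.permutation(idx), j]
        pool[it] = _exceedance_counts(work, threshold_T)
    return PermutationNull(counts=pool.ravel(), n_perm=n_perm, seed=seed)


def enrichment_pvalues(observed_counts: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Add-one empirical p-values against the pooled null counts."""
    pool = np.sort(null.counts)
    n = len(pool)
    if n == 0:
        raise ValueError("empty permutation null pool")
    obs = np.asarray(observed_counts)
    # number of null counts >= observed, via sorted search
    geq = n - np.searchsorted(pool, obs, side="left")
    return (1.0 + geq) / (1.0 + n)


# ---------------------------------------------------------------------------


def run_oppti(m: AbundanceMatrix, params: OpptiParams | None = None) -> OpptiResult:
    """Full outlier-overexpression analysis of a tumor-sample matrix.

    The input should be sample-MAD-normalized (or otherwise scale-aligned);
    per-marker robust z-scoring is applied here.  PRO is the fraction of
    quantified samples (non-missing abundance for the marker) that are
    called.  Markers dropped along the way (constant, no positive correlate,
    degenerate deviation spread) appear in the table with missing statistics.
    """
    params = params or OpptiParams()
    z = marker_standardize(m)
    nb = build_neighbor_map(z, params)
    inferred = infer_background(z, nb)
    d = dysregulation(z, inferred)
    tested = d.index[d.notna().any(axis=1)]
    d_tested = d.loc[tested]
    calls = call_overexpression(d_tested, params.threshold_T)

    observed = calls.sum(axis=1).to_numpy()
    null = permutation_null(
        d_tested,
        params.threshold_T,
        n_perm=params.n_perm,
        seed=params.seed,
        exhaustive=params.exhaustive,
    )
    perm_p = enrichment_pvalues(observed, null)
    fdr = bh_fdr(perm_p)

    n_quant = m.data.loc[tested].notna().sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pro = np.where(n_quant > 0, observed / n_quant, np.nan)
    tested_table = pd.DataFrame(
        {
            "marker": tested,
            "pro": pro,
            "perm_p": perm_p,
            "fdr": fdr,
            "n_called": observed,
            "n_quantified": n_quant,
        }
    )
    dropped = [mk for mk in m.data.index if mk not in set(tested)]
    if dropped:
        dropped_table = pd.DataFrame(
            {
                "marker": dropped,
                "pro": np.nan,
                "perm_p": np.nan,
                "fdr": np.nan,
                "n_called": 0,
                "n_quantified": m.data.loc[dropped].notna().sum(axis=1).to_numpy(),
            }
        )
        table = pd.concat([tested_table, dropped_table], ignore_index=True)
        table = table.set_index("marker").loc[list(m.data.index)].reset_index()
    else:
        table = tested_table.reset_index(drop=True)
    return OpptiResult(table=table, dysregulation=d, calls=calls, params=params)
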