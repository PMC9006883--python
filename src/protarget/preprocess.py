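"""Cohort-level normalization and filtering for proteomic and transcriptomic matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from protarget.io_model import AbundanceMatrix


@dataclass
class PreprocessParams:
    max_missing_frac: float = 0.20
    rna_zero_frac: float = 0.20
    rna_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("max_missing_frac", "rna_zero_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def _sample_mad(col: np.ndarray) -> float:
    # plain MAD, no Gaussian consistency constant: the target is unit MAD
    obs = col[~np.isnan(col)]
    med = np.median(obs)
    return float(np.median(np.abs(obs - med)))


def mad_normalize(m: AbundanceMatrix, center: bool = False) -> AbundanceMatrix:
    """Divide each sample's values by that sample's median absolute deviation.

    After the transform every sample has unit MAD over its non-missing values.
    Missing entries are preserved.  ``center=True`` additionally subtracts the
    sample median first (off by default; log-ratio data are already near-centered).

    Raises
    ------
    ValueError
        If any sample has MAD 0 (degenerate sample) or fewer than 2 distinct
        non-missing values.
    """
    values = m.data.to_numpy(copy=True)
    degenerate = []
    for j, sample in enumerate(m.data.columns):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if len(np.unique(obs)) < 2:
            degenerate.append(sample)
            continue
        med = np.median(obs)
        mad = np.median(np.abs(obs - med))
        if mad == 0:
            degenerate.append(sample)
            continue
        if center:
            values[:, j] = (col - med) / mad
        else:
            values[:, j] = col / mad
    if degenerate:
        raise ValueError(f"samples with zero MAD (degenerate): {degenerate}")
    out = pd.DataFrame(values, index=m.data.index, columns=m.data.columns)
    return AbundanceMatrix(out, scale_tag="mad_normalized")


def filter_missing_markers(
    m: AbundanceMatrix, max_missing_frac: float = 0.20
) -> AbundanceMatrix:
    """Drop markers whose missing fraction is at least ``max_missing_frac``.

    The boundary is inclusive ("at least 20%" removed).  Retained values and
    marker order are untouched.
    """
    frac = m.data.isna().mean(axis=1)
    keep = frac < max_missing_frac
    if not keep.any():
        raise ValueError("all markers removed by missingness filter (empty cohort)")
    return AbundanceMatrix(m.data.loc[keep].copy(), scale_tag=m.scale_tag)


def missingness_report(m: AbundanceMatrix, max_missing_frac: float = 0.20) -> pd.DataFrame:
    frac = m.data.isna().mean(axis=1)
    return pd.DataFrame(
        {
            "marker": m.data.index,
            "missing_frac": frac.to_numpy(),
            "kept": (frac < max_missing_frac).to_numpy(),
        }
    )


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one sorted value vector.

    The reference distribution is the mean of order statistics across samples.
    Tied values receive the mean of their reference quantiles.  Missing values
    are normalized per sample using only observed entries' ranks (mapped onto
    the reference by linear interpolation on quantile position).
    """
    values = df.to_numpy(dtype=float)
    n_rows = values.shape[0]
    # reference: average of per-sample sorted values, interpolated onto the
    # common 0..1 quantile grid when samples have unequal observed counts
    grid = np.linspace(0.0, 1.0, n_rows)
    sorted_cols = []
    for j in range(values.shape[1]):
        obs = np.sort(values[~np.isnan(values[:, j]), j])
        if len(obs) == 0:
            raise ValueError(f"sample {df.columns[j]!r} has no observed values")
        if len(obs) == 1:
            sorted_cols.append(np.full(n_rows, obs[0]))
        else:
            q = np.linspace(0.0, 1.0, len(obs))
            sorted_cols.append(np.interp(grid, q, obs))
    reference = np.mean(sorted_cols, axis=0)

    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        mask = ~np.isnan(values[:, j])
        col = values[mask, j]
        n_obs = len(col)
        # average rank handles ties -> mean of reference quantiles
        order = pd.Series(col).rank(method="average").to_numpy() - 1.0
        q = order / (n_obs - 1) if n_obs > 1 else np.zeros(n_obs)
        out[mask, j] = np.interp(q, grid, reference)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_rna(
    fpkm: AbundanceMatrix, params: PreprocessParams | None = None
) -> AbundanceMatrix:
    """Filter near-silent genes, log2-transform and quantile-normalize FPKM values.

    Genes with zero expression in at least ``rna_zero_frac`` of samples are
    removed; survivors are transformed log2(FPKM + pseudocount) and then
    quantile-normalized.  Values must be nonnegative.
    """
    params = params or PreprocessParams()
    values = fpkm.data
    if (values < 0).any().any():
        bad = values.stack()
        bad = bad[bad < 0]
        raise ValueError(f"negative FPKM values, e.g. {bad.index[0]} = {bad.iloc[0]}")
    zero_frac = (values == 0).mean(axis=1)
    keep = zero_frac < params.rna_zero_frac
    if not keep.any():
        raise ValueError("all genes removed by the zero-expression filter")
    logged = np.log2(values.loc[keep] + params.rna_pseudocount)
    normalized = quantile_normalize(logged)
    return AbundanceMatrix(normalized, scale_tag="rna_normalized")
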