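"""Paired tumor-vs-normal differential expression with variance moderation.

The model works on within-pair differences (tumor minus matched normal) with
mean-centered subject-level covariates, so the intercept is the adjusted log2
fold change.  Per-marker residual variances are shrunk toward a common prior
estimated by matching moments of log variances against the scaled-F model,
and the moderated t statistic is referred to a t distribution with augmented
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from protarget.io_model import AbundanceMatrix

DEFAULT_COVARIATES = ("age", "gender")


@dataclass
class ModerationFit:
    """Prior degrees of freedom and prior variance for the moderated t."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError(f"d0 must be positive, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be positive, got {self.s0_sq}")


# ---------------------------------------------------------------------------
# pairing


def build_paired_differences(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-subject difference matrix and centered covariate table.

    Returns ``(diffs, X)`` where ``diffs`` is markers x subjects with
    d = tumor - normal (NaN when either tissue is unobserved) and ``X`` is
    subjects x covariates, mean-centered.  Categorical covariates (gender,
    batch) are dummy-encoded; missing covariate values are mean-imputed
    (zero after centering).
    """
    tumor = meta[meta["tissue"] == "tumor"].set_index("subject_id")["sample_id"]
    normal = meta[meta["tissue"] == "normal"].set_index("subject_id")["sample_id"]
    if tumor.index.has_duplicates or normal.index.has_duplicates:
        raise ValueError("a subject has more than one sample of the same tissue")
    subjects = [
        s
        for s in tumor.index
        if s in normal.index
        and tumor[s] in m.data.columns
        and normal[s] in m.data.columns
    ]
    if not subjects:
        raise ValueError("no subjects with both tumor and normal samples in the matrix")
    t_cols = [tumor[s] for s in subjects]
    n_cols = [normal[s] for s in subjects]
    diffs = pd.DataFrame(
        m.data[t_cols].to_numpy() - m.data[n_cols].to_numpy(),
        index=m.data.index,
        columns=subjects,
    )

    meta_sub = meta.drop_duplicates("subject_id").set_index("subject_id").loc[subjects]
    cols = {}
    for cov in covariates:
        if cov not in meta_sub.columns:
            continue
        raw = meta_sub[cov]
        if pd.api.types.is_numeric_dtype(raw):
            cols[cov] = pd.to_numeric(raw, errors="coerce")
        else:
            levels = sorted(x for x in raw.dropna().unique())
            for lv in levels[1:]:  # first level is the reference
                cols[f"{cov}_{lv}"] = (raw == lv).astype(float).where(raw.notna())
    X = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"), dtype=float)
    X = X - X.mean()
    X = X.fillna(0.0)  # missing covariate -> mean imputation after centering
    return diffs, X


# ---------------------------------------------------------------------------
# per-marker fit


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep_idx: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep_idx + [j]]
        if np.linalg.matrix_rank(trial) > len(keep_idx):
            keep_idx.append(j)
        else:
            warnings.warn(f"dropping collinear covariate {names[j]!r}", stacklevel=3)
    return X[:, keep_idx], [names[i] for i in keep_idx]


def fit_marker_model(
    d: np.ndarray, covariates: np.ndarray | None = None, names: list[str] | None = None
) -> tuple[float, float, int, float]:
    """OLS fit of differences on an intercept plus centered covariates.

    Returns ``(log2fc, s_sq, df, v)`` where log2fc is the intercept estimate,
    s_sq the residual variance, df the residual degrees of freedom and v the
    unscaled variance of the intercept estimate (diagonal of (X'X)^-1).
    Collinear covariates are dropped with a warning.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    if covariates is None or covariates.size == 0:
        X = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        X = np.column_stack([np.ones(n), covariates])
        names = ["intercept"] + (names or [f"x{j}" for j in range(covariates.shape[1])])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            X, _ = _drop_collinear(X, names)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    beta, _, _, _ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ beta
    df = n - p
    s_sq = float(resid @ resid / df)
    xtx_inv = np.linalg.inv(X.T @ X)
    return float(beta[0]), s_sq, df, float(xtx_inv[0, 0])


# ---------------------------------------------------------------------------
# empirical Bayes moderation


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires positive input")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_moderation(
    s_sq: np.ndarray, df: np.ndarray, min_markers: int = 10
) -> ModerationFit:
    """Estimate the variance prior (d0, s0_sq) by moment matching on log s^2.

    Matches the mean and variance of ``log(s^2)`` against the scaled-F model
    using digamma/trigamma identities.  When the trigamma equation has no
    positive solution (observed spread no larger than expected under a fixed
    variance), d0 is infinite and s0_sq is the consistent (geometric-scale)
    mean.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (df > 0)
    s_sq, df = s_sq[ok], df[ok]
    if len(s_sq) < min_markers:
        raise ValueError(
            f"need at least {min_markers} markers with positive residual variance, got {len(s_sq)}"
        )
    z = np.log(s_sq)
    if np.ptp(z) == 0:  # degenerate: identical variances, no spread to model
        return ModerationFit(d0=np.inf, s0_sq=float(s_sq[0]))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return ModerationFit(d0=d0, s0_sq=s0_sq)


def moderated_t(
    log2fc: float | np.ndarray,
    s_sq: float | np.ndarray,
    df: float | np.ndarray,
    fit: ModerationFit | None,
    v: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistic and two-sided p-value.

    The posterior variance is ``(d0*s0^2 + df*s^2)/(d0 + df)`` and the test
    is referred to a t distribution with ``df + d0`` degrees of freedom
    (standard normal when d0 is infinite).  ``fit=None`` or d0 = 0 reduces to
    the ordinary OLS t-test.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    v = np.asarray(v, dtype=float)
    if fit is None:
        d0, s0_sq = 0.0, 1.0
    else:
        d0, s0_sq = fit.d0, fit.s0_sq
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        t = log2fc / np.sqrt(s_tilde_sq * v)
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s_tilde_sq = (d0 * s0_sq + df * s_sq) / (d0 + df)
        t = log2fc / np.sqrt(s_tilde_sq * v)
        p = 2.0 * stats.t.sf(np.abs(t), df + d0)
    return t, p


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1.

    Missing p-values propagate as missing and do not count toward the number
    of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = q
    out[ok] = adjusted
    return out


# ---------------------------------------------------------------------------
# pipeline entry


def run_diffexp(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_pairs: int = 10,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-marker paired differential-expression table.

    Columns: marker, log2fc, t_mod, pvalue, fdr, n_pairs, significant
    (fdr < ``fdr_threshold``), up2fold (log2fc >= ``fc_threshold``).  Markers
    with fewer complete pairs than ``min_pairs`` appear with missing
    statistics.  ``moderate=False`` skips the empirical-Bayes shrinkage and
    reports classic OLS t-tests.
    """
    diffs, X = build_paired_differences(m, meta, covariates)
    markers = diffs.index.to_numpy()
    Xv = X.to_numpy()
    names = list(X.columns)

    n_mk = len(markers)
    log2fc = np.full(n_mk, np.nan)
    s_sq = np.full(n_mk, np.nan)
    dfree = np.full(n_mk, np.nan)
    vcoef = np.full(n_mk, np.nan)
    n_pairs = np.zeros(n_mk, dtype=int)

    D = diffs.to_numpy()
    for i in range(n_mk):
        obs = ~np.isnan(D[i])
        n_pairs[i] = int(obs.sum())
        if n_pairs[i] < min_pairs:
            continue
        d = D[i, obs]
        covs = Xv[obs] if Xv.size else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fc, s2, df_i, v_i = fit_marker_model(d, covs, names)
        except ValueError:
            continue
        log2fc[i], s_sq[i], dfree[i], vcoef[i] = fc, s2, df_i, v_i

    testable = ~np.isnan(s_sq) & (dfree > 0) & (s_sq > 0)
    fit: ModerationFit | None = None
    if moderate and testable.sum() >= 10:
        fit = fit_moderation(s_sq[testable], dfree[testable])

    t_mod = np.full(n_mk, np.nan)
    pvalue = np.full(n_mk, np.nan)
    est = ~np.isnan(log2fc) & (dfree > 0)
    if est.any():
        t_mod[est], pvalue[est] = moderated_t(
            log2fc[est], s_sq[est], dfree[est], fit, vcoef[est]
        )
    fdr = bh_fdr(pvalue)

    table = pd.DataFrame(
        {
            "marker": markers,
            "log2fc": log2fc,
            "t_mod": t_mod,
            "pvalue": pvalue,
            "fdr": fdr,
            "n_pairs": n_pairs,
        }
    )
    table["significant"] = table["fdr"] < fdr_threshold
    table["up2fold"] = table["log2fc"] >= fc_threshold
    return table
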