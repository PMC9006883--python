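"""Driver-mutation filtering, DNA/RNA/protein alteration-rate comparison,
candidate-target intersection, and cross-cohort concordance."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from protarget.io_model import (
    MutationTable,
    RecurrenceCatalog,
    TRUNCATING_CLASSES,
)


def filter_driver_mutations(
    muts: MutationTable, catalog: RecurrenceCatalog, min_recurrence: int = 3
) -> MutationTable:
    """Keep truncating mutations plus recurrent missense mutations.

    A row survives iff its variant class is truncating, or it is a missense
    change whose (gene, protein_change) occurs at least ``min_recurrence``
    times in the reference catalog.  Idempotent.
    """
    rows = muts.rows
    truncating = rows["variant_class"].isin(TRUNCATING_CLASSES)
    recurrent = (rows["variant_class"] == "missense") & rows.apply(
        lambda r: catalog.count(r["gene"], r["protein_change"]) >= min_recurrence, axis=1
    )
    return MutationTable(rows[truncating | recurrent].reset_index(drop=True))


def dna_alteration_fraction(
    muts: MutationTable, gene: str, cohort_samples: Iterable[str]
) -> float:
    """Fraction of cohort samples carrying >= 1 retained mutation in the gene.

    Carriers are deduplicated; samples outside the cohort are ignored.
    A gene absent from the table scores 0.
    """
    cohort = set(cohort_samples)
    if not cohort:
        raise ValueError("cohort_samples must be non-empty")
    rows = muts.rows
    carriers = set(rows.loc[rows["gene"] == gene, "sample_id"]) & cohort
    return len(carriers) / len(cohort)


def dna_alteration_fractions(
    muts: MutationTable, genes: Iterable[str], cohort_samples: Iterable[str]
) -> pd.Series:
    """Vectorized :func:`dna_alteration_fraction` over a gene list."""
    cohort = set(cohort_samples)
    if not cohort:
        raise ValueError("cohort_samples must be non-empty")
    rows = muts.rows[muts.rows["sample_id"].isin(cohort)]
    carriers = rows.groupby("gene")["sample_id"].nunique()
    genes = list(genes)
    out = carriers.reindex(genes).fillna(0).astype(float) / len(cohort)
    out.index.name = "gene"
    return out


def _pro_series(oppti_like) -> pd.Series:
    """Accept an OpptiResult, its table, or a plain gene->rate Series/dict."""
    if hasattr(oppti_like, "table"):
        oppti_like = oppti_like.table
    if isinstance(oppti_like, pd.DataFrame):
        return oppti_like.set_index("marker")["pro"]
    return pd.Series(oppti_like, dtype=float)


def build_alteration_summary(
    dna_fracs: Mapping[str, float] | pd.Series,
    rna_oppti,
    pro_oppti,
    high_pro_min: float = 0.10,
    rna_fold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene DNA mutation fraction, mRNA and protein overexpression rates.

    The gene universe is the union of genes with any measurement; layers a
    gene lacks stay missing.  Flags: ``high_pro`` iff PRO >= ``high_pro_min``;
    ``pro_over_rna_2x`` iff PRO >= ``rna_fold`` * RNA (never flagged when the
    RNA rate is missing — absence of data is not a 2-fold claim);
    ``candidate`` is their conjunction.
    """
    dna = pd.Series(dna_fracs, dtype=float)
    rna = _pro_series(rna_oppti)
    pro = _pro_series(pro_oppti)
    genes = sorted(set(dna.index) | set(rna.index) | set(pro.index))
    out = pd.DataFrame(
        {
            "gene": genes,
            "dna_frac": dna.reindex(genes).to_numpy(),
            "rna_over": rna.reindex(genes).to_numpy(),
            "pro": pro.reindex(genes).to_numpy(),
        }
    )
    for col in ("dna_frac", "rna_over", "pro"):
        vals = out[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} values must lie in [0, 1]")
    out["high_pro"] = out["pro"] >= high_pro_min
    out["pro_over_rna_2x"] = (
        out["pro"].notna() & out["rna_over"].notna() & (out["pro"] >= rna_fold * out["rna_over"])
    )
    out["candidate"] = out["high_pro"] & out["pro_over_rna_2x"]
    return out


def select_candidates(
    dep: pd.DataFrame,
    oppti,
    druggable: set[str],
    fc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Intersect differential-expression and overexpression evidence on
    druggable markers.

    The ``strict`` tier requires log2fc >= ``fc_min``, DE FDR < ``fdr_max``
    and overexpression FDR < ``fdr_max``; the ``positive`` tier only requires
    log2fc > 0 and PRO > 0.  Output rows are druggable markers present in
    both tables, sorted by marker, with boolean tier columns.
    """
    oppti_table = oppti.table if hasattr(oppti, "table") else oppti
    merged = dep.merge(
        oppti_table[["marker", "pro", "perm_p", "fdr"]].rename(
            columns={"perm_p": "oppti_p", "fdr": "oppti_fdr"}
        ),
        on="marker",
        how="inner",
    )
    merged = merged[merged["marker"].isin(druggable)].copy()
    merged["tier_positive"] = (merged["log2fc"] > 0) & (merged["pro"] > 0)
    merged["tier_strict"] = (
        (merged["log2fc"] >= fc_min)
        & (merged["fdr"] < fdr_max)
        & (merged["oppti_fdr"] < fdr_max)
    )
    cols = [
        "marker", "log2fc", "fdr", "pro", "oppti_p", "oppti_fdr",
        "tier_positive", "tier_strict",
    ]
    return merged[cols].sort_values("marker", kind="mergesort").reset_index(drop=True)


def cohort_concordance(pro_a, pro_b) -> tuple[float, float, int]:
    """Pearson correlation of overexpression rates over shared markers.

    Returns ``(r, pvalue, n_shared)`` with the two-sided t-based p-value.
    Requires at least 3 shared markers with rates in both cohorts.
    """
    a = _pro_series(pro_a).dropna()
    b = _pro_series(pro_b).dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared markers, got {len(shared)}")
    r, p = stats.pearsonr(a[shared], b[shared])
    return float(r), float(p), len(shared)
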