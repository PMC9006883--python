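"""Expression-driven drug-dependency analysis on a cell-line screen.

For every (drug, target) pair in the drug-target map, cell viability under
the drug is regressed on the target's baseline expression across the shared
cell lines; a negative slope marks an expression-driven dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from protarget.diffexp import bh_fdr


@dataclass
class DrugScreen:
    """Viability (drugs x lines), expression (targets x lines) and drug->targets map."""

    viability: pd.DataFrame
    expression: pd.DataFrame
    drug_target_map: dict[str, set[str]]
    skipped_targets: list[tuple[str, str]] = field(default_factory=list)
    untestable_pairs: list[tuple[str, str]] = field(default_factory=list)


def align_screen(screen: DrugScreen, min_lines: int = 3) -> DrugScreen:
    """Intersect cell-line sets and flag unusable (drug, target) pairs.

    Targets missing from the expression matrix are recorded in
    ``skipped_targets``; mapped pairs with fewer than ``min_lines`` complete
    observations land in ``untestable_pairs``.
    """
    lines = [c for c in screen.viability.columns if c in set(screen.expression.columns)]
    if not lines:
        raise ValueError("no shared cell lines between viability and expression matrices")
    viability = screen.viability[lines].astype(float)
    expression = screen.expression[lines].astype(float)
    skipped: list[tuple[str, str]] = []
    untestable: list[tuple[str, str]] = []
    for drug, targets in screen.drug_target_map.items():
        for target in sorted(targets):
            if target not in expression.index or drug not in viability.index:
                skipped.append((drug, target))
                continue
            complete = viability.loc[drug].notna() & expression.loc[target].notna()
            if complete.sum() < min_lines:
                untestable.append((drug, target))
    return DrugScreen(
        viability=viability,
        expression=expression,
        drug_target_map=screen.drug_target_map,
        skipped_targets=skipped,
        untestable_pairs=untestable,
    )


def fit_dependency(
    viability_row: pd.Series | np.ndarray, expression_row: pd.Series | np.ndarray
) -> tuple[float, float, int]:
    """OLS slope of viability on expression with the two-sided t-test p-value.

    Returns ``(slope, pvalue, n_lines)``; raises on fewer than 3 complete
    pairs and returns missing statistics for constant expression.
    """
    v = np.asarray(viability_row, dtype=float)
    e = np.asarray(expression_row, dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(e)
    v, e = v[ok], e[ok]
    n = len(v)
    if n < 3:
        raise ValueError(f"need >= 3 complete (viability, expression) pairs, got {n}")
    if np.ptp(e) == 0:
        return np.nan, np.nan, n
    fit = stats.linregress(e, v)
    return float(fit.slope), float(fit.pvalue), n


def run_dependency(screen: DrugScreen, min_lines: int = 3) -> pd.DataFrame:
    """Dependency table over all testable (drug, target) pairs.

    Columns: drug, target, slope, pvalue, fdr, n_lines — BH-adjusted jointly
    across every tested pair and sorted by slope ascending (most dependent
    first).  Skipped/untestable pairs from alignment are not re-reported.
    """
    aligned = align_screen(screen, min_lines=min_lines)
    bad = set(aligned.skipped_targets) | set(aligned.untestable_pairs)
    rows = []
    for drug in sorted(aligned.drug_target_map):
        for target in sorted(aligned.drug_target_map[drug]):
            if (drug, target) in bad:
                continue
            slope, p, n = fit_dependency(
                aligned.viability.loc[drug], aligned.expression.loc[target]
            )
            rows.append({"drug": drug, "target": target, "slope": slope,
                         "pvalue": p, "n_lines": n})
    table = pd.DataFrame(rows, columns=["drug", "target", "slope", "pvalue", "n_lines"])
    table["fdr"] = bh_fdr(table["pvalue"]) if len(table) else np.nan
    table = table[["drug", "target", "slope", "pvalue", "fdr", "n_lines"]]
    return table.sort_values("slope", kind="mergesort").reset_index(drop=True)


def biomarker_correlation(
    x_row: pd.Series | np.ndarray, y_row: pd.Series | np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation of two rows over complete pairs.

    Returns ``(r, pvalue, n)``; constant input yields missing r/p.
    """
    x = np.asarray(x_row, dtype=float)
    y = np.asarray(y_row, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
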