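"""Domain types and readers/writers for matrices, metadata, mutations and gene lists.

All tabular I/O is plain TSV.  Marker/gene identity is the plain symbol
string, case-sensitive, with no alias resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: accepted spellings for a missing cell in matrix files
NA_SPELLINGS = ("", "NA", "NaN", "nan")

#: closed vocabulary for somatic variant classes
VARIANT_CLASSES = frozenset(
    {"missense", "frameshift_indel", "nonframeshift_indel", "stopgain", "stoploss", "other"}
)

#: classes treated as protein-truncating events
TRUNCATING_CLASSES = frozenset(
    {"frameshift_indel", "nonframeshift_indel", "stopgain", "stoploss"}
)

SCALE_TAGS = ("raw", "mad_normalized", "marker_zscore", "rna_normalized")


class FormatError(ValueError):
    """Raised when an input file violates its contract."""


@dataclass
class AbundanceMatrix:
    """Markers-by-samples real-valued matrix with missing entries allowed.

    ``data`` is a float DataFrame whose index holds marker IDs and whose
    columns hold sample IDs; NaN encodes a missing measurement.  ``scale_tag``
    records the normalization state the values are on.
    """

    data: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_TAGS}")
        _check_unique(self.data.index, "marker")
        _check_unique(self.data.columns, "sample")
        self.data = self.data.astype(float)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        keep = [s for s in sample_ids if s in self.data.columns]
        return AbundanceMatrix(self.data[keep].copy(), scale_tag=self.scale_tag)


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = sorted(ids[ids.duplicated()].unique().tolist())
        raise FormatError(f"duplicate {what} IDs: {dup}")


# ---------------------------------------------------------------------------
# matrix I/O


def read_abundance_matrix(
    path: str | Path, orientation: str = "markers_rows", scale_tag: str = "raw"
) -> AbundanceMatrix:
    """Read a TSV matrix (first row sample IDs, first column marker IDs).

    ``orientation="samples_rows"`` reads a transposed file.  Empty cells and
    the spellings "NA"/"NaN" are missing.  Duplicate IDs and non-numeric
    cells are hard errors.
    """
    if orientation not in ("markers_rows", "samples_rows"):
        raise ValueError(f"orientation must be markers_rows or samples_rows, got {orientation!r}")
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        comment="#",
    )
    df.index = df.index.astype(str)
    if orientation == "samples_rows":
        df = df.T
    _check_unique(df.index, "marker")
    _check_unique(df.columns, "sample")
    values = np.full(df.shape, np.nan)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell in NA_SPELLINGS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric cell {cell!r} at marker {df.index[i]!r}, "
                    f"sample {df.columns[j]!r} in {path}"
                ) from exc
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = None
    return AbundanceMatrix(out, scale_tag=scale_tag)


def write_abundance_matrix(
    m: AbundanceMatrix, path: str | Path, comment: str | None = None
) -> None:
    """Write a matrix as TSV; missing values become "NA"."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        m.data.to_csv(fh, sep="\t", na_rep="NA", index_label="marker")


# ---------------------------------------------------------------------------
# sample metadata

META_COLUMNS = ["sample_id", "subject_id", "tissue", "age", "gender", "batch"]


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table.

    Requires columns sample_id, subject_id, tissue; age, gender, batch are
    optional (added as missing when absent).  Each subject may contribute at
    most one tumor and one normal sample.
    """
    for col in ("sample_id", "subject_id", "tissue"):
        if col not in meta.columns:
            raise FormatError(f"sample metadata missing required column {col!r}")
    meta = meta.copy()
    for col in ("age", "gender", "batch"):
        if col not in meta.columns:
            meta[col] = np.nan
    bad = set(meta["tissue"]) - {"tumor", "normal"}
    if bad:
        raise FormatError(f"tissue values must be tumor/normal; got {sorted(bad)}")
    if meta["sample_id"].duplicated().any():
        dup = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"].unique())
        raise FormatError(f"duplicate sample IDs in metadata: {dup}")
    counts = meta.groupby(["subject_id", "tissue"]).size()
    multi = counts[counts > 1]
    if len(multi):
        raise FormatError(
            "subjects with more than one sample per tissue: "
            + ", ".join(f"{s}/{t}" for s, t in multi.index)
        )
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    return meta[META_COLUMNS]


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return validate_sample_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# mutations

MUTATION_COLUMNS = ["gene", "sample_id", "variant_class", "protein_change"]


@dataclass
class MutationTable:
    """Somatic mutation rows (gene, sample, variant class, protein change)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MUTATION_COLUMNS if c not in self.rows.columns]
        if missing:
            raise FormatError(f"mutation table missing columns {missing}")
        bad = set(self.rows["variant_class"]) - VARIANT_CLASSES
        if bad:
            raise FormatError(
                f"unknown variant_class values {sorted(bad)}; "
                f"allowed: {sorted(VARIANT_CLASSES)}"
            )
        self.rows = self.rows[MUTATION_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)


def read_mutation_table(path: str | Path) -> MutationTable:
    """Read a MAF-like TSV with columns gene, sample, variant_class, protein_change.

    Extra columns are ignored.  Accepts either ``sample`` or ``sample_id``
    for the sample column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample" in df.columns and "sample_id" not in df.columns:
        df = df.rename(columns={"sample": "sample_id"})
    return MutationTable(df)


def write_mutation_table(muts: MutationTable, path: str | Path) -> None:
    muts.rows.to_csv(path, sep="\t", index=False)


@dataclass
class RecurrenceCatalog:
    """Occurrence counts of (gene, protein_change) in a reference call set."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items() if v < 1}
        if bad:
            raise FormatError(f"catalog counts must be >= 1; offending entries: {bad}")

    def count(self, gene: str, protein_change: str) -> int:
        return self.counts.get((gene, protein_change), 0)


def read_recurrence_catalog(path: str | Path) -> RecurrenceCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "protein_change": str, "count": int},
                     comment="#")
    for col in ("gene", "protein_change", "count"):
        if col not in df.columns:
            raise FormatError(f"recurrence catalog missing column {col!r}")
    counts = {
        (r.gene, r.protein_change): int(r.count) for r in df.itertuples(index=False)
    }
    return RecurrenceCatalog(counts)


def write_recurrence_catalog(catalog: RecurrenceCatalog, path: str | Path) -> None:
    rows = [
        {"gene": g, "protein_change": pc, "count": c}
        for (g, pc), c in sorted(catalog.counts.items())
    ]
    pd.DataFrame(rows, columns=["gene", "protein_change", "count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene lists and annotation


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; blank lines and # comments skipped."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            out.add(sym)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def annotate_markers(
    markers: Iterable[str], gene_lists: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Per-marker membership flags for each named gene list.

    Non-members get all-false rows; annotation is idempotent and independent
    of marker order.
    """
    markers = list(markers)
    data = {name: [m in members for m in markers] for name, members in gene_lists.items()}
    return pd.DataFrame(data, index=pd.Index(markers, name="marker"), dtype=bool)


# ---------------------------------------------------------------------------
# result tables


def write_result_table(
    df: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    """Write a result TSV with a leading comment line recording parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        if params:
            meta = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
            fh.write(f"# {meta}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
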