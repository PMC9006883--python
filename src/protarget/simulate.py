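"""Seeded synthetic-cohort generators with recorded ground truth.

The generators emit every input the pipeline consumes: paired tumor/normal
proteomes with latent co-expression structure, planted fold changes and
outlier-overexpression events, protein-coupled RNA, mutation tables with a
recurrence catalog, gene lists and a drug screen with planted
viability-expression slopes.  Every generator is a pure function of
(params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from protarget.io_model import (
    AbundanceMatrix,
    MutationTable,
    RecurrenceCatalog,
    write_abundance_matrix,
    write_gene_list,
    write_mutation_table,
    write_recurrence_catalog,
    write_sample_meta,
)


@dataclass
class SimParams:
    """Knobs for the synthetic cohort, RNA, mutation and screen generators."""

    n_markers: int = 500
    n_subjects: int = 150
    n_factors: int = 8
    signal_sd: float = 1.0
    loading_jitter: float = 0.05
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    # differential expression
    n_de: int = 0
    de_shift: float = 1.0
    # outlier overexpression
    n_outlier_markers: int = 0
    outlier_rate: float = 0.15
    outlier_rate_range: tuple[float, float] | None = None  # per-marker U(a, b)
    outlier_amplitude: float = 3.0
    # covariate confounding (off by default)
    age_confounding: float = 0.0
    # RNA coupling
    rna_protein_corr: float = 0.8
    rna_protein_only_frac: float = 0.5
    rna_zero_gene_frac: float = 0.1
    # mutations
    truncating_rate: float = 0.02
    recurrent_missense_rate: float = 0.02
    nonrecurrent_missense_rate: float = 0.02
    # drug screen
    n_lines: int = 34
    n_drugs: int = 31
    n_dependent_drugs: int = 3
    dependent_slope: float = -10.0
    screen_noise_sd: float = 5.0
    viability_base: float = 100.0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "outlier_rate", "rna_protein_only_frac",
                     "rna_zero_gene_frac", "truncating_rate",
                     "recurrent_missense_rate", "nonrecurrent_missense_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")


@dataclass
class CohortTruth:
    """Everything planted into a simulated cohort, sufficient to predict the
    expected value of every downstream headline statistic."""

    seed: int
    de_markers: dict[str, float] = field(default_factory=dict)
    outlier_markers: dict[str, tuple[float, float]] = field(default_factory=dict)
    outlier_cells: list[tuple[str, str]] = field(default_factory=list)
    factor_loadings: dict = field(default_factory=dict)
    baseline: pd.DataFrame | None = None  # markers x subjects latent signal

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "de_markers": self.de_markers,
            "outlier_markers": {k: list(v) for k, v in self.outlier_markers.items()},
            "outlier_cells": [list(c) for c in self.outlier_cells],
        }


def _ids(prefix: str, n: int, width: int = 4) -> list[str]:
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(
    p: SimParams, seed: int
) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.DataFrame, CohortTruth]:
    """Simulate a paired tumor/normal proteomic cohort.

    Subject-level latent factor scores induce co-expression across markers;
    tumors add planted log2 shifts on DE markers and sparse +delta events on
    outlier markers, with delta expressed in robust-z units of the marker
    (model-implied total SD), so planted amplitudes line up with the
    detector's standardized dysregulation scale.  Missingness is MCAR.
    Returns ``(tumor, normal, meta, truth)``.
    """
    rng = np.random.default_rng(seed)
    markers = _ids("M", p.n_markers)
    subjects = _ids("S", p.n_subjects, width=4)
    tumor_ids = [f"{s}-T" for s in subjects]
    normal_ids = [f"{s}-N" for s in subjects]

    # block-structured loadings: each marker loads mainly on one factor (its
    # co-expression cluster) plus small Gaussian jitter, so genuinely
    # co-expressed neighbor sets exist for the KNN background
    clusters = rng.integers(p.n_factors, size=p.n_markers)
    loadings = rng.normal(scale=p.loading_jitter, size=(p.n_markers, p.n_factors))
    loadings[np.arange(p.n_markers), clusters] += p.signal_sd
    scores = rng.normal(size=(p.n_factors, p.n_subjects))
    baseline = loadings @ scores

    tumor = baseline + rng.normal(scale=p.noise_sd, size=baseline.shape)
    normal = baseline + rng.normal(scale=p.noise_sd, size=baseline.shape)

    ages = rng.uniform(40, 75, size=p.n_subjects)
    genders = np.where(rng.random(p.n_subjects) < 0.5, "F", "M")
    if p.age_confounding:
        age_z = (ages - ages.mean()) / ages.std()
        tumor = tumor + p.age_confounding * age_z[None, :]

    special = rng.choice(
        p.n_markers, size=p.n_de + p.n_outlier_markers, replace=False
    )
    de_idx = special[: p.n_de]
    out_idx = special[p.n_de:]
    truth = CohortTruth(seed=seed)
    for i in de_idx:
        truth.de_markers[markers[i]] = p.de_shift
        tumor[i] += p.de_shift
    marker_sd = np.sqrt((loadings**2).sum(axis=1) + p.noise_sd**2)
    for i in out_idx:
        marker = markers[i]
        if p.outlier_rate_range is not None:
            rate = float(rng.uniform(*p.outlier_rate_range))
        else:
            rate = p.outlier_rate
        truth.outlier_markers[marker] = (rate, p.outlier_amplitude)
        hit = rng.random(p.n_subjects) < rate
        tumor[i, hit] += p.outlier_amplitude * marker_sd[i]
        truth.outlier_cells.extend(
            (marker, tumor_ids[j]) for j in np.flatnonzero(hit)
        )

    if p.missing_rate > 0:
        tumor[rng.random(tumor.shape) < p.missing_rate] = np.nan
        normal[rng.random(normal.shape) < p.missing_rate] = np.nan

    tumor_m = AbundanceMatrix(pd.DataFrame(tumor, index=markers, columns=tumor_ids))
    normal_m = AbundanceMatrix(pd.DataFrame(normal, index=markers, columns=normal_ids))
    meta = pd.DataFrame(
        {
            "sample_id": tumor_ids + normal_ids,
            "subject_id": subjects + subjects,
            "tissue": ["tumor"] * p.n_subjects + ["normal"] * p.n_subjects,
            "age": np.concatenate([ages, ages]).round(1),
            "gender": np.concatenate([genders, genders]),
            "batch": ["B1"] * (2 * p.n_subjects),
        }
    )
    truth.factor_loadings = {"loadings": loadings, "scores": scores, "noise_sd": p.noise_sd}
    truth.baseline = pd.DataFrame(baseline, index=markers, columns=subjects)
    return tumor_m, normal_m, meta, truth


def generate_cohort_pair(
    p: SimParams, seed: int
) -> tuple[tuple, tuple]:
    """Two cohorts sharing the planted truth but with independent noise.

    Both cohorts use the same loadings, planted marker sets, shifts and
    rates; factor scores, noise, event draws, missingness and demographics
    are independent.  Useful for cross-cohort concordance checks.
    """
    rng = np.random.default_rng(seed)
    s_a, s_b = rng.integers(2**31, size=2)
    a = generate_cohort(p, int(s_a))
    # regenerate cohort B with identical structural randomness by replaying
    # the same seed for loadings/planting but fresh seeds for everything else
    b = _generate_cohort_like(a[3], p, int(s_b))
    return a, b


def _generate_cohort_like(truth: CohortTruth, p: SimParams, seed: int):
    """Draw a new cohort that reuses another cohort's loadings and planted sets."""
    rng = np.random.default_rng(seed)
    loadings = truth.factor_loadings["loadings"]
    markers = list(truth.baseline.index)
    subjects = _ids("S", p.n_subjects, width=4)
    tumor_ids = [f"{s}-Tb" for s in subjects]
    normal_ids = [f"{s}-Nb" for s in subjects]
    scores = rng.normal(size=(loadings.shape[1], p.n_subjects))
    baseline = loadings @ scores
    tumor = baseline + rng.normal(scale=p.noise_sd, size=baseline.shape)
    normal = baseline + rng.normal(scale=p.noise_sd, size=baseline.shape)
    idx = {m: i for i, m in enumerate(markers)}
    new_truth = CohortTruth(seed=seed, de_markers=dict(truth.de_markers),
                            outlier_markers=dict(truth.outlier_markers))
    marker_sd = np.sqrt((loadings**2).sum(axis=1) + p.noise_sd**2)
    for marker, shift in truth.de_markers.items():
        tumor[idx[marker]] += shift
    for marker, (rate, amplitude) in truth.outlier_markers.items():
        hit = rng.random(p.n_subjects) < rate
        tumor[idx[marker], hit] += amplitude * marker_sd[idx[marker]]
        new_truth.outlier_cells.extend(
            (marker, tumor_ids[j]) for j in np.flatnonzero(hit)
        )
    if p.missing_rate > 0:
        tumor[rng.random(tumor.shape) < p.missing_rate] = np.nan
        normal[rng.random(normal.shape) < p.missing_rate] = np.nan
    ages = rng.uniform(40, 75, size=p.n_subjects)
    genders = np.where(rng.random(p.n_subjects) < 0.5, "F", "M")
    meta = pd.DataFrame(
        {
            "sample_id": tumor_ids + normal_ids,
            "subject_id": subjects + subjects,
            "tissue": ["tumor"] * p.n_subjects + ["normal"] * p.n_subjects,
            "age": np.concatenate([ages, ages]).round(1),
            "gender": np.concatenate([genders, genders]),
            "batch": ["B1"] * (2 * p.n_subjects),
        }
    )
    new_truth.factor_loadings = truth.factor_loadings
    new_truth.baseline = pd.DataFrame(baseline, index=markers, columns=subjects)
    tumor_m = AbundanceMatrix(pd.DataFrame(tumor, index=markers, columns=tumor_ids))
    normal_m = AbundanceMatrix(pd.DataFrame(normal, index=markers, columns=normal_ids))
    return tumor_m, normal_m, meta, new_truth


def generate_rna(
    truth: CohortTruth, p: SimParams, seed: int
) -> tuple[AbundanceMatrix, dict]:
    """FPKM-like RNA matrix for the tumor samples, coupled to the protein baseline.

    Per gene the log-scale RNA signal mixes the protein latent baseline with
    independent noise at correlation ~``rna_protein_corr``.  A configurable
    fraction of protein outlier markers is protein-only (their events do not
    appear in RNA), so PRO > RNA genes exist by construction.  Structural
    zeros are injected into a subset of genes for the zero filter.
    """
    if truth.baseline is None:
        raise ValueError("truth must carry the cohort baseline; run generate_cohort first")
    rng = np.random.default_rng(seed)
    base = truth.baseline.to_numpy()
    markers = list(truth.baseline.index)
    tumor_ids = [f"{s}-T" for s in truth.baseline.columns]
    rho = p.rna_protein_corr
    noise = rng.normal(size=base.shape)
    rna_log = rho * base + np.sqrt(max(0.0, 1 - rho**2)) * noise

    out_markers = sorted(truth.outlier_markers)
    n_only = int(round(p.rna_protein_only_frac * len(out_markers)))
    protein_only = set(
        rng.choice(out_markers, size=n_only, replace=False)
    ) if n_only else set()
    idx = {m: i for i, m in enumerate(markers)}
    col = {s: j for j, s in enumerate(tumor_ids)}
    rna_sd = np.sqrt((rho * base.std(axis=1)) ** 2 + (1 - rho**2))
    for marker, sample in truth.outlier_cells:
        if marker in protein_only:
            continue
        rna_log[idx[marker], col[sample]] += p.outlier_amplitude * rna_sd[idx[marker]]

    fpkm = np.power(2.0, rna_log + 3.0)
    zero_genes: list[str] = []
    n_zero = int(round(p.rna_zero_gene_frac * len(markers)))
    if n_zero:
        chosen = rng.choice(len(markers), size=n_zero, replace=False)
        for i in chosen:
            n_hit = max(1, int(np.ceil(0.25 * len(tumor_ids))))
            cols = rng.choice(len(tumor_ids), size=n_hit, replace=False)
            fpkm[i, cols] = 0.0
            zero_genes.append(markers[i])
    rna = AbundanceMatrix(pd.DataFrame(fpkm, index=markers, columns=tumor_ids))
    return rna, {"protein_only_markers": sorted(protein_only), "zero_genes": sorted(zero_genes)}


def generate_mutations(
    p: SimParams, genes: list[str], samples: list[str], seed: int
) -> tuple[MutationTable, RecurrenceCatalog, dict[str, float]]:
    """Mutation table plus recurrence catalog with per-gene retained-carrier truth.

    Carriers are drawn independently per (gene, class); recurrent missense
    hotspots get catalog count 5 (>= the retain threshold), non-recurrent
    changes count 1.  The truth maps each gene to the fraction of samples
    carrying a mutation the driver filter should retain.
    """
    rng = np.random.default_rng(seed)
    rows = []
    catalog: dict[tuple[str, str], int] = {}
    retained_frac: dict[str, float] = {}
    n = len(samples)
    trunc_classes = ["frameshift_indel", "nonframeshift_indel", "stopgain", "stoploss"]
    for gene in genes:
        retained: set[str] = set()
        for j, s in enumerate(samples):
            if rng.random() < p.truncating_rate:
                vc = trunc_classes[rng.integers(len(trunc_classes))]
                rows.append((gene, s, vc, f"p.X{j + 1}fs"))
                retained.add(s)
            if rng.random() < p.recurrent_missense_rate:
                hotspot = "p.R100H"
                rows.append((gene, s, "missense", hotspot))
                catalog[(gene, hotspot)] = 5
                retained.add(s)
            if rng.random() < p.nonrecurrent_missense_rate:
                change = f"p.A{j + 1}V"
                rows.append((gene, s, "missense", change))
                catalog.setdefault((gene, change), 1)
        retained_frac[gene] = len(retained) / n
    table = MutationTable(
        pd.DataFrame(rows, columns=["gene", "sample_id", "variant_class", "protein_change"])
    )
    return table, RecurrenceCatalog(catalog), retained_frac


def generate_screen(
    p: SimParams, seed: int, targets: list[str] | None = None
) -> tuple["DrugScreen", dict[tuple[str, str], float]]:
    """Cell-line drug screen with planted viability~expression slopes.

    One target per drug; the first ``n_dependent_drugs`` drugs carry
    ``dependent_slope``, the rest slope 0.  Returns the screen and the map of
    planted slopes per (drug, target).
    """
    from protarget.dependency import DrugScreen

    rng = np.random.default_rng(seed)
    lines = _ids("L", p.n_lines, width=2)
    drugs = _ids("D", p.n_drugs, width=2)
    if targets is None:
        targets = _ids("T", p.n_drugs, width=2)
    if len(targets) < p.n_drugs:
        raise ValueError("need at least one target per drug")
    expression = rng.normal(loc=2.0, scale=1.0, size=(len(targets), p.n_lines))
    planted: dict[tuple[str, str], float] = {}
    viability = np.empty((p.n_drugs, p.n_lines))
    for i, drug in enumerate(drugs):
        target = targets[i]
        slope = p.dependent_slope if i < p.n_dependent_drugs else 0.0
        planted[(drug, target)] = slope
        viability[i] = (
            p.viability_base
            + slope * expression[i]
            + rng.normal(scale=p.screen_noise_sd, size=p.n_lines)
        )
    screen = DrugScreen(
        viability=pd.DataFrame(viability, index=drugs, columns=lines),
        expression=pd.DataFrame(expression, index=targets, columns=lines),
        drug_target_map={d: {targets[i]} for i, d in enumerate(drugs)},
    )
    return screen, planted


def generate_gene_lists(
    truth: CohortTruth, markers: list[str], seed: int, druggable_frac: float = 0.5
) -> dict[str, set[str]]:
    """Druggable and kinase lists covering all planted markers plus a random fill."""
    rng = np.random.default_rng(seed)
    planted = set(truth.de_markers) | set(truth.outlier_markers)
    pool = [m for m in markers if m not in planted]
    n_extra = max(0, int(druggable_frac * len(markers)) - len(planted))
    extra = set(rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
    druggable = planted | extra
    kinase = set(rng.choice(sorted(druggable), size=max(1, len(druggable) // 3), replace=False))
    return {"druggable": druggable, "kinase": kinase}


def write_bundle(outdir: str | Path, p: SimParams, seed: int) -> dict:
    """Generate and write the full input bundle for a pipeline run.

    Emits proteome tumor/normal matrices, sample metadata, RNA FPKM matrix,
    mutation table + recurrence catalog, gene lists, drug-screen tables and a
    truth JSON.  Returns the truth dictionary.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    s_cohort, s_rna, s_mut, s_screen, s_lists = [
        int(s.generate_state(1)[0]) for s in root.spawn(5)
    ]
    tumor, normal, meta, truth = generate_cohort(p, s_cohort)
    rna, rna_truth = generate_rna(truth, p, s_rna)
    markers = tumor.marker_ids
    muts, catalog, retained = generate_mutations(p, markers, tumor.sample_ids, s_mut)
    screen, planted_slopes = generate_screen(p, s_screen)
    lists = generate_gene_lists(truth, markers, s_lists)

    write_abundance_matrix(tumor, outdir / "proteome_tumor.tsv")
    write_abundance_matrix(normal, outdir / "proteome_normal.tsv")
    write_sample_meta(meta, outdir / "sample_meta.tsv")
    write_abundance_matrix(rna, outdir / "rna_fpkm.tsv")
    write_mutation_table(muts, outdir / "mutations.tsv")
    write_recurrence_catalog(catalog, outdir / "recurrence_catalog.tsv")
    write_gene_list(lists["druggable"], outdir / "druggable.txt")
    write_gene_list(lists["kinase"], outdir / "kinase.txt")
    screen.viability.to_csv(outdir / "screen_viability.tsv", sep="\t",
                            na_rep="NA", index_label="drug")
    screen.expression.to_csv(outdir / "screen_expression.tsv", sep="\t",
                             na_rep="NA", index_label="target")
    pd.DataFrame(
        [(d, t) for d, ts in screen.drug_target_map.items() for t in sorted(ts)],
        columns=["drug", "target"],
    ).to_csv(outdir / "drug_targets.tsv", sep="\t", index=False)

    truth_dict = truth.to_dict()
    truth_dict["rna"] = rna_truth
    truth_dict["mutation_retained_frac"] = retained
    truth_dict["screen_slopes"] = {f"{d}:{t}": s for (d, t), s in planted_slopes.items()}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
    return truth_dict
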