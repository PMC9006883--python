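"""End-to-end orchestration: simulate/load inputs, run every stage, write
per-stage TSVs, a candidate summary and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from protarget import __version__
from protarget.dependency import DrugScreen, run_dependency
from protarget.diffexp import run_diffexp
from protarget.io_model import (
    AbundanceMatrix,
    read_abundance_matrix,
    read_gene_list,
    read_mutation_table,
    read_recurrence_catalog,
    read_sample_meta,
    write_result_table,
)
from protarget.oppti import OpptiParams, run_oppti
from protarget.preprocess import (
    PreprocessParams,
    filter_missing_markers,
    mad_normalize,
    missingness_report,
    normalize_rna,
)
from protarget.proteogenomics import (
    build_alteration_summary,
    cohort_concordance,
    dna_alteration_fractions,
    filter_driver_mutations,
    select_candidates,
)
from protarget.simulate import SimParams, write_bundle

DEFAULT_PARAMS = {
    "max_missing_frac": 0.20,
    "min_pairs": 10,
    "fdr_max": 0.05,
    "fc_min": 1.0,
    "pro_min": 0.10,
    "min_recurrence": 3,
    "oppti": {"k": 10, "threshold_T": 2.0, "n_perm": 100, "min_overlap": None},
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def _preprocess_cohort(
    tumor: AbundanceMatrix, normal: AbundanceMatrix | None, max_missing_frac: float
) -> AbundanceMatrix:
    if normal is not None:
        combined = AbundanceMatrix(pd.concat([tumor.data, normal.data], axis=1))
    else:
        combined = tumor
    normalized = mad_normalize(combined)
    return filter_missing_markers(normalized, max_missing_frac)


def run_full_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every configured stage and persist outputs under ``outdir``.

    The config carries a global ``seed``, either a ``simulate`` block (params
    for :func:`protarget.simulate.write_bundle`) or an ``inputs`` block of
    file paths, and an optional ``params`` block overriding thresholds.
    Returns the in-memory stage bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    seeds = _stage_seeds(seed)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    oppti_cfg = {**DEFAULT_PARAMS["oppti"], **params.get("oppti", {})}

    if "simulate" in config:
        sim_params = SimParams(**config["simulate"])
        input_dir = outdir / "inputs"
        write_bundle(input_dir, sim_params, seed=seeds[0])
        inputs = {
            "proteome_tumor": input_dir / "proteome_tumor.tsv",
            "proteome_normal": input_dir / "proteome_normal.tsv",
            "sample_meta": input_dir / "sample_meta.tsv",
            "rna_fpkm": input_dir / "rna_fpkm.tsv",
            "mutations": input_dir / "mutations.tsv",
            "recurrence_catalog": input_dir / "recurrence_catalog.tsv",
            "druggable": input_dir / "druggable.txt",
            "screen": {
                "viability": input_dir / "screen_viability.tsv",
                "expression": input_dir / "screen_expression.tsv",
                "drug_targets": input_dir / "drug_targets.tsv",
            },
        }
    elif "inputs" in config:
        inputs = {
            k: (v if isinstance(v, dict) else Path(v))
            for k, v in config["inputs"].items()
        }
        for key in ("proteome_tumor", "proteome_normal", "sample_meta"):
            if key not in inputs:
                raise ValueError(f"config inputs missing required entry {key!r}")
        for key, val in list(inputs.items()):
            if isinstance(val, dict):
                inputs[key] = {k: Path(p) for k, p in val.items()}
    else:
        raise ValueError("config must contain a 'simulate' or an 'inputs' block")

    bundle: dict = {"seed": seed, "params": params}

    # --- preprocess -------------------------------------------------------
    tumor_raw = read_abundance_matrix(inputs["proteome_tumor"])
    normal_raw = read_abundance_matrix(inputs["proteome_normal"])
    meta = read_sample_meta(inputs["sample_meta"])
    combined = _preprocess_cohort(tumor_raw, normal_raw, params["max_missing_frac"])
    report = missingness_report(
        AbundanceMatrix(pd.concat([tumor_raw.data, normal_raw.data], axis=1)),
        params["max_missing_frac"],
    )
    write_result_table(report, outdir / "preprocess_report.tsv",
                       {"max_missing_frac": params["max_missing_frac"]})
    bundle["preprocessed"] = combined

    # --- differential expression -----------------------------------------
    dep = run_diffexp(
        combined, meta,
        min_pairs=params["min_pairs"],
        fdr_threshold=params["fdr_max"],
        fc_threshold=params["fc_min"],
    )
    write_result_table(dep, outdir / "diffexp.tsv",
                       {"min_pairs": params["min_pairs"], "seed": seed})
    bundle["diffexp"] = dep

    # --- protein overexpression ------------------------------------------
    tumor_ids = meta.loc[meta["tissue"] == "tumor", "sample_id"]
    tumor_norm = combined.subset_samples(tumor_ids)
    oppti_params = OpptiParams(**{**oppti_cfg, "seed": seeds[1]})
    pro_res = run_oppti(tumor_norm, oppti_params)
    write_result_table(
        pro_res.table, outdir / "oppti_protein.tsv",
        {"k": oppti_params.k, "T": oppti_params.threshold_T,
         "n_perm": oppti_params.n_perm, "seed": oppti_params.seed},
    )
    bundle["oppti_protein"] = pro_res

    # --- RNA overexpression (same parameters) -----------------------------
    rna_res = None
    if inputs.get("rna_fpkm"):
        fpkm = read_abundance_matrix(inputs["rna_fpkm"])
        rna_norm = normalize_rna(fpkm, PreprocessParams(
            max_missing_frac=params["max_missing_frac"]))
        rna_params = OpptiParams(**{**oppti_cfg, "seed": seeds[2]})
        rna_res = run_oppti(rna_norm, rna_params)
        write_result_table(
            rna_res.table, outdir / "oppti_rna.tsv",
            {"k": rna_params.k, "T": rna_params.threshold_T,
             "n_perm": rna_params.n_perm, "seed": rna_params.seed},
        )
    bundle["oppti_rna"] = rna_res

    # --- proteogenomic comparison ----------------------------------------
    if inputs.get("mutations") and inputs.get("recurrence_catalog"):
        muts = read_mutation_table(inputs["mutations"])
        catalog = read_recurrence_catalog(inputs["recurrence_catalog"])
        kept = filter_driver_mutations(muts, catalog, params["min_recurrence"])
        dna = dna_alteration_fractions(kept, tumor_norm.marker_ids, list(tumor_ids))
        summary = build_alteration_summary(
            dna, rna_res if rna_res is not None else pd.Series(dtype=float),
            pro_res, high_pro_min=params["pro_min"],
        )
        write_result_table(summary, outdir / "alteration_summary.tsv",
                           {"min_recurrence": params["min_recurrence"],
                            "pro_min": params["pro_min"]})
        bundle["alteration_summary"] = summary

    # --- candidate selection ---------------------------------------------
    if inputs.get("druggable"):
        druggable = read_gene_list(inputs["druggable"])
        candidates = select_candidates(
            dep, pro_res, druggable,
            fc_min=params["fc_min"], fdr_max=params["fdr_max"],
        )
        write_result_table(candidates, outdir / "candidates.tsv",
                           {"fc_min": params["fc_min"], "fdr_max": params["fdr_max"]})
        bundle["candidates"] = candidates

    # --- cross-cohort concordance ----------------------------------------
    if inputs.get("cohort_b_tumor"):
        other_raw = read_abundance_matrix(inputs["cohort_b_tumor"])
        other = _preprocess_cohort(other_raw, None, params["max_missing_frac"])
        other_res = run_oppti(other, OpptiParams(**{**oppti_cfg, "seed": seeds[3]}))
        r, p, n_shared = cohort_concordance(pro_res, other_res)
        conc = pd.DataFrame([{"r": r, "pvalue": p, "n_shared": n_shared}])
        write_result_table(conc, outdir / "concordance.tsv", {"seed": seed})
        bundle["concordance"] = conc

    # --- drug dependency --------------------------------------------------
    if isinstance(inputs.get("screen"), dict):
        sc = inputs["screen"]
        viability = pd.read_csv(sc["viability"], sep="\t", index_col=0, na_values=["NA"])
        expression = pd.read_csv(sc["expression"], sep="\t", index_col=0, na_values=["NA"])
        pairs = pd.read_csv(sc["drug_targets"], sep="\t")
        dt_map: dict[str, set[str]] = {}
        for row in pairs.itertuples(index=False):
            dt_map.setdefault(row.drug, set()).add(row.target)
        screen = DrugScreen(viability=viability, expression=expression,
                            drug_target_map=dt_map)
        deps = run_dependency(screen)
        write_result_table(deps, outdir / "dependency.tsv", {"seed": seed})
        bundle["dependency"] = deps

    # --- manifest + summary ----------------------------------------------
    digests = {}
    for key, val in inputs.items():
        if isinstance(val, dict):
            for k2, p2 in val.items():
                digests[f"{key}.{k2}"] = _digest(Path(p2))
        elif val:
            digests[key] = _digest(Path(val))
    manifest = {
        "version": __version__,
        "seed": seed,
        "params": {k: v for k, v in params.items()},
        "stage_seeds": seeds,
        "inputs": digests,
        "stages_run": sorted(k for k in bundle if k not in ("seed", "params")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    (outdir / "summary.txt").write_text(report_summary(bundle))
    bundle["manifest"] = manifest
    return bundle


def report_summary(bundle: dict) -> str:
    """Human-readable per-stage counts."""
    lines = []
    params = bundle.get("params", {})
    fdr_max = params.get("fdr_max", 0.05)
    if "preprocessed" in bundle:
        m = bundle["preprocessed"]
        lines.append(f"markers after preprocessing: {m.shape[0]} "
                     f"({m.shape[1]} samples)")
    if "diffexp" in bundle:
        dep = bundle["diffexp"]
        n_sig = int((dep["fdr"] < fdr_max).sum())
        n_up = int(((dep["fdr"] < fdr_max) & dep["up2fold"]).sum())
        lines.append(f"differentially expressed markers (FDR < {fdr_max}): {n_sig}"
                     f" ({n_up} with >= 2-fold up-regulation)")
    if bundle.get("oppti_protein") is not None:
        t = bundle["oppti_protein"].table
        lines.append(f"overexpressed markers (FDR < {fdr_max}): "
                     f"{int((t['fdr'] < fdr_max).sum())} of {len(t)} tested")
    if bundle.get("oppti_rna") is not None:
        t = bundle["oppti_rna"].table
        lines.append(f"RNA-overexpressed genes (FDR < {fdr_max}): "
                     f"{int((t['fdr'] < fdr_max).sum())} of {len(t)} tested")
    if "alteration_summary" in bundle:
        s = bundle["alteration_summary"]
        lines.append(f"genes with high PRO and >= 2x RNA rate: "
                     f"{int(s['candidate'].sum())}")
    if "candidates" in bundle:
        c = bundle["candidates"]
        lines.append(f"druggable candidates: {int(c['tier_strict'].sum())} strict, "
                     f"{int(c['tier_positive'].sum())} positive-tier")
        if not len(c):
            lines.append("zero candidates")
    if "concordance" in bundle:
        row = bundle["concordance"].iloc[0]
        lines.append(f"cross-cohort concordance: r = {row['r']:.3f} "
                     f"(p = {row['pvalue']:.3g}, n = {int(row['n_shared'])})")
    if "dependency" in bundle:
        d = bundle["dependency"]
        lines.append(f"dependency pairs tested: {len(d)}; "
                     f"FDR < {fdr_max}: {int((d['fdr'] < fdr_max).sum())}")
    return "\n".join(lines) + "\n"
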