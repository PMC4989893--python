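"""End-to-end orchestration: simulate/load -> compare x3 -> rates -> union ->
filter -> enrichment -> shared pathways -> bootstrap correlation.

Every stage writes a plain TSV artifact into the output directory, and the
run closes with a ``run_manifest.json`` listing all outputs, the parameters
and policy defaults actually used, package versions and the seed, so a run
is fully reproducible from its manifest.  With a fixed seed the whole output
directory is byte-identical across runs (no timestamps, relative paths
only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io
from .config import COMPARISONS, ConfigError, DataError, SimulationConfig, comparison_name
from .bootstrap import bootstrap_correlation, methylation_expression_report
from .diffmeth import compare_groups, neg_log10_p, significance_rate, union_significant
from .enrichment import hypergeometric_enrichment, markers_to_genes, shared_pathways
from .filtering import filter_altered_markers, relative_methylation
from .simulate import (
    GeneSetCollection,
    generate_beta,
    generate_expression_pools,
    generate_gene_sets,
    generate_manifest,
    group_mean_matrix,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Inputs and policy knobs for one pipeline run.

    Either ``sim`` (self-contained synthetic run) or the input paths
    (``manifest_path``, ``beta_path``, ``sample_sheet_path``; optionally
    ``gmt_path`` and ``pools_path``) must be provided.
    """

    outdir: str | Path = "meth3way_run"
    sim: SimulationConfig | None = None
    manifest_path: str | Path | None = None
    beta_path: str | Path | None = None
    sample_sheet_path: str | Path | None = None
    gmt_path: str | Path | None = None
    pools_path: str | Path | None = None

    alpha: float = 0.05
    test: str = "student"  # or "welch"
    p_thresh: float = 0.05
    min_alteration: float = 0.10
    min_comparisons: int = 2
    alteration_metric: str = "absolute"  # or "relative"
    universe_policy: str = "intersect"  # intersect | gmt | manifest
    include_kd1_enrichment: bool = False
    B: int = 10_000
    bootstrap_mode: str = "draw"
    correlate_marker: str | None = None
    # Gene-set simulation knobs (self-contained runs without a GMT file).
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (20, 200)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        have_paths = all(
            p is not None
            for p in (self.manifest_path, self.beta_path, self.sample_sheet_path)
        )
        if self.sim is None and not have_paths:
            raise ConfigError(
                "provide either a SimulationConfig or manifest/beta/sample-sheet paths"
            )
        if self.universe_policy not in ("intersect", "gmt", "manifest"):
            raise ConfigError(f"unknown universe policy {self.universe_policy!r}")


def _resolve_universe(
    policy: str, manifest: pd.DataFrame, collection: GeneSetCollection
) -> frozenset[str]:
    manifest_genes = frozenset(manifest["gene"])
    if policy == "manifest":
        return manifest_genes
    if policy == "gmt":
        return collection.universe
    return manifest_genes & collection.universe


def _pick_correlation_marker(
    cfg: PipelineConfig, filtered: pd.DataFrame, tables: Mapping[str, pd.DataFrame]
) -> str | None:
    if cfg.correlate_marker is not None:
        return cfg.correlate_marker
    ref = tables[comparison_name("FC", "KD3")]
    candidates = filtered.index if len(filtered) else ref.index[ref["significant"]]
    if len(candidates) == 0:
        return None
    # Strongest post-treatment shift: the marker whose promoter methylation
    # moved most between FC and KD3.
    deltas = ref.loc[candidates, "delta_beta"].abs()
    return str(deltas.idxmax())


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(key: str, filename: str, writer, obj) -> None:
        writer(obj, outdir / filename)
        outputs[key] = filename

    # --- inputs ---------------------------------------------------------
    simulated = cfg.sim is not None
    if simulated:
        # The pipeline seed is the single source of randomness for a run.
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        manifest = generate_manifest(sim)
        if len(manifest) == 0:
            raise ConfigError("simulation produced an empty manifest")
        beta, design = generate_beta(manifest, sim)
        emit("manifest", "manifest.tsv", io.write_manifest, manifest)
        emit("beta", "beta.tsv", io.write_beta, beta)
        emit("samples", "samples.tsv", io.write_sample_sheet, design)
    else:
        sim = None
        manifest = io.read_manifest(cfg.manifest_path)
        beta = io.read_beta(cfg.beta_path)
        design = io.read_sample_sheet(cfg.sample_sheet_path)

    # --- differential testing -------------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    rates_summary_rows = []
    for group_a, group_b in COMPARISONS:
        name = comparison_name(group_a, group_b)
        table = compare_groups(beta, design, group_a, group_b, alpha=cfg.alpha, test=cfg.test)
        table = table.assign(neg_log10_p=neg_log10_p(table))
        tables[name] = table
        emit(f"comparison_{name}", f"comparison_{name}.tsv", io.write_table, table)
        rates = significance_rate(table, manifest)
        emit(f"rates_{name}", f"rates_{name}.tsv", io.write_table, rates.per_chromosome)
        rates_summary_rows.append(
            {
                "comparison": name,
                "n_significant": int(table["significant"].sum()),
                "n_testable": int((~table["untestable"]).sum()),
                "mean_rate": rates.mean_rate,
                "sd_rate": rates.sd_rate,
            }
        )
    rates_summary = pd.DataFrame(rates_summary_rows).set_index("comparison")
    emit("rates_summary", "rates_summary.tsv", io.write_table, rates_summary)

    union = union_significant(tables.values())
    (outdir / "union_markers.txt").write_text("".join(f"{m}\n" for m in sorted(union)))
    outputs["union_markers"] = "union_markers.txt"

    # --- alteration filter ----------------------------------------------
    rel = relative_methylation(beta, design)
    emit("relative_methylation", "relative_methylation.tsv", io.write_table, rel)
    filtered = filter_altered_markers(
        tables,
        p_thresh=cfg.p_thresh,
        min_alteration=cfg.min_alteration,
        min_comparisons=cfg.min_comparisons,
        metric=cfg.alteration_metric,
    )
    filtered_out = filtered.join(
        manifest.set_index("marker_id")[["gene", "chromosome"]], how="left"
    ).join(rel[["rel_KD1", "rel_KD3"]], how="left")
    emit("altered_markers", "altered_markers.tsv", io.write_table, filtered_out)

    # --- enrichment -------------------------------------------------------
    if cfg.gmt_path is not None:
        collection = io.read_gmt(cfg.gmt_path)
    elif simulated:
        planted_genes = sorted(
            markers_to_genes(
                tables[comparison_name("FC", "KD3")]
                .index[tables[comparison_name("FC", "KD3")]["significant"]],
                manifest,
            )
        )
        collection = generate_gene_sets(
            manifest,
            n_sets=cfg.n_gene_sets,
            set_size_range=cfg.set_size_range,
            enriched_gene_pool=planted_genes,
            seed=cfg.seed,
        )
        emit("gene_sets", "gene_sets.gmt", io.write_gmt, collection)
    else:
        collection = None

    enrichment_names = [comparison_name("FC", "KD3"), comparison_name("KD1", "KD3")]
    if cfg.include_kd1_enrichment:
        enrichment_names.insert(0, comparison_name("FC", "KD1"))
    shared = None
    if collection is not None:
        universe = _resolve_universe(cfg.universe_policy, manifest, collection)
        enr_tables = {}
        for name in enrichment_names:
            query = markers_to_genes(
                tables[name].index[tables[name]["significant"]], manifest
            )
            enr = hypergeometric_enrichment(
                query, collection, alpha=cfg.alpha, universe=universe
            )
            enr_tables[name] = enr
            emit(f"enrichment_{name}", f"enrichment_{name}.tsv", io.write_table, enr)
        shared = shared_pathways(
            enr_tables[comparison_name("FC", "KD3")],
            enr_tables[comparison_name("KD1", "KD3")],
            alpha=cfg.alpha,
        )
        emit("shared_pathways", "shared_pathways.tsv", io.write_table, shared)

    # --- bootstrap correlation -------------------------------------------
    report = None
    pools = None
    marker = _pick_correlation_marker(cfg, filtered, tables)
    if cfg.pools_path is not None:
        pools = io.read_pools(cfg.pools_path)
    elif simulated and marker is not None:
        means = group_mean_matrix(manifest, sim).loc[marker]
        pools = generate_expression_pools(marker, manifest, means.to_dict(), sim)
        emit("pools", "pools.tsv", io.write_pools, pools)
    if pools is not None:
        result = bootstrap_correlation(
            pools, B=cfg.B, mode=cfg.bootstrap_mode, seed=cfg.seed
        )
        gene = (
            manifest.set_index("marker_id")["gene"].get(marker, "NA")
            if marker is not None
            else "NA"
        )
        report = methylation_expression_report(marker or "NA", str(gene), result)
        points = pd.DataFrame(result.points, columns=["beta", "dct"])
        points.insert(
            0, "group", np.repeat(list(result.groups), result.B)
        )
        emit(
            "correlation_points",
            "correlation_points.tsv",
            lambda obj, p: obj.to_csv(p, sep="\t", index=False, float_format="%.10g"),
            points,
        )
        summary = pd.DataFrame([report]).drop(columns=["interpretation"])
        emit(
            "correlation_summary",
            "correlation_summary.tsv",
            lambda obj, p: obj.to_csv(p, sep="\t", index=False, float_format="%.10g"),
            summary,
        )

    # --- run manifest -----------------------------------------------------
    run_manifest = {
        "tool": "meth3way",
        "version": _version(),
        "library_versions": _library_versions(),
        "seed": cfg.seed,
        "parameters": {
            "alpha": cfg.alpha,
            "significance_policy": f"p < {cfg.alpha}",
            "test": cfg.test,
            "p_thresh": cfg.p_thresh,
            "min_alteration": cfg.min_alteration,
            "min_comparisons": cfg.min_comparisons,
            "alteration_metric": cfg.alteration_metric,
            "universe_policy": cfg.universe_policy,
            "bootstrap_mode": cfg.bootstrap_mode,
            "B": cfg.B,
            "comparisons": [comparison_name(a, b) for a, b in COMPARISONS],
            "simulated": simulated,
            "simulation": _sim_dict(sim) if simulated else None,
        },
        "results": {
            "n_markers": int(len(manifest)),
            "n_samples": int(len(design)),
            "n_significant": {
                name: int(t["significant"].sum()) for name, t in tables.items()
            },
            "n_union": len(union),
            "n_filtered": int(len(filtered)),
            "n_shared_pathways": int(len(shared)) if shared is not None else None,
            "correlation": _jsonable(report) if report is not None else None,
        },
        "outputs": outputs,
    }
    log.info(
        "policies used: test=%s, alteration_metric=%s, universe=%s, bootstrap_mode=%s",
        cfg.test, cfg.alteration_metric, cfg.universe_policy, cfg.bootstrap_mode,
    )
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    outputs["run_manifest"] = "run_manifest.json"
    return run_manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("meth3way")
    except Exception:  # pragma: no cover
        return "unknown"


def _library_versions() -> dict[str, str]:
    import scipy

    return {"numpy": np.__version__, "pandas": pd.__version__, "scipy": scipy.__version__}


def _sim_dict(sim: SimulationConfig) -> dict:
    d = dataclasses.asdict(sim)
    d["chromosome_weights"] = {k: float(v) for k, v in d["chromosome_weights"].items()}
    d["planted_effects"] = [
        {
            "markers": e["markers"] if isinstance(e["markers"], int) else list(e["markers"]),
            "group": e["group"],
            "delta_beta": e["delta_beta"],
        }
        for e in d["planted_effects"]
    ]
    return d


def _jsonable(report: dict) -> dict:
    out = {}
    for key, value in report.items():
        if isinstance(value, float) and np.isnan(value):
            out[key] = None
        elif isinstance(value, (np.integer, np.floating)):
            out[key] = value.item()
        else:
            out[key] = value
    return out
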