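"""Synthetic data generator for the three-group methylation analysis.

Generates the four inputs the pipeline consumes: a marker manifest
(chromosome, gene, TSS offset per marker), a markers x samples beta-value
matrix with a group design, gene sets in GMT form, and per-group unpaired
measurement pools (beta assays and qPCR delta-Ct assays) for the
methylation-expression bootstrap.

Everything is driven by a :class:`~meth3way.config.SimulationConfig`; the
same config (including seed) reproduces bit-identical outputs.  Independent
seed streams are derived per product so that, e.g., regenerating the beta
matrix does not perturb the gene sets.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CHROMOSOMES, GROUPS, ConfigError, PlantedEffect, SimulationConfig

__all__ = [
    "GeneSetCollection",
    "PairedPools",
    "generate_manifest",
    "generate_baseline_means",
    "generate_beta",
    "generate_expression_pools",
    "generate_gene_sets",
]

# Stream offsets: one RNG lineage per generated product.
_STREAM_MANIFEST = 0
_STREAM_BASELINE = 1
_STREAM_BETA = 2
_STREAM_POOLS = 3
_STREAM_GENESETS = 4

#: qPCR assay counts of the motivating study (shared methylation assays are
#: the 4 + 7 + 7 array samples themselves).
DEFAULT_DCT_POOL_SIZES: dict[str, int] = {"FC": 26, "KD1": 24, "KD3": 10}

# Average markers per gene on a 27K-style promoter array (~27.6k markers on
# ~14.5k genes).
_MARKERS_PER_GENE = 1.9


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg_seed])


@dataclasses.dataclass(frozen=True)
class PairedPools:
    """One group's two unpaired measurement pools.

    ``beta_pool`` holds fractional methylation assay values and ``dct_pool``
    qPCR delta-Ct values; the pools may differ in length and carry no
    per-sample pairing.
    """

    group: str
    beta_pool: np.ndarray
    dct_pool: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta_pool, dtype=float)
        dct = np.asarray(self.dct_pool, dtype=float)
        if beta.size == 0 or dct.size == 0:
            raise ConfigError(f"group {self.group!r} has an empty measurement pool")
        if np.any((beta < 0) | (beta > 1)):
            raise ConfigError(f"group {self.group!r} beta pool leaves [0, 1]")
        object.__setattr__(self, "beta_pool", beta)
        object.__setattr__(self, "dct_pool", dct)


@dataclasses.dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the gene universe they live in."""

    sets: dict[str, list[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            extra = set(genes) - self.universe
            if extra:
                raise ConfigError(
                    f"gene set {name!r} contains genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def restricted(self, universe: frozenset[str]) -> "GeneSetCollection":
        """The collection with every set intersected with a new universe."""
        return GeneSetCollection(
            sets={n: [g for g in genes if g in universe] for n, genes in self.sets.items()},
            universe=universe,
        )


def generate_manifest(cfg: SimulationConfig) -> pd.DataFrame:
    """Generate the marker manifest: marker_id, chromosome, gene, tss_offset.

    Chromosome counts are a single multinomial draw over
    ``cfg.chromosome_weights``; markers are laid out chromosome by chromosome
    in the canonical 1..22, X, Y order.  Genes are synthetic symbols
    (GENE000001, ...) local to a chromosome, with on average ~1.9 markers per
    gene so that multi-marker genes exist.  TSS offsets are promoter-centric
    (mostly upstream of the transcription start site).
    """
    rng = _rng(cfg.seed, _STREAM_MANIFEST)
    labels = [c for c in CHROMOSOMES if cfg.chromosome_weights.get(c, 0.0) > 0]
    if cfg.n_markers == 0 or not labels:
        return pd.DataFrame(
            {"marker_id": [], "chromosome": [], "gene": [], "tss_offset": []}
        ).astype({"marker_id": str, "chromosome": str, "gene": str, "tss_offset": int})

    probs = np.array([cfg.chromosome_weights[c] for c in labels], dtype=float)
    counts = rng.multinomial(cfg.n_markers, probs)

    chrom_col = np.repeat(labels, counts)
    gene_col = np.empty(cfg.n_markers, dtype=object)
    next_gene = 1
    pos = 0
    for label, count in zip(labels, counts):
        if count == 0:
            continue
        n_genes = max(1, int(round(count / _MARKERS_PER_GENE)))
        assignment = rng.integers(0, n_genes, size=count)
        # Renumber so only genes that actually own a marker get a symbol.
        used, dense = np.unique(assignment, return_inverse=True)
        symbols = np.array(
            [f"GENE{next_gene + i:06d}" for i in range(len(used))], dtype=object
        )
        gene_col[pos : pos + count] = symbols[dense]
        next_gene += len(used)
        pos += count

    tss = rng.integers(-1500, 201, size=cfg.n_markers)
    marker_ids = np.array(
        [f"cg{i:08d}" for i in range(1, cfg.n_markers + 1)], dtype=object
    )
    return pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chromosome": chrom_col,
            "gene": gene_col,
            "tss_offset": tss,
        }
    )


def generate_baseline_means(manifest: pd.DataFrame, cfg: SimulationConfig) -> pd.Series:
    """Per-marker baseline beta means from the bimodal promoter-array mixture.

    Means are clipped to [0.02, 0.98] so that moderate planted shifts cannot
    push a group mean onto the boundary of (0, 1).
    """
    rng = _rng(cfg.seed, _STREAM_BASELINE)
    n = len(manifest)
    lo_a, lo_b = cfg.baseline_low
    hi_a, hi_b = cfg.baseline_high
    low = rng.beta(lo_a, lo_b, size=n)
    high = rng.beta(hi_a, hi_b, size=n)
    is_high = rng.random(n) < cfg.baseline_high_fraction
    means = np.clip(np.where(is_high, high, low), 0.02, 0.98)
    return pd.Series(means, index=pd.Index(manifest["marker_id"], name="marker_id"))


def _resolve_selector(
    effect: PlantedEffect,
    marker_ids: pd.Index,
    rng: np.random.Generator,
    current_means: np.ndarray,
) -> np.ndarray:
    """Indices of the markers an effect lands on.

    Integer selectors draw (without replacement) only among markers whose
    current group mean leaves the shifted mean strictly inside (0, 1), so a
    hyper-methylating shift is planted on markers that can still gain
    methylation.  Explicit marker-ID selectors are taken literally; an
    out-of-range shifted mean then raises a configuration error downstream.
    """
    if isinstance(effect.markers, int):
        eligible = np.flatnonzero(
            (current_means + effect.delta_beta > 0.0)
            & (current_means + effect.delta_beta < 1.0)
        )
        if effect.markers > eligible.size:
            raise ConfigError(
                f"planted effect asks for {effect.markers} markers but only "
                f"{eligible.size} can absorb a shift of {effect.delta_beta:+g}"
            )
        return eligible[rng.choice(eligible.size, size=effect.markers, replace=False)]
    missing = [m for m in effect.markers if m not in marker_ids]
    if missing:
        raise ConfigError(f"planted effect names unknown markers: {missing[:5]}")
    return marker_ids.get_indexer(pd.Index(effect.markers))


def _group_means(
    manifest: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    baseline = generate_baseline_means(manifest, cfg)
    means = pd.DataFrame(
        {g: baseline.to_numpy(copy=True) for g in GROUPS}, index=baseline.index
    )
    for effect in cfg.planted_effects:
        col = means.columns.get_loc(effect.group)
        idx = _resolve_selector(
            effect, means.index, rng, means.iloc[:, col].to_numpy()
        )
        means.iloc[idx, col] += effect.delta_beta
    bad = (means <= 0) | (means >= 1)
    if bad.to_numpy().any():
        offender = means.index[bad.any(axis=1)][0]
        raise ConfigError(
            f"planted effects push the group mean of {offender!r} outside (0, 1)"
        )
    return means


def group_mean_matrix(manifest: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Per-marker true beta mean for each group (baseline plus planted shifts)."""
    return _group_means(manifest, cfg, _rng(cfg.seed, _STREAM_BETA))


def generate_beta(
    manifest: pd.DataFrame, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate the beta matrix (markers x samples) and its group design.

    Each observation is Beta(mean * precision, (1 - mean) * precision) around
    the group's true marker mean.  Entries are set to NaN at
    ``cfg.missing_rate``; missing values are flagged, never imputed.

    Returns ``(beta, design)`` with ``design`` a sample_id -> group Series.
    """
    if len(manifest) == 0:
        raise ConfigError("cannot generate a beta matrix from an empty manifest")
    rng = _rng(cfg.seed, _STREAM_BETA)
    means = _group_means(manifest, cfg, rng)

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    design: dict[str, str] = {}
    prec = cfg.beta_precision
    for group in GROUPS:
        size = cfg.group_sizes[group]
        mu = means[group].to_numpy()[:, None]
        draws = rng.beta(mu * prec, (1.0 - mu) * prec, size=(len(means), size))
        blocks.append(draws)
        for i in range(1, size + 1):
            sample = f"{group}_{i}"
            columns.append(sample)
            design[sample] = group
    values = np.concatenate(blocks, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = np.where(mask, np.nan, values)
    beta = pd.DataFrame(values, index=means.index, columns=columns)
    return beta, pd.Series(design, name="group").rename_axis("sample_id")


def generate_expression_pools(
    marker_id: str,
    manifest: pd.DataFrame,
    group_means: Mapping[str, float],
    cfg: SimulationConfig,
    dct_pool_sizes: Mapping[str, int] | None = None,
    beta_pool_sizes: Mapping[str, int] | None = None,
) -> dict[str, PairedPools]:
    """Per-group unpaired beta / delta-Ct pools for one marker.

    The delta-Ct pool of group g is Normal(intercept + coupling * mu_g,
    expr_noise_sd) with ``mu_g`` the group's true beta mean; positive coupling
    plants the "methylation up, expression down" association.  Beta pools are
    drawn exactly as in :func:`generate_beta`.  Default pool sizes are the
    study's: methylation assays = group sizes, qPCR assays = 26/24/10.
    """
    if marker_id not in set(manifest["marker_id"]):
        raise ConfigError(f"marker {marker_id!r} not present in the manifest")
    dct_sizes = dict(dct_pool_sizes or DEFAULT_DCT_POOL_SIZES)
    beta_sizes = dict(beta_pool_sizes or cfg.group_sizes)
    for sizes in (dct_sizes, beta_sizes):
        for group, size in sizes.items():
            if size <= 0:
                raise ConfigError(f"pool size for group {group!r} must be positive")
    rng = _rng(cfg.seed, _STREAM_POOLS)
    prec = cfg.beta_precision
    pools: dict[str, PairedPools] = {}
    for group in GROUPS:
        mu = float(group_means[group])
        if not 0 < mu < 1:
            raise ConfigError(f"group mean for {group!r} must lie in (0, 1), got {mu}")
        beta_pool = rng.beta(mu * prec, (1.0 - mu) * prec, size=beta_sizes[group])
        dct_mean = cfg.expr_intercept + cfg.expr_coupling * mu
        dct_pool = rng.normal(dct_mean, cfg.expr_noise_sd, size=dct_sizes[group])
        pools[group] = PairedPools(group=group, beta_pool=beta_pool, dct_pool=dct_pool)
    return pools


def generate_gene_sets(
    manifest: pd.DataFrame,
    n_sets: int,
    set_size_range: tuple[int, int],
    enriched_gene_pool: Sequence[str] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over the manifest's genes, in a GMT-like collection.

    If ``enriched_gene_pool`` is given, the first set (``SET001``) is stocked
    with as many pool genes as fit its size before being topped up at random,
    so over-representation of that pool is recoverable by construction.
    """
    genes = pd.unique(manifest["gene"]).tolist()
    lo, hi = set_size_range
    if n_sets > 0 and (lo < 1 or hi < lo):
        raise ConfigError(f"invalid set_size_range {set_size_range!r}")
    if n_sets > 0 and hi > len(genes):
        raise ConfigError(
            f"set_size_range max {hi} exceeds the {len(genes)} available genes"
        )
    rng = _rng(seed, _STREAM_GENESETS)
    sets: dict[str, list[str]] = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET{i:03d}"
        if i == 1 and enriched_gene_pool is not None:
            pool = [g for g in dict.fromkeys(enriched_gene_pool) if g in set(genes)]
            take = pool[: min(size, len(pool))]
            rest_candidates = [g for g in genes if g not in set(take)]
            rest = rng.choice(rest_candidates, size=size - len(take), replace=False)
            members = take + [str(g) for g in rest]
        else:
            members = [str(g) for g in rng.choice(genes, size=size, replace=False)]
        sets[name] = members
    return GeneSetCollection(sets=sets, universe=frozenset(genes))
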