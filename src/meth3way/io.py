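"""Plain-text readers and writers for every pipeline artifact.

All tabular files are TSV with a header row; gene sets use standard GMT
(set name, description, then tab-separated gene symbols).  Writers and
readers round-trip: every file the pipeline emits can be re-read by the
function next to the writer.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DataError
from .simulate import GeneSetCollection, PairedPools

_FLOAT_FMT = "%.10g"


# -- manifest -----------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene": str})
    required = {"marker_id", "chromosome", "gene", "tss_offset"}
    if not required.issubset(df.columns):
        raise DataError(f"manifest {path} lacks columns {sorted(required - set(df.columns))}")
    if df["marker_id"].duplicated().any():
        raise DataError(f"manifest {path} has duplicate marker IDs")
    return df


# -- beta matrix & sample sheet ----------------------------------------------

def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    beta.rename_axis("marker_id").to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_beta(path: str | Path) -> pd.DataFrame:
    beta = pd.read_csv(path, sep="\t", index_col="marker_id")
    values = beta.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if np.any(bad & ~np.isnan(values)):
        raise DataError(f"beta matrix {path} has entries outside [0, 1]")
    return beta


def write_sample_sheet(design: pd.Series, path: str | Path) -> None:
    design.rename("group").rename_axis("sample_id").to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"}.issubset(df.columns):
        raise DataError(f"sample sheet {path} needs columns sample_id, group")
    return df.set_index("sample_id")["group"]


# -- comparison & rate tables -------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Generic indexed-table writer (comparison tables, filter output, ...)."""
    table.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_comparison(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="marker_id")
    required = {"mean_beta_a", "mean_beta_b", "delta_beta", "p_value", "significant"}
    if not required.issubset(df.columns):
        raise DataError(f"comparison table {path} lacks {sorted(required - set(df.columns))}")
    return df


def read_rates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="chromosome", dtype={"chromosome": str})


# -- gene sets (GMT) ----------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str | Path, universe: frozenset[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file; the universe defaults to the union of all members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{line_no}: GMT line has fewer than 3 fields")
            name, _desc, *genes = fields
            if name in sets:
                raise DataError(f"{path}:{line_no}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in genes if g]
    if universe is None:
        universe = frozenset(g for genes in sets.values() for g in genes)
    collection = GeneSetCollection(
        sets={n: [g for g in genes if g in universe] for n, genes in sets.items()},
        universe=universe,
    )
    return collection


# -- expression pools ---------------------------------------------------------

def write_pools(pools: Mapping[str, PairedPools], path: str | Path) -> None:
    """Long-format TSV: group, assay_type (beta|dct), assay_id, value."""
    rows = []
    for group in pools:
        pool = pools[group]
        for i, v in enumerate(pool.beta_pool, 1):
            rows.append((group, "beta", f"{group}_beta_{i}", v))
        for i, v in enumerate(pool.dct_pool, 1):
            rows.append((group, "dct", f"{group}_dct_{i}", v))
    pd.DataFrame(rows, columns=["group", "assay_type", "assay_id", "value"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_pools(path: str | Path) -> dict[str, PairedPools]:
    df = pd.read_csv(path, sep="\t")
    required = {"group", "assay_type", "value"}
    if not required.issubset(df.columns):
        raise DataError(f"pools file {path} needs columns {sorted(required)}")
    bad = set(df["assay_type"]) - {"beta", "dct"}
    if bad:
        raise DataError(f"pools file {path} has unknown assay types {sorted(bad)}")
    pools = {}
    for group, sub in df.groupby("group", sort=False):
        pools[str(group)] = PairedPools(
            group=str(group),
            beta_pool=sub.loc[sub["assay_type"] == "beta", "value"].to_numpy(),
            dct_pool=sub.loc[sub["assay_type"] == "dct", "value"].to_numpy(),
        )
    return pools
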