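"""Gene-set over-representation analysis for marker-derived gene lists.

Significant markers are mapped to their nearby genes (deduplicated), each
gene set is scored with the upper-tail hypergeometric test
P(X >= k) for X ~ Hypergeom(N, K, n) -- N universe genes, K set members,
n query genes, k overlap -- and pathway lists from two comparisons can be
intersected to find co-enriched sets.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .config import DataError
from .simulate import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "markers_to_genes",
    "hypergeom_upper_tail",
    "hypergeometric_enrichment",
    "shared_pathways",
]


def markers_to_genes(markers: Iterable[str], manifest: pd.DataFrame) -> set[str]:
    """Unique gene symbols annotated to the given markers.

    Genes owning several input markers are counted once.  Markers absent from
    the manifest are excluded with a logged warning.
    """
    markers = set(markers)
    annot = manifest.set_index("marker_id")["gene"]
    known = markers & set(annot.index)
    dropped = markers - known
    if dropped:
        log.warning(
            "%d markers not annotated in the manifest were excluded, e.g. %s",
            len(dropped),
            sorted(dropped)[:5],
        )
    return set(annot.loc[list(known)])


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); P(X >= 0) is exactly 1."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    The query and every set are intersected with the universe (the
    collection's own universe unless one is supplied) before testing.
    Returns a DataFrame indexed by set name with columns k, K, n, N, p_value,
    significant (p strictly below alpha), sorted by ascending p then name.
    """
    uni = frozenset(universe) if universe is not None else collection.universe
    if not uni:
        raise DataError("enrichment universe is empty")
    query_u = set(query) & uni
    n = len(query_u)
    N = len(uni)
    rows = []
    for name, genes in collection.sets.items():
        members = set(genes) & uni
        k = len(query_u & members)
        p = hypergeom_upper_tail(k, N, len(members), n)
        rows.append((name, k, len(members), n, N, p, p < alpha))
    out = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "p_value", "significant"]
    ).set_index("set_name")
    out.sort_values(["p_value", "set_name"], inplace=True)
    out.attrs["alpha"] = alpha
    return out


def shared_pathways(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Sets significant (p < alpha) in both enrichment tables.

    Returns set names with both p-values, ordered by the larger of the two
    (most robustly shared first).
    """
    if set(table_a.index) != set(table_b.index):
        raise DataError("enrichment tables cover different gene-set collections")
    sig_a = table_a.index[table_a["p_value"] < alpha]
    sig_b = table_b.index[table_b["p_value"] < alpha]
    shared = sig_a.intersection(sig_b)
    out = pd.DataFrame(
        {
            "p_value_a": table_a.loc[shared, "p_value"],
            "p_value_b": table_b.loc[shared, "p_value"],
        },
        index=shared.rename("set_name"),
    )
    out["p_max"] = out[["p_value_a", "p_value_b"]].max(axis=1)
    out.sort_values(["p_max", "set_name"], inplace=True)
    return out.drop(columns="p_max")
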