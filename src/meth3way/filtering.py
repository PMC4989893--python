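"""FC-normalized relative methylation and the multi-comparison alteration filter.

The filter keeps markers that are both statistically significant (p strictly
below a threshold) and biologically altered (group-mean methylation change
strictly above a magnitude threshold) in at least a minimum number of the
three pairwise comparisons, then labels each kept marker hyper- or
hypo-methylated relative to the febrile-control group.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DataError

log = logging.getLogger(__name__)

__all__ = ["relative_methylation", "filter_altered_markers", "classify_direction"]


def relative_methylation(beta: pd.DataFrame, design: pd.Series) -> pd.DataFrame:
    """Group-mean methylation as a percentage of the FC group mean.

    ``rel_FC`` is 100 exactly by construction; ``rel_KD1``/``rel_KD3`` are
    100 * mean_beta(group) / mean_beta(FC).  Markers whose FC mean is zero
    (or undefined) are flagged ``defined = False`` with NaN relatives and a
    log entry.
    """
    groups = ("FC", "KD1", "KD3")
    means = {}
    for g in groups:
        cols = design.index[design == g].intersection(beta.columns)
        if len(cols) == 0:
            raise DataError(f"group {g!r} has no samples in the beta matrix")
        means[g] = beta[cols].mean(axis=1, skipna=True)
    fc = means["FC"].to_numpy(dtype=float)
    defined = np.isfinite(fc) & (fc > 0)
    n_bad = int((~defined).sum())
    if n_bad:
        log.warning(
            "%d markers have zero/undefined FC mean; relative methylation undefined",
            n_bad,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_kd1 = np.where(defined, 100.0 * means["KD1"].to_numpy() / fc, np.nan)
        rel_kd3 = np.where(defined, 100.0 * means["KD3"].to_numpy() / fc, np.nan)
    return pd.DataFrame(
        {
            "rel_FC": np.where(defined, 100.0, np.nan),
            "rel_KD1": rel_kd1,
            "rel_KD3": rel_kd3,
            "defined": defined,
        },
        index=beta.index.rename("marker_id"),
    )


def classify_direction(table: pd.DataFrame) -> pd.Series:
    """Hyper/hypo label per marker from a comparison's delta_beta sign.

    ``hyper`` when the test group's mean exceeds the reference group's,
    ``hypo`` when below, ``unclassified`` on exact ties or undefined deltas.
    """
    delta = table["delta_beta"].to_numpy(dtype=float)
    out = np.where(delta > 0, "hyper", np.where(delta < 0, "hypo", "unclassified"))
    out = np.where(np.isnan(delta), "unclassified", out)
    return pd.Series(out, index=table.index, name="direction")


def _alteration(table: pd.DataFrame, metric: str) -> np.ndarray:
    """Per-marker alteration magnitude for one comparison.

    ``absolute``: |delta_beta| in beta units (0.10 = 10 percentage points).
    ``relative``: |mean_B / mean_A - 1|, i.e. the shift on the scale where the
    comparison's reference group is 100% (undefined when mean_A is 0).
    """
    if metric == "absolute":
        return np.abs(table["delta_beta"].to_numpy(dtype=float))
    if metric == "relative":
        a = table["mean_beta_a"].to_numpy(dtype=float)
        b = table["mean_beta_b"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(a > 0, np.abs(b / a - 1.0), np.nan)
    raise DataError(f"unknown alteration metric {metric!r}")


def filter_altered_markers(
    tables: Mapping[str, pd.DataFrame],
    p_thresh: float = 0.05,
    min_alteration: float = 0.10,
    min_comparisons: int = 2,
    metric: str = "absolute",
) -> pd.DataFrame:
    """Markers passing "p < p_thresh AND alteration > min_alteration" in
    at least ``min_comparisons`` of the supplied comparisons.

    ``tables`` maps comparison name -> comparison table; all tables must
    cover the same marker universe.  Both inequalities are strict.  The
    returned DataFrame (selected markers only) carries per-comparison
    p-values, alteration magnitudes and pass flags, the number of passing
    comparisons, and a hyper/hypo direction taken from the first
    FC-referenced comparison.
    """
    names = list(tables)
    if not names:
        raise DataError("no comparison tables supplied")
    universe = tables[names[0]].index
    for name in names[1:]:
        if not tables[name].index.equals(universe):
            raise DataError(f"comparison {name!r} covers a different marker universe")

    out = pd.DataFrame(index=universe.rename("marker_id"))
    passes = np.zeros((len(universe), len(names)), dtype=bool)
    for j, name in enumerate(names):
        table = tables[name]
        p = table["p_value"].to_numpy(dtype=float)
        alt = _alteration(table, metric)
        ok = np.zeros(len(table), dtype=bool)
        valid = ~np.isnan(p) & ~np.isnan(alt)
        ok[valid] = (p[valid] < p_thresh) & (alt[valid] > min_alteration)
        passes[:, j] = ok
        out[f"p_{name}"] = p
        out[f"alteration_{name}"] = alt
        out[f"pass_{name}"] = ok
    out["n_passed"] = passes.sum(axis=1)

    fc_ref = next(
        (n for n in names if tables[n].attrs.get("group_a") == "FC"), names[0]
    )
    out["direction"] = classify_direction(tables[fc_ref])
    selected = out[out["n_passed"] >= min_comparisons].copy()
    selected.attrs.update(
        {
            "p_thresh": p_thresh,
            "min_alteration": min_alteration,
            "min_comparisons": min_comparisons,
            "metric": metric,
            "direction_reference": fc_ref,
        }
    )
    return selected
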