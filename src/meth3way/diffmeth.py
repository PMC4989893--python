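"""Per-marker differential methylation testing and chromosome rollups.

For each pairwise group contrast a two-sample t-test is run marker by marker
on the beta values; a marker is called significantly altered when its p-value
falls strictly below alpha.  The per-chromosome significance rate is the
fraction of tested markers on a chromosome that are significant, and the
cross-comparison union collects every marker significant in any contrast.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

try:  # scipy >= 1.13
    from scipy.stats import SmallSampleWarning as _SmallSampleWarning
except ImportError:  # pragma: no cover
    _SmallSampleWarning = None

from .config import CHROMOSOMES, DataError

log = logging.getLogger(__name__)

__all__ = [
    "compare_groups",
    "significance_rate",
    "SignificanceRateResult",
    "union_significant",
    "neg_log10_p",
]


def compare_groups(
    beta: pd.DataFrame,
    design: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    test: str = "student",
) -> pd.DataFrame:
    """Two-sided two-sample t-test per marker between ``group_a`` and ``group_b``.

    Parameters
    ----------
    beta
        Markers x samples beta-value matrix (NaN = missing).
    design
        sample_id -> group label Series covering the beta columns.
    group_a, group_b
        Reference and test group; ``delta_beta`` is mean(B) - mean(A).
    alpha
        Strict significance cutoff on the raw p-value.
    test
        ``"student"`` (pooled variance, default) or ``"welch"``.

    Missing entries are dropped marker-wise; a marker with fewer than two
    observations in either group is flagged untestable (p undefined, never
    significant), as is a marker with zero variance in both groups and equal
    means.  Returns a DataFrame indexed by marker_id with columns
    mean_beta_a, mean_beta_b, delta_beta, t_stat, p_value, n_a, n_b,
    untestable, significant.
    """
    if test not in ("student", "welch"):
        raise DataError(f"unknown test flavor {test!r}")
    for g in (group_a, group_b):
        if g not in set(design):
            raise DataError(f"unknown group label {g!r}")
    cols_a = design.index[design == group_a].intersection(beta.columns)
    cols_b = design.index[design == group_b].intersection(beta.columns)
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise DataError(
            f"no beta columns for group {group_a if len(cols_a) == 0 else group_b!r}"
        )

    a = beta[cols_a].to_numpy(dtype=float)
    b = beta[cols_b].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    # Untestable / degenerate rows surface as NaN below; their warnings are noise.
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if _SmallSampleWarning is not None:
            warnings.simplefilter("ignore", _SmallSampleWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        t_stat, p_value = stats.ttest_ind(
            a, b, axis=1, equal_var=(test == "student"), nan_policy="omit"
        )
    t_stat = np.asarray(t_stat, dtype=float)
    p_value = np.asarray(p_value, dtype=float)
    # Sign convention: positive t for mean(B) > mean(A).
    t_stat = -t_stat

    untestable = (n_a < 2) | (n_b < 2)
    t_stat[untestable] = np.nan
    p_value[untestable] = np.nan
    significant = np.where(np.isnan(p_value), False, p_value < alpha)

    out = pd.DataFrame(
        {
            "mean_beta_a": mean_a,
            "mean_beta_b": mean_b,
            "delta_beta": mean_b - mean_a,
            "t_stat": t_stat,
            "p_value": p_value,
            "n_a": n_a,
            "n_b": n_b,
            "untestable": untestable,
            "significant": significant.astype(bool),
        },
        index=beta.index.rename("marker_id"),
    )
    out.attrs.update({"group_a": group_a, "group_b": group_b, "alpha": alpha, "test": test})
    return out


@dataclasses.dataclass(frozen=True)
class SignificanceRateResult:
    """Per-chromosome significance rates plus their mean and sample SD."""

    per_chromosome: pd.DataFrame  # index chromosome; n_total, n_significant, rate
    mean_rate: float
    sd_rate: float


def significance_rate(
    table: pd.DataFrame, manifest: pd.DataFrame
) -> SignificanceRateResult:
    """Ratio of significantly altered to tested markers per chromosome.

    Denominators count the markers that entered testing on each chromosome
    (untestable markers are excluded from both counts).  The mean and sample
    standard deviation are taken across the chromosomes present.
    """
    annot = manifest.set_index("marker_id")["chromosome"]
    missing = table.index.difference(annot.index)
    if len(missing) > 0:
        raise DataError(
            f"{len(missing)} tested markers missing from the manifest, "
            f"e.g. {list(missing[:5])}"
        )
    tested = table.loc[~table["untestable"]]
    chrom = annot.reindex(tested.index)
    order = [c for c in CHROMOSOMES if c in set(chrom)]
    n_total = chrom.value_counts().reindex(order).astype(int)
    n_sig = (
        chrom[tested["significant"]].value_counts().reindex(order).fillna(0).astype(int)
    )
    per = pd.DataFrame(
        {
            "n_total": n_total,
            "n_significant": n_sig,
            "rate": n_sig / n_total,
        }
    ).rename_axis("chromosome")
    rates = per["rate"].to_numpy()
    mean = float(np.mean(rates)) if len(rates) else float("nan")
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0
    return SignificanceRateResult(per_chromosome=per, mean_rate=mean, sd_rate=sd)


def union_significant(tables: Iterable[pd.DataFrame]) -> set[str]:
    """Markers significant in at least one comparison."""
    out: set[str] = set()
    for table in tables:
        out |= set(table.index[table["significant"]])
    return out


def neg_log10_p(table: pd.DataFrame, cap: float = 300.0) -> pd.Series:
    """-log10(p) per marker, for Manhattan-style displays.

    Undefined p-values propagate as NaN; p = 0 maps to ``cap`` (logged).
    """
    p = table["p_value"].to_numpy(dtype=float)
    out = np.full(p.shape, np.nan)
    zero = p == 0
    pos = p > 0
    out[pos] = -np.log10(p[pos])
    if zero.any():
        log.warning("%d markers have p = 0; capping -log10(p) at %g", zero.sum(), cap)
        out[zero] = cap
    out = np.minimum(out, cap, where=~np.isnan(out), out=out)
    return pd.Series(out, index=table.index, name="neg_log10_p")
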