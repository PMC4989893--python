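import numpy as np
import pandas as pd
import pytest

from meth3way import SimulationConfig, generate_beta, generate_manifest


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_markers=300, seed=11)


@pytest.fixture(scope="session")
def manifest(small_cfg):
    return generate_manifest(small_cfg)


@pytest.fixture(scope="session")
def beta_design(small_cfg, manifest):
    return generate_beta(manifest, small_cfg)


def make_comparison_table(
    marker_ids,
    p_values,
    delta_betas,
    mean_a=None,
    group_a="FC",
    group_b="KD1",
    alpha=0.05,
):
    """Hand-build a comparison table with the schema compare_groups emits."""
    p = np.asarray(p_values, dtype=float)
    delta = np.asarray(delta_betas, dtype=float)
    mean_a = np.full(len(p), 0.4) if mean_a is None else np.asarray(mean_a, dtype=float)
    table = pd.DataFrame(
        {
            "mean_beta_a": mean_a,
            "mean_beta_b": mean_a + delta,
            "delta_beta": delta,
            "t_stat": np.zeros(len(p)),
            "p_value": p,
            "n_a": np.full(len(p), 4),
            "n_b": np.full(len(p), 7),
            "untestable": np.isnan(p),
            "significant": np.where(np.isnan(p), False, p < alpha),
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    table.attrs.update(
        {"group_a": group_a, "group_b": group_b, "alpha": alpha, "test": "student"}
    )
    return table
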