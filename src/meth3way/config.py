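"""Configuration objects and validation for simulation and pipeline runs.

The simulation emulates a promoter-centric methylation BeadChip experiment:
a fixed marker manifest, per-sample fractional methylation (beta values) for
three clinical groups -- febrile controls (FC), acute Kawasaki disease (KD1)
and Kawasaki disease three weeks after IVIG treatment (KD3) -- plus qPCR
delta-Ct expression pools coupled to promoter methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

GROUPS: tuple[str, str, str] = ("FC", "KD1", "KD3")

#: The three pairwise contrasts, as (reference, test) group pairs.  The
#: comparison "KD1_vs_FC" reports delta_beta = mean(KD1) - mean(FC).
COMPARISONS: tuple[tuple[str, str], ...] = (("FC", "KD1"), ("FC", "KD3"), ("KD1", "KD3"))


def comparison_name(group_a: str, group_b: str) -> str:
    return f"{group_b}_vs_{group_a}"


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent data (CLI exit code 3)."""


# Approximate human protein-coding gene counts per chromosome, used as default
# marker-placement weights: a promoter array tracks gene density, not length.
_GENE_COUNTS: dict[str, int] = {
    "1": 2058, "2": 1309, "3": 1078, "4": 752, "5": 876, "6": 1048,
    "7": 989, "8": 677, "9": 786, "10": 733, "11": 1298, "12": 1034,
    "13": 327, "14": 830, "15": 613, "16": 873, "17": 1197, "18": 270,
    "19": 1472, "20": 544, "21": 234, "22": 488, "X": 842, "Y": 71,
}


def default_chromosome_weights() -> dict[str, float]:
    total = sum(_GENE_COUNTS.values())
    return {c: _GENE_COUNTS[c] / total for c in CHROMOSOMES}


@dataclass(frozen=True)
class PlantedEffect:
    """A methylation shift planted on a subset of markers in one group.

    ``markers`` is either an explicit sequence of marker IDs or an integer
    count, in which case that many markers are chosen (reproducibly, from the
    config seed) when the beta matrix is generated.
    """

    markers: Union[int, Sequence[str]]
    group: str
    delta_beta: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"planted effect targets unknown group {self.group!r}")
        if isinstance(self.markers, int) and self.markers < 0:
            raise ConfigError("planted effect marker count must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic three-group methylation experiment.

    Defaults mirror the study design: 27,578 CpG markers and group sizes
    FC=4, KD1=7, KD3=7.  Beta noise follows a Beta(mean * precision,
    (1 - mean) * precision) distribution; ``beta_precision`` = 200 gives a
    within-group standard deviation of roughly 0.02-0.035, typical of
    replicate BeadChip probes.  Baseline marker means are drawn from a
    bimodal mixture (mostly-unmethylated and mostly-methylated modes), the
    marginal shape characteristic of promoter arrays.
    """

    n_markers: int = 27578
    chromosome_weights: Mapping[str, float] = field(default_factory=default_chromosome_weights)
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"FC": 4, "KD1": 7, "KD3": 7}
    )
    planted_effects: tuple[PlantedEffect, ...] = ()
    beta_precision: float = 200.0
    missing_rate: float = 0.0
    # Baseline mixture: unmethylated mode Beta(2, 18) (mean 0.10), methylated
    # mode Beta(17, 3) (mean 0.85); means clipped to keep planted shifts inside (0, 1).
    baseline_low: tuple[float, float] = (2.0, 18.0)
    baseline_high: tuple[float, float] = (17.0, 3.0)
    baseline_high_fraction: float = 0.3
    # Expression model: delta-Ct mean = intercept + coupling * group beta mean.
    # Positive coupling encodes "more methylation -> higher delta-Ct -> lower
    # expression"; 8 cycles per unit beta spans a realistic qPCR dynamic range.
    expr_intercept: float = 6.0
    expr_coupling: float = 8.0
    expr_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 0:
            raise ConfigError("n_markers must be >= 0")
        weight_sum = 0.0
        for label, w in self.chromosome_weights.items():
            if label not in CHROMOSOMES:
                raise ConfigError(f"chromosome_weights has unknown label {label!r}")
            if w < 0:
                raise ConfigError(f"chromosome_weights[{label!r}] is negative")
            weight_sum += w
        if abs(weight_sum - 1.0) > 1e-9:
            raise ConfigError(f"chromosome_weights sum to {weight_sum!r}, expected 1")
        for group, size in self.group_sizes.items():
            if group not in GROUPS:
                raise ConfigError(f"group_sizes has unknown group {group!r}")
            if size < 2:
                raise ConfigError(
                    f"group_sizes[{group!r}] = {size}; two-sample tests need >= 2 per group"
                )
        if set(self.group_sizes) != set(GROUPS):
            raise ConfigError(f"group_sizes must cover all of {GROUPS}")
        if self.beta_precision <= 0:
            raise ConfigError("beta_precision must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.expr_noise_sd <= 0:
            raise ConfigError("expr_noise_sd must be positive")
        if self.baseline_high_fraction < 0 or self.baseline_high_fraction > 1:
            raise ConfigError("baseline_high_fraction must be in [0, 1]")
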