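"""Control-vs-treated comparison statistics.

Replicate groups (typically n = 3 trough runs per condition) are
summarized per cycle by mean and sample standard deviation; differences
between a control group and a nanoparticle-exposed (ECN) group carry the
propagated standard deviation σ_total = √(σ_control² + σ_ECN²). No
hypothesis tests are performed — the analysis reports means and
propagated SDs only.

Sign convention (stated here once, applied everywhere): for material-like
metrics (auc, log_auc, omega_eff — all increasing with material at the
interface), ``mean_difference = control − treated``, so a POSITIVE
difference means LESS material at the interface when ECN is added and a
negative difference means more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EquationDomainError, InsufficientDataError

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize_group",
    "propagate_sd",
    "compare_groups",
]

_KNOWN_METRICS = ("log_auc", "auc", "omega_eff")


@dataclass(frozen=True)
class GroupSummary:
    """Mean and sample SD of one metric for one group at one cycle."""

    label: str
    cycle_index: int
    n: int
    mean: float
    sd: float
    metric: str = "log_auc"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class GroupComparison:
    """Per-cycle difference between control and treated groups.

    ``mean_difference`` is control − treated (positive = less material
    with ECN); ``sd_total`` is the propagated SD of the difference.
    """

    metric: str
    cycle_index: int
    mean_difference: float
    sd_total: float

    def __post_init__(self) -> None:
        if self.sd_total < 0:
            raise ValueError("sd_total must be non-negative")


def summarize_group(
    values: Sequence[float], label: str, cycle_index: int, metric: str = "log_auc"
) -> GroupSummary:
    """Mean and sample SD (n−1 denominator; 0 for a singleton)."""
    values = [float(v) for v in values]
    if not values:
        raise InsufficientDataError("cannot summarize an empty group")
    arr = np.asarray(values)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return GroupSummary(
        label=label,
        cycle_index=cycle_index,
        n=len(arr),
        mean=float(np.mean(arr)),
        sd=sd,
        metric=metric,
    )


def propagate_sd(sd_control: float, sd_ecn: float) -> float:
    """Standard deviation of a group difference: √(σ_c² + σ_e²)."""
    if sd_control < 0 or sd_ecn < 0:
        raise EquationDomainError("standard deviations must be non-negative")
    return math.hypot(sd_control, sd_ecn)


def compare_groups(control: GroupSummary, treated: GroupSummary) -> GroupComparison:
    """Control-minus-treated difference with propagated SD.

    Positive values indicate less material at the interface in the
    treated (ECN) group. Cycle indices and metrics must match.
    """
    if control.cycle_index != treated.cycle_index:
        raise ValueError(
            f"cycle index mismatch: control cycle {control.cycle_index} vs "
            f"treated cycle {treated.cycle_index}"
        )
    if control.metric != treated.metric:
        raise ValueError(
            f"metric mismatch: {control.metric!r} vs {treated.metric!r}"
        )
    return GroupComparison(
        metric=control.metric,
        cycle_index=control.cycle_index,
        mean_difference=control.mean - treated.mean,
        sd_total=propagate_sd(control.sd, treated.sd),
    )
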