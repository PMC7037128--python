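"""End-to-end trace analysis and cohort comparison helpers.

``analyze_trace`` runs the full per-sample pipeline: segmentation →
per-cycle hysteresis/lift-off/collapse metrics → Volmer fits on each
compression branch. ``compare_cohorts`` aggregates per-cycle metric
values across replicate traces and emits control-vs-treated differences
with propagated SDs.
"""

from __future__ import annotations

from typing import Sequence

from .cycles import segment_cycles, liftoff_area
from .errors import InsufficientDataError
from .io_isotherm import IsothermTrace
from .metrics import (
    CycleMetrics,
    collapse_area,
    compressibility_modulus,
    hysteresis_auc,
    log_transform,
    peak_modulus,
)
from .stats import GroupComparison, compare_groups, summarize_group
from .volmer import DEFAULT_PI_RANGE, VolmerFit, fit_volmer

__all__ = ["analyze_trace", "compare_cohorts"]


def analyze_trace(
    trace: IsothermTrace,
    *,
    turn_tolerance: float = 1.0,
    liftoff_delta: float = 1.0,
    smooth_window: int = 11,
    collapse_prominence: float = 5.0,
    log_base: float = 10.0,
    pi_range: tuple[float, float] = DEFAULT_PI_RANGE,
    fit: bool = True,
    fix_scale: float | None = None,
) -> tuple[list[CycleMetrics], list[VolmerFit]]:
    """Segment a trace and compute all per-cycle observables.

    Returns per-cycle :class:`CycleMetrics` and (when ``fit`` is true)
    per-cycle :class:`VolmerFit` results; fits that cannot run (no LE
    window) appear with ``converged=False``.
    """
    cycles = segment_cycles(trace, turn_tolerance)
    metrics: list[CycleMetrics] = []
    fits: list[VolmerFit] = []
    for cycle in cycles:
        auc = hysteresis_auc(cycle)
        collapse = peak = None
        if len(cycle.compression) >= smooth_window:
            series = compressibility_modulus(cycle.compression, smooth_window)
            collapse = collapse_area(
                cycle.compression, series, smooth_window, collapse_prominence
            )
            peak = peak_modulus(series, smooth_window)
        metrics.append(
            CycleMetrics(
                cycle_index=cycle.index,
                auc=auc,
                log_auc=log_transform(auc, log_base),
                liftoff_area=liftoff_area(cycle, liftoff_delta),
                collapse_area=collapse,
                peak_modulus=peak,
            )
        )
        if fit:
            fits.append(
                fit_volmer(
                    cycle.compression,
                    pi_range=pi_range,
                    fix_scale=fix_scale,
                    cycle_index=cycle.index,
                )
            )
    return metrics, fits


def _metric_value(
    metrics: list[CycleMetrics], fits: list[VolmerFit], metric: str, cycle: int
) -> float | None:
    if metric == "omega_eff":
        for f in fits:
            if f.cycle_index == cycle and f.converged and f.params is not None:
                return f.params.omega_eff
        return None
    for m in metrics:
        if m.cycle_index == cycle:
            return getattr(m, metric)
    return None


def compare_cohorts(
    control: Sequence[IsothermTrace],
    treated: Sequence[IsothermTrace],
    metric: str = "log_auc",
    **analyze_kwargs,
) -> list[GroupComparison]:
    """Per-cycle control-vs-treated comparison of one metric.

    ``metric`` is one of ``log_auc``, ``auc`` or ``omega_eff``. Each
    trace is analyzed independently; per-cycle values are pooled across
    replicates and compared cycle-by-cycle over the cycles both cohorts
    cover. Replicates missing a value for a cycle (non-converged fit,
    zero-area loop) are dropped from that cycle's group.
    """
    if metric not in ("log_auc", "auc", "omega_eff"):
        raise ValueError(f"unknown metric {metric!r}")
    need_fit = metric == "omega_eff"

    def collect(traces: Sequence[IsothermTrace]) -> dict[int, list[float]]:
        per_cycle: dict[int, list[float]] = {}
        for trace in traces:
            metrics, fits = analyze_trace(trace, fit=need_fit, **analyze_kwargs)
            for m in metrics:
                value = _metric_value(metrics, fits, metric, m.cycle_index)
                if value is not None:
                    per_cycle.setdefault(m.cycle_index, []).append(value)
        return per_cycle

    control_values = collect(control)
    treated_values = collect(treated)
    comparisons: list[GroupComparison] = []
    for cycle in sorted(set(control_values) & set(treated_values)):
        if not control_values[cycle] or not treated_values[cycle]:
            continue
        ctrl = summarize_group(control_values[cycle], "control", cycle, metric)
        trt = summarize_group(treated_values[cycle], "treated", cycle, metric)
        comparisons.append(compare_groups(ctrl, trt))
    if not comparisons:
        raise InsufficientDataError("no cycle has values in both cohorts")
    return comparisons
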