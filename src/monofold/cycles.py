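"""Compression/expansion cycle segmentation and lift-off localization.

The barrier (ribbon) motion defines the cycle: turning points are local
extrema of the *trough area* signal only — surface pressure is the
measured response and never participates in segmentation. Extrema are
found on a 5-sample centered moving median of the area and accepted only
when the area moves by more than ``turn_tolerance`` on both sides, which
makes segmentation immune to pressure noise and to sub-tolerance barrier
jitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_isotherm import IsothermRecord, IsothermTrace

__all__ = ["Branch", "Cycle", "segment_cycles", "liftoff_area"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Branch:
    """One monotone leg of a cycle: ``compression`` or ``expansion``."""

    kind: str  # "compression" | "expansion"
    records: tuple[IsothermRecord, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("compression", "expansion"):
            raise ValueError(f"unknown branch kind {self.kind!r}")

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def areas(self) -> np.ndarray:
        return np.array([r.trough_area for r in self.records])

    @property
    def pressures(self) -> np.ndarray:
        return np.array([r.surface_pressure for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Cycle:
    """A compression branch plus the expansion that follows it (1-based)."""

    index: int
    compression: Branch
    expansion: Branch

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("cycle index is 1-based")


def moving_median(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving median with shrinking windows at the edges."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    if n <= window:
        return np.array([
            np.median(values[max(0, i - half): i + half + 1]) for i in range(n)
        ])
    out = np.empty(n)
    view = np.lib.stride_tricks.sliding_window_view(values, window)
    out[half: n - half] = np.median(view, axis=1)
    for i in range(half):
        out[i] = np.median(values[: i + half + 1])
        out[n - 1 - i] = np.median(values[n - 1 - i - half:])
    return out


def _turning_points(area: np.ndarray, tol: float) -> list[tuple[int, str]]:
    """Zigzag extrema of ``area`` with reversal tolerance ``tol``.

    Returns time-ordered ``(index, kind)`` pivots, alternating min/max.
    The temporally first sample of a plateau extremum is kept (strict
    comparison when updating candidates).
    """
    pivots: list[tuple[int, str]] = []
    direction = 0  # 0 unknown, +1 rising, -1 falling
    max_i = min_i = 0
    for i in range(1, len(area)):
        if area[i] > area[max_i]:
            max_i = i
        if area[i] < area[min_i]:
            min_i = i
        if direction <= 0 and area[i] - area[min_i] > tol:
            pivots.append((min_i, "min"))
            direction = 1
            max_i = i
        elif direction >= 0 and area[max_i] - area[i] > tol:
            pivots.append((max_i, "max"))
            direction = -1
            min_i = i
    if direction == 1:
        pivots.append((max_i, "max"))
    elif direction == -1:
        pivots.append((min_i, "min"))
    return pivots


def segment_cycles(trace: IsothermTrace, turn_tolerance: float = 1.0) -> list[Cycle]:
    """Split a trace into compression/expansion cycles.

    A cycle is one descent of the trough area (compression) followed by
    the next ascent (expansion). Turning points are detected on the
    5-sample moving median of the area; an extremum counts only if the
    area changes by more than ``turn_tolerance`` [cm²] on both sides.
    A trailing compression with no paired expansion is discarded with a
    logged warning, as is a cycle whose branch would hold fewer than two
    records. When no complete cycle exists an empty list is returned
    (with a warning), never an exception.

    Adjacent cycles partition the record list: the record at a shared
    area maximum belongs to the earlier cycle's expansion, and the next
    compression starts at the following sample.
    """
    if turn_tolerance <= 0:
        raise ValueError("turn_tolerance must be positive")
    smoothed = moving_median(trace.areas, 5)
    pivots = _turning_points(smoothed, turn_tolerance)

    # Discard any leading ascent: a cycle must start with a compression.
    while pivots and pivots[0][1] == "min":
        pivots.pop(0)

    cycles: list[Cycle] = []
    records = trace.records
    index = 1
    pos = 0
    start: int | None = None  # record index opening the next compression
    while pos + 2 < len(pivots):
        (i_max, k_max), (i_min, k_min), (i_end, k_end) = pivots[pos: pos + 3]
        if k_max != "max" or k_min != "min" or k_end != "max":
            break  # defensive; zigzag output alternates by construction
        comp_start = i_max if start is None else start
        comp = records[comp_start: i_min + 1]
        expa = records[i_min + 1: i_end + 1]
        if len(comp) < 2 or len(expa) < 2:
            logger.warning(
                "dropping cycle candidate at records %d..%d: branch shorter "
                "than 2 samples", comp_start, i_end,
            )
        else:
            cycles.append(
                Cycle(
                    index=index,
                    compression=Branch("compression", tuple(comp)),
                    expansion=Branch("expansion", tuple(expa)),
                )
            )
            index += 1
        start = i_end + 1
        pos += 2

    if pivots and pivots[-1][1] == "min" and len(pivots) >= 2:
        logger.warning("trailing unpaired compression discarded")
    if not cycles:
        logger.warning("no complete compression/expansion cycle found")
    return cycles


def liftoff_area(cycle: Cycle, delta: float = 1.0) -> float | None:
    """Trough area [cm²] where the compression leaves its baseline.

    The baseline Π_base is the 5th percentile of the compression branch's
    surface pressure; lift-off is the largest area (scanning from large
    to small, i.e. temporal order of a compression) at which the pressure
    first reaches Π_base + ``delta``. Returns ``None`` when the branch
    never reaches the threshold.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    pressures = cycle.compression.pressures
    areas = cycle.compression.areas
    threshold = np.percentile(pressures, 5) + delta
    hits = np.flatnonzero(pressures >= threshold)
    if hits.size == 0:
        return None
    return float(areas[hits[0]])
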