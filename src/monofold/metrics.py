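"""Per-cycle scalar observables of a Π–A cycle.

The central quantity is the hysteresis "area under the curve": the area
enclosed between the compression and expansion branches of one cycle,
measured as the absolute shoelace (Gauss) signed area of the polygon
formed by the measured (A, Π) points in temporal order. Its decay across
cycles tracks loss of material from the interface. The compressibility
modulus C_s⁻¹ = −A·(dΠ/dA) localizes monolayer collapse: collapse shows
up as a sharp modulus maximum on the compression branch just before the
plateau.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._numerics import local_quadratic_slope, shoelace_area
from .cycles import Branch, Cycle
from .errors import EquationDomainError, InsufficientDataError

__all__ = [
    "CycleMetrics",
    "surface_pressure",
    "hysteresis_auc",
    "log_transform",
    "compressibility_modulus",
    "collapse_area",
    "peak_modulus",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CycleMetrics:
    """Derived scalars for one compression/expansion cycle.

    ``auc`` is in mN/m·cm²; ``log_auc`` is log₁₀(auc) (None when auc is
    exactly zero); areas in cm²; ``peak_modulus`` in mN/m. Absent values
    are ``None``.
    """

    cycle_index: int
    auc: float
    log_auc: float | None
    liftoff_area: float | None
    collapse_area: float | None
    peak_modulus: float | None

    def __post_init__(self) -> None:
        if self.auc < 0:
            raise ValueError("auc must be non-negative")


def surface_pressure(gamma_water: float, gamma_film: float) -> float:
    """Surface pressure Π = γ₀ − γ [mN/m].

    γ₀ is the clean-water surface tension and γ the film-covered one.
    Slightly negative results are permitted (sensor artifacts).
    """
    return gamma_water - gamma_film


def hysteresis_auc(cycle: Cycle) -> float:
    """Hysteresis loop area [mN/m·cm²] of one cycle by the shoelace rule.

    The closed polygon concatenates the compression branch's (A, Π)
    points with the expansion branch's, in temporal order; the loop
    closes implicitly back to the start. The absolute signed area is
    returned, so self-intersecting (noisy) loops are handled as the
    polygon-area semantics dictate; a warning is logged when the two
    branches cross more than twice.
    """
    comp, expa = cycle.compression, cycle.expansion
    if len(comp) < 2 or len(expa) < 2:
        raise InsufficientDataError("each branch needs at least 2 records")
    x = np.concatenate([comp.areas, expa.areas])
    y = np.concatenate([comp.pressures, expa.pressures])
    _warn_if_many_crossings(comp, expa)
    return shoelace_area(x, y)


def _warn_if_many_crossings(comp: Branch, expa: Branch) -> None:
    """Advisory: count compression/expansion crossings on a common grid."""
    a_lo = max(comp.areas.min(), expa.areas.min())
    a_hi = min(comp.areas.max(), expa.areas.max())
    if a_hi <= a_lo:
        return
    grid = np.linspace(a_lo, a_hi, 101)
    order_c = np.argsort(comp.areas, kind="stable")
    order_e = np.argsort(expa.areas, kind="stable")
    pc = np.interp(grid, comp.areas[order_c], comp.pressures[order_c])
    pe = np.interp(grid, expa.areas[order_e], expa.pressures[order_e])
    diff = pc - pe
    signs = np.sign(diff[np.abs(diff) > 0])
    crossings = int(np.sum(signs[1:] != signs[:-1])) if signs.size else 0
    if crossings > 2:
        logger.warning(
            "compression and expansion branches cross %d times; loop is "
            "self-intersecting, absolute polygon area reported", crossings,
        )


def log_transform(auc: float, base: float = 10.0) -> float | None:
    """Log-scale AUC (base 10 by default); ``None`` for a zero-area loop."""
    if auc < 0:
        raise EquationDomainError("auc must be non-negative")
    if auc == 0:
        return None
    return math.log(auc, base)


def compressibility_modulus(
    branch: Branch, smooth_window: int = 11
) -> list[tuple[float, float]]:
    """Compressibility modulus C_s⁻¹(A) = −A·(dΠ/dA) along a branch.

    dΠ/dA is estimated by centered local least-squares quadratic fitting
    over ``smooth_window`` samples (shrinking one-sided windows at the
    ends), which is noise-robust, deterministic, and exact for locally
    quadratic Π(A). Output pairs ``(area, modulus)`` [cm², mN/m] are
    aligned with the input samples.
    """
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if len(branch) < smooth_window:
        raise InsufficientDataError(
            f"branch has {len(branch)} records, need >= {smooth_window}"
        )
    areas = branch.areas
    slope = local_quadratic_slope(areas, branch.pressures, smooth_window)
    modulus = -areas * slope
    return list(zip(areas.tolist(), modulus.tolist()))


def collapse_area(
    branch: Branch,
    modulus_series: list[tuple[float, float]],
    smooth_window: int = 11,
    prominence: float = 5.0,
) -> float | None:
    """Trough area of monolayer collapse, or ``None`` if no sharp feature.

    Collapse is taken at the global maximum of the compressibility
    modulus along the compression branch, excluding the first and last
    ``smooth_window`` samples (edge estimates are one-sided and noisy).
    The maximum must exceed ``prominence`` times the branch's median
    modulus — and an absolute floor of 1e-6 mN/m, so that a branch whose
    modulus is zero everywhere (constant Π) is featureless — otherwise
    ``None`` is returned.
    """
    if not modulus_series:
        raise InsufficientDataError("modulus series is empty")
    areas = np.array([a for a, _ in modulus_series])
    values = np.array([m for _, m in modulus_series])
    interior = slice(smooth_window, len(values) - smooth_window)
    vals_int = values[interior]
    if vals_int.size == 0:
        return None
    peak = int(np.argmax(vals_int))
    if vals_int[peak] <= 1e-6 or vals_int[peak] < prominence * np.median(values):
        return None
    return float(areas[interior][peak])


def peak_modulus(
    modulus_series: list[tuple[float, float]], smooth_window: int = 11
) -> float | None:
    """Maximum interior modulus value [mN/m] of a series, or ``None``."""
    values = np.array([m for _, m in modulus_series])
    vals_int = values[smooth_window: len(values) - smooth_window]
    if vals_int.size == 0:
        return None
    return float(np.max(vals_int))
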