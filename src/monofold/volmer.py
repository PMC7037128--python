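"""Volmer equation of state: evaluation, LE-window fitting, ω_eff tracking.

At trough scale the Volmer EOS reads

    Π(A_T) = c · ω_eff / (A_T − ω_eff) − Π_coh,

where ω_eff = n·ω is the effective *total* molecular area of the film
[cm²], Π_coh the cohesion pressure [mN/m], and c the pressure-scale
coefficient kT/ω₀ [mN/m], fitted here as a single free parameter rather
than pinned to a literature water-molecule area. The EOS holds only in
the liquid-expanded (LE) region, so fitting is restricted to a pressure
window on the compression branch, truncated below any LE–LC coexistence
plateau. A per-cycle decrease of fitted ω_eff quantifies loss of
material from the interface across compression/expansion cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._numerics import local_quadratic_slope
from .cycles import Branch
from .errors import EquationDomainError, InsufficientDataError

__all__ = [
    "VolmerParams",
    "VolmerFit",
    "volmer_pressure",
    "select_le_window",
    "fit_volmer",
    "omega_trajectory",
]

DEFAULT_PI_RANGE: tuple[float, float] = (2.0, 30.0)


@dataclass(frozen=True)
class VolmerParams:
    """Trough-scale Volmer EOS parameters.

    ``omega_eff`` [cm²] (> 0), ``pi_coh`` [mN/m], and ``pressure_scale``
    [mN/m] — the composite kT/ω₀ coefficient.
    """

    omega_eff: float
    pi_coh: float
    pressure_scale: float

    def __post_init__(self) -> None:
        if not self.omega_eff > 0:
            raise ValueError("omega_eff must be positive")
        if not self.pressure_scale > 0:
            raise ValueError("pressure_scale must be positive")


@dataclass(frozen=True)
class VolmerFit:
    """Result of fitting the Volmer EOS to one compression branch.

    ``params`` is ``None`` when the fit could not run (insufficient LE
    window); ``converged`` is False both then and on optimizer failure.
    ``fit_window`` is (area_min, area_max, pi_min, pi_max) over the
    points actually fitted; ``rmse`` [mN/m] is over those points.
    """

    params: VolmerParams | None
    fit_window: tuple[float, float, float, float]
    n_points: int
    rmse: float
    converged: bool
    cycle_index: int = 0


def volmer_pressure(area_trough, params: VolmerParams):
    """Volmer EOS surface pressure [mN/m] at trough area(s) [cm²].

    Accepts a scalar or array ``area_trough``; every value must lie on
    the physical branch ``A_T > omega_eff`` or :class:`EquationDomainError`
    is raised (the EOS has a pole at A_T = ω_eff).
    """
    area = np.asarray(area_trough, dtype=float)
    if np.any(area <= params.omega_eff):
        raise EquationDomainError(
            f"area_trough must exceed omega_eff={params.omega_eff} cm² "
            "(pole of the Volmer EOS)"
        )
    out = (
        params.pressure_scale * params.omega_eff / (area - params.omega_eff)
        - params.pi_coh
    )
    if np.isscalar(area_trough):
        return float(out)
    return out


def select_le_window(
    branch: Branch, pi_range: tuple[float, float] = DEFAULT_PI_RANGE
) -> Branch:
    """Liquid-expanded sub-branch of a compression for EOS fitting.

    Returns the contiguous run of compression records whose pressures
    lie within ``pi_range`` (inclusive; longest run if noise fragments
    it), truncated below any detected LE–LC plateau — a run of ≥ 5
    consecutive points where |dΠ/dA| falls under 10% of its running
    median inside the window. At least 4 points must survive.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 qualifying points (the caller records the fit as
        non-converged rather than failing).
    """
    lo, hi = pi_range
    if not lo < hi:
        raise ValueError("pi_range must be (lower, upper) with lower < upper")
    pressures = branch.pressures
    mask = (pressures >= lo) & (pressures <= hi)
    start, stop = _longest_run(mask)
    if stop - start < 4:
        raise InsufficientDataError(
            f"only {stop - start} points with Π in [{lo}, {hi}] mN/m"
        )
    records = branch.records[start:stop]
    areas = np.array([r.trough_area for r in records])
    pis = np.array([r.surface_pressure for r in records])

    cut = _plateau_onset(areas, pis)
    if cut is not None:
        records = records[:cut]
    if len(records) < 4:
        raise InsufficientDataError(
            "fewer than 4 LE points remain after plateau truncation"
        )
    return Branch("compression", tuple(records))


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """Half-open bounds of the longest True run (first on ties)."""
    best = (0, 0)
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def _plateau_onset(areas: np.ndarray, pressures: np.ndarray) -> int | None:
    """Index where an LE–LC plateau starts inside the window, else None."""
    n = len(areas)
    if n < 10:
        return None
    slopes = np.abs(local_quadratic_slope(areas, pressures, 5))
    running_median = np.array(
        [np.median(slopes[: i + 1]) for i in range(n)]
    )
    flat = slopes < 0.1 * running_median
    run = 0
    for i, f in enumerate(flat):
        run = run + 1 if f else 0
        if run >= 5:
            return i - run + 1
    return None


def fit_volmer(
    branch: Branch,
    pi_range: tuple[float, float] = DEFAULT_PI_RANGE,
    init: VolmerParams | None = None,
    fix_scale: float | None = None,
    cycle_index: int = 0,
) -> VolmerFit:
    """Nonlinear least-squares Volmer fit to a compression branch.

    The LE window is selected with :func:`select_le_window`; the three
    parameters (ω_eff, Π_coh, c) are then fitted by trust-region least
    squares with bounds ω_eff ∈ (0, 0.95·min A_T) and c > 0. Default
    initialization: ω_eff = 0.5·min A_T, Π_coh = −min Π, c = 50 mN/m.
    ``fix_scale`` pins c and fits only the remaining two parameters.

    Never raises on fit trouble: an insufficient window or optimizer
    failure is reported via ``converged=False``.
    """
    try:
        window = select_le_window(branch, pi_range)
    except InsufficientDataError:
        count = int(
            np.sum(
                (branch.pressures >= pi_range[0])
                & (branch.pressures <= pi_range[1])
            )
        )
        return VolmerFit(
            params=None,
            fit_window=(math.nan, math.nan, math.nan, math.nan),
            n_points=count,
            rmse=math.nan,
            converged=False,
            cycle_index=cycle_index,
        )

    areas = window.areas
    pis = window.pressures
    a_min = float(areas.min())
    omega_hi = 0.95 * a_min

    if init is not None:
        x0_omega = min(init.omega_eff, 0.999 * omega_hi)
        x0_coh = init.pi_coh
        x0_scale = init.pressure_scale
    else:
        x0_omega = 0.5 * a_min
        x0_coh = -float(pis.min())
        x0_scale = 50.0

    tiny = 1e-12
    if fix_scale is not None:
        if fix_scale <= 0:
            raise ValueError("fix_scale must be positive")

        def residual(x):
            omega, coh = x
            return fix_scale * omega / (areas - omega) - coh - pis

        def jac(x):
            omega, coh = x
            d = areas - omega
            return np.column_stack([fix_scale * areas / d**2, -np.ones_like(d)])

        x0 = [x0_omega, x0_coh]
        bounds = ([tiny, -np.inf], [omega_hi, np.inf])
    else:

        def residual(x):
            omega, coh, scale = x
            return scale * omega / (areas - omega) - coh - pis

        def jac(x):
            omega, coh, scale = x
            d = areas - omega
            return np.column_stack(
                [scale * areas / d**2, -np.ones_like(d), omega / d]
            )

        x0 = [x0_omega, x0_coh, x0_scale]
        bounds = ([tiny, -np.inf, tiny], [omega_hi, np.inf, np.inf])

    result = least_squares(
        residual,
        x0,
        jac=jac,
        bounds=bounds,
        method="trf",
        xtol=1e-12,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    if fix_scale is not None:
        omega, coh = result.x
        scale = fix_scale
    else:
        omega, coh, scale = result.x
    params = VolmerParams(
        omega_eff=float(omega), pi_coh=float(coh), pressure_scale=float(scale)
    )
    rmse = float(np.sqrt(np.mean(result.fun**2)))
    return VolmerFit(
        params=params,
        fit_window=(a_min, float(areas.max()), float(pis.min()), float(pis.max())),
        n_points=len(areas),
        rmse=rmse,
        converged=bool(result.success),
        cycle_index=cycle_index,
    )


def omega_trajectory(fits: list[VolmerFit]) -> list[tuple[int, float]]:
    """Cycle-ordered (cycle_index, ω_eff) pairs from converged fits.

    Non-converged cycles are omitted; a per-cycle decrease of ω_eff is
    the EOS-based estimate of material loss across cycles (consecutive
    ratios estimate the per-cycle retention fraction).
    """
    pairs = [
        (f.cycle_index, f.params.omega_eff)
        for f in fits
        if f.converged and f.params is not None
    ]
    return sorted(pairs, key=lambda p: p[0])
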