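"""Hysteresis AUC, log transform, compressibility modulus, collapse point."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monofold import (
    Branch,
    Cycle,
    EquationDomainError,
    InsufficientDataError,
    VolmerParams,
    collapse_area,
    compressibility_modulus,
    hysteresis_auc,
    log_transform,
    surface_pressure,
    volmer_pressure,
)
from conftest import build_branch


def loop_cycle(comp_areas, comp_pis, exp_areas, exp_pis):
    comp = build_branch(comp_areas, comp_pis, "compression", t0=0.0)
    expa = build_branch(exp_areas, exp_pis, "expansion", t0=len(comp_areas))
    return Cycle(1, comp, expa)


def trapezoid_loop_area(areas, comp_pis, exp_pis):
    """Independent oracle: |∫Π dA| over compression minus over expansion."""
    comp = np.trapezoid(comp_pis, areas)
    expa = np.trapezoid(exp_pis, areas)
    return abs(comp - expa)


class TestSurfacePressure:
    @pytest.mark.parametrize(
        "g0,g,expected", [(72.8, 72.8, 0.0), (72.8, 0.8, 72.0), (72.8, 72.9, -0.1)]
    )
    def test_definition(self, g0, g, expected):
        assert surface_pressure(g0, g) == pytest.approx(expected)


class TestHysteresisAuc:
    def test_identical_path_has_zero_area(self):
        areas = np.linspace(160, 60, 30)
        pis = 70 * (160 - areas) / 100
        cycle = loop_cycle(areas, pis, areas[::-1], pis[::-1])
        assert hysteresis_auc(cycle) == pytest.approx(0.0, abs=1e-9)

    def test_unit_square_loop(self):
        """4-vertex unit-square loop encloses exactly 1 (hand shoelace)."""
        comp = build_branch([2.0, 1.0], [0.0, 0.0], "compression", 0)
        expa = build_branch([1.0, 2.0], [1.0, 1.0], "expansion", 2)
        assert hysteresis_auc(Cycle(1, comp, expa)) == 1.0

    def test_matches_trapezoid_oracle_on_volmer_plateau_loop(self):
        params = VolmerParams(50.0, 5.0, 40.0)
        areas = np.linspace(166.0, 80.0, 300)
        comp = np.minimum(volmer_pressure(areas, params), 60.0)
        expa_params = VolmerParams(45.0, 5.0, 40.0)
        expa = np.maximum(
            np.minimum(volmer_pressure(areas, expa_params), 60.0) - 20.0, 0.0
        )
        cycle = loop_cycle(areas, comp, areas[::-1], expa[::-1])
        oracle = trapezoid_loop_area(areas, comp, expa)
        assert hysteresis_auc(cycle) == pytest.approx(oracle, rel=1e-9)

    def test_branch_too_short_raises(self):
        comp = build_branch([100.0], [5.0], "compression")
        expa = build_branch([100.0, 120.0], [1.0, 0.5], "expansion", 1)
        with pytest.raises(InsufficientDataError):
            hysteresis_auc(Cycle(1, comp, expa))

    @given(
        offset=st.floats(-50, 50, allow_nan=False),
        scale_a=st.floats(0.1, 10),
        scale_p=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_and_bilinear_scaling(self, offset, scale_a, scale_p):
        """Π offsets cancel in a closed loop; axis scalings multiply AUC."""
        areas = np.linspace(150.0, 50.0, 40)
        comp = 60 * (150 - areas) / 100
        expa = np.maximum(comp - 10, 0.0)
        base = hysteresis_auc(loop_cycle(areas, comp, areas[::-1], expa[::-1]))
        shifted = hysteresis_auc(
            loop_cycle(areas, comp + offset, areas[::-1], expa[::-1] + offset)
        )
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        scaled = hysteresis_auc(
            loop_cycle(
                areas * scale_a,
                comp * scale_p,
                areas[::-1] * scale_a,
                expa[::-1] * scale_p,
            )
        )
        assert scaled == pytest.approx(base * scale_a * scale_p, rel=1e-9)

    def test_reversal_and_cyclic_permutation_invariance(self):
        from monofold._numerics import shoelace_area

        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 12)
        y = rng.uniform(0, 10, 12)
        base = shoelace_area(x, y)
        assert shoelace_area(x[::-1], y[::-1]) == pytest.approx(base, rel=1e-12)
        for k in (1, 5, 11):
            assert shoelace_area(np.roll(x, k), np.roll(y, k)) == pytest.approx(
                base, rel=1e-12
            )


class TestLogTransform:
    def test_power_of_ten(self):
        assert log_transform(1000.0) == pytest.approx(3.0)

    def test_typical_first_cycle_scale(self):
        # 10**3.45 = 2818.38...; log10(2818.4) = 3.45 to 1e-3
        assert log_transform(2818.4) == pytest.approx(3.45, abs=1e-3)

    def test_zero_loop_absent(self):
        assert log_transform(0.0) is None

    def test_negative_rejected(self):
        with pytest.raises(EquationDomainError):
            log_transform(-1.0)

    def test_alternative_base(self):
        assert log_transform(8.0, base=2.0) == pytest.approx(3.0)


class TestCompressibilityModulus:
    def test_logarithmic_isotherm_gives_constant_modulus(self):
        """Π = c − k·ln A  ⇒  C = −A·(−k/A) = k everywhere."""
        areas = np.linspace(160.0, 60.0, 2001)
        k = 37.5
        pis = 100.0 - k * np.log(areas)
        series = compressibility_modulus(build_branch(areas, pis), 11)
        mods = np.array([m for _, m in series])
        np.testing.assert_allclose(mods, k, rtol=1e-4)

    def test_constant_pressure_gives_zero(self):
        areas = np.linspace(160.0, 60.0, 50)
        series = compressibility_modulus(build_branch(areas, np.full(50, 30.0)), 11)
        mods = np.array([m for _, m in series])
        np.testing.assert_allclose(mods, 0.0, atol=1e-10)

    def test_volmer_branch_matches_closed_form(self):
        """C(A_T) = c·ω_eff·A_T/(A_T − ω_eff)², checked away from edges."""
        params = VolmerParams(50.0, 8.0, 40.0)
        areas = np.linspace(160.0, 110.0, 4001)
        pis = volmer_pressure(areas, params)
        series = compressibility_modulus(build_branch(areas, pis), 11)
        mods = np.array([m for _, m in series])
        closed = (
            params.pressure_scale
            * params.omega_eff
            * areas
            / (areas - params.omega_eff) ** 2
        )
        interior = slice(22, -22)
        rel = np.abs(mods[interior] - closed[interior]) / closed[interior]
        assert rel.max() < 1e-6

    def test_too_few_records(self):
        areas = np.linspace(100, 90, 5)
        with pytest.raises(InsufficientDataError):
            compressibility_modulus(build_branch(areas, areas), 11)


class TestCollapseArea:
    @staticmethod
    def _knee_branch():
        """Shallow Volmer rise with a hard plateau: sharp modulus knee."""
        params = VolmerParams(40.0, 8.0, 10.0)
        pi_c = 72.0
        areas = np.linspace(166.0, 42.0, 600)
        with np.errstate(divide="ignore"):
            raw = np.where(
                areas > params.omega_eff,
                params.pressure_scale
                * params.omega_eff
                / np.maximum(areas - params.omega_eff, 1e-12)
                - params.pi_coh,
                np.inf,
            )
        pis = np.clip(raw, 0.0, pi_c)
        knee = params.omega_eff * (
            1.0 + params.pressure_scale / (pi_c + params.pi_coh)
        )
        return build_branch(areas, pis), knee

    def test_knee_located_within_sample_spacing(self):
        branch, knee = self._knee_branch()
        series = compressibility_modulus(branch, 11)
        got = collapse_area(branch, series, 11)
        spacing = abs(branch.areas[1] - branch.areas[0])
        # Closed-form modulus is maximal just above the plateau onset; the
        # smoothed estimate may sit a few samples into the knee.
        assert got == pytest.approx(knee, abs=12 * spacing)

    def test_ideal_gas_like_branch_has_no_collapse(self):
        """Π ∝ 1/A ⇒ C = Π itself: slowly varying, max < 5× median."""
        areas = np.linspace(166.0, 60.0, 300)
        pis = 500.0 / areas
        series = compressibility_modulus(build_branch(areas, pis), 11)
        mods = np.array([m for _, m in series])
        assert mods.max() < 5 * np.median(mods)  # the gate's own premise
        assert collapse_area(build_branch(areas, pis), series, 11) is None

    def test_constant_pressure_has_no_collapse(self):
        areas = np.linspace(166.0, 60.0, 100)
        branch = build_branch(areas, np.full(100, 40.0))
        series = compressibility_modulus(branch, 11)
        assert collapse_area(branch, series, 11) is None
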