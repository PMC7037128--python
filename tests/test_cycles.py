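"""Cycle segmentation and lift-off localization."""

import logging

import numpy as np
import pytest

from monofold import SyntheticModel, liftoff_area, segment_cycles, simulate_trace
from conftest import build_trace


def triangle(n_periods, n_leg=60, top=166.0, bottom=46.0):
    down = np.linspace(top, bottom, n_leg)
    up = np.linspace(bottom, top, n_leg)
    return np.concatenate([np.concatenate([down, up]) for _ in range(n_periods)])


class TestSegmentation:
    def test_single_triangle_gives_one_cycle(self):
        area = triangle(1)
        trace = build_trace(area, np.zeros_like(area))
        cycles = segment_cycles(trace)
        assert len(cycles) == 1
        assert cycles[0].index == 1
        comp, expa = cycles[0].compression, cycles[0].expansion
        spacing = 120.0 / 59  # one leg sample step in cm²
        # The 5-sample median smoothing may place the turning point within
        # a couple of samples of the true vertex.
        assert comp.areas[0] == pytest.approx(166.0, abs=2 * spacing)
        assert comp.areas[-1] == pytest.approx(46.0, abs=2 * spacing)
        assert expa.areas[-1] == pytest.approx(166.0, abs=2 * spacing)
        assert comp.times[-1] < expa.times[0]

    def test_five_periods_give_five_consecutive_cycles(self):
        area = triangle(5)
        trace = build_trace(area, np.zeros_like(area))
        cycles = segment_cycles(trace)
        # Independent oracle: count descents paired with ascents by scanning
        # the derivative sign of the known waveform (zeros dropped).
        sign = np.sign(np.diff(area))
        sign = sign[sign != 0]
        descents = int(np.sum((sign[:-1] < 0) & (sign[1:] > 0)))
        assert len(cycles) == descents == 5
        assert [c.index for c in cycles] == [1, 2, 3, 4, 5]

    def test_cycles_are_disjoint_and_time_ordered(self):
        area = triangle(3)
        trace = build_trace(area, np.zeros_like(area))
        cycles = segment_cycles(trace)
        seen = []
        for c in cycles:
            seen.extend(c.compression.times.tolist())
            seen.extend(c.expansion.times.tolist())
        assert seen == sorted(seen)
        assert len(seen) == len(set(seen))

    def test_monotone_decrease_yields_empty_with_warning(self, caplog):
        area = np.linspace(166, 46, 80)
        trace = build_trace(area, np.zeros_like(area))
        with caplog.at_level(logging.WARNING, logger="monofold.cycles"):
            cycles = segment_cycles(trace)
        assert cycles == []
        assert any("no complete" in r.message for r in caplog.records)

    def test_trailing_unpaired_compression_discarded(self, caplog):
        area = np.concatenate([triangle(2), np.linspace(166, 46, 60)])
        trace = build_trace(area, np.zeros_like(area))
        with caplog.at_level(logging.WARNING, logger="monofold.cycles"):
            cycles = segment_cycles(trace)
        assert len(cycles) == 2
        assert any("trailing" in r.message for r in caplog.records)

    def test_segmentation_idempotent(self, default_model):
        """Re-segmenting the concatenated branches reproduces boundaries."""
        trace = simulate_trace(default_model)
        cycles = segment_cycles(trace)
        records = []
        for c in cycles:
            records.extend(c.compression.records)
            records.extend(c.expansion.records)
        again = segment_cycles(build_trace(
            [r.trough_area for r in records],
            [r.surface_pressure for r in records],
            times=[r.time for r in records],
        ))
        assert len(again) == len(cycles)
        for a, b in zip(again, cycles):
            np.testing.assert_array_equal(a.compression.areas, b.compression.areas)
            np.testing.assert_array_equal(a.expansion.areas, b.expansion.areas)

    def test_pressure_noise_does_not_move_boundaries(self, noise_free_model):
        """Segmentation depends on area only: Π noise of SD 0.1 is inert."""
        trace = simulate_trace(noise_free_model)
        rng = np.random.default_rng(11)
        noisy = build_trace(
            trace.areas,
            trace.pressures + rng.normal(0, 0.1, len(trace)),
            times=trace.times,
        )
        ref = segment_cycles(trace)
        got = segment_cycles(noisy)
        assert len(got) == len(ref)
        for a, b in zip(got, ref):
            assert a.compression.times[0] == b.compression.times[0]
            assert a.compression.times[-1] == b.compression.times[-1]
            assert a.expansion.times[-1] == b.expansion.times[-1]

    def test_subtolerance_jitter_ignored(self):
        """Barrier jitter below turn_tolerance creates no extra cycles."""
        area = triangle(2)
        rng = np.random.default_rng(5)
        jittered = area + rng.uniform(-0.2, 0.2, area.size)
        trace = build_trace(jittered, np.zeros_like(area))
        assert len(segment_cycles(trace, turn_tolerance=1.0)) == 2


class TestLiftoff:
    def _one_cycle(self, areas, pressures):
        full_a = np.concatenate([areas, areas[::-1]])
        full_p = np.concatenate([pressures, pressures[::-1]])
        (cycle,) = segment_cycles(build_trace(full_a, full_p))
        return cycle

    def test_piecewise_linear_liftoff_matches_analytic(self):
        """Π = 0 above 100 cm², rising 0.5 mN/m per cm² below: Π=1 at 98."""
        areas = np.linspace(166.0, 46.0, 241)  # 0.5 cm² spacing
        pressures = np.where(areas > 100.0, 0.0, 0.5 * (100.0 - areas))
        cycle = self._one_cycle(areas, pressures)
        got = liftoff_area(cycle, delta=1.0)
        # Baseline is the 5th pressure percentile (>0 here since much of the
        # branch rises); solve Π(A) = baseline + 1 on the linear part.
        base = np.percentile(cycle.compression.pressures, 5)
        expected = 100.0 - 2.0 * (base + 1.0)
        assert got == pytest.approx(expected, abs=0.5)  # one sample spacing

    def test_flat_pressure_has_no_liftoff(self):
        areas = np.linspace(166.0, 46.0, 50)
        cycle = self._one_cycle(areas, np.zeros_like(areas))
        assert liftoff_area(cycle) is None

    def test_already_lifted_branch_lifts_off_at_start(self):
        """A run started at Π ≈ 10 mN/m and rising steeply lifts off at
        the very start of the compression (within the few samples the
        percentile baseline needs to establish itself)."""
        areas = np.linspace(166.0, 46.0, 50)
        pressures = 10.0 + 60.0 * (166.0 - areas) / 120.0
        cycle = self._one_cycle(areas, pressures)
        got = liftoff_area(cycle)
        assert got is not None
        assert got >= cycle.compression.areas[4]

    def test_liftoff_nonincreasing_under_material_loss(self):
        model = SyntheticModel(retention=0.85, noise_sd=0.0, seed=3)
        cycles = segment_cycles(simulate_trace(model))
        values = [liftoff_area(c) for c in cycles]
        assert all(v is not None for v in values)
        assert all(b <= a for a, b in zip(values, values[1:]))
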