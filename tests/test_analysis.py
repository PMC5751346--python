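"""Bilayer observables: density profiles, z-MSD, diffusion fits, pores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permeatrace import (
    InputError,
    MSDSeries,
    OccupancySeries,
    ValidationError,
    density_profile,
    detect_pores,
    diffusion_coefficient,
    msd_z,
    pore_occupancy_series,
    select_beads,
)
from permeatrace.analysis import NM2_PER_NS_TO_CM2_PER_S
from tests.test_trajectory import make_traj


def rle_pore_oracle(counts, times, min_count, min_persistence):
    """Brute-force run-length enumeration of qualifying occupancy runs."""
    events = []
    run_start = None
    for i, c in enumerate(list(counts) + [-1]):  # sentinel closes any open run
        if c >= min_count and run_start is None:
            run_start = i
        elif c < min_count and run_start is not None:
            if i - run_start >= min_persistence:
                open_at_end = i >= len(counts)
                close = times[-1] if open_at_end else times[i]
                events.append(
                    (times[run_start], close, max(counts[run_start:i]), open_at_end)
                )
            run_start = None
    return events


class TestDensityProfile:
    def test_single_bead_lands_in_its_bin(self):
        pos = np.zeros((1, 1, 3))
        pos[0, 0] = [1.0, 1.0, 2.5]
        traj = make_traj(pos, ["FU"], box=(2.0, 2.0, 5.0))
        prof = density_profile(traj, select_beads(traj, "FU"), bin_width_nm=0.5)
        hit = (prof.bin_edges_nm[:-1] <= 2.5) & (prof.bin_edges_nm[1:] > 2.5)
        assert prof.values[hit] == pytest.approx(1.0 / (2.0 * 2.0 * 0.5))
        assert np.all(prof.values[~hit] == 0.0)

    def test_uniform_grid_gives_flat_profile(self):
        lz, n = 10.0, 100
        pos = np.zeros((1, n, 3))
        pos[0, :, 2] = (np.arange(n) + 0.5) * lz / n
        traj = make_traj(pos, ["SOLVENT"] * n, box=(4.0, 4.0, lz))
        prof = density_profile(traj, select_beads(traj, "SOLVENT"), bin_width_nm=0.5)
        np.testing.assert_allclose(prof.values, n / (4.0 * 4.0 * lz), rtol=1e-12)

    def test_matches_per_bead_counting_oracle(self, rng):
        lz, n = 6.0, 10_000
        z = np.mod(rng.normal(3.0, 0.3, size=n), lz)
        pos = np.zeros((1, n, 3))
        pos[0, :, 2] = z
        traj = make_traj(pos, ["FU"] * n, box=(5.0, 5.0, lz))
        prof = density_profile(traj, select_beads(traj, "FU"), bin_width_nm=0.1)
        edges = prof.bin_edges_nm
        oracle = np.zeros(len(edges) - 1)
        for zi in z:  # brute force: one bead at a time, half-open intervals
            k = np.searchsorted(edges, zi, side="right") - 1
            oracle[min(k, len(oracle) - 1)] += 1
        np.testing.assert_allclose(
            prof.values, oracle / (5.0 * 5.0 * np.diff(edges)), rtol=1e-12
        )

    def test_number_density_integrates_to_mean_count(self, small_bilayer):
        for tag in ("CER_HEAD", "SOLVENT", "FU"):
            sel = select_beads(small_bilayer, tag)
            prof = density_profile(small_bilayer, sel)
            lx, ly, _ = small_bilayer.boxes_nm[0]
            total = (prof.values * np.diff(prof.bin_edges_nm) * lx * ly).sum()
            assert total == pytest.approx(len(sel), rel=1e-9)

    def test_translation_equivariance_modulo_box(self, rng):
        lz, n, delta = 10.0, 500, 1.7
        z = rng.uniform(0, lz, size=n)
        pos = np.zeros((1, n, 3))
        pos[0, :, 2] = z
        traj = make_traj(pos, ["FU"] * n, box=(4.0, 4.0, lz))
        shifted = pos.copy()
        shifted[0, :, 2] = np.mod(z + delta, lz)
        traj2 = make_traj(shifted, ["FU"] * n, box=(4.0, 4.0, lz))
        p1 = density_profile(traj, select_beads(traj, "FU"), bin_width_nm=0.5)
        p2 = density_profile(traj2, select_beads(traj2, "FU"), bin_width_nm=0.5)
        # delta=1.7 is not a bin multiple: mass is conserved but redistributed
        assert p1.values.sum() == pytest.approx(p2.values.sum())
        # exact equivariance when the shift is a whole number of bins
        traj3 = make_traj(
            np.concatenate([pos[:, :, :2], np.mod(pos[:, :, 2:] + 1.5, lz)], axis=2),
            ["FU"] * n,
            box=(4.0, 4.0, lz),
        )
        p3 = density_profile(traj3, select_beads(traj3, "FU"), bin_width_nm=0.5)
        np.testing.assert_allclose(p3.values, np.roll(p1.values, 3), rtol=1e-12)

    def test_mass_mode_requires_and_uses_masses(self, small_bilayer):
        sel = select_beads(small_bilayer, "FU")
        with pytest.raises(ValidationError):
            density_profile(small_bilayer, sel, mode="mass")
        num = density_profile(small_bilayer, sel, mode="number")
        mass = density_profile(small_bilayer, sel, mode="mass", masses={"FU": 72.0})
        np.testing.assert_allclose(mass.values, 72.0 * num.values, rtol=1e-12)

    def test_bin_width_larger_than_box_rejected(self, small_bilayer):
        with pytest.raises(InputError):
            density_profile(small_bilayer, select_beads(small_bilayer, "FU"), bin_width_nm=11.0)

    def test_trailing_sliver_merged(self):
        pos = np.zeros((1, 1, 3))
        pos[0, 0, 2] = 0.5
        traj = make_traj(pos, ["FU"], box=(1.0, 1.0, 1.04))
        prof = density_profile(traj, select_beads(traj, "FU"), bin_width_nm=0.1)
        widths = np.diff(prof.bin_edges_nm)
        assert prof.bin_edges_nm[-1] == pytest.approx(1.04)
        assert widths.min() > 0.05  # no bin narrower than half a width


class TestMsdZ:
    def test_stationary_beads_have_zero_msd(self):
        pos = np.tile(np.array([[1.0, 2.0, 3.0]]), (10, 1, 1))
        traj = make_traj(pos, ["FU"])
        series = msd_z(traj, select_beads(traj, "FU"))
        assert np.all(series.msd_nm2 == 0.0)

    def test_ballistic_closed_form(self):
        f = 20
        pos = np.zeros((f, 1, 3))
        t = 0.1 * np.arange(f)
        pos[:, 0, 2] = 0.1 * t
        traj = make_traj(pos, ["FU"])
        series = msd_z(traj, select_beads(traj, "FU"))
        np.testing.assert_allclose(series.msd_nm2, 0.01 * t**2, atol=1e-15)

    def test_invariant_to_global_z_translation(self, small_bilayer):
        sel = select_beads(small_bilayer, "FU")
        shifted = small_bilayer.copy()
        shifted.positions_nm[:, :, 2] += 123.4
        m1 = msd_z(small_bilayer, sel)
        m2 = msd_z(shifted, select_beads(shifted, "FU"))
        np.testing.assert_allclose(m1.msd_nm2, m2.msd_nm2, atol=1e-8)

    def test_single_frame_rejected(self):
        traj = make_traj(np.zeros((1, 1, 3)), ["FU"])
        with pytest.raises(InputError):
            msd_z(traj, select_beads(traj, "FU"))

    def test_multiple_origin_agrees_with_direct_double_loop(self, rng):
        f, n = 40, 3
        pos = np.zeros((f, n, 3))
        pos[:, :, 2] = np.cumsum(rng.normal(0, 0.2, size=(f, n)), axis=0)
        traj = make_traj(pos, ["FU"] * n)
        series = msd_z(traj, select_beads(traj, "FU"), multiple_origins=True)
        z = pos[:, :, 2]
        for k in (0, 1, 5, f - 1):  # direct average over all origins
            expected = np.mean((z[k:] - z[: f - k]) ** 2)
            assert series.msd_nm2[k] == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestDiffusionCoefficient:
    def test_exact_linear_msd_paper_convention(self):
        t = np.linspace(0, 10, 50)
        est = diffusion_coefficient(MSDSeries(t, 4 * 0.37 * t), convention="paper")
        assert est.d_nm2_ns == pytest.approx(0.37)

    def test_zero_msd_gives_zero(self):
        t = np.linspace(0, 10, 50)
        est = diffusion_coefficient(MSDSeries(t, np.zeros_like(t)), convention="paper")
        assert est.d_nm2_ns == 0.0

    def test_paper_is_exactly_half_physical(self, rng):
        t = np.linspace(0, 10, 50)
        msd = 2 * 0.1 * t + rng.normal(0, 0.01, size=t.shape)
        series = MSDSeries(t, msd)
        paper = diffusion_coefficient(series, convention="paper")
        phys = diffusion_coefficient(series, convention="physical_1d")
        assert paper.d_nm2_ns == phys.d_nm2_ns / 2.0

    def test_default_window_is_second_half(self):
        t = np.linspace(0, 10, 11)
        est = diffusion_coefficient(MSDSeries(t, 2 * t))
        assert est.fit_window_ns == (5.0, 10.0)

    def test_unit_conversion_to_cm2_s(self):
        t = np.linspace(0, 10, 11)
        est = diffusion_coefficient(MSDSeries(t, 4 * t), convention="paper")
        assert est.d_cm2_s == pytest.approx(1.0 * NM2_PER_NS_TO_CM2_PER_S)

    def test_degenerate_window_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(InputError):
            diffusion_coefficient(MSDSeries(t, 2 * t), fit_window_ns=(20.0, 30.0))

    def test_unknown_convention_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(InputError):
            diffusion_coefficient(MSDSeries(t, 2 * t), convention="3d")


class TestPoreOccupancy:
    def _traj_with_midplane_visits(self, visit_frames, n_heads=5, f=120):
        pos = np.zeros((f, n_heads + 2, 3))
        pos[:, :n_heads, 2] = 8.0  # heads far from midplane (Lz/2 = 5)
        pos[visit_frames, :n_heads, 2] = 5.0
        pos[:, n_heads:, 2] = 5.0  # tails define the midplane
        species = ["CER_HEAD"] * n_heads + ["CER_TAIL"] * 2
        return make_traj(pos, species)

    def test_no_visits_means_all_zero(self):
        traj = self._traj_with_midplane_visits(np.array([], dtype=int))
        occ = pore_occupancy_series(traj, select_beads(traj, "CER_HEAD"))
        assert np.all(occ.counts == 0)

    def test_constructed_visit_window_counts(self):
        frames = np.arange(50, 81)
        traj = self._traj_with_midplane_visits(frames)
        occ = pore_occupancy_series(traj, select_beads(traj, "CER_HEAD"))
        assert np.all(occ.counts[frames] == 5)
        mask = np.ones(120, dtype=bool)
        mask[frames] = False
        assert np.all(occ.counts[mask] == 0)

    def test_degenerate_slab_counts_everything(self):
        traj = self._traj_with_midplane_visits(np.array([], dtype=int))
        occ = pore_occupancy_series(
            traj, select_beads(traj, "CER_HEAD"), slab_half_width_nm=5.0
        )
        assert np.all(occ.counts == 5)

    def test_nonpositive_slab_rejected(self):
        traj = self._traj_with_midplane_visits(np.array([], dtype=int))
        with pytest.raises(InputError):
            pore_occupancy_series(traj, select_beads(traj, "CER_HEAD"), slab_half_width_nm=0.0)


class TestDetectPores:
    def _occ(self, counts, dt=0.1):
        counts = np.asarray(counts)
        return OccupancySeries(np.arange(len(counts)) * dt, counts, 0.5)

    def test_all_zero_occupancy_yields_no_events(self):
        assert detect_pores(self._occ(np.zeros(50, dtype=int))) == []

    def test_isolated_frame_filtered_by_persistence(self):
        counts = np.zeros(50, dtype=int)
        counts[10] = 7
        assert detect_pores(self._occ(counts), min_count=3, min_persistence_frames=2) == []

    def test_constructed_event_times_and_duration(self):
        counts = np.zeros(120, dtype=int)
        counts[50:81] = 5
        events = detect_pores(self._occ(counts), min_count=3, min_persistence_frames=2)
        assert len(events) == 1
        ev = events[0]
        assert ev.open_ns == pytest.approx(5.0)
        assert ev.close_ns == pytest.approx(8.1)
        assert ev.duration_ns == pytest.approx(3.1)
        assert ev.max_occupancy == 5
        assert not ev.open_at_end

    def test_event_open_at_trajectory_end_is_flagged(self):
        counts = np.zeros(20, dtype=int)
        counts[15:] = 4
        events = detect_pores(self._occ(counts))
        assert len(events) == 1
        assert events[0].open_at_end
        assert events[0].close_ns == pytest.approx(1.9)

    @given(
        counts=st.lists(st.integers(0, 6), min_size=1, max_size=200),
        min_count=st.integers(1, 5),
        min_persistence=st.integers(1, 4),
    )
    @settings(deadline=None, derandomize=True, max_examples=300)
    def test_property_matches_rle_oracle(self, counts, min_count, min_persistence):
        counts = np.asarray(counts)
        times = np.arange(len(counts)) * 0.1
        events = detect_pores(self._occ(counts), min_count, min_persistence)
        oracle = rle_pore_oracle(counts, times, min_count, min_persistence)
        assert len(events) == len(oracle)
        for ev, (o, c, mx, at_end) in zip(events, oracle):
            assert ev.open_ns == pytest.approx(o)
            assert ev.close_ns == pytest.approx(c)
            assert ev.max_occupancy == mx
            assert ev.open_at_end == at_end
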