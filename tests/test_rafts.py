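"""Raft segmentation, size estimators and the component-label oracle."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

import raftsim as rs
from raftsim.rafts import CHORD_TO_DIAMETER

from .conftest import disc_mask


class TestRaftMask:
    def test_tau_zero_empty(self):
        mob = np.random.default_rng(0).random((20, 20))
        assert not rs.raft_mask(mob, 0.0).mask.any()

    def test_tau_above_one_full(self):
        mob = np.random.default_rng(0).random((20, 20))
        assert rs.raft_mask(mob, 1.1).mask.all()

    def test_low_mobility_block_recovered(self):
        mob = np.full((40, 40), 0.5)
        mob[5:15, 20:30] = 0.0
        mask = rs.raft_mask(mob, 0.1).mask
        expected = np.zeros((40, 40), dtype=bool)
        expected[5:15, 20:30] = True
        assert np.array_equal(mask, expected)

    @hyp_settings(max_examples=25, deadline=None)
    @given(taus=st.tuples(st.floats(0, 1), st.floats(0, 1)))
    def test_area_monotone_in_tau(self, taus):
        mob = np.random.default_rng(1).random((30, 30))
        lo, hi = sorted(taus)
        assert rs.raft_mask(mob, lo).mask.sum() <= rs.raft_mask(mob, hi).mask.sum()


class TestRowScan:
    def test_full_mask_rows(self):
        mean, sd, runs = rs.raft_size_rowscan(np.ones((200, 200), dtype=bool))
        assert mean == 200.0
        assert sd == 0.0
        assert len(runs) == 200

    def test_single_square(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 10:20] = True
        mean, sd, runs = rs.raft_size_rowscan(mask)
        assert mean == 10.0
        assert sd == 0.0
        assert len(runs) == 10

    def test_empty_mask(self):
        mean, sd, runs = rs.raft_size_rowscan(np.zeros((10, 10), dtype=bool))
        assert mean == 0.0
        assert runs.size == 0

    def test_periodic_wrap_merged(self):
        mask = np.zeros((5, 10), dtype=bool)
        mask[2, :3] = True
        mask[2, 7:] = True  # wraps around into one run of 6
        mean, sd, runs = rs.raft_size_rowscan(mask)
        assert list(runs) == [6]

    def test_disc_mean_chord(self):
        # mean chord of a disc of radius r over uniformly spaced rows: pi*r/2
        mask = disc_mask((100, 100), (50, 50), 20)
        mean, _, _ = rs.raft_size_rowscan(mask)
        assert mean == pytest.approx(np.pi * 20 / 2, rel=0.05)


class TestRaftCount:
    def test_empty(self):
        assert rs.raft_count(np.zeros((10, 10), dtype=bool), 0.0) == 0

    def test_single_disc_with_and_without_correction(self):
        mask = disc_mask((100, 100), (50, 50), 20)
        mean, _, _ = rs.raft_size_rowscan(mask)
        # raw mean-chord reading over-counts; the 4/pi correction fixes it
        assert rs.raft_count(mask, mean, chord_correction=False) == 2
        assert rs.raft_count(mask, mean, chord_correction=True) == 1

    def test_five_disjoint_discs(self):
        mask = np.zeros((120, 120), dtype=bool)
        for center in [(20, 20), (20, 70), (70, 20), (70, 70), (45, 100)]:
            mask |= disc_mask((120, 120), center, 8)
        mean, _, _ = rs.raft_size_rowscan(mask)
        count = rs.raft_count(mask, mean)
        assert abs(count - 5) <= 1

    def test_correction_factor_is_four_over_pi(self):
        assert CHORD_TO_DIAMETER == pytest.approx(4 / np.pi)


class TestLabelDomains:
    def test_single_square(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:15, 5:15] = True
        domains = rs.label_domains(mask)
        assert len(domains) == 1
        assert domains[0]["area"] == 100

    def test_checkerboard_isolated_cells(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[::2, ::2] = True  # isolated under 4-connectivity (odd spacing)
        domains = rs.label_domains(mask)
        assert len(domains) == int(mask.sum())

    def test_areas_partition_mask(self):
        rng = np.random.default_rng(4)
        mask = rng.random((40, 40)) < 0.3
        domains = rs.label_domains(mask)
        assert sum(d["area"] for d in domains) == int(mask.sum())

    def test_periodic_merge_across_seam(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0, 5:10] = True
        mask[-1, 5:10] = True  # touches across the vertical wrap
        assert len(rs.label_domains(mask)) == 1

    def test_estimator_matches_oracle_on_disc_grids(self):
        # k disjoint discs: circular-count estimator vs direct labelling
        rng = np.random.default_rng(9)
        for k, r in [(1, 25), (3, 15), (6, 10), (10, 5)]:
            n = 300
            mask = np.zeros((n, n), dtype=bool)
            placed = 0
            centers = []
            while placed < k:
                cand = rng.integers(r + 1, n - r - 1, size=2)
                if all(np.hypot(*(cand - c)) > 2 * r + 4 for c in centers):
                    mask |= disc_mask((n, n), tuple(cand), r)
                    centers.append(cand)
                    placed += 1
            mean, _, _ = rs.raft_size_rowscan(mask)
            count = rs.raft_count(mask, mean)
            assert abs(count - len(rs.label_domains(mask))) <= 1


class TestSizeHistogram:
    def test_square_all_mass_in_one_bin(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:15, 5:15] = True
        _, _, runs = rs.raft_size_rowscan(mask)
        counts, edges = rs.size_histogram(runs, bins=np.arange(0.5, 20.5))
        assert counts.sum() == len(runs)
        assert counts[9] == 10  # bin covering run length 10

    def test_empty_runs(self):
        counts, _ = rs.size_histogram(np.array([]), bins=5)
        assert counts.sum() == 0

    def test_disc_support_bounded_by_diameter(self):
        mask = disc_mask((100, 100), (50, 50), 20)
        _, _, runs = rs.raft_size_rowscan(mask)
        assert runs.min() >= 1
        assert runs.max() <= 40


class TestDomainComposition:
    def test_full_mask_rejected(self, control_composition):
        grid = rs.initialize_lattice(control_composition, (20, 20), seed=0)
        with pytest.raises(rs.EmptyRegionError):
            rs.domain_composition(grid, np.ones((20, 20), dtype=bool))

    def test_empty_mask_rejected(self, control_composition):
        grid = rs.initialize_lattice(control_composition, (20, 20), seed=0)
        with pytest.raises(rs.EmptyRegionError):
            rs.domain_composition(grid, np.zeros((20, 20), dtype=bool))

    def test_both_sides_sum_to_100(self, control_composition):
        grid = rs.initialize_lattice(control_composition, (20, 20), seed=0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10] = True
        inside, outside = rs.domain_composition(grid, mask)
        assert inside.percent.sum() == pytest.approx(100.0)
        assert outside.percent.sum() == pytest.approx(100.0)

    def test_halves_recombine_to_whole(self, control_composition):
        from raftsim.lattice import class_counts

        grid = rs.initialize_lattice(control_composition, (20, 20), seed=0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10] = True
        inside, outside = rs.domain_composition(grid, mask)
        whole = 100.0 * class_counts(grid) / grid.size
        assert np.allclose(0.5 * inside.percent + 0.5 * outside.percent, whole)


class TestAutoThreshold:
    def test_bimodal_map_picks_lower_mode(self):
        rng = np.random.default_rng(0)
        low = rng.normal(0.05, 0.01, size=2000).clip(0, 1)
        high = rng.normal(0.7, 0.05, size=8000).clip(0, 1)
        mob = np.concatenate([low, high]).reshape(100, 100)
        tau = rs.auto_threshold(mob)
        assert 0.0 < tau < 0.2

    def test_unimodal_falls_back_to_percentile(self):
        rng = np.random.default_rng(1)
        mob = rng.normal(0.5, 0.02, size=(50, 50)).clip(0, 1)
        tau = rs.auto_threshold(mob)
        assert tau == pytest.approx(np.percentile(mob, 10), abs=0.05)
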