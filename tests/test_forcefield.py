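"""Cylinder LVW interaction energies and force-field assembly."""

import itertools
import math

import numpy as np
import pytest

from raftsim import (
    CLASS_NAMES,
    CylinderParams,
    ForceField,
    ForceFieldError,
    InteractionSettings,
    build_force_field,
    lvw_energy,
)

from .conftest import TABLE_CYLINDERS


def direct_lvw(A, L, D, Ri, Rj):
    """Independent direct evaluation of the printed cylinder-attraction formula."""
    return A * L / (12.0 * math.sqrt(2.0) * D ** 1.5) * math.sqrt(Ri * Rj / (Ri + Rj))


@pytest.fixture()
def cylinders():
    return {k: CylinderParams(radius=r, length=l) for k, (r, l) in TABLE_CYLINDERS.items()}


@pytest.fixture()
def settings():
    return InteractionSettings(hamaker=1e-19, distance=1.50)


class TestLvwEnergy:
    def test_cholesterol_self_energy(self, settings):
        # A = 1e-19 J, L = 19.99 A, D = 1.50 A, R = 5.94 A -> ~1.10e-19 J
        chol = CylinderParams(radius=5.94, length=19.99)
        e = lvw_energy(chol, chol, settings)
        assert e == pytest.approx(1.1049888259867405e-19, rel=1e-12)
        assert e == pytest.approx(1.10e-19, rel=5e-3)

    def test_matches_direct_evaluation_all_pairs(self, cylinders, settings):
        for ni, nj in itertools.combinations_with_replacement(CLASS_NAMES, 2):
            pi, pj = cylinders[ni], cylinders[nj]
            expected = direct_lvw(
                settings.hamaker,
                0.5 * (pi.length + pj.length),
                settings.distance,
                pi.radius,
                pj.radius,
            )
            assert lvw_energy(pi, pj, settings) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_all_pairs(self, cylinders, settings):
        for ni, nj in itertools.combinations(CLASS_NAMES, 2):
            assert lvw_energy(cylinders[ni], cylinders[nj], settings) == lvw_energy(
                cylinders[nj], cylinders[ni], settings
            )

    def test_scaling_laws(self, settings):
        a = CylinderParams(radius=5.94, length=19.99)
        b = CylinderParams(radius=6.14, length=22.44)
        base = lvw_energy(a, b, settings)
        # linear in the Hamaker constant
        double_a = InteractionSettings(hamaker=2e-19, distance=1.50)
        assert lvw_energy(a, b, double_a) == pytest.approx(2 * base, rel=1e-12)
        # doubling D divides the energy by 2^(3/2)
        double_d = InteractionSettings(hamaker=1e-19, distance=3.00)
        assert base / lvw_energy(a, b, double_d) == pytest.approx(2**1.5, rel=1e-12)
        # linear in the (common) length
        a2 = CylinderParams(radius=5.94, length=2 * 19.99)
        b2 = CylinderParams(radius=6.14, length=2 * 22.44)
        assert lvw_energy(a2, b2, settings) == pytest.approx(2 * base, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [{"radius": -1.0, "length": 19.99}, {"radius": 5.94, "length": 0.0}],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ForceFieldError):
            CylinderParams(**kwargs)

    @pytest.mark.parametrize("kwargs", [{"hamaker": 0.0}, {"distance": -1.5}])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ForceFieldError):
            InteractionSettings(**kwargs)


class TestBuildForceField:
    def test_entries_match_lvw_energy(self, cylinders, settings):
        ff = build_force_field(cylinders, settings)
        for i, ni in enumerate(CLASS_NAMES):
            for j, nj in enumerate(CLASS_NAMES):
                assert ff.energy[i, j] == pytest.approx(
                    lvw_energy(cylinders[ni], cylinders[nj], settings), rel=1e-12
                )

    def test_symmetric_and_positive(self, cylinders, settings):
        ff = build_force_field(cylinders, settings)
        assert np.array_equal(ff.energy, ff.energy.T)
        assert np.all(ff.energy > 0)

    def test_max_entry_pair(self, cylinders, settings):
        # brute force over all 28 unordered pairs with the direct formula
        ff = build_force_field(cylinders, settings)
        best = max(
            itertools.combinations_with_replacement(CLASS_NAMES, 2),
            key=lambda p: direct_lvw(
                settings.hamaker,
                0.5 * (cylinders[p[0]].length + cylinders[p[1]].length),
                settings.distance,
                cylinders[p[0]].radius,
                cylinders[p[1]].radius,
            ),
        )
        i, j = CLASS_NAMES.index(best[0]), CLASS_NAMES.index(best[1])
        assert ff.energy[i, j] == ff.energy.max()

    def test_row_permutation_invariance(self, cylinders, settings):
        ff = build_force_field(cylinders, settings)
        shuffled = dict(reversed(list(cylinders.items())))
        ff2 = build_force_field(shuffled, settings)
        assert np.array_equal(ff.energy, ff2.energy)

    def test_hamaker_scales_every_entry(self, cylinders):
        ff1 = build_force_field(cylinders, InteractionSettings(hamaker=1e-19))
        ff3 = build_force_field(cylinders, InteractionSettings(hamaker=3e-19))
        assert np.allclose(ff3.energy, 3 * ff1.energy, rtol=1e-12)

    def test_missing_class_listed(self, cylinders, settings):
        incomplete = {k: v for k, v in cylinders.items() if k != "sphingolipids"}
        with pytest.raises(ForceFieldError, match="sphingolipids"):
            build_force_field(incomplete, settings)

    def test_negative_entries_rejected(self, settings):
        bad = -np.ones((7, 7))
        with pytest.raises(ForceFieldError):
            ForceField(energy=bad, settings=settings)
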