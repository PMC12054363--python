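"""Structure factors, scaling/R factors, map coefficients, density synthesis."""

import numpy as np
import pandas as pd
import pytest

import xtaldecon as xd
from xtaldecon.errors import MissingPhaseError, NoOverlapError, UnknownElementError
from xtaldecon.scatter import fcalc_complex, map_coefficients, scale_and_rfactor


@pytest.fixture
def some_hkl():
    return np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0], [1, 2, 3], [2, 1, 1], [0, 3, 2]])


def test_single_atom_at_origin_scatters_z(cube_cell, some_hkl):
    """A B=0 carbon at the origin gives F = 6 with zero phase everywhere."""
    model = xd.StructureModel(cube_cell, "P1", {"A": [xd.AtomSite("C", (0, 0, 0), b_factor=0.0)]})
    f = fcalc_complex(model, some_hkl)
    assert np.allclose(f, 6.0)


def test_translation_shift_theorem(cube_cell, some_hkl):
    """Translating the model multiplies F by a pure phase; |F| is unchanged."""
    rng = np.random.default_rng(2)
    sites = [xd.AtomSite("N", tuple(rng.random(3)), b_factor=7.0) for _ in range(5)]
    model = xd.StructureModel(cube_cell, "P1", {"A": sites})
    v = np.array([0.11, 0.07, 0.31])
    shifted = xd.StructureModel(
        cube_cell,
        "P1",
        {"A": [xd.AtomSite("N", tuple(np.array(s.position) + v), b_factor=7.0) for s in sites]},
    )
    f0 = fcalc_complex(model, some_hkl)
    f1 = fcalc_complex(shifted, some_hkl)
    expected = f0 * np.exp(2j * np.pi * some_hkl @ v)
    assert np.allclose(f1, expected)
    assert np.allclose(np.abs(f1), np.abs(f0))


def test_half_cell_pair_extinguishes_odd_orders(cube_cell):
    """Two identical atoms half a cell apart interfere destructively at odd h."""
    sites = [
        xd.AtomSite("C", (0.13, 0.2, 0.3), b_factor=0.0),
        xd.AtomSite("C", (0.63, 0.2, 0.3), b_factor=0.0),
    ]
    model = xd.StructureModel(cube_cell, "P1", {"A": sites})
    hkl = np.array([[h, 0, 0] for h in range(1, 7)])
    f = fcalc_complex(model, hkl)
    assert np.abs(f[::2]).max() < 1e-10  # h = 1, 3, 5
    assert np.abs(f[1::2]).min() > 1.0  # h = 2, 4, 6


@pytest.mark.parametrize("symbol, cell_params", [
    ("P21", (12, 9, 11, 90, 100, 90)),
    ("C2221", (14, 10, 12, 90, 90, 90)),
    ("P63", (12, 12, 10, 90, 90, 120)),
])
def test_symmetry_sum_matches_expanded_p1_oracle(symbol, cell_params):
    """fcalc with symmetry equals a plain P1 sum over the expanded model."""
    cell = xd.UnitCell(*cell_params)
    rng = np.random.default_rng(5)
    sites = [
        xd.AtomSite("O", tuple(rng.random(3) * 0.2 + 0.05), b_factor=float(3 + 5 * rng.random()))
        for _ in range(4)
    ]
    model = xd.StructureModel(cell, symbol, {"A": sites})
    expanded = xd.StructureModel(cell, "P1", {"A": xd.apply_symmetry(model)})
    refls = xd.generate_unique_hkl(cell, model.spacegroup, 3.0)
    f_sym = fcalc_complex(model, refls.hkl)
    f_p1 = fcalc_complex(expanded, refls.hkl)
    assert np.abs(f_sym - f_p1).max() / np.abs(f_sym).max() < 1e-8


def test_friedel_symmetry(ortho_cell):
    rng = np.random.default_rng(6)
    sites = [xd.AtomSite("S", tuple(rng.random(3)), b_factor=9.0) for _ in range(5)]
    model = xd.StructureModel(ortho_cell, "P1", {"A": sites})
    hkl = rng.integers(-5, 6, size=(40, 3))
    assert np.allclose(np.abs(fcalc_complex(model, hkl)), np.abs(fcalc_complex(model, -hkl)))


def test_unknown_element_rejected(cube_cell, some_hkl):
    model = xd.StructureModel(cube_cell, "P1", {"A": [xd.AtomSite("Xx", (0, 0, 0))]})
    with pytest.raises(UnknownElementError):
        fcalc_complex(model, some_hkl)


class TestScaleAndR:
    def _sets(self, cube_cell, fo, fc):
        refls = xd.generate_unique_hkl(cube_cell, xd.get_spacegroup("P1"), 3.0)
        n = len(refls)
        obs = refls.copy()
        obs.data["f_obs"] = fo[:n]
        obs.data["observed"] = True
        calc = refls.copy()
        calc.data["f_calc"] = fc[:n]
        return obs, calc

    def test_exact_scale_recovered(self, cube_cell):
        f = np.abs(np.random.default_rng(0).normal(size=1000)) + 0.1
        obs, calc = self._sets(cube_cell, 2.0 * f, f)
        res = scale_and_rfactor(obs, calc)
        assert res.scale == pytest.approx(2.0)
        assert res.r_factor == pytest.approx(0.0, abs=1e-14)

    def test_r_scale_invariance(self, cube_cell):
        rng = np.random.default_rng(1)
        fo, fc = rng.rayleigh(size=1000), rng.rayleigh(size=1000)
        obs, calc = self._sets(cube_cell, fo, fc)
        r1 = scale_and_rfactor(obs, calc).r_factor
        obs2, _ = self._sets(cube_cell, 7.3 * fo, fc)
        assert scale_and_rfactor(obs2, calc).r_factor == pytest.approx(r1)

    def test_independent_wilson_sets_reach_random_r(self):
        """Two unrelated acentric data sets give the classic random-model R.

        On a common absolute scale (k = 1) the limit is 2 - sqrt(2) ~ 0.586;
        with the least-squares scale the Monte-Carlo oracle (Rayleigh
        amplitudes, 1e5 draws) gives ~0.552. Both are checked.
        """
        rng = np.random.default_rng(42)
        fo = rng.rayleigh(size=100_000)
        fc = rng.rayleigh(size=100_000)
        assert np.abs(fo - fc).sum() / fo.sum() == pytest.approx(2 - np.sqrt(2), abs=0.01)
        cell = xd.UnitCell(50, 50, 50)
        refls = xd.generate_unique_hkl(cell, xd.get_spacegroup("P1"), 1.7)
        n = len(refls)
        assert n > 40_000
        obs = refls.copy()
        obs.data["f_obs"] = fo[:n]
        obs.data["observed"] = True
        calc = refls.copy()
        calc.data["f_calc"] = fc[:n]
        assert scale_and_rfactor(obs, calc, scale=1.0).r_factor == pytest.approx(0.586, abs=0.01)
        assert scale_and_rfactor(obs, calc).r_factor == pytest.approx(0.552, abs=0.01)

    def test_no_overlap_raises(self, cube_cell):
        refls = xd.generate_unique_hkl(cube_cell, xd.get_spacegroup("P1"), 3.0)
        calc = refls.copy()
        calc.data["f_calc"] = 1.0
        with pytest.raises(NoOverlapError):
            scale_and_rfactor(refls, calc)  # nothing observed


class TestMapCoefficients:
    def _model_and_data(self, cell, observe_mask=None, seed=0):
        rng = np.random.default_rng(seed)
        sites = [xd.AtomSite("C", tuple(rng.random(3)), b_factor=8.0) for _ in range(4)]
        model = xd.StructureModel(cell, "P1", {"A": sites})
        refls = xd.fcalc(model, xd.generate_unique_hkl(cell, model.spacegroup, 3.0))
        if observe_mask is None:
            observe_mask = np.ones(len(refls), dtype=bool)
        refls.data.loc[observe_mask, "f_obs"] = refls.data.loc[observe_mask, "f_calc"]
        refls.data["observed"] = observe_mask
        return model, refls

    def test_perfect_data_gives_fc_map_and_zero_difference(self, cube_cell):
        _, refls = self._model_and_data(cube_cell)
        coeffs = map_coefficients(refls)
        fc = refls.data["f_calc"].to_numpy() * np.exp(
            1j * np.radians(refls.data["phi_calc"].to_numpy())
        )
        assert np.allclose(coeffs.two_fo_fc, fc)
        assert np.abs(coeffs.fo_fc).max() < 1e-12

    def test_all_unmeasured_reduces_to_fc_coefficients(self, cube_cell):
        """With no observations at all, the 2Fo-Fc map is exactly the Fc map."""
        _, refls = self._model_and_data(cube_cell)
        refls.data["observed"] = False
        refls.data["f_obs"] = np.nan
        coeffs = map_coefficients(refls)
        fc = refls.data["f_calc"].to_numpy() * np.exp(
            1j * np.radians(refls.data["phi_calc"].to_numpy())
        )
        assert np.allclose(coeffs.two_fo_fc, fc)
        assert np.abs(coeffs.fo_fc).max() == 0.0

    def test_substitution_exactly_on_unmeasured_subset(self, cube_cell):
        rng = np.random.default_rng(3)
        _, refls = self._model_and_data(cube_cell)
        mask = rng.random(len(refls)) < 0.4
        refls.data["observed"] = mask
        refls.data.loc[~mask, "f_obs"] = np.nan
        coeffs = map_coefficients(refls)
        kfc = coeffs.scale * refls.data["f_calc"].to_numpy() * np.exp(
            1j * np.radians(refls.data["phi_calc"].to_numpy())
        )
        un = ~mask
        assert np.allclose(coeffs.two_fo_fc[un], kfc[un])
        assert np.abs(coeffs.fo_fc[un]).max() == 0.0
        assert (np.abs(coeffs.fo_fc[mask]) >= 0).all()

    def test_missing_phases_rejected(self, cube_cell):
        refls = xd.generate_unique_hkl(cube_cell, xd.get_spacegroup("P1"), 3.0)
        with pytest.raises(MissingPhaseError):
            map_coefficients(refls)


class TestDensity:
    def test_one_term_synthesis_closed_form(self, cube_cell):
        """A single (1,0,0) coefficient gives rho(x) = (2A/V) cos(2 pi x)."""
        refls = xd.ReflectionSet(cube_cell, xd.get_spacegroup("P1"))
        refls.data = refls.data.reindex(range(1))
        refls.data.loc[0, ["h", "k", "l", "f_calc", "phi_calc", "observed"]] = [1, 0, 0, 3.0, 0.0, False]
        refls.data["observed"] = False
        refls.data[["h", "k", "l"]] = refls.data[["h", "k", "l"]].astype(int)
        coeffs = map_coefficients(refls, scale=1.0)
        x = np.linspace(0, 1, 9, endpoint=False)
        pts = np.column_stack([x, np.zeros(9), np.zeros(9)])
        rho = xd.density_at_points(coeffs, cube_cell, pts)
        expected = (2 * 3.0 / cube_cell.volume) * np.cos(2 * np.pi * x)
        assert np.allclose(rho, expected, atol=1e-12)

    def test_linearity(self, cube_cell):
        rng = np.random.default_rng(1)
        sites = [xd.AtomSite("C", tuple(rng.random(3)), b_factor=10.0) for _ in range(3)]
        model = xd.StructureModel(cube_cell, "P1", {"A": sites})
        refls = xd.fcalc(model, xd.generate_unique_hkl(cube_cell, model.spacegroup, 3.0))
        refls.data["observed"] = False
        coeffs = map_coefficients(refls, scale=1.0)
        pts = rng.random((20, 3))
        rho = xd.density_at_points(coeffs, cube_cell, pts)
        doubled = map_coefficients(refls, scale=2.0)  # doubles every coefficient
        assert np.allclose(xd.density_at_points(doubled, cube_cell, pts), 2 * rho)

    def test_density_peaks_at_atoms(self, ortho_cell):
        """Fc-map density at atom centres beats random points almost always."""
        rng = np.random.default_rng(9)
        wins = 0
        trials = 20
        for t in range(trials):
            sites = [
                xd.AtomSite("C", tuple(rng.random(3)), b_factor=10.0) for _ in range(4)
            ]
            model = xd.StructureModel(ortho_cell, "P1", {"A": sites})
            refls = xd.fcalc(model, xd.generate_unique_hkl(ortho_cell, model.spacegroup, 2.0))
            refls.data["observed"] = False
            coeffs = map_coefficients(refls, scale=1.0)
            at_atoms = xd.density_at_points(coeffs, ortho_cell, np.array([s.position for s in sites]))
            at_random = xd.density_at_points(coeffs, ortho_cell, rng.random((50, 3)))
            wins += at_atoms.min() > np.quantile(at_random, 0.95)
        assert wins >= int(0.95 * trials) - 1

    def test_sigma_level_matches_parseval(self, cube_cell):
        """Grid rms agrees with the Parseval closed form sqrt(sum|F|^2)/V."""
        rng = np.random.default_rng(4)
        sites = [xd.AtomSite("C", tuple(rng.random(3)), b_factor=12.0) for _ in range(3)]
        model = xd.StructureModel(cube_cell, "P1", {"A": sites})
        refls = xd.fcalc(model, xd.generate_unique_hkl(cube_cell, model.spacegroup, 3.5))
        refls.data["observed"] = False
        coeffs = map_coefficients(refls, scale=1.0)
        from xtaldecon.scatter import _expand_coefficients

        _, expanded = _expand_coefficients(coeffs, "2fofc")
        parseval = np.sqrt((np.abs(expanded) ** 2).sum()) / cube_cell.volume
        assert coeffs.sigma_level("2fofc", grid=32) == pytest.approx(parseval, rel=1e-10)
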