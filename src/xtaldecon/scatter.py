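"""Direct-summation structure factors, scaling/R factors, map coefficients.

The structure-factor sum is

    F(h) = Σ_sym Σ_atoms occ · f_elem · exp(−B s²/4) · exp(2πi h·(Rx + t)),

with s = 1/d and point-atom form factors f_elem equal to the atomic number.
Point atoms keep every identity in this package exact (the supercell
deconvolution theorem is form-factor independent); resolution-dependent
Gaussian form factors are an extension point.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .cell import UnitCell
from .errors import (
    MissingPhaseError,
    NoOverlapError,
    UnknownElementError,
)
from .reflections import ReflectionSet, canonical_hkl

__all__ = [
    "fcalc",
    "scale_and_rfactor",
    "ScaleResult",
    "MapCoefficientSet",
    "map_coefficients",
    "density_at_points",
]


def scattering_power(element: str) -> float:
    """Point-atom form factor: the atomic number of the element."""
    el = gemmi.Element(element.strip())
    if el.atomic_number == 0:
        raise UnknownElementError(f"unknown element symbol {element!r}")
    return float(el.atomic_number)


def fcalc_complex(model, hkl: np.ndarray) -> np.ndarray:
    """Complex structure factors of ``model`` at integer indices ``hkl``."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    sites = model.all_sites()
    cell: UnitCell = model.cell
    sg = model.spacegroup
    f = np.zeros(len(hkl), dtype=complex)
    if not sites:
        return f
    x = np.array([s.position for s in sites])
    w = np.array([s.occupancy * scattering_power(s.element) for s in sites])
    b = np.array([s.b_factor for s in sites])
    s2 = np.einsum("ni,ij,nj->n", hkl.astype(float), cell.reciprocal_metric_tensor, hkl.astype(float))
    debye = np.exp(-np.outer(s2 / 4.0, b))  # (N_refl, N_atoms)
    for op in sg.operations:
        y = x @ op.rot_array.T.astype(float) + op.tran_array
        phase = hkl.astype(float) @ y.T
        f += ((np.exp(2j * np.pi * phase) * debye) * w).sum(axis=1)
    cen = sg.centring_vectors()
    f *= np.exp(2j * np.pi * hkl.astype(float) @ cen.T).sum(axis=1)
    return f


def fcalc(model, hkls: ReflectionSet) -> ReflectionSet:
    """Fill ``f_calc`` and ``phi_calc`` (degrees) of a reflection set."""
    out = hkls.copy()
    f = fcalc_complex(model, out.hkl)
    out.data["f_calc"] = np.abs(f)
    out.data["phi_calc"] = np.degrees(np.angle(f))
    return out


@dataclass(frozen=True)
class ScaleResult:
    """Least-squares scale k and conventional R factor on the compared set.

    R = Σ| |Fo| − k·|Fc| | / Σ|Fo|; zero iff the scaled amplitudes agree
    everywhere.
    """

    scale: float
    r_factor: float
    n_common: int


def scale_and_rfactor(obs: ReflectionSet, calc: ReflectionSet, scale: float | None = None) -> ScaleResult:
    """Scale calculated to observed amplitudes and compute R.

    The comparison runs over the intersection of observed indices carrying
    f_obs and calculated indices carrying f_calc (canonical reduction applied
    to both); by default k = Σ|Fo||Fc| / Σ|Fc|² (least squares), or pass a
    fixed ``scale``. Note the classic random-model limit R = 2 − √2 ≈ 0.586
    between independent acentric sets refers to amplitudes on a common
    absolute scale (k = 1); with the least-squares k the limit is ≈ 0.552.
    """
    left = pd.DataFrame(canonical_hkl(obs.hkl, obs.spacegroup), columns=["h", "k", "l"])
    left["f_obs"] = obs.data["f_obs"].to_numpy(float)
    left = left[obs.data["observed"].to_numpy(bool) & ~left["f_obs"].isna()]
    right = pd.DataFrame(canonical_hkl(calc.hkl, calc.spacegroup), columns=["h", "k", "l"])
    right["f_calc"] = calc.data["f_calc"].to_numpy(float)
    right = right[~right["f_calc"].isna()]
    merged = left.merge(right, on=["h", "k", "l"], how="inner")
    if merged.empty:
        raise NoOverlapError("no common reflections between observed and calculated sets")
    fo = merged["f_obs"].to_numpy()
    fc = merged["f_calc"].to_numpy()
    if scale is not None:
        k = float(scale)
    else:
        denom = float((fc**2).sum())
        k = float((fo * fc).sum() / denom) if denom > 0 else 1.0
    r = float(np.abs(fo - k * fc).sum() / fo.sum())
    return ScaleResult(scale=k, r_factor=r, n_common=len(merged))


@dataclass
class MapCoefficientSet:
    """Complex Fourier coefficients for 2Fo−Fc- and Fo−Fc-type maps.

    For observed reflections the coefficients are (2|Fo| − k|Fc|)·exp(iφc)
    and (|Fo| − k|Fc|)·exp(iφc). For unmeasured reflections Fcalc is
    substituted: the 2Fo−Fc coefficient becomes k|Fc|·exp(iφc) and the
    difference coefficient is exactly zero, so missing observations never
    contribute to difference maps.
    """

    cell: UnitCell
    spacegroup: object
    hkl: np.ndarray
    two_fo_fc: np.ndarray  # complex
    fo_fc: np.ndarray  # complex
    observed: np.ndarray  # bool
    scale: float

    def coefficients(self, map_type: str = "2fofc") -> np.ndarray:
        if map_type in ("2fofc", "2fo-fc"):
            return self.two_fo_fc
        if map_type in ("fofc", "fo-fc"):
            return self.fo_fc
        raise ValueError(f"unknown map type {map_type!r}")

    def sigma_level(self, map_type: str = "2fofc", grid: int = 64) -> float:
        """Map σ: rms density over a uniform grid (default 64³ divisions)."""
        n = grid
        axes = [np.arange(n) / n for _ in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        total = 0.0
        mean = 0.0
        for chunk in np.array_split(pts, max(1, len(pts) // 16384)):
            rho = density_at_points(self, self.cell, chunk, map_type)
            total += float((rho**2).sum())
            mean += float(rho.sum())
        m = mean / len(pts)
        return float(np.sqrt(total / len(pts) - m * m))


def map_coefficients(refls: ReflectionSet, scale: float | None = None) -> MapCoefficientSet:
    """Map coefficients with Fcalc substitution for unmeasured reflections.

    ``scale`` defaults to the least-squares scale of f_calc to the observed
    subset (1.0 when nothing is observed).
    """
    fc = refls.data["f_calc"].to_numpy(float)
    phi = refls.data["phi_calc"].to_numpy(float)
    if np.isnan(fc).any() or np.isnan(phi).any():
        raise MissingPhaseError("f_calc and phi_calc must be present for all reflections")
    observed = refls.data["observed"].to_numpy(bool)
    fo = refls.data["f_obs"].to_numpy(float)
    if scale is None:
        if observed.any():
            sub = refls.select(observed)
            scale = scale_and_rfactor(sub, sub).scale
        else:
            scale = 1.0
    phase = np.exp(1j * np.radians(phi))
    kfc = scale * fc
    two = np.where(observed, 2.0 * np.where(observed, fo, 0.0) - kfc, kfc) * phase
    diff = np.where(observed, np.where(observed, fo, 0.0) - kfc, 0.0) * phase
    return MapCoefficientSet(
        cell=refls.cell,
        spacegroup=refls.spacegroup,
        hkl=refls.hkl.copy(),
        two_fo_fc=two,
        fo_fc=diff,
        observed=observed.copy(),
        scale=float(scale),
    )


def _expand_coefficients(coeffs: MapCoefficientSet, map_type: str):
    """Expand unique coefficients over the Laue group for Fourier synthesis.

    Uses F(h·R) = F(h)·exp(−2πi h·t) for each operation (R, t) plus the
    Friedel mate F(−h) = conj(F(h)); duplicates keep the first expansion.
    """
    sg = coeffs.spacegroup
    c = coeffs.coefficients(map_type)
    seen: dict = {}
    for i in range(len(coeffs.hkl)):
        h = coeffs.hkl[i]
        for op in sg.operations:
            h2 = h @ op.rot_array
            c2 = c[i] * np.exp(-2j * np.pi * float(h @ op.tran_array))
            for hh, cc in ((tuple(h2), c2), (tuple(-h2), np.conj(c2))):
                if hh not in seen:
                    seen[hh] = cc
    hkl = np.array(list(seen.keys()), dtype=float)
    coef = np.array(list(seen.values()), dtype=complex)
    return hkl, coef


def density_at_points(
    coeffs: MapCoefficientSet,
    cell: UnitCell,
    points: np.ndarray,
    map_type: str = "2fofc",
) -> np.ndarray:
    """Fourier synthesis ρ(x) = (1/V)·Σ_h F(h)·exp(−2πi h·x).

    The stored unique reflections are expanded over the Laue group (Friedel
    mates included), making ρ real up to roundoff; the real part is returned.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hkl, coef = _expand_coefficients(coeffs, map_type)
    if len(hkl) == 0:
        return np.zeros(len(pts))
    rho = (np.exp(-2j * np.pi * pts @ hkl.T) @ coef) / cell.volume
    return rho.real
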