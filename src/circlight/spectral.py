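"""Spectral weighting functions for the circadian phototransduction model.

The model weighs a stimulus spectral power distribution with five curves:

``Mc``      melanopsin spectral sensitivity as seen through the crystalline
            lens (the ipRGC's effective in-vivo action spectrum),
``S``       the S-cone fundamental with macular screening removed (so that
            the product ``S * mp`` appearing in the model equations
            reconstitutes the corneal S-cone fundamental),
``mp``      macular pigment transmittance,
``V``       the CIE 1924 photopic luminous efficiency function,
``Vprime``  the CIE 1951 scotopic luminous efficiency function,

plus two renormalized products used by the revised model,
``Vc = (V*mp)/max(V*mp)`` and ``Sc = (S*mp)/max(S*mp)``.

V and V' are bundled from their published 5-nm tabulations (smoothly
interpolated to 1 nm).  The S-cone, macular and lens curves are synthetic
stand-ins with the standard shapes (see the bundled files' headers and
docs/methods.md).  The melanopsin template is built analytically from the
Govardovskii vitamin-A1 photopigment nomogram filtered by lens
transmittance; the nomogram peak and a lens-density scale are tuned once so
the in-vivo curve matches the template constraints of each variant:

* ``rea`` — peak 485 nm, full width at half maximum 89 nm;
* ``cie`` — peak 490 nm, full width at half maximum 84 nm.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .errors import DomainError, TruncationError, UndefinedPeakError, ValidationError
from .grid import DEFAULT_GRID, WavelengthGrid

__all__ = [
    "SpectralFunction",
    "SpectralFunctionSet",
    "build_weighting_function",
    "build_function_set",
    "resample_function",
    "peak_wavelength",
    "fwhm",
    "govardovskii_a1",
    "melanopsin_template_params",
]

# Tabulated data cover 380-780 nm; the analytic nomogram is valid wider.
TABLE_DOMAIN = (380.0, 780.0)
NOMOGRAM_DOMAIN = (360.0, 830.0)

WEIGHTING_FUNCTION_NAMES = (
    "melanopsin_invivo",
    "scone",
    "macular_transmittance",
    "photopic",
    "scotopic",
)


@dataclass(frozen=True)
class SpectralFunction:
    """A sampled spectral curve on a wavelength grid.

    ``kind`` is "sensitivity" (peak-normalized to exactly 1) or
    "transmittance" (values in [0, 1], not renormalized).
    """

    grid: WavelengthGrid
    values: np.ndarray
    name: str
    kind: str = "sensitivity"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.n,):
            raise ValidationError(
                f"{self.name}: {v.shape[0]} values for a {self.grid.n}-point grid"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError(f"{self.name}: values must be finite and >= 0")
        if self.kind == "transmittance" and np.any(v > 1.0 + 1e-12):
            raise ValidationError(f"{self.name}: transmittance values must be <= 1")

    def integrate_against(self, spd_values: np.ndarray) -> float:
        """Rectangle-rule integral of self * spd over wavelength."""
        return self.grid.integrate(self.values * spd_values)


@dataclass(frozen=True)
class SpectralFunctionSet:
    """All weighting functions of the model on one shared grid."""

    Mc: SpectralFunction
    S: SpectralFunction
    mp: SpectralFunction
    V: SpectralFunction
    Vprime: SpectralFunction
    Vc: SpectralFunction
    Sc: SpectralFunction
    melanopsin_variant: str = "rea"

    @property
    def grid(self) -> WavelengthGrid:
        return self.Mc.grid

    def __post_init__(self) -> None:
        for fn in (self.S, self.mp, self.V, self.Vprime, self.Vc, self.Sc):
            if fn.grid != self.Mc.grid:
                raise ValidationError("all functions of a set must share one grid")


# ---------------------------------------------------------------------------
# bundled tables

_TABLE_FILES = {
    "photopic": "photopic_1924.tsv",
    "scotopic": "scotopic_1951.tsv",
    "scone_corneal": "scone_fundamental_synthetic.tsv",
    "macular_transmittance": "macular_transmittance_synthetic.tsv",
    "lens_transmittance": "lens_transmittance_synthetic.tsv",
}


@lru_cache(maxsize=None)
def _load_table(key: str) -> tuple[np.ndarray, np.ndarray]:
    fname = _TABLE_FILES[key]
    text = importlib.resources.files("circlight.data").joinpath(fname).read_text()
    rows = [
        line.split() for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def _table_on_grid(key: str, grid: WavelengthGrid) -> np.ndarray:
    wl, val = _load_table(key)
    if grid.start_nm < wl[0] - 1e-9 or grid.end_nm > wl[-1] + 1e-9:
        raise DomainError(
            f"grid {grid.start_nm}-{grid.end_nm} nm outside the {wl[0]}-{wl[-1]} nm "
            f"tabulated domain of '{key}'"
        )
    return np.interp(grid.wavelengths, wl, val)


# ---------------------------------------------------------------------------
# melanopsin template

def govardovskii_a1(lambda_max: float, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Vitamin-A1 visual pigment absorbance template (alpha + beta band).

    The standard nomogram parameterized only by the pigment's peak
    wavelength; returns relative absorbance (peak about 1 before lens
    filtering).
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lambda_max
    bb = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((lam - lmb) / bb) ** 2))
    return alpha + beta


@dataclass(frozen=True)
class MelanopsinTemplateParams:
    """Frozen tuning of the in-vivo melanopsin template for one variant."""

    lambda_max: float  # nomogram peak, nm (at the retina, pre-lens)
    lens_density_scale: float  # multiplier on the bundled lens optical density
    peak_nm: float  # resulting in-vivo peak (constraint target)
    fwhm_nm: float  # resulting in-vivo FWHM (constraint target)


# Tuned once on the default 1-nm grid so the lens-filtered nomogram meets
# each variant's (peak, FWHM) constraints; see tune_melanopsin_template().
MELANOPSIN_VARIANTS: dict[str, MelanopsinTemplateParams] = {
    "rea": MelanopsinTemplateParams(480.3384692, 0.6511486, 485.0, 89.0),
    "cie": MelanopsinTemplateParams(479.3905704, 1.5088204, 490.0, 84.0),
}


def _melanopsin_values(params: MelanopsinTemplateParams, grid: WavelengthGrid) -> np.ndarray:
    lens_t = _table_on_grid("lens_transmittance", grid)
    lens_od = -np.log10(np.clip(lens_t, 1e-12, 1.0))
    m = govardovskii_a1(params.lambda_max, grid.wavelengths) * 10.0 ** (
        -params.lens_density_scale * lens_od
    )
    return m / m.max()


def melanopsin_template_params(variant: str) -> MelanopsinTemplateParams:
    try:
        return MELANOPSIN_VARIANTS[variant]
    except KeyError:
        raise ValidationError(
            f"unknown melanopsin variant {variant!r}; expected one of "
            f"{sorted(MELANOPSIN_VARIANTS)}"
        ) from None


def tune_melanopsin_template(
    peak_target_nm: float, fwhm_target_nm: float, grid: WavelengthGrid = DEFAULT_GRID
) -> MelanopsinTemplateParams:
    """Solve for (lambda_max, lens scale) meeting an in-vivo (peak, FWHM) pair.

    Used once to derive the frozen constants in MELANOPSIN_VARIANTS; kept in
    the public API so the provenance of those constants is reproducible.
    """
    from scipy.optimize import least_squares

    lens_t = _table_on_grid("lens_transmittance", grid)
    lens_od = -np.log10(np.clip(lens_t, 1e-12, 1.0))
    wl = grid.wavelengths

    def measures(p):
        m = govardovskii_a1(p[0], wl) * 10.0 ** (-p[1] * lens_od)
        m = m / m.max()
        i = int(np.argmax(m))
        # sub-grid peak via local quadratic fit
        pk = wl[i]
        if 0 < i < len(wl) - 1:
            denom = m[i - 1] - 2 * m[i] + m[i + 1]
            if denom != 0:
                pk = wl[i] + 0.5 * grid.step_nm * (m[i - 1] - m[i + 1]) / denom
        lo = np.interp(0.5, m[: i + 1], wl[: i + 1])
        hi = np.interp(0.5, m[i:][::-1], wl[i:][::-1])
        return pk, hi - lo

    def resid(p):
        pk, width = measures(p)
        return [pk - peak_target_nm, width - fwhm_target_nm]

    sol = least_squares(resid, x0=[peak_target_nm - 5.0, 1.0], diff_step=1e-3)
    return MelanopsinTemplateParams(
        float(sol.x[0]), float(sol.x[1]), peak_target_nm, fwhm_target_nm
    )


# ---------------------------------------------------------------------------
# public builders

def _normalized(values: np.ndarray) -> np.ndarray:
    m = values.max()
    if m <= 0:
        raise ValidationError("cannot peak-normalize an all-zero function")
    return values / m


def build_weighting_function(
    name: str,
    grid: WavelengthGrid = DEFAULT_GRID,
    melanopsin_variant: str = "rea",
) -> SpectralFunction:
    """Construct one of the model's weighting functions on a grid.

    ``scone`` is the macular-free S-cone fundamental: the bundled corneal
    tabulation divided by macular pigment transmittance and renormalized,
    so that the product S*mp used by the model equations recovers the
    corneal fundamental's shape.
    """
    if grid.start_nm < NOMOGRAM_DOMAIN[0] or grid.end_nm > NOMOGRAM_DOMAIN[1]:
        raise DomainError(
            f"grid {grid.start_nm}-{grid.end_nm} nm outside the supported "
            f"{NOMOGRAM_DOMAIN[0]}-{NOMOGRAM_DOMAIN[1]} nm range"
        )
    if name == "photopic":
        return SpectralFunction(grid, _normalized(_table_on_grid("photopic", grid)), name)
    if name == "scotopic":
        return SpectralFunction(grid, _normalized(_table_on_grid("scotopic", grid)), name)
    if name == "macular_transmittance":
        return SpectralFunction(
            grid, _table_on_grid("macular_transmittance", grid), name, kind="transmittance"
        )
    if name == "scone":
        corneal = _table_on_grid("scone_corneal", grid)
        mp = _table_on_grid("macular_transmittance", grid)
        return SpectralFunction(grid, _normalized(corneal / mp), name)
    if name == "melanopsin_invivo":
        params = melanopsin_template_params(melanopsin_variant)
        return SpectralFunction(
            grid, _melanopsin_values(params, grid), f"{name}_{melanopsin_variant}"
        )
    raise ValidationError(
        f"unknown weighting function {name!r}; expected one of {WEIGHTING_FUNCTION_NAMES}"
    )


@lru_cache(maxsize=8)
def _build_function_set_cached(grid: WavelengthGrid, variant: str) -> SpectralFunctionSet:
    Mc = build_weighting_function("melanopsin_invivo", grid, variant)
    S = build_weighting_function("scone", grid)
    mp = build_weighting_function("macular_transmittance", grid)
    V = build_weighting_function("photopic", grid)
    Vp = build_weighting_function("scotopic", grid)
    Vc = SpectralFunction(grid, _normalized(V.values * mp.values), "Vc")
    Sc = SpectralFunction(grid, _normalized(S.values * mp.values), "Sc")
    return SpectralFunctionSet(Mc, S, mp, V, Vp, Vc, Sc, melanopsin_variant=variant)


def build_function_set(
    grid: WavelengthGrid = DEFAULT_GRID, melanopsin_variant: str = "rea"
) -> SpectralFunctionSet:
    """Build all seven weighting functions on one shared grid (cached)."""
    melanopsin_template_params(melanopsin_variant)  # validate early
    return _build_function_set_cached(grid, melanopsin_variant)


def resample_function(fn: SpectralFunction, grid: WavelengthGrid) -> SpectralFunction:
    """Linear interpolation of a function onto a target grid.

    Sensitivity functions are re-normalized to peak 1 after interpolation.
    Extrapolation outside the source grid is refused.
    """
    src = fn.grid
    if not src.contains(grid):
        raise DomainError(
            f"target grid {grid.start_nm}-{grid.end_nm} nm extends outside the source "
            f"domain {src.start_nm}-{src.end_nm} nm"
        )
    vals = np.interp(grid.wavelengths, src.wavelengths, fn.values)
    if fn.kind == "sensitivity":
        vals = _normalized(vals)
    return SpectralFunction(grid, vals, fn.name, kind=fn.kind)


def peak_wavelength(fn: SpectralFunction) -> float:
    """Wavelength of maximum value; ties break toward the shorter wavelength."""
    if fn.values.max() <= 0:
        raise UndefinedPeakError(f"{fn.name}: all-zero function has no peak")
    return float(fn.grid.wavelengths[int(np.argmax(fn.values))])


def fwhm(fn: SpectralFunction) -> float:
    """Full width at half maximum, with linear interpolation between samples.

    Requires the function to cross half maximum on both sides of its peak
    within the grid; raises TruncationError naming the missing side.
    """
    v = fn.values
    if v.max() <= 0:
        raise UndefinedPeakError(f"{fn.name}: all-zero function has no half-maximum")
    half = v.max() / 2.0
    wl = fn.grid.wavelengths
    i = int(np.argmax(v))
    if v[: i + 1].min() > half:
        raise TruncationError("short")
    if v[i:].min() > half:
        raise TruncationError("long")
    # monotone bracketing from the peak outward
    lo = np.interp(half, v[: i + 1], wl[: i + 1])
    hi = np.interp(half, v[i:][::-1], wl[i:][::-1])
    return float(hi - lo)
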