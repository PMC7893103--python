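"""Spectral power distributions: I/O, generators, and photometry.

An :class:`SPD` holds corneal spectral irradiance in W·m⁻²·nm⁻¹ on a
wavelength grid.  The toolkit treats all input as corneal irradiance with a
cosine-corrected detector; no pupil correction is applied.

Photometric constants follow standard practice: maximum luminous efficacy
683 lm·W⁻¹ (photopic, at 555 nm) and 1700 lm·W⁻¹ (scotopic, at 507 nm).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import GridError, SPDFormatError, UnscalableError, ValidationError
from .grid import DEFAULT_GRID, WavelengthGrid, require_same_grid
from .spectral import SpectralFunctionSet

__all__ = [
    "SPD",
    "PhotometricSummary",
    "read_spd",
    "write_spd",
    "illuminance",
    "total_irradiance",
    "photometric_summary",
    "scale_spd_to",
    "photon_irradiance_convert",
    "generate_spd",
]

KM_PHOTOPIC = 683.0  # lm/W at 555 nm
KM_SCOTOPIC = 1700.0  # lm/W at 507 nm
PLANCK_C2 = 1.4388e-2  # m K, second radiation constant used for Illuminant A
HC = 6.62607015e-34 * 2.99792458e8  # J m

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SPD:
    """A sampled spectral irradiance distribution (W·m⁻²·nm⁻¹)."""

    grid: WavelengthGrid
    values: np.ndarray
    label: str = "spd"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.n,):
            raise ValidationError(
                f"{self.label}: {v.shape[0]} values for a {self.grid.n}-point grid"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{self.label}: spectral irradiance must be finite")
        if np.any(v < 0):
            raise ValidationError(f"{self.label}: spectral irradiance must be >= 0")

    def scaled(self, factor: float) -> "SPD":
        return replace(self, values=self.values * factor)


@dataclass(frozen=True)
class PhotometricSummary:
    photopic_lux: float
    scotopic_lux: float
    total_irradiance: float


# ---------------------------------------------------------------------------
# I/O

def read_spd(
    source: TextIO | str,
    grid: WavelengthGrid = DEFAULT_GRID,
    label: str = "spd",
    dialect: str = "two_column",
) -> SPD:
    """Read a two-column (wavelength_nm, W·m⁻²·nm⁻¹) text stream.

    '#' lines are comments; one non-numeric header row is tolerated.
    The SPD is linearly interpolated onto ``grid`` and set to zero outside
    the supplied wavelength range.
    """
    if dialect != "two_column":
        raise ValidationError(f"unknown SPD dialect {dialect!r}")
    if isinstance(source, str):
        source = io.StringIO(source)
    wl: list[float] = []
    vals: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise SPDFormatError("expected two columns", line=lineno)
        try:
            w, v = float(parts[0]), float(parts[1])
        except ValueError:
            if not header_seen and not wl:
                header_seen = True
                continue
            raise SPDFormatError(f"non-numeric row {parts[:2]}", line=lineno) from None
        if wl and w <= wl[-1]:
            raise SPDFormatError(
                f"wavelengths must be strictly ascending ({wl[-1]} then {w})", line=lineno
            )
        if v < 0:
            raise ValidationError(f"line {lineno}: negative spectral irradiance {v}")
        wl.append(w)
        vals.append(v)
    if len(wl) < 2:
        raise SPDFormatError(f"need at least 2 data rows, found {len(wl)}")
    values = np.interp(grid.wavelengths, wl, vals, left=0.0, right=0.0)
    return SPD(grid, values, label=label)


def write_spd(spd: SPD, stream: TextIO, comment: str | None = None) -> None:
    """Write an SPD as two-column text with 6 significant digits."""
    if comment:
        for line in comment.strip().splitlines():
            stream.write(f"# {line}\n")
    stream.write("# wavelength_nm\tspectral_irradiance_W_m2_nm\n")
    for w, v in zip(spd.grid.wavelengths, spd.values):
        stream.write(f"{w:g}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# photometry

def illuminance(spd: SPD, system: str, fns: SpectralFunctionSet) -> float:
    """Photopic or scotopic illuminance (lx) of an SPD."""
    require_same_grid(spd.grid, fns.grid)
    if system == "photopic":
        return KM_PHOTOPIC * fns.V.integrate_against(spd.values)
    if system == "scotopic":
        return KM_SCOTOPIC * fns.Vprime.integrate_against(spd.values)
    raise ValidationError(f"unknown photometric system {system!r}")


def total_irradiance(spd: SPD) -> float:
    """Total irradiance (W·m⁻²) — the integral of the SPD over wavelength."""
    return spd.grid.integrate(spd.values)


def photometric_summary(spd: SPD, fns: SpectralFunctionSet) -> PhotometricSummary:
    return PhotometricSummary(
        photopic_lux=illuminance(spd, "photopic", fns),
        scotopic_lux=illuminance(spd, "scotopic", fns),
        total_irradiance=total_irradiance(spd),
    )


def _measure(spd: SPD, quantity: str, fns: SpectralFunctionSet | None) -> float:
    if quantity == "total_irradiance":
        return total_irradiance(spd)
    if quantity in ("photopic_lux", "scotopic_lux"):
        if fns is None:
            raise ValidationError(f"{quantity} scaling requires a SpectralFunctionSet")
        return illuminance(spd, quantity.split("_")[0], fns)
    raise ValidationError(f"unknown quantity {quantity!r}")


def scale_spd_to(
    spd: SPD,
    quantity: str,
    target: float,
    fns: SpectralFunctionSet | None = None,
) -> SPD:
    """Scale an SPD by one scalar so ``quantity`` equals ``target``."""
    if target < 0:
        raise ValidationError(f"target {quantity} must be >= 0, got {target}")
    current = _measure(spd, quantity, fns)
    if current <= 0:
        raise UnscalableError(f"{spd.label}: current {quantity} is zero; cannot scale")
    return spd.scaled(target / current)


def photon_irradiance_convert(wavelength_nm: float, value: float, direction: str) -> float:
    """Convert between photon rate density (photons·cm⁻²·s⁻¹) and W·m⁻².

    Uses the photon energy hc/λ and the 10⁴ cm²→m² area factor; the two
    directions are exact mutual inverses.
    """
    if wavelength_nm <= 0:
        raise ValidationError(f"wavelength must be > 0 nm, got {wavelength_nm}")
    if value < 0:
        raise ValidationError(f"value must be >= 0, got {value}")
    e_photon = HC / (wavelength_nm * 1e-9)  # J per photon
    if direction == "photons_to_watts":
        return value * e_photon * 1e4
    if direction == "watts_to_photons":
        return value / (e_photon * 1e4)
    raise ValidationError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# generators

def _planck_relative(grid: WavelengthGrid, temperature_k: float) -> np.ndarray:
    """Planckian spectral exitance, normalized to 100 at 560 nm."""
    lam_m = grid.wavelengths * 1e-9
    m = lam_m**-5.0 / (np.exp(PLANCK_C2 / (lam_m * temperature_k)) - 1.0)
    ref = np.interp(560.0, grid.wavelengths, m)
    return 100.0 * m / ref


def _gaussian(grid: WavelengthGrid, center_nm: float, fwhm_nm: float) -> np.ndarray:
    sigma = fwhm_nm * FWHM_TO_SIGMA
    return np.exp(-((grid.wavelengths - center_nm) ** 2) / (2.0 * sigma**2))


def generate_spd(
    kind: str,
    params: dict | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> SPD:
    """Generate a standard stimulus SPD.

    kinds and their params:

    * ``illuminant_a``: Planckian radiator at 2856 K (c2 = 1.4388e-2 m·K),
      relative value 100 at 560 nm; optional ``total_irradiance`` rescales.
    * ``blackbody``: ``temperature_k`` (> 0), optional ``total_irradiance``;
      normalized like illuminant_a.
    * ``narrowband``: Gaussian line at ``center_nm`` with ``fwhm_nm``
      (default 10 nm) whose integral is ``total_irradiance`` (default 1).
    * ``led_composite``: ``components`` = list of (center_nm, fwhm_nm,
      weight); optional ``notch`` = (center_nm, width_nm) multiplies values
      inside the band by ``notch_depth`` (default 0.02); optional
      ``total_irradiance`` (default 1).
    * ``equal_energy``: flat spectrum; optional ``total_irradiance``
      (default 1).
    """
    p = dict(params or {})

    def _finish(values: np.ndarray, label: str, default_total: float | None) -> SPD:
        spd = SPD(grid, values, label=label)
        total = p.get("total_irradiance", default_total)
        if total is not None:
            if total <= 0:
                raise ValidationError("total_irradiance must be > 0")
            spd = scale_spd_to(spd, "total_irradiance", float(total))
        return spd

    if kind == "illuminant_a":
        return _finish(_planck_relative(grid, 2856.0), "illuminant_a", None)
    if kind == "blackbody":
        t = float(p.get("temperature_k", 0.0))
        if t <= 0:
            raise ValidationError("blackbody requires temperature_k > 0")
        return _finish(_planck_relative(grid, t), f"blackbody_{t:g}K", None)
    if kind == "narrowband":
        if "center_nm" not in p:
            raise ValidationError("narrowband requires center_nm")
        center = float(p["center_nm"])
        fwhm_nm = float(p.get("fwhm_nm", 10.0))
        if fwhm_nm <= 0:
            raise ValidationError("narrowband fwhm_nm must be > 0")
        return _finish(
            _gaussian(grid, center, fwhm_nm), f"narrowband_{center:g}nm", 1.0
        )
    if kind == "led_composite":
        comps = p.get("components")
        if not comps:
            raise ValidationError("led_composite requires a nonempty components list")
        values = np.zeros(grid.n)
        for comp in comps:
            center, fwhm_nm, weight = (float(x) for x in comp)
            if fwhm_nm <= 0 or weight < 0:
                raise ValidationError(f"invalid component {comp}")
            values += weight * _gaussian(grid, center, fwhm_nm)
        notch = p.get("notch")
        if notch is not None:
            n_center, n_width = (float(x) for x in notch)
            depth = float(p.get("notch_depth", 0.02))
            if not (0 <= depth <= 1) or n_width <= 0:
                raise ValidationError("notch needs width > 0 and 0 <= notch_depth <= 1")
            inside = np.abs(grid.wavelengths - n_center) <= n_width / 2.0
            values[inside] *= depth
        return _finish(values, "led_composite", 1.0)
    if kind == "equal_energy":
        return _finish(np.ones(grid.n), "equal_energy", 1.0)
    raise ValidationError(f"unknown SPD kind {kind!r}")
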