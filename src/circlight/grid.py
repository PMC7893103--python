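"""Uniform wavelength grids.

Every spectral object in circlight (weighting function or SPD) lives on a
:class:`WavelengthGrid` — a uniform sampling of wavelength in nm.  Spectral
integrals are evaluated trapezoidally (the rectangle rule with
half-weighted endpoints), which at the default 1-nm resolution is accurate
to well under 1% for the smooth curves involved (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridError

#: Default visible-range grid: 380-780 nm at 1 nm.
DEFAULT_START = 380.0
DEFAULT_END = 780.0
DEFAULT_STEP = 1.0


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform wavelength grid [start_nm, end_nm] with spacing step_nm."""

    start_nm: float = DEFAULT_START
    end_nm: float = DEFAULT_END
    step_nm: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        if not (self.start_nm < self.end_nm):
            raise GridError(f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})")
        if not (self.step_nm > 0):
            raise GridError(f"step_nm ({self.step_nm}) must be > 0")
        n = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise GridError(
                f"grid span {self.start_nm}-{self.end_nm} is not a whole number of "
                f"{self.step_nm}-nm steps"
            )

    @property
    def n(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """Grid wavelengths in nm, shape (n,)."""
        return self.start_nm + self.step_nm * np.arange(self.n)

    def integrate(self, values: np.ndarray) -> float:
        """Trapezoidal integral of sampled values over wavelength (per-nm units).

        Equivalent to the rectangle rule except for half-weighted endpoints,
        which removes the closed-interval bias for integrands that do not
        vanish at the grid edges.
        """
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n,):
            raise GridError(f"expected {self.n} samples on this grid, got {values.shape}")
        return float(np.trapezoid(values, dx=self.step_nm))

    def contains(self, other: "WavelengthGrid") -> bool:
        """True if the other grid's span lies within this grid's span."""
        return other.start_nm >= self.start_nm - 1e-9 and other.end_nm <= self.end_nm + 1e-9


def require_same_grid(a: WavelengthGrid, b: WavelengthGrid) -> None:
    if a != b:
        raise GridError(f"wavelength grids differ: {a} vs {b}")


DEFAULT_GRID = WavelengthGrid()
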