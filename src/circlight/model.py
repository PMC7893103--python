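"""Circadian light (CL_A) and circadian stimulus (CS) model equations.

Two generations of the circadian-light model are implemented:

* the 2005 two-state model — melanopsin plus, for "cool" spectra
  (blue-yellow opponent signal b−y > 0), a spectrally opponent S-ON term
  and a rod-driven threshold term;
* the revised model (CL_A 2.0) — adds a rod/cone interaction term to both
  branches, with separate gains on the melanopsin and opponent pathways.

Circadian light maps to the circadian stimulus CS (predicted fractional
nocturnal melatonin suppression for a 1-h exposure) through a fixed
logistic with asymptote 0.7 and half-saturation constant 355.7; exposure
duration t (h) and retinal distribution factor f enter as a product t·f·CL_A
in the same logistic, equivalent to dividing the half-saturation constant
by t·f.

Branch selection is two-state by design: b−y > 0 selects the "cool" branch;
b−y ≤ 0 (including the boundary) the "warm" branch.  Negative intermediate
results are floored at CL_A = 0 (circadian light is a stimulus magnitude),
and rod ratio terms are defined as 0 for a dark stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import UnreachableError, ValidationError
from .grid import require_same_grid
from .spd import SPD, KM_SCOTOPIC, illuminance
from .spectral import SpectralFunctionSet

__all__ = [
    "ModelParams2005",
    "ModelParams2020",
    "CSParams",
    "ExposureContext",
    "PhotometricReport",
    "opponent_by",
    "rod_term",
    "cla_2005",
    "cla_2020",
    "cs_from_cla",
    "halfsat_for_duration",
    "cs_tf",
    "cla_for_target_cs",
    "report",
]


def _require_positive(obj, names) -> None:
    for name in names:
        if not getattr(obj, name) > 0:
            raise ValidationError(f"{type(obj).__name__}.{name} must be > 0")


@dataclass(frozen=True)
class ModelParams2005:
    """Constants of the 2005 circadian-light equation."""

    k: float = 0.2616  # opponent constant
    a_by: float = 0.7  # blue-yellow opponent gain
    a_rod: float = 3.3  # rod gain
    rod_sat: float = 6.5  # W m^-2, rod saturation constant
    norm: float = 1548.0  # calibration constant (CL_A = 1000 at 1000 lx Illuminant A)

    def __post_init__(self) -> None:
        _require_positive(self, ("k", "a_by", "a_rod", "rod_sat", "norm"))


@dataclass(frozen=True)
class ModelParams2020:
    """Constants of the revised (CL_A 2.0) equation."""

    k: float = 0.2616
    a_by: float = 0.21
    a_rod1: float = 2.30  # rod gain on the melanopsin pathway
    a_rod2: float = 1.60  # rod gain on the opponent pathway
    g1: float = 1.00  # S-cone weight in the melanopsin-pathway rod denominator
    g2: float = 0.16  # S-cone weight in the opponent-pathway rod denominator
    rod_sat: float = 6.50
    norm: float = 1548.0

    def __post_init__(self) -> None:
        _require_positive(
            self, ("k", "a_by", "a_rod1", "a_rod2", "g1", "g2", "rod_sat", "norm")
        )


@dataclass(frozen=True)
class CSParams:
    """Fixed shape of the CS logistic and the duration law."""

    max_response: float = 0.7  # asymptotic fractional suppression
    half_sat: float = 355.7  # CL_A at half of the asymptote (1-h exposure)
    exponent: float = 1.1026  # logistic steepness
    duration_exponent: float = -1.0  # half_sat(t) = half_sat * t**duration_exponent

    def __post_init__(self) -> None:
        if not (0 < self.max_response <= 1):
            raise ValidationError("max_response must be in (0, 1]")
        _require_positive(self, ("half_sat", "exponent"))


VALID_F = (2.0, 1.0, 0.5)


@dataclass(frozen=True)
class ExposureContext:
    """Exposure duration t (hours) and retinal distribution factor f.

    f = 2.0 full field (Ganzfeld), 1.0 central field, 0.5 superior field.
    Values outside the modeled ranges are accepted with a warning.
    """

    t: float = 1.0
    f: float = 1.0

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValidationError(f"exposure duration t must be > 0 h, got {self.t}")
        if not self.f > 0:
            raise ValidationError(f"distribution factor f must be > 0, got {self.f}")
        if not (0.5 <= self.t <= 3.0):
            warnings.warn(
                f"t = {self.t} h is outside the modeled 0.5-3.0 h range", stacklevel=2
            )
        if self.f not in VALID_F:
            warnings.warn(
                f"f = {self.f} is outside the modeled levels {VALID_F}", stacklevel=2
            )


@dataclass(frozen=True)
class PhotometricReport:
    """All derived quantities for one stimulus."""

    label: str
    photopic_lux: float
    scotopic_lux: float
    b_minus_y: float  # revised-model opponent value
    branch: str  # "cool" (b-y > 0) or "warm"
    cla_2005: float
    cla_2020: float
    cs: float  # 1-h CS of cla_2020
    cs_tf: float  # duration/distribution-augmented CS
    context: ExposureContext


# ---------------------------------------------------------------------------
# spectral building blocks

def opponent_by(spd: SPD, fns: SpectralFunctionSet, version: int = 2020) -> float:
    """Blue-versus-yellow opponent signal b−y of a stimulus.

    The 2005 form weighs the macular-screened S and V curves directly;
    the revised form uses their peak-renormalized versions Sc and Vc.
    Both share the opponent constant k = 0.2616.
    """
    require_same_grid(spd.grid, fns.grid)
    k = 0.2616
    if version == 2005:
        s = fns.grid.integrate(fns.S.values * fns.mp.values * spd.values)
        v = fns.grid.integrate(fns.V.values * fns.mp.values * spd.values)
    elif version == 2020:
        s = fns.Sc.integrate_against(spd.values)
        v = fns.Vc.integrate_against(spd.values)
    else:
        raise ValidationError(f"unknown model version {version!r}")
    return s - k * v


def _rod_saturation_factor(
    vprime_e: float, rod_sat: float, rod_adaptation_scotopic_lux: float | None
) -> float:
    """1 − exp(−∫V'E/RodSat), optionally evaluated at a fixed adaptation level.

    When ``rod_adaptation_scotopic_lux`` is given, the factor is computed at
    that scotopic illuminance instead of the stimulus's own rod excitation —
    the "constant adaptation" evaluation used for constant-criterion
    sensitivity derivations at a stated reference level.
    """
    if rod_adaptation_scotopic_lux is not None:
        if rod_adaptation_scotopic_lux < 0:
            raise ValidationError("rod_adaptation_scotopic_lux must be >= 0")
        vprime_e = rod_adaptation_scotopic_lux / KM_SCOTOPIC
    return 1.0 - np.exp(-vprime_e / rod_sat)


def rod_term(
    spd: SPD,
    fns: SpectralFunctionSet,
    a_rod: float,
    g: float,
    rod_sat: float,
    rod_adaptation_scotopic_lux: float | None = None,
) -> float:
    """Rod/cone interaction term of the revised model.

    a_rod · [∫V′E / (∫VcE + g·∫ScE)] · (1 − exp(−∫V′E/RodSat)); defined as
    0 for a dark stimulus (no rod signal, no suppression).
    """
    require_same_grid(spd.grid, fns.grid)
    vprime_e = fns.Vprime.integrate_against(spd.values)
    denom = fns.Vc.integrate_against(spd.values) + g * fns.Sc.integrate_against(spd.values)
    if vprime_e <= 0 or denom <= 0:
        return 0.0
    sat = _rod_saturation_factor(vprime_e, rod_sat, rod_adaptation_scotopic_lux)
    return a_rod * (vprime_e / denom) * sat


# ---------------------------------------------------------------------------
# circadian light

def cla_2005(
    spd: SPD,
    fns: SpectralFunctionSet,
    params: ModelParams2005 | None = None,
    rod_adaptation_scotopic_lux: float | None = None,
) -> float:
    """Circadian light CL_A (2005 two-state model), floored at 0."""
    p = params or ModelParams2005()
    require_same_grid(spd.grid, fns.grid)
    mc_e = fns.Mc.integrate_against(spd.values)
    by = opponent_by(spd, fns, version=2005)
    if by > 0:
        vprime_e = fns.Vprime.integrate_against(spd.values)
        sat = (
            _rod_saturation_factor(vprime_e, p.rod_sat, rod_adaptation_scotopic_lux)
            if vprime_e > 0
            else 0.0
        )
        core = mc_e + p.a_by * by - p.a_rod * sat
    else:
        core = mc_e
    return max(0.0, p.norm * core)


def cla_2020(
    spd: SPD,
    fns: SpectralFunctionSet,
    params: ModelParams2020 | None = None,
    rod_adaptation_scotopic_lux: float | None = None,
) -> float:
    """Revised circadian light CL_A 2.0, floored at 0."""
    p = params or ModelParams2020()
    require_same_grid(spd.grid, fns.grid)
    mc_e = fns.Mc.integrate_against(spd.values)
    core = mc_e - rod_term(
        spd, fns, p.a_rod1, p.g1, p.rod_sat, rod_adaptation_scotopic_lux
    )
    by = opponent_by(spd, fns, version=2020)
    if by > 0:
        core += p.a_by * by - rod_term(
            spd, fns, p.a_rod2, p.g2, p.rod_sat, rod_adaptation_scotopic_lux
        )
    return max(0.0, p.norm * core)


# ---------------------------------------------------------------------------
# circadian stimulus

def cs_from_cla(cla: float, p: CSParams | None = None) -> float:
    """CS logistic: max_response · [1 − 1/(1 + (CL_A/half_sat)^exponent)]."""
    p = p or CSParams()
    if cla < 0:
        raise ValidationError(f"CL_A must be >= 0, got {cla}")
    if cla == 0.0:
        return 0.0
    return p.max_response * (1.0 - 1.0 / (1.0 + (cla / p.half_sat) ** p.exponent))


def halfsat_for_duration(t: float, p: CSParams | None = None) -> float:
    """Duration-adjusted half-saturation constant, half_sat · t^(−1)."""
    p = p or CSParams()
    if t <= 0:
        raise ValidationError(f"duration t must be > 0 h, got {t}")
    if not (0.5 <= t <= 3.0):
        warnings.warn(f"t = {t} h is outside the modeled 0.5-3.0 h range", stacklevel=2)
    return p.half_sat * t**p.duration_exponent


def cs_tf(cla: float, ctx: ExposureContext, p: CSParams | None = None) -> float:
    """Duration/distribution-augmented CS: the CS logistic of t·f·CL_A 2.0."""
    ctx = ctx if isinstance(ctx, ExposureContext) else ExposureContext(*ctx)
    return cs_from_cla(ctx.t * ctx.f * cla, p)


def cla_for_target_cs(
    target: float, ctx: ExposureContext | None = None, p: CSParams | None = None
) -> float:
    """Closed-form inverse of cs_tf: the CL_A 2.0 giving a target CS."""
    p = p or CSParams()
    ctx = ctx or ExposureContext()
    if target < 0:
        raise ValidationError(f"target CS must be >= 0, got {target}")
    if target >= p.max_response:
        raise UnreachableError(
            f"target CS {target} is unreachable (asymptote {p.max_response})"
        )
    if target == 0.0:
        return 0.0
    x = (target / (p.max_response - target)) ** (1.0 / p.exponent)
    return p.half_sat * x / (ctx.t * ctx.f)


def report(
    spd: SPD,
    fns: SpectralFunctionSet,
    ctx: ExposureContext | None = None,
    cs_params: CSParams | None = None,
) -> PhotometricReport:
    """Evaluate every model quantity for one stimulus."""
    ctx = ctx or ExposureContext()
    by = opponent_by(spd, fns, version=2020)
    c20 = cla_2020(spd, fns)
    return PhotometricReport(
        label=spd.label,
        photopic_lux=illuminance(spd, "photopic", fns),
        scotopic_lux=illuminance(spd, "scotopic", fns),
        b_minus_y=by,
        branch="cool" if by > 0 else "warm",
        cla_2005=cla_2005(spd, fns),
        cla_2020=c20,
        cs=cs_from_cla(c20, cs_params),
        cs_tf=cs_tf(c20, ctx, cs_params),
        context=ctx,
    )
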