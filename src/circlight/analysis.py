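"""Analysis procedures: constant-criterion sensitivity, logistic fitting,
log-abscissa alignment, the duration-exponent fit, and synthetic
suppression datasets.

The constant-criterion spectral sensitivity mirrors the classical action
spectrum procedure: for each narrowband stimulus, find the irradiance at
which the model's predicted suppression reaches a fixed criterion (0.35,
half the response asymptote); relative sensitivity is the reciprocal
criterion irradiance normalized to the most sensitive wavelength.  The
derivation is performed about a stated reference operating point
(300 scotopic lx by default): the model's rod saturation factor is held at
that level while the criterion irradiance is solved for (see
docs/methods.md for why the derivation is anchored this way).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .errors import (
    AlignmentError,
    DegenerateFitError,
    OutOfRangeError,
    ValidationError,
)
from .grid import DEFAULT_GRID
from .model import (
    CSParams,
    ExposureContext,
    ModelParams2020,
    cla_2020,
    cla_for_target_cs,
    cs_tf,
)
from .spd import SPD, generate_spd, illuminance, scale_spd_to, total_irradiance
from .spectral import SpectralFunctionSet, build_function_set

__all__ = [
    "DoseResponseCurve",
    "SensitivityCurve",
    "SuppressionDataset",
    "LogisticFit",
    "predict_suppression_curve",
    "criterion_level",
    "derive_relative_sensitivity",
    "fit_half_saturation",
    "align_log_shift",
    "fit_duration_exponent",
    "generate_synthetic_dataset",
    "simulate_dose_response",
]

DEFAULT_CRITERION = 0.35  # half of the 0.7 asymptote
DEFAULT_REFERENCE_SCOTOPIC_LUX = 300.0
DATASET_COLUMNS = ["spd_label", "level", "level_units", "t_hours", "f_factor", "suppression"]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Stimulus levels (ascending) and fractional suppression responses."""

    levels: np.ndarray
    responses: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        rs = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "responses", rs)
        if lv.ndim != 1 or lv.shape != rs.shape:
            raise ValidationError("levels and responses must be 1-D arrays of equal length")
        if lv.size and np.any(np.diff(lv) <= 0):
            raise ValidationError("levels must be strictly ascending")
        if np.any((rs < 0) | (rs > 1)):
            raise ValidationError("responses must lie in [0, 1]")


@dataclass(frozen=True)
class SensitivityCurve:
    """Relative spectral sensitivity (max exactly 1 at one wavelength)."""

    wavelengths: np.ndarray
    relative_sensitivity: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LogisticFit:
    """Result of a fixed-shape logistic fit (half-saturation only free)."""

    half_sat_estimate: float
    residual_sse: float
    r_squared: float


@dataclass(frozen=True)
class SuppressionDataset:
    """Rows of (spd_label, level, level_units, t_hours, f_factor, suppression)."""

    table: pd.DataFrame
    noise_sigma: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"dataset missing columns {missing}")
        t = self.table
        if np.any(t["suppression"] < -0.2) or np.any(t["suppression"] > 1.0):
            raise ValidationError("suppression values must lie in [-0.2, 1]")
        if np.any(t["t_hours"] <= 0) or np.any(t["f_factor"] <= 0):
            raise ValidationError("t_hours and f_factor must be > 0")
        if np.any(t["level"] < 0):
            raise ValidationError("levels must be >= 0")

    @classmethod
    def from_csv(cls, path_or_buf) -> "SuppressionDataset":
        return cls(pd.read_csv(path_or_buf, comment="#"))

    def to_csv(self, path_or_buf) -> None:
        self.table.to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# model-predicted curves and the criterion procedure

def predict_suppression_curve(
    center_nm: float,
    fwhm_nm: float,
    level_grid: Sequence[float],
    ctx: ExposureContext | None = None,
    fns: SpectralFunctionSet | None = None,
    cs_params: CSParams | None = None,
    model_params: ModelParams2020 | None = None,
) -> DoseResponseCurve:
    """Predicted CS_t,f for a narrowband stimulus over scotopic-lux levels."""
    ctx = ctx or ExposureContext()
    fns = fns or build_function_set()
    levels = np.asarray(level_grid, dtype=float)
    if levels.size and (np.any(levels <= 0) or np.any(np.diff(levels) <= 0)):
        raise ValidationError("level grid must be positive and strictly ascending")
    unit = generate_spd(
        "narrowband", {"center_nm": center_nm, "fwhm_nm": fwhm_nm}, fns.grid
    )
    slux_per_unit = illuminance(unit, "scotopic", fns)
    responses = []
    for lv in levels:
        spd = unit.scaled(lv / slux_per_unit)
        responses.append(cs_tf(cla_2020(spd, fns, model_params), ctx, cs_params))
    return DoseResponseCurve(
        levels,
        np.asarray(responses),
        meta={
            "center_nm": center_nm,
            "fwhm_nm": fwhm_nm,
            "level_units": "scotopic_lux",
            "t": ctx.t,
            "f": ctx.f,
        },
    )


def criterion_level(curve: DoseResponseCurve, criterion: float) -> float:
    """Stimulus level reaching a criterion response, interpolated in log-level.

    The curve's responses must be monotone nondecreasing (the model's CS
    curves are); the criterion must lie within the spanned response range.
    """
    lv, rs = curve.levels, curve.responses
    if lv.size < 2:
        raise ValidationError("need at least 2 curve points")
    if np.any(np.diff(rs) < 0):
        raise ValidationError("curve responses must be monotone nondecreasing")
    if criterion < rs[0]:
        raise OutOfRangeError(
            f"criterion {criterion} below the lowest response {rs[0]:.4g}", side="low"
        )
    if criterion > rs[-1]:
        raise OutOfRangeError(
            f"criterion {criterion} above the highest response {rs[-1]:.4g}", side="high"
        )
    if criterion == rs[0]:
        return float(lv[0])
    i = int(np.searchsorted(rs, criterion, side="left"))
    lo, hi = i - 1, i
    if rs[hi] == rs[lo]:
        return float(lv[hi])
    frac = (criterion - rs[lo]) / (rs[hi] - rs[lo])
    return float(10.0 ** (np.log10(lv[lo]) + frac * (np.log10(lv[hi]) - np.log10(lv[lo]))))


def _criterion_irradiance(
    center_nm: float,
    fwhm_nm: float,
    target_cla: float,
    fns: SpectralFunctionSet,
    model_params: ModelParams2020 | None,
    reference_scotopic_lux: float | None,
) -> float:
    """Total irradiance at which a narrowband stimulus reaches a target CL_A 2.0."""
    unit = generate_spd(
        "narrowband",
        {"center_nm": center_nm, "fwhm_nm": fwhm_nm, "total_irradiance": 1.0},
        fns.grid,
    )

    def gap(log10_irr: float) -> float:
        spd = unit.scaled(10.0**log10_irr)
        return (
            cla_2020(
                spd,
                fns,
                model_params,
                rod_adaptation_scotopic_lux=reference_scotopic_lux,
            )
            - target_cla
        )

    return 10.0 ** brentq(gap, -8.0, 6.0, xtol=1e-12)


def derive_relative_sensitivity(
    wavelengths: Sequence[float],
    criterion: float = DEFAULT_CRITERION,
    reference_scotopic_lux: float | None = DEFAULT_REFERENCE_SCOTOPIC_LUX,
    ctx: ExposureContext | None = None,
    fns: SpectralFunctionSet | None = None,
    fwhm_nm: float = 10.0,
    cs_params: CSParams | None = None,
    model_params: ModelParams2020 | None = None,
) -> SensitivityCurve:
    """Constant-criterion relative spectral sensitivity of the revised model.

    For each wavelength the criterion irradiance (W·m⁻²) at which the
    narrowband stimulus reaches the criterion CS_t,f is solved; sensitivity
    is its reciprocal, normalized to the most sensitive wavelength.  The rod
    saturation factor is held at ``reference_scotopic_lux`` (pass None for a
    fully self-consistent evaluation at each stimulus's own level).
    Wavelengths failing to reach criterion are excluded with a warning and
    recorded in ``meta['excluded']``.
    """
    wl = [float(w) for w in wavelengths]
    if len(wl) < 2:
        raise ValidationError("need at least 2 wavelengths")
    ctx = ctx or ExposureContext()
    fns = fns or build_function_set()
    target_cla = cla_for_target_cs(criterion, ctx, cs_params)
    crit_irr: dict[float, float] = {}
    excluded: list[float] = []
    for w in wl:
        try:
            crit_irr[w] = _criterion_irradiance(
                w, fwhm_nm, target_cla, fns, model_params, reference_scotopic_lux
            )
        except ValueError:
            warnings.warn(
                f"{w:g} nm cannot reach the criterion response; excluded", stacklevel=2
            )
            excluded.append(w)
    if not crit_irr:
        raise OutOfRangeError("no wavelength reaches the criterion response")
    best = min(crit_irr.values())
    kept = np.asarray(sorted(crit_irr), dtype=float)
    sens = np.asarray([best / crit_irr[w] for w in kept])
    return SensitivityCurve(
        kept,
        sens,
        meta={
            "criterion": criterion,
            "reference_scotopic_lux": reference_scotopic_lux,
            "fwhm_nm": fwhm_nm,
            "t": ctx.t,
            "f": ctx.f,
            "excluded": excluded,
            "criterion_irradiance_w_m2": {w: crit_irr[w] for w in kept},
        },
    )


# ---------------------------------------------------------------------------
# fitting

def _predicted_suppression(
    levels: np.ndarray, tf: np.ndarray, half_sat: float, p: CSParams
) -> np.ndarray:
    x = tf * levels / half_sat
    return p.max_response * (1.0 - 1.0 / (1.0 + x**p.exponent))


def fit_half_saturation(
    data: SuppressionDataset, p: CSParams | None = None
) -> LogisticFit:
    """Least-squares fit of the half-saturation constant alone.

    The logistic's asymptote and exponent stay fixed at their printed
    values; only the half-saturation constant is searched (log-spaced scan
    with local refinement).
    """
    p = p or CSParams()
    t = data.table
    units = set(t["level_units"])
    if units - {"cla"}:
        raise ValidationError(f"fit requires levels in CL_A units, found {units}")
    levels = t["level"].to_numpy(dtype=float)
    tf = (t["t_hours"] * t["f_factor"]).to_numpy(dtype=float)
    obs = t["suppression"].to_numpy(dtype=float)
    if len(np.unique(levels)) < 3:
        raise DegenerateFitError("need at least 3 distinct stimulus levels")
    if np.allclose(obs, obs[0]):
        raise DegenerateFitError("all responses are identical; half-saturation unidentified")

    def sse(log10_hs: float) -> float:
        pred = _predicted_suppression(levels, tf, 10.0**log10_hs, p)
        return float(np.sum((obs - pred) ** 2))

    scan = np.linspace(-2.0, 7.0, 181)
    best = scan[int(np.argmin([sse(x) for x in scan]))]
    res = minimize_scalar(sse, bounds=(best - 0.2, best + 0.2), method="bounded",
                          options={"xatol": 1e-10})
    hs = float(10.0**res.x)
    resid = float(res.fun)
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - resid / sstot if sstot > 0 else float("nan")
    return LogisticFit(half_sat_estimate=hs, residual_sse=resid, r_squared=r2)


def align_log_shift(curve_a: DoseResponseCurve, curve_b: DoseResponseCurve) -> float:
    """log10 shift of curve_b's levels that best aligns it to curve_a.

    Minimizes the squared response difference after translating curve_b
    along the log-level abscissa (responses compared by interpolation on
    the overlapping range).  A negative shift moves curve_b toward lower
    levels.
    """
    if (
        curve_a.responses.max() < curve_b.responses.min()
        or curve_b.responses.max() < curve_a.responses.min()
    ):
        raise AlignmentError("curves share no overlapping response range")
    la = np.log10(curve_a.levels)
    lb = np.log10(curve_b.levels)

    def sse(shift: float) -> float:
        lo = max(la.min(), lb.min() + shift)
        hi = min(la.max(), lb.max() + shift)
        if hi <= lo:
            return 1e6 + abs(shift)
        xs = np.linspace(lo, hi, 64)
        ra = np.interp(xs, la, curve_a.responses)
        rb = np.interp(xs, lb + shift, curve_b.responses)
        return float(np.mean((ra - rb) ** 2))

    scan = np.arange(-5.0, 5.0 + 1e-9, 0.02)
    best = scan[int(np.argmin([sse(s) for s in scan]))]
    res = minimize_scalar(
        sse, bounds=(best - 0.05, best + 0.05), method="bounded", options={"xatol": 1e-8}
    )
    shift = float(res.x)
    if sse(shift) > sse(0.0) + 1e-15:
        return 0.0
    return shift


def fit_duration_exponent(
    pairs: Iterable[tuple[float, float]], fix_coefficient: bool = True,
    p: CSParams | None = None,
) -> tuple[float, float]:
    """Fit the exponent of half_sat(t) = coefficient · t^exponent in log-log space.

    With ``fix_coefficient`` the coefficient is pinned to the 1-h
    half-saturation constant (355.7) and only the exponent is estimated;
    otherwise both are free.  Returns (exponent, r_squared).
    """
    p = p or CSParams()
    pairs = [(float(t), float(h)) for t, h in pairs]
    if len(pairs) < 3:
        raise ValidationError("need at least 3 (t, half_sat) pairs")
    t = np.asarray([q[0] for q in pairs])
    h = np.asarray([q[1] for q in pairs])
    if np.any(t <= 0):
        raise ValidationError("durations must be > 0")
    if np.any(h <= 0):
        raise ValidationError("half-saturation values must be > 0")
    x = np.log10(t)
    y = np.log10(h)
    if fix_coefficient:
        y0 = y - np.log10(p.half_sat)
        if np.sum(x**2) == 0:
            raise ValidationError("all durations equal; exponent unidentified")
        expo = float(np.sum(x * y0) / np.sum(x**2))
        yhat = np.log10(p.half_sat) + expo * x
    else:
        expo_f, intercept = np.polyfit(x, y, 1)
        expo = float(expo_f)
        yhat = intercept + expo * x
    sstot = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else float("nan")
    return expo, r2


# ---------------------------------------------------------------------------
# synthetic data

def generate_synthetic_dataset(
    protocol: Sequence[dict],
    noise_sigma: float = 0.0,
    seed: int | None = None,
    fns: SpectralFunctionSet | None = None,
    cs_params: CSParams | None = None,
    model_params: ModelParams2020 | None = None,
) -> SuppressionDataset:
    """Simulated suppression measurements for a stimulus protocol.

    Each protocol row is a dict with keys ``spd`` (a generate_spd spec:
    {"kind": ..., "params": {...}}), ``level`` and ``level_units``
    (photopic_lux | scotopic_lux | total_irradiance), ``t`` and ``f``, and
    optionally ``n`` (subjects averaged into the row; the noise scales as
    noise_sigma/sqrt(n), default 1).  Responses are cs_tf(cla_2020(SPD))
    plus additive Gaussian noise, clipped to [-0.2, 1]; the recorded ``level`` column holds the computed
    CL_A 2.0 (units "cla") so the dataset feeds fit_half_saturation
    directly.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    fns = fns or build_function_set()
    rng = np.random.default_rng(seed)
    rows = []
    for i, entry in enumerate(protocol):
        try:
            spec = entry["spd"]
            spd = generate_spd(spec["kind"], spec.get("params"), fns.grid)
            level = float(entry["level"])
            units = entry.get("level_units", "total_irradiance")
            ctx = ExposureContext(float(entry.get("t", 1.0)), float(entry.get("f", 1.0)))
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"protocol row {i}: invalid spec ({exc})") from None
        spd = scale_spd_to(spd, units, level, fns)
        cla = cla_2020(spd, fns, model_params)
        resp = cs_tf(cla, ctx, cs_params)
        n = int(entry.get("n", 1))  # subjects averaged into this row
        if n < 1:
            raise ValidationError(f"protocol row {i}: n must be >= 1")
        if noise_sigma > 0:
            resp += rng.normal(0.0, noise_sigma / np.sqrt(n))
        rows.append(
            {
                "spd_label": spd.label,
                "level": cla,
                "level_units": "cla",
                "t_hours": ctx.t,
                "f_factor": ctx.f,
                "suppression": float(np.clip(resp, -0.2, 1.0)),
                "n": n,
            }
        )
    return SuppressionDataset(pd.DataFrame(rows), noise_sigma=noise_sigma, seed=seed)


def simulate_dose_response(
    levels: Sequence[float],
    half_sat: float | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    t: float = 1.0,
    f: float = 1.0,
    n_per_level: int = 8,
    p: CSParams | None = None,
) -> SuppressionDataset:
    """Noisy samples of the CS logistic at given CL_A levels.

    Emulates the structure of a suppression dose-response study: each row is
    the mean observed suppression of a panel of ``n_per_level`` subjects at
    one stimulus level, so with per-subject assay noise ``noise_sigma`` the
    recorded mean carries noise ``noise_sigma / sqrt(n_per_level)``.  Pass
    ``n_per_level=1`` for raw single observations.  A lighter-weight
    companion to generate_synthetic_dataset for exercising the fitting
    routines: responses come straight from the logistic with an optional
    alternative generating half-saturation constant.
    """
    p = p or CSParams()
    if n_per_level < 1:
        raise ValidationError("n_per_level must be >= 1")
    if half_sat is not None:
        p = CSParams(p.max_response, half_sat, p.exponent, p.duration_exponent)
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0):
        raise ValidationError("levels must be >= 0")
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctx = ExposureContext(t, f)
    resp = np.array([cs_tf(lv, ctx, p) for lv in levels])
    if noise_sigma > 0:
        resp = resp + rng.normal(
            0.0, noise_sigma / np.sqrt(n_per_level), size=resp.shape
        )
    table = pd.DataFrame(
        {
            "spd_label": "logistic_sim",
            "level": levels,
            "level_units": "cla",
            "t_hours": ctx.t,
            "f_factor": ctx.f,
            "suppression": np.clip(resp, -0.2, 1.0),
            "n": n_per_level,
        }
    )
    return SuppressionDataset(table, noise_sigma=noise_sigma, seed=seed)
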