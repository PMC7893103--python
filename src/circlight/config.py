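"""Run configuration: TOML config file plus CLI overrides.

Sections and keys:

    [model]     version = "2020" | "2005"; melanopsin_variant = "rea" | "cie";
                parameter overrides by field name (e.g. a_by = 0.25)
    [exposure]  t_hours, f_factor
    [grid]      start_nm, end_nm, step_nm
    [cs]        max_response, half_sat, exponent, duration_exponent

Unknown sections or keys are rejected.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .grid import WavelengthGrid
from .model import CSParams, ExposureContext, ModelParams2005, ModelParams2020

_MODEL_KEYS = {"version", "melanopsin_variant"}


@dataclass
class RunConfig:
    version: str = "2020"
    melanopsin_variant: str = "rea"
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    context: ExposureContext = field(default_factory=ExposureContext)
    cs_params: CSParams = field(default_factory=CSParams)
    params_2005: ModelParams2005 = field(default_factory=ModelParams2005)
    params_2020: ModelParams2020 = field(default_factory=ModelParams2020)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.version not in ("2005", "2020"):
            raise ValidationError(f"model version must be '2005' or '2020', got {self.version!r}")


def _build(cls, overrides: dict, what: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - fields
    if unknown:
        raise ValidationError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**overrides)


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Parse a TOML config file (or literal text) into a RunConfig."""
    if text is None:
        if path is None:
            return RunConfig()
        text = Path(path).read_text()
    raw = tomllib.loads(text)
    known_sections = {"model", "exposure", "grid", "cs"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")

    model = dict(raw.get("model", {}))
    version = str(model.pop("version", "2020"))
    variant = str(model.pop("melanopsin_variant", "rea"))
    # remaining [model] keys override the per-version parameter dataclass
    params_2005 = ModelParams2005()
    params_2020 = ModelParams2020()
    if model:
        if version == "2005":
            params_2005 = _build(ModelParams2005, model, "[model] parameter")
        else:
            params_2020 = _build(ModelParams2020, model, "[model] parameter")

    exposure = dict(raw.get("exposure", {}))
    ctx_kwargs = {}
    if "t_hours" in exposure:
        ctx_kwargs["t"] = float(exposure.pop("t_hours"))
    if "f_factor" in exposure:
        ctx_kwargs["f"] = float(exposure.pop("f_factor"))
    if exposure:
        raise ValidationError(f"unknown [exposure] keys: {sorted(exposure)}")

    grid_raw = dict(raw.get("grid", {}))
    grid_kwargs = {}
    for key, fieldname in (("start_nm", "start_nm"), ("end_nm", "end_nm"), ("step_nm", "step_nm")):
        if key in grid_raw:
            grid_kwargs[fieldname] = float(grid_raw.pop(key))
    if grid_raw:
        raise ValidationError(f"unknown [grid] keys: {sorted(grid_raw)}")

    cs = _build(CSParams, dict(raw.get("cs", {})), "[cs]")

    return RunConfig(
        version=version,
        melanopsin_variant=variant,
        grid=WavelengthGrid(**grid_kwargs),
        context=ExposureContext(**ctx_kwargs),
        cs_params=cs,
        params_2005=params_2005,
        params_2020=params_2020,
    )
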