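"""Run configuration: strict YAML/JSON schema with explicit pressure units.

The schema is strict (unknown keys are rejected with their field path) and
pressures may be given as a bare number in kPa or as a string with an
explicit unit (``"114 mmHg"`` or ``"15.2 kPa"``); everything is normalized
to kPa internally, preventing silent unit errors.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .units import mmhg_to_kpa

__all__ = ["RunConfig", "GeneratorConfig", "SolverSettings", "PlanConfig",
           "load_config", "parse_pressure"]


def parse_pressure(value) -> float:
    """Normalize a pressure to kPa; accepts numbers (kPa) or '<x> mmHg' /
    '<x> kPa' strings."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*(mmHg|kPa)\s*", str(value))
    if not m:
        raise ValueError(
            f"cannot parse pressure {value!r}; use a number (kPa) or e.g. '114 mmHg'"
        )
    x = float(m.group(1))
    return mmhg_to_kpa(x) if m.group(2) == "mmHg" else x


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorConfig(_Strict):
    """Overrides of the synthetic-apparatus defaults (all optional)."""

    annular_area: float | None = None
    intercommissural: float | None = None
    septal_lateral: float | None = None
    saddle_height: float | None = None
    aml_height_mid: float | None = None
    pml_height_mid: float | None = None
    p1_deficit: float | None = None
    thickness_aml: float | None = None
    thickness_pml: float | None = None
    tether_magnitudes: list[float] | None = None
    systolic_origin_motion: float | None = None
    n_circ: int | None = None
    n_rad: int | None = None
    jitter: float | None = None

    def to_params_kwargs(self) -> dict:
        d = {k: v for k, v in self.model_dump().items() if v is not None}
        if "tether_magnitudes" in d:
            d["tether_magnitudes"] = tuple(d["tether_magnitudes"])
        return d


class SolverSettings(_Strict):
    ramp_steps: int = 1600
    max_steps: int = 24000
    tol_rel: float = 0.008
    penalty: float = 800.0
    friction: str = "rough"
    viscous: float = 0.01
    strict: bool = False

    def to_solver_config(self):
        from .fe import SolverConfig

        return SolverConfig(ramp_steps=self.ramp_steps, max_steps=self.max_steps,
                            tol_rel=self.tol_rel, penalty=self.penalty,
                            friction=self.friction, viscous=self.viscous,
                            strict=self.strict)


class PlanConfig(_Strict):
    ring: str | None = None        # e.g. 'classic:38' or 'geoform:36'
    pmr: bool = False
    pmr_magnitude: float = 5.0
    closure_pressure: float | str = "114 mmHg"

    @field_validator("ring")
    @classmethod
    def _check_ring(cls, v):
        if v is None:
            return v
        fam, _, size = str(v).partition(":")
        from .rings import SUPPORTED_FAMILIES, SUPPORTED_SIZES

        if fam.lower() not in SUPPORTED_FAMILIES or not size.isdigit() \
                or int(size) not in SUPPORTED_SIZES:
            raise ValueError(
                f"ring must be '<family>:<size>' with family in "
                f"{SUPPORTED_FAMILIES} and size in {SUPPORTED_SIZES}; got {v!r}"
            )
        return v.lower()

    def to_plan(self):
        from .procedures import ProcedurePlan

        ring = None
        if self.ring:
            fam, _, size = self.ring.partition(":")
            ring = (fam, int(size))
        return ProcedurePlan(ring=ring, pmr=self.pmr,
                             pmr_magnitude=self.pmr_magnitude,
                             closure_pressure_kpa=parse_pressure(self.closure_pressure))


class RunConfig(_Strict):
    """Top-level configuration of a pipeline run."""

    seed: int = 0
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    plans: list[PlanConfig] = Field(default_factory=lambda: [PlanConfig()])
    out_dir: str = "cases"
    log_level: str = "INFO"

    def normalized(self) -> dict:
        """Defaults filled and pressures normalized to kPa (the echoed form)."""
        d = self.model_dump()
        for plan in d["plans"]:
            plan["closure_pressure_kpa"] = parse_pressure(plan.pop("closure_pressure"))
        return d


def load_config(path) -> RunConfig:
    """Read and validate a YAML or JSON run configuration.

    Unknown keys fail validation with the offending field path.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)
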