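"""Run configuration files and deterministic parameter-set fixtures."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .equilibria import chemo_intensity_I2, immune_intensity_I1
from .params import PARAMETER_NAMES, PARAMETER_RANGES, ModelParameters
from .sensitivity import SensitivitySpec
from .simulate import ScenarioConfig

__all__ = ["RunConfig", "load_config", "generate_fixtures"]

_TOP_LEVEL_KEYS = {"params", "scenario", "cohort", "sensitivity", "seed", "outdir", "log_level"}
_SCENARIO_KEYS = {"T0", "M0", "E0", "treated", "horizon", "cure_threshold"}
_COHORT_KEYS = {"n", "variation", "variant", "max_mg", "min_mg"}
_SENSITIVITY_KEYS = {"n_samples", "range_factor", "output_time", "parameters", "alpha"}


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for a run: parameters, blocks, seed, output."""

    params: ModelParameters
    scenario: ScenarioConfig | None = None
    cohort: dict = dataclasses.field(default_factory=dict)
    sensitivity: SensitivitySpec | None = None
    seed: int | None = None
    outdir: Path = Path(".")
    log_level: str = "INFO"

    def describe(self) -> dict:
        """The resolved parameter set and seed, for provenance records."""
        return {"params": self.params.to_dict(), "seed": self.seed}


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Missing parameters fall back to the package defaults; unknown keys at
    any level are rejected with the offending key names.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    _check_keys(data, _TOP_LEVEL_KEYS, str(path))

    params = ModelParameters.from_dict(data.get("params", {}))

    scenario = None
    if "scenario" in data:
        block = dict(data["scenario"])
        _check_keys(block, _SCENARIO_KEYS, f"{path}:scenario")
        scenario = ScenarioConfig(**block)

    cohort = dict(data.get("cohort", {}))
    _check_keys(cohort, _COHORT_KEYS, f"{path}:cohort")

    sensitivity = None
    if "sensitivity" in data:
        block = dict(data["sensitivity"])
        _check_keys(block, _SENSITIVITY_KEYS, f"{path}:sensitivity")
        if "range_factor" in block:
            block["range_factor"] = tuple(block["range_factor"])
        if "parameters" in block:
            block["parameters"] = tuple(block["parameters"])
        sensitivity = SensitivitySpec(seed=data.get("seed"), **block)

    return RunConfig(
        params=params,
        scenario=scenario,
        cohort=cohort,
        sensitivity=sensitivity,
        seed=data.get("seed"),
        outdir=Path(data.get("outdir", ".")),
        log_level=str(data.get("log_level", "INFO")),
    )


def generate_fixtures(seed: int, n: int, outdir: str | Path) -> list[Path]:
    """Write ``n`` random parameter-set files plus a stable and an unstable set.

    Random sets draw the ranged parameters (r, k, p1, p2, p3) uniformly
    within their literature ranges.  The two constructed sets bracket the
    tumor-free stability criterion: the stable one has a growth rate below
    ``I1 + I2``, the unstable one above (still strictly positive).  Output
    is deterministic for a given seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = ModelParameters()
    paths = []
    for i in range(n):
        draws = {name: float(rng.uniform(*PARAMETER_RANGES[name])) for name in sorted(PARAMETER_RANGES)}
        p = base.replace(**draws)
        path = outdir / f"param_set_{i:02d}.yaml"
        p.to_file(path)
        paths.append(path)

    total = immune_intensity_I1(base) + chemo_intensity_I2(base)
    stable = base.replace(r=0.5 * total)
    unstable = base.replace(r=2.0 * total)
    for name, p in (("stable_eb2.yaml", stable), ("unstable_eb2.yaml", unstable)):
        path = outdir / name
        p.to_file(path)
        paths.append(path)
    return paths
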