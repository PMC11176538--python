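"""Model parameters for the bladder tumor / immune / mitomycin-C system.

The model tracks three state variables — intravesical mitomycin-C (MMC)
amount ``M`` [uM], bladder tumor cells ``T`` [cells], and effector
(dendritic + cytotoxic T) cells ``E`` [cells] — coupled by eleven rate
constants.  Literature estimates give point values for some constants and
ranges for others; package defaults use the point values and the range
midpoints, and every default can be overridden from a YAML/JSON file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ModelParameters",
    "PARAMETER_RANGES",
    "DEFAULT_PARAMETERS",
    "PARAMETER_NAMES",
]

#: Literature ranges for the constants that are only known to an interval.
#: Keys are parameter names; values are (low, high) in the parameter's units.
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "r": (0.01, 0.045),          # tumor proliferation rate [1/day]
    "k": (0.09e9, 1.0e9),        # tumor carrying capacity [cells]
    "p1": (0.12, 0.20),          # MMC kill rate of tumor cells [1/day]
    "p2": (3.7e-6, 5.5e-6),      # effector kill rate of tumor cells [1/(cells day)]
    "p3": (1.1e-6, 1.59e-6),     # effector deactivation rate [1/(cells day)]
}

PARAMETER_NAMES = ("mu1", "m", "r", "k", "p1", "a", "p2", "d0", "gamma", "mu2", "p3")


def _midpoint(name: str) -> float:
    lo, hi = PARAMETER_RANGES[name]
    return 0.5 * (lo + hi)


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """The eleven rate constants of the tumor-immune-chemotherapy system.

    Parameters
    ----------
    mu1 : float
        MMC washout (absorption + degradation + voiding) rate [1/day].
    m : float
        Continuous MMC instillation rate [uM/day]; ``m = 0`` encodes the
        untreated case.
    r : float
        Tumor proliferation rate [1/day].
    k : float
        Tumor carrying capacity [cells]; interpreted as the no-cure state.
    p1 : float
        Tumor inhibition rate by MMC [1/day] (Michaelis-Menten kill).
    a : float
        Half-saturation constant of the MMC kill term [uM].
    p2 : float
        Tumor kill rate by effector cells [1/(cells day)].
    d0 : float
        Constant effector production rate [cells/day].
    gamma : float
        Effector activation multiplier on the MMC-induced apoptosis flux
        (carried as a pure number; see the methods note on its units).
    mu2 : float
        Effector natural death rate [1/day].
    p3 : float
        Effector deactivation rate on tumor encounter [1/(cells day)].
    """

    mu1: float = 21.05
    m: float = 6.561
    r: float = _midpoint("r")
    k: float = _midpoint("k")
    p1: float = _midpoint("p1")
    a: float = 100.0
    p2: float = _midpoint("p2")
    d0: float = 1.032e5
    gamma: float = 9.12
    mu2: float = 9.12
    p3: float = _midpoint("p3")

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be a finite number, got {value!r}")
        if self.m < 0:
            raise ValueError(f"instillation rate m must be >= 0, got {self.m}")
        for name in PARAMETER_NAMES:
            if name == "m":
                continue
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"parameter {name!r} must be strictly positive, got {getattr(self, name)}"
                )

    # -- conversion helpers -------------------------------------------------

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given parameters replaced."""
        return dataclasses.replace(self, **changes)

    def untreated(self) -> "ModelParameters":
        """Copy with the drug source switched off (``m = 0``)."""
        return self.replace(m=0.0)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParameters":
        """Build a parameter set from a mapping keyed by symbol name.

        Missing keys fall back to the package defaults; unknown keys are
        rejected so that typos do not silently leave a default in place.
        """
        unknown = set(data) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Read a parameter set from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a mapping of parameter names to values")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


#: Package default parameter set (point estimates + range midpoints).
DEFAULT_PARAMETERS = ModelParameters()
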