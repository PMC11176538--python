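"""Virtual-patient cohort experiment for the dose-determination algorithm.

Each hypothetical patient is a parameter set drawn around the defaults:
parameters known only to a literature range (k, p1, p2, p3) are sampled
uniformly within that range, while point-estimate parameters are held
fixed unless a custom variation spec widens them.  The growth rate ``r``
is not sampled with the others — the algorithm first computes the
patient's eligibility window ``(I1, I1 + w)``, then one ``r`` is drawn
uniformly from the open window (so the immune intensity is always below
the sampled growth rate), and the dose bound follows.

All randomness flows through a single seeded generator, so a cohort is
fully reproducible from ``(seed, n, variation)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dosing import DoseRecommendation, eligibility_window, recommend
from .equilibria import immune_intensity_I1
from .params import PARAMETER_RANGES, ModelParameters

__all__ = ["VirtualPatient", "default_variation", "sample_cohort", "run_cohort", "virtual_experiment"]


@dataclasses.dataclass
class VirtualPatient:
    """One sampled patient: parameters plus the algorithm's outputs."""

    id: int
    params: ModelParameters
    r_window: tuple[float, float] | None = None
    r_sampled: float | None = None
    recommendation: DoseRecommendation | None = None


def default_variation() -> dict[str, tuple[float, float]]:
    """Default sampling intervals: the literature ranges of k, p1, p2, p3."""
    return {name: PARAMETER_RANGES[name] for name in ("k", "p1", "p2", "p3")}


def sample_cohort(
    n: int,
    base_params: ModelParameters | None = None,
    variation: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[VirtualPatient]:
    """Draw ``n`` hypothetical patients (parameters only; ``r`` comes later)."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    base = base_params if base_params is not None else ModelParameters()
    if variation is None:
        variation = default_variation()
    for name, (lo, hi) in variation.items():
        if not (0 < lo <= hi):
            raise ValueError(f"variation range for {name!r} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    patients = []
    names = sorted(variation)  # fixed order for reproducibility
    for i in range(n):
        draws = {name: float(rng.uniform(*variation[name])) for name in names}
        patients.append(VirtualPatient(id=i, params=base.replace(**draws)))
    return patients


def run_cohort(
    patients: list[VirtualPatient],
    variant: str = "scaled",
    seed: int | np.random.Generator | None = None,
    *,
    max_mg: float = 40.0,
    min_mg: float = 1.0,
) -> pd.DataFrame:
    """Sample each patient's growth rate and compute their dose bound.

    Returns one row per patient with the parameter draws, the eligibility
    window, the sampled ``r``, the bound (uM/day and mg), and the
    classification.  Patients are mutated in place with the results.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for patient in patients:
        window = eligibility_window(patient.params, variant)
        # open-interval draw: resample the (measure-zero) endpoints
        r = float(rng.uniform(*window))
        while r <= window[0] or r >= window[1]:  # pragma: no cover
            r = float(rng.uniform(*window))
        rec = recommend(patient.params, r, variant=variant, max_mg=max_mg, min_mg=min_mg)
        patient.r_window = window
        patient.r_sampled = r
        patient.recommendation = rec
        row = {"id": patient.id}
        row.update(patient.params.to_dict())
        row.update(
            {
                "I1": immune_intensity_I1(patient.params),
                "r_low": window[0],
                "r_high": window[1],
                "r_sampled": r,
                "bound_rate": rec.bound_rate,
                "bound_mg": rec.bound_mg,
                "classification": rec.classification,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def virtual_experiment(
    n: int = 2000,
    base_params: ModelParameters | None = None,
    variation: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    variant: str = "scaled",
    **recommend_kwargs,
) -> pd.DataFrame:
    """Sample a cohort and run the dose algorithm with one seeded generator."""
    rng = np.random.default_rng(seed)
    patients = sample_cohort(n, base_params, variation, seed=rng)
    return run_cohort(patients, variant=variant, seed=rng, **recommend_kwargs)
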