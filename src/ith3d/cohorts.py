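"""Synthetic patient cohorts with planted feature effects.

Rows mimic the schema of a multicenter lung-nodule cohort: demographics,
nodule size, CT density class, lobe location, eight binary CT signs, the
2D/3D ITH scores, a binary visceral-pleural-invasion (VPI) outcome and a
center id.  Marginal distributions follow the published cohort structure
(prevalence ~13.4% positive, three centers, density/location/sign rates),
and the outcome is drawn from a logistic model over planted effects whose
intercept is calibrated so the expected prevalence matches the request.

These cohorts exercise the modelling pipeline end to end; they do not
emulate between-feature correlation structure of real patients beyond what
the planted effects induce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: feature columns in schema order
CLINICORADIOLOGIC_FEATURES = [
    "sex", "age", "size_mm", "density", "location", "boundary", "lobulation",
    "spiculation", "vascular_convergence", "vacuole", "pleural_indentation",
    "shape",
]
ITH_FEATURES = ["ith2d", "ith3d"]
ALL_FEATURES = CLINICORADIOLOGIC_FEATURES + ITH_FEATURES

#: multi-level categorical columns (one-hot encoded for most learners)
CATEGORICAL_FEATURES = ["density", "location"]

#: continuous columns (candidates for interpolation during resampling)
CONTINUOUS_FEATURES = ["age", "size_mm", "ith2d", "ith3d"]

DENSITY_LEVELS = ["pGGN", "SSN", "SN"]          # coded 0, 1, 2
LOCATION_LEVELS = ["RUL", "RLL", "RML", "LUL", "LLL"]  # coded 0..4

#: marginal rates of the emulated cohort structure
_MARGINALS = {
    "sex_male": 0.347,
    "density": (0.502, 0.251, 0.247),
    "location": (0.348, 0.078, 0.174, 0.267, 0.133),
    "boundary_ill": 0.238,
    "lobulation": 0.530,
    "spiculation": 0.448,
    "vascular_convergence": 0.762,
    "vacuole": 0.176,
    "pleural_indentation": 0.559,
    "shape_irregular": 0.433,
}


def default_effects() -> dict[str, float]:
    """Planted log-odds effects (per SD for continuous, per unit otherwise).

    The 3D ITH score carries the strongest signal, followed by nodule size
    and density — the ordering the attribution analyses are expected to
    recover.
    """
    return {
        "ith3d": 1.2,
        "size_mm": 0.7,
        "density": 0.5,       # per density level (ordinal 0/1/2)
        "ith2d": 0.3,
        "pleural_indentation": 0.4,
        "spiculation": 0.3,
    }


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort; all randomness flows from ``seed``."""

    n: int = 1301
    prevalence: float = 0.134
    effects: dict[str, float] = field(default_factory=default_effects)
    center_proportions: tuple[float, ...] = (600 / 1301, 310 / 1301, 391 / 1301)
    external_center: int = 3        # center reserved as the external split
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n < 20:
            raise ValueError("need n >= 20")
        if abs(sum(self.center_proportions) - 1.0) > 1e-6:
            raise ValueError("center proportions must sum to 1")
        unknown = set(self.effects) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(
                f"effects refer to unknown features: {sorted(unknown)}; "
                f"declared features are {ALL_FEATURES}")


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / sd if sd > 1e-12 else np.zeros_like(col)


def _calibrate_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Bisection on the intercept so mean sigmoid(lp + c) = prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(lp + mid)))) < prevalence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table; identical seed => identical table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    df = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "center": rng.choice(np.arange(1, len(spec.center_proportions) + 1),
                             size=n, p=spec.center_proportions),
        "sex": (rng.random(n) < _MARGINALS["sex_male"]).astype(int),
        "age": np.clip(np.round(rng.normal(58, 10, n)), 25, 90),
        # median 17.9 mm with Q1/Q3 13.2/24.5 -> lognormal(log 17.9, 0.46)
        "size_mm": np.clip(np.round(
            np.exp(rng.normal(np.log(17.9), 0.46, n)), 1), 4.0, 80.0),
        "density": rng.choice(3, size=n, p=_MARGINALS["density"]),
        "location": rng.choice(5, size=n, p=_MARGINALS["location"]),
        "boundary": (rng.random(n) < _MARGINALS["boundary_ill"]).astype(int),
        "lobulation": (rng.random(n) < _MARGINALS["lobulation"]).astype(int),
        "spiculation": (rng.random(n) < _MARGINALS["spiculation"]).astype(int),
        "vascular_convergence": (rng.random(n)
                                 < _MARGINALS["vascular_convergence"]).astype(int),
        "vacuole": (rng.random(n) < _MARGINALS["vacuole"]).astype(int),
        "pleural_indentation": (rng.random(n)
                                < _MARGINALS["pleural_indentation"]).astype(int),
        "shape": (rng.random(n) < _MARGINALS["shape_irregular"]).astype(int),
        # score marginals matching the published medians/quartiles
        "ith2d": np.round(rng.beta(2.0, 2.0, n), 4),        # median ~0.5
        "ith3d": np.round(rng.beta(3.1, 1.0, n), 4),        # median ~0.8
    })

    lp = np.zeros(n)
    for name, eff in spec.effects.items():
        col = df[name].to_numpy(dtype=float)
        if name in CONTINUOUS_FEATURES:
            lp += eff * _standardize(col)
        else:
            lp += eff * col
    intercept = _calibrate_intercept(lp, spec.prevalence)
    prob = 1.0 / (1.0 + np.exp(-(lp + intercept)))
    df["vpi"] = (rng.random(n) < prob).astype(int)
    df["split"] = np.where(df["center"] == spec.external_center,
                           "external", "development")
    return df


def split_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (development, external) partitions of a cohort table."""
    dev = table[table["split"] == "development"].reset_index(drop=True)
    ext = table[table["split"] == "external"].reset_index(drop=True)
    return dev, ext
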