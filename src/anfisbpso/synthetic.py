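"""Synthetic clinical-style tabular data with controlled target correlations.

The private stroke cohort cannot ship, so fixtures emulate its
*structure*: a handful of 0/1 comorbidity indicators, a handful of
continuous measurements, and a continuous target whose per-feature
Pearson correlations span the near-irrelevant (~0.006) to the dominant
(~0.75). Correlations are hit by construction, not rejection sampling:
with mutually independent features, a target

    z = sum_j rho_j * (x_j - mu_j) / sigma_j + eps,   eps ~ N(0, 1 - sum rho^2)

has unit variance and population correlation rho_j with feature j,
provided sum_j rho_j^2 < 1. The target is then affinely mapped to a
clinically plausible scale (which leaves correlations untouched).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from anfisbpso import anfis
from anfisbpso.anfis import AnfisConfig, AnfisModel
from anfisbpso.datasets import STROKE_FEATURE_TABLE
from anfisbpso.preprocessing import BINARY, CONTINUOUS, Dataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic cohort.

    ``target_correlations`` gives the population Pearson correlation of
    each feature with the target; features absent from the mapping get
    coefficient zero (their empirical correlation is then noise around
    zero). ``missing_rate`` is the per-feature-cell probability of a
    missing marker.
    """

    n_samples: int = 204
    binary_features: tuple[tuple[str, float], ...] = ()  # (name, prevalence)
    continuous_features: tuple[tuple[str, float, float], ...] = ()  # (name, mean, sd)
    target_correlations: dict[str, float] = field(default_factory=dict)
    target_mean: float = 0.0
    target_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_samples < 1:
            problems.append(f"n_samples must be >= 1, got {self.n_samples}")
        for name, prev in self.binary_features:
            if not 0.0 < prev < 1.0:
                problems.append(f"prevalence of {name!r} must be in (0,1), got {prev}")
        for name, _, sd in self.continuous_features:
            if sd <= 0:
                problems.append(f"sd of {name!r} must be > 0, got {sd}")
        if not 0.0 <= self.missing_rate < 1.0:
            problems.append(f"missing_rate must be in [0,1), got {self.missing_rate}")
        if self.target_sd <= 0:
            problems.append(f"target_sd must be > 0, got {self.target_sd}")
        names = self.feature_names()
        if len(set(names)) != len(names):
            problems.append("duplicate feature names")
        unknown = set(self.target_correlations) - set(names)
        if unknown:
            problems.append(f"correlations given for unknown features {sorted(unknown)}")
        ssq = sum(r * r for r in self.target_correlations.values())
        if ssq >= 1.0:
            problems.append(
                f"sum of squared target correlations is {ssq:.3f} >= 1; "
                "not representable with independent features"
            )
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    def feature_names(self) -> tuple[str, ...]:
        return tuple(n for n, *_ in self.binary_features) + tuple(
            n for n, *_ in self.continuous_features
        )


def generate(spec: SyntheticSpec) -> Dataset:
    """Seeded draw of one cohort according to ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    cols, names, kinds, mus, sigmas = [], [], [], [], []
    for name, prev in spec.binary_features:
        cols.append((rng.random(n) < prev).astype(float))
        names.append(name)
        kinds.append(BINARY)
        mus.append(prev)
        sigmas.append(math.sqrt(prev * (1.0 - prev)))
    for name, mean, sd in spec.continuous_features:
        cols.append(rng.normal(mean, sd, size=n))
        names.append(name)
        kinds.append(CONTINUOUS)
        mus.append(mean)
        sigmas.append(sd)
    X = np.column_stack(cols) if cols else np.empty((n, 0))

    rhos = np.array([spec.target_correlations.get(nm, 0.0) for nm in names])
    noise_sd = math.sqrt(max(1.0 - float(rhos @ rhos), 0.0))
    z = rng.normal(0.0, noise_sd, size=n)
    for j, rho in enumerate(rhos):
        if rho != 0.0:
            z += rho * (X[:, j] - mus[j]) / sigmas[j]
    y = spec.target_mean + spec.target_sd * z

    if spec.missing_rate > 0:
        holes = rng.random(X.shape) < spec.missing_rate
        X = np.where(holes, np.nan, X)
    return Dataset(X=X, y=y, names=tuple(names), kinds=tuple(kinds))


def stroke_like_spec(seed: int = 0, n_samples: int = 204) -> SyntheticSpec:
    """Default fixture mirroring the stroke cohort's shape: 204 rows,
    5 binary + 6 continuous features, target correlations set to the
    cohort's published values, and a per-cell missing rate calibrated so
    roughly 13% of rows carry at least one hole.

    Prevalences and moments are structural stand-ins (the cohort
    publishes none); correlations are the published ones.
    """
    binary_prevalence = {
        "HTN": 0.60,
        "DM": 0.35,
        "DYSLIP": 0.40,
        "UNCAL": 0.25,
        "TEMPORAL": 0.30,
    }
    continuous_moments = {
        "AGE": (55.0, 12.0),
        "SBP": (140.0, 20.0),
        "DBP": (85.0, 12.0),
        "INFVOL1": (150.0, 60.0),
        "INFVOL2": (220.0, 70.0),
        "Growthrate_1": (5.0, 3.0),
    }
    corr = {name: r for name, _, _, r in STROKE_FEATURE_TABLE}
    return SyntheticSpec(
        n_samples=n_samples,
        binary_features=tuple(
            (name, binary_prevalence[name])
            for name, kind, *_ in STROKE_FEATURE_TABLE
            if kind == BINARY
        ),
        continuous_features=tuple(
            (name, *continuous_moments[name])
            for name, kind, *_ in STROKE_FEATURE_TABLE
            if kind == CONTINUOUS
        ),
        target_correlations=corr,
        target_mean=4.0,
        target_sd=2.0,
        missing_rate=0.013,
        seed=seed,
    )


def generate_sugeno(
    n_inputs: int, n_mfs: int, seed: int = 0, n_samples: int = 200
) -> tuple[Dataset, AnfisModel]:
    """Ground-truth generator for parameter-recovery tests.

    Draws a random first-order Sugeno ANFIS (jittered premise, Gaussian
    consequent coefficients), samples inputs uniformly on [0,1]^d and
    emits noiseless forward-pass targets together with the generating
    model.
    """
    rng = np.random.default_rng(seed)
    cfg = AnfisConfig(n_mfs=n_mfs)
    model = anfis.build_model(n_inputs, cfg)
    premise = model.premise.copy()
    premise[:, :, -1] += rng.uniform(-0.1, 0.1, size=premise.shape[:2])  # centers
    premise[:, :, 0] *= rng.uniform(0.8, 1.2, size=premise.shape[:2])  # widths
    consequent = rng.normal(0.0, 1.0, size=model.consequent.shape)
    model = AnfisModel(
        rulebase=model.rulebase,
        premise=premise,
        consequent=consequent,
        mask=model.mask,
        config=cfg,
    )
    X = rng.uniform(0.0, 1.0, size=(n_samples, n_inputs))
    y = anfis.predict(model, X)
    names = tuple(f"x{j}" for j in range(n_inputs))
    data = Dataset(X=X, y=y, names=names, kinds=(CONTINUOUS,) * n_inputs)
    return data, model
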