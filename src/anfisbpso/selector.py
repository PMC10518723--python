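"""BPSO rule selection between the ANFIS antecedent and consequent parts.

Grid partitioning enumerates every rule, relevant or not; the swarm
searches over binary masks of rule firing strengths. Each candidate
mask zeroes its de-selected rules before layer-3 normalization, the
consequent is re-solved in closed form under the mask, and the fitness
is the resulting training MSE (layers 4-5 output vs target). Premise
parameters are fitted once by a conventional hybrid run and frozen
during the search, so every fitness evaluation is a single
least-squares solve.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from anfisbpso import anfis
from anfisbpso.anfis import AnfisConfig, AnfisModel
from anfisbpso.bpso import SwarmConfig, optimize
from anfisbpso.errors import DegenerateActivationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskedTrainingResult:
    """A trained masked model plus selection bookkeeping."""

    model: AnfisModel
    n_rules_full: int
    n_rules_selected: int
    bpso_trace: np.ndarray
    train_time_s: float

    def __post_init__(self) -> None:
        if not (1 <= self.n_rules_selected <= self.n_rules_full):
            raise ValueError("selected rule count must be in [1, n_rules_full]")


def rule_fitness(
    mask: np.ndarray, model: AnfisModel, X: np.ndarray, y: np.ndarray
) -> float:
    """Training MSE of ``model`` under ``mask`` after re-solving the
    consequent by least squares; the all-zero mask (no active rule) is
    an invalid candidate and maps to +inf."""
    mask = np.asarray(mask)
    if mask.shape != (model.n_rules,):
        raise ValueError(f"mask length {mask.shape} != rule count {model.n_rules}")
    if not mask.any():
        return np.inf
    try:
        masked = anfis.lse_consequent(model.with_mask(mask), X, y)
    except DegenerateActivationError:
        return np.inf
    return anfis.training_mse(masked, X, y)


def train_anfis_bpso(
    X: np.ndarray,
    y: np.ndarray,
    anfis_cfg: AnfisConfig | None = None,
    swarm_cfg: SwarmConfig | None = None,
    premise_epochs: int | None = None,
) -> MaskedTrainingResult:
    """Full selection protocol.

    1. Fit premise parameters with a conventional hybrid run
       (``premise_epochs``, defaulting to the config's epoch budget).
    2. Freeze the premise.
    3. Run BPSO over rule masks with the masked-LSE training MSE as
       fitness.
    4. Adopt the global-best mask and perform a final consequent solve
       under it.
    """
    t0 = time.perf_counter()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    anfis_cfg = anfis_cfg or AnfisConfig()
    base = anfis.build_model(X.shape[1], anfis_cfg)
    base, _ = anfis.train_hybrid(base, X, y, epochs=premise_epochs)

    if swarm_cfg is None:
        swarm_cfg = SwarmConfig(dim=base.n_rules)
    if swarm_cfg.dim != base.n_rules:
        raise ValueError(
            f"swarm dim {swarm_cfg.dim} != rule count {base.n_rules}"
        )
    gbest, _, trace = optimize(lambda m: rule_fitness(m, base, X, y), swarm_cfg)
    if gbest.all():
        logger.info("BPSO kept the full rule base (no reduction achieved)")
    model = anfis.lse_consequent(base.with_mask(gbest), X, y)
    return MaskedTrainingResult(
        model=model,
        n_rules_full=base.n_rules,
        n_rules_selected=int(gbest.sum()),
        bpso_trace=trace,
        train_time_s=time.perf_counter() - t0,
    )


def predict(result: MaskedTrainingResult, X: np.ndarray) -> np.ndarray:
    """Forward pass under the stored mask."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != result.model.n_inputs:
        raise ValueError(
            f"expected {result.model.n_inputs} features, got {X.shape[1]}"
        )
    return anfis.predict(result.model, X)
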