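"""Five-layer Takagi-Sugeno ANFIS with grid partitioning and hybrid learning.

Layers: (1) fuzzification — membership degrees of each input under each
membership function; (2) rule layer — per-rule firing strength, the
product t-norm of the degrees selected by the rule's index tuple;
(3) normalization — firing strengths scaled to relative weights;
(4) defuzzification — each rule contributes its normalized weight times
a first-order (linear + intercept) consequent; (5) output — the sum.

Training alternates a closed-form least-squares solve for the consequent
coefficients (forward pass) with a gradient-descent step on the premise
(membership-function) parameters (backward pass).

A binary ``mask`` over rules zeroes the firing strength of de-selected
rules *before* normalization, so masked rules consume no weight and
contribute nothing downstream; with an all-ones mask the model is the
conventional ANFIS.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from anfisbpso.errors import (
    DegenerateActivationError,
    ParameterError,
    RuleExplosionError,
)

logger = logging.getLogger(__name__)

GBELL = "generalized_bell"
GAUSSIAN = "gaussian"

# minimum width/slope kept during gradient updates; membership degrees
# would otherwise collapse to a spike and the product t-norm underflow
_MIN_SHAPE = 1e-3
_EPS = 1e-300


@dataclass(frozen=True)
class MembershipFunction:
    """A single membership function.

    ``generalized_bell`` params are (a, b, c): width, slope, center,
    evaluating 1 / (1 + |(x - c)/a|^(2b)).  ``gaussian`` params are
    (sigma, c), evaluating exp(-(x - c)^2 / (2 sigma^2)).  Both map any
    finite input into (0, 1] and peak at 1 when x == c.
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind == GBELL:
            a, b, _ = self.params
            if a <= 0 or b <= 0:
                raise ParameterError(f"generalized_bell needs a>0, b>0; got a={a}, b={b}")
        elif self.kind == GAUSSIAN:
            sigma, _ = self.params
            if sigma <= 0:
                raise ParameterError(f"gaussian needs sigma>0; got {sigma}")
        else:
            raise ParameterError(f"unknown membership kind {self.kind!r}")

    def __call__(self, x):
        return eval_membership(self, x)


def eval_membership(mf: MembershipFunction, x):
    """Membership degree of ``x`` (scalar or array) under ``mf``."""
    p = np.asarray(mf.params, dtype=float)
    return _eval_kind(mf.kind, p[np.newaxis, :], np.asarray(x, dtype=float)[..., np.newaxis])[..., 0]


def _eval_kind(kind: str, params: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized membership evaluation; params last axis holds the
    per-function parameters, broadcast against x."""
    if kind == GBELL:
        a, b, c = params[..., 0], params[..., 1], params[..., 2]
        t = ((x - c) / a) ** 2
        return 1.0 / (1.0 + t**b)
    if kind == GAUSSIAN:
        sigma, c = params[..., 0], params[..., 1]
        return np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
    raise ParameterError(f"unknown membership kind {kind!r}")


@dataclass(frozen=True)
class FuzzyRuleBase:
    """Grid-partition rule base: the full Cartesian product of membership
    function indices, one per input, in lexicographic order."""

    n_inputs: int
    n_mfs: int
    rules: np.ndarray  # (n_rules, n_inputs) int

    @property
    def n_rules(self) -> int:
        return self.rules.shape[0]


def grid_partition(n_inputs: int, n_mfs: int, rule_cap: int = 10_000) -> FuzzyRuleBase:
    """Enumerate all n_mfs**n_inputs rules (lexicographic).

    Grid partitioning generates every combination of membership
    functions across inputs — relevant and irrelevant rules alike —
    which is exactly the combinatorial growth the rule selector prunes.
    """
    if n_inputs < 1 or n_mfs < 1:
        raise ValueError("n_inputs and n_mfs must be >= 1")
    n_rules = n_mfs**n_inputs
    if n_rules > rule_cap:
        raise RuleExplosionError(
            f"{n_mfs}^{n_inputs} = {n_rules} rules exceeds cap {rule_cap}; "
            "reduce inputs/membership functions or raise rule_cap"
        )
    rules = np.array(
        list(itertools.product(range(n_mfs), repeat=n_inputs)), dtype=np.intp
    ).reshape(n_rules, n_inputs)
    return FuzzyRuleBase(n_inputs=n_inputs, n_mfs=n_mfs, rules=rules)


@dataclass(frozen=True)
class AnfisConfig:
    """Training configuration.

    ``premise_grad`` selects analytic chain-rule gradients (default) or
    central finite differences; ``layer3_norm`` selects the canonical
    sum-normalization w_r / sum(w) or a per-sample min-max rescaling of
    the firing strengths (non-convex weights; finite-difference
    gradients are used automatically in that mode).
    """

    n_mfs: int = 2
    mf_kind: str = GBELL
    epochs: int = 150
    lr: float = 0.01
    premise_grad: str = "analytic"  # "analytic" | "fd"
    layer3_norm: str = "sum"  # "sum" | "minmax"
    adaptive_lr: bool = True  # halve lr when training MSE increases
    rule_cap: int = 10_000


@dataclass(frozen=True)
class AnfisModel:
    """Premise parameters, per-rule linear consequents, and a rule mask.

    ``premise`` has shape (n_inputs, n_mfs, P) with P = 3 for the
    generalized bell (a, b, c) and P = 2 for the Gaussian (sigma, c).
    ``consequent`` has shape (n_rules, n_inputs + 1): slopes then
    intercept. ``mask`` is a {0,1} vector over rules.
    """

    rulebase: FuzzyRuleBase
    premise: np.ndarray
    consequent: np.ndarray
    mask: np.ndarray
    config: AnfisConfig = field(default_factory=AnfisConfig)

    def __post_init__(self) -> None:
        rb = self.rulebase
        if self.consequent.shape != (rb.n_rules, rb.n_inputs + 1):
            raise ValueError(
                f"consequent shape {self.consequent.shape} != "
                f"({rb.n_rules}, {rb.n_inputs + 1})"
            )
        if self.mask.shape != (rb.n_rules,):
            raise ValueError("mask length must equal rule count")
        if not self.mask.any():
            raise ValueError("mask must keep at least one rule")

    @property
    def n_inputs(self) -> int:
        return self.rulebase.n_inputs

    @property
    def n_rules(self) -> int:
        return self.rulebase.n_rules

    def with_mask(self, mask: np.ndarray) -> "AnfisModel":
        return replace(self, mask=np.asarray(mask, dtype=np.int8))

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "config": self.config.__dict__,
            "n_inputs": self.rulebase.n_inputs,
            "n_mfs": self.rulebase.n_mfs,
            "premise": self.premise.tolist(),
            "consequent": self.consequent.tolist(),
            "mask": self.mask.astype(int).tolist(),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnfisModel":
        doc = json.loads(text)
        cfg = AnfisConfig(**doc["config"])
        rb = grid_partition(doc["n_inputs"], doc["n_mfs"], rule_cap=cfg.rule_cap)
        return cls(
            rulebase=rb,
            premise=np.array(doc["premise"], dtype=float),
            consequent=np.array(doc["consequent"], dtype=float),
            mask=np.array(doc["mask"], dtype=np.int8),
            config=cfg,
        )


def init_premise(n_inputs: int, n_mfs: int, mf_kind: str = GBELL) -> np.ndarray:
    """Equally spaced membership functions tiling [0, 1].

    Centers at k/(m-1); widths tied to the spacing (bell width a equal
    to the spacing with slope b = 2; Gaussian sigma at half the spacing
    so neighbouring functions cross near degree 0.6).
    """
    spacing = 1.0 / (n_mfs - 1) if n_mfs > 1 else 1.0
    centers = np.linspace(0.0, 1.0, n_mfs) if n_mfs > 1 else np.array([0.5])
    if mf_kind == GBELL:
        premise = np.zeros((n_inputs, n_mfs, 3))
        premise[:, :, 0] = spacing
        premise[:, :, 1] = 2.0
        premise[:, :, 2] = centers
    elif mf_kind == GAUSSIAN:
        premise = np.zeros((n_inputs, n_mfs, 2))
        premise[:, :, 0] = spacing / 2.0
        premise[:, :, 1] = centers
    else:
        raise ParameterError(f"unknown membership kind {mf_kind!r}")
    return premise


def build_model(n_inputs: int, config: AnfisConfig | None = None) -> AnfisModel:
    """Fresh grid-partitioned model: tiled premise, zero consequent,
    all-ones mask (conventional ANFIS)."""
    config = config or AnfisConfig()
    rb = grid_partition(n_inputs, config.n_mfs, rule_cap=config.rule_cap)
    return AnfisModel(
        rulebase=rb,
        premise=init_premise(n_inputs, config.n_mfs, config.mf_kind),
        consequent=np.zeros((rb.n_rules, n_inputs + 1)),
        mask=np.ones(rb.n_rules, dtype=np.int8),
        config=config,
    )


# -- forward pass -----------------------------------------------------


def membership_matrix(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Layer 1: degrees of shape (n_samples, n_inputs, n_mfs)."""
    # params (d, m, P) against x (n, d, 1)
    return _eval_kind(model.config.mf_kind, model.premise[np.newaxis], X[:, :, np.newaxis])


def firing_strengths(model: AnfisModel, X: np.ndarray, M: np.ndarray | None = None) -> np.ndarray:
    """Layer 2: per-rule product t-norm, masked rules forced to zero."""
    if M is None:
        M = membership_matrix(model, X)
    rules = model.rulebase.rules
    W = np.ones((X.shape[0], model.n_rules))
    for j in range(model.n_inputs):
        W *= M[:, j, rules[:, j]]
    return W * model.mask


def _normalize(model: AnfisModel, W: np.ndarray) -> np.ndarray:
    """Layer 3: relative rule weights per sample."""
    if model.config.layer3_norm == "minmax":
        active = model.mask.astype(bool)
        Wa = W[:, active]
        lo = Wa.min(axis=1, keepdims=True)
        hi = Wa.max(axis=1, keepdims=True)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        Wn = np.zeros_like(W)
        Wn[:, active] = (Wa - lo) / span
        return Wn
    S = W.sum(axis=1, keepdims=True)
    if np.any(S <= 0):
        i = int(np.argmax(S[:, 0] <= 0))
        raise DegenerateActivationError(
            f"all unmasked rules have zero firing strength at sample {i}"
        )
    return W / S


def rule_outputs(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Layer-4 linear consequents f_r(x) = slopes . x + intercept."""
    X1 = np.column_stack([X, np.ones(X.shape[0])])
    return X1 @ model.consequent.T


def forward(model: AnfisModel, x: np.ndarray):
    """Full forward pass.

    Accepts a single input vector or a (n, d) matrix; returns
    (firing strengths, normalized strengths, output(s)). For a single
    vector the three results are squeezed to 1-D/scalar.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[np.newaxis, :] if single else x
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {X.shape[1]}")
    W = firing_strengths(model, X)
    Wn = _normalize(model, W)
    out = (Wn * rule_outputs(model, X)).sum(axis=1)
    if single:
        return W[0], Wn[0], float(out[0])
    return W, Wn, out


def predict(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    return forward(model, np.atleast_2d(np.asarray(X, dtype=float)))[2]


def training_mse(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> float:
    r = predict(model, X) - y
    return float(np.mean(r * r))


# -- hybrid learning --------------------------------------------------


def design_matrix(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """LSE design: row i concatenates, per rule r, Wn_ir * [x_i, 1].
    Masked rules contribute all-zero column blocks."""
    Wn = _normalize(model, firing_strengths(model, X))
    X1 = np.column_stack([X, np.ones(X.shape[0])])
    n, R, d1 = X.shape[0], model.n_rules, X.shape[1] + 1
    return (Wn[:, :, np.newaxis] * X1[:, np.newaxis, :]).reshape(n, R * d1)


def lse_consequent(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> AnfisModel:
    """Forward-pass consequent update: minimum-norm least squares.

    Zero columns from masked rules receive exactly-zero coefficients
    under the pseudo-inverse solution, so masked rules stay inert.
    """
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    Phi = design_matrix(model, X)
    theta, *_ = np.linalg.lstsq(Phi, y, rcond=None)
    consequent = theta.reshape(model.n_rules, model.n_inputs + 1)
    consequent[model.mask == 0] = 0.0
    return replace(model, consequent=consequent)


def _premise_gradient_analytic(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(training MSE)/d(premise params), chain rule through layers 1-5.

    Valid for sum-normalized layer 3 only.
    """
    n = X.shape[0]
    M = membership_matrix(model, X)
    W = firing_strengths(model, X, M)
    S = W.sum(axis=1, keepdims=True)
    if np.any(S <= 0):
        i = int(np.argmax(S[:, 0] <= 0))
        raise DegenerateActivationError(
            f"all unmasked rules have zero firing strength at sample {i}"
        )
    F = rule_outputs(model, X)
    yhat = (W / S * F).sum(axis=1)
    e = yhat - y
    # dMSE/dW_ir (masked rules carry no gradient: their W is pinned at 0)
    Gw = (2.0 / n) * e[:, None] * (F - yhat[:, None]) / S * model.mask

    rules = model.rulebase.rules
    d, m, P = model.premise.shape
    grad = np.zeros_like(model.premise)
    for j in range(d):
        xj = X[:, j]
        for k in range(m):
            sel = rules[:, j] == k
            if not sel.any():
                continue
            # dMSE/dmu_ijk = sum_{r: rule_r[j]=k} Gw_ir * W_ir / mu_ijk
            dmu = (Gw[:, sel] * W[:, sel]).sum(axis=1) / np.maximum(M[:, j, k], _EPS)
            p = model.premise[j, k]
            if model.config.mf_kind == GBELL:
                a, b, c = p
                t = ((xj - c) / a) ** 2
                mu = M[:, j, k]
                mu2 = mu * mu
                u = t**b
                with np.errstate(divide="ignore", invalid="ignore"):
                    dlog = np.where(t > 0, np.log(t), 0.0)
                    tb1 = np.where(t > 0, t ** (b - 1.0), 0.0)
                grad[j, k, 0] = np.dot(dmu, 2.0 * b * u * mu2 / a)
                grad[j, k, 1] = np.dot(dmu, -mu2 * u * dlog)
                grad[j, k, 2] = np.dot(dmu, 2.0 * b * mu2 * tb1 * (xj - c) / a**2)
            else:  # gaussian
                sigma, c = p
                mu = M[:, j, k]
                grad[j, k, 0] = np.dot(dmu, mu * (xj - c) ** 2 / sigma**3)
                grad[j, k, 1] = np.dot(dmu, mu * (xj - c) / sigma**2)
    return grad


def _premise_gradient_fd(
    model: AnfisModel, X: np.ndarray, y: np.ndarray, h: float = 1e-6
) -> np.ndarray:
    """Central finite differences over every premise parameter."""
    grad = np.zeros_like(model.premise)
    it = np.nditer(model.premise, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        for sign in (+1, -1):
            p = model.premise.copy()
            p[idx] += sign * h
            grad[idx] += sign * training_mse(replace(model, premise=p), X, y)
        grad[idx] /= 2.0 * h
    return grad


def premise_gradient(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    if model.config.premise_grad == "fd" or model.config.layer3_norm == "minmax":
        return _premise_gradient_fd(model, X, y)
    return _premise_gradient_analytic(model, X, y)


def gd_premise_step(
    model: AnfisModel, X: np.ndarray, y: np.ndarray, lr: float
) -> AnfisModel:
    """Backward-pass premise update: one gradient-descent step on the
    training MSE with the consequent held fixed.

    Widths/slopes are floored at a small positive value to keep the
    membership functions valid; a non-finite gradient skips the step.
    """
    grad = premise_gradient(model, X, y)
    if not np.isfinite(grad).all():
        logger.warning("non-finite premise gradient; skipping descent step")
        return model
    premise = model.premise - lr * grad
    if model.config.mf_kind == GBELL:
        premise[:, :, 0] = np.maximum(premise[:, :, 0], _MIN_SHAPE)  # a > 0
        premise[:, :, 1] = np.maximum(premise[:, :, 1], _MIN_SHAPE)  # b > 0
    else:
        premise[:, :, 0] = np.maximum(premise[:, :, 0], _MIN_SHAPE)  # sigma > 0
    return replace(model, premise=premise)


def train_hybrid(
    model: AnfisModel, X: np.ndarray, y: np.ndarray, epochs: int | None = None
) -> tuple[AnfisModel, np.ndarray]:
    """Two-pass hybrid learning.

    Per epoch: forward pass, least-squares consequent solve, then a
    gradient-descent premise step. The returned trace holds the
    training MSE recorded after each epoch's consequent solve. With
    ``adaptive_lr`` the premise learning rate halves whenever the
    recorded MSE rises relative to the previous epoch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    epochs = model.config.epochs if epochs is None else epochs
    lr = model.config.lr
    trace = np.zeros(epochs)
    prev = np.inf
    for ep in range(epochs):
        model = lse_consequent(model, X, y)
        cur = training_mse(model, X, y)
        trace[ep] = cur
        if model.config.adaptive_lr and cur > prev:
            lr *= 0.5
        prev = cur
        if lr > 0:
            model = gd_premise_step(model, X, y, lr)
    if epochs > 0:
        # leave the model consistent with its final premise
        model = lse_consequent(model, X, y)
    return model, trace
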