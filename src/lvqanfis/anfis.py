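"""First-order Takagi-Sugeno adaptive neuro-fuzzy inference system (ANFIS).

The five-layer network: layer 1 evaluates membership functions per input,
layer 2 takes the product t-norm over each rule's antecedents (firing
strength), layer 3 normalizes firing strengths, layer 4 weights each rule's
first-order linear consequent, layer 5 sums. Training is hybrid: a ridge
least-squares solve for the consequent coefficients with premises frozen,
alternating with a batch gradient-descent step (with step halving) on the
membership-function parameters.

Rule generation is either ``grid`` (full cross product of per-input MFs —
refused above ``max_grid_inputs`` because the rule count is
mfs_per_input**p) or ``scatter`` (one rule per data-driven input cluster,
which keeps high-dimensional problems tractable).
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

FAMILIES = ("triangular", "trapezoidal", "gbell", "gaussian")
MODEL_FORMAT_VERSION = 1


class DegenerateCoverageError(ValueError):
    """No rule fires for a query (possible outside the support of
    triangular/trapezoidal membership grids)."""


@dataclass
class ANFISConfig:
    mf_family: str = "gaussian"
    mfs_per_input: int = 3
    epochs: int = 200
    premise_step: float = 1e-3
    lse_ridge: float = 1e-8
    rule_generation: str = "grid"
    max_grid_inputs: int = 6
    scatter_rules: int = 9
    seed: int = 0

    def __post_init__(self):
        if self.mf_family not in FAMILIES:
            raise ValueError(f"mf_family must be one of {FAMILIES}")
        if self.epochs < 1 or self.premise_step <= 0 or self.lse_ridge < 0:
            raise ValueError("epochs >= 1, premise_step > 0, lse_ridge >= 0")
        if self.rule_generation not in ("grid", "scatter"):
            raise ValueError("rule_generation must be 'grid' or 'scatter'")


@dataclass
class MembershipFunction:
    """One parameterized fuzzy set on one input dimension.

    Parameter layout per family: triangular (a, b, c) feet/peak with
    a <= b <= c; trapezoidal (a, b, c, d) with a <= b <= c <= d; gbell
    (a, b, c) width/slope/center with a, b > 0; gaussian (c, sigma) with
    sigma > 0. ``shoulder`` clamps an outermost piecewise-linear MF to 1
    beyond the data range end ("left": mu = 1 for x <= peak; "right":
    mu = 1 for x >= peak).
    """

    family: str
    params: np.ndarray
    shoulder: str | None = None

    def __post_init__(self):
        self.params = np.asarray(self.params, float)
        self.validate()

    def validate(self):
        p = self.params
        if self.family == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]):
                raise ValueError(f"triangular needs a <= b <= c, got {p}")
        elif self.family == "trapezoidal":
            if len(p) != 4 or not (p[0] <= p[1] <= p[2] <= p[3]):
                raise ValueError(f"trapezoidal needs a <= b <= c <= d, got {p}")
        elif self.family == "gbell":
            if len(p) != 3 or p[0] <= 0 or p[1] <= 0:
                raise ValueError(f"gbell needs a > 0, b > 0, got {p}")
        elif self.family == "gaussian":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError(f"gaussian needs sigma > 0, got {p}")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    def __call__(self, x):
        """Membership degree in [0, 1] at x (scalar or array)."""
        x = np.asarray(x, float)
        p = self.params
        if self.family == "gaussian":
            c, sig = p
            return np.exp(-((x - c) ** 2) / (2.0 * sig ** 2))
        if self.family == "gbell":
            a, b, c = p
            return 1.0 / (1.0 + np.abs((x - c) / a) ** (2.0 * b))
        if self.family == "triangular":
            a, b, c = p
            mu = np.minimum(_ramp_up(x, a, b), _ramp_down(x, b, c))
        else:  # trapezoidal
            a, b, c, d = p
            mu = np.minimum(np.minimum(_ramp_up(x, a, b), 1.0),
                            _ramp_down(x, c, d))
        if self.shoulder == "left":
            peak = p[1]
            mu = np.where(x <= peak, 1.0, mu)
        elif self.shoulder == "right":
            peak = p[-2]
            mu = np.where(x >= peak, 1.0, mu)
        return np.clip(mu, 0.0, 1.0)

    def log_eval(self, x):
        """log of the membership degree, stable for extreme tail queries."""
        x = np.asarray(x, float)
        p = self.params
        if self.family == "gaussian":
            c, sig = p
            return -((x - c) ** 2) / (2.0 * sig ** 2)
        if self.family == "gbell":
            a, b, c = p
            with np.errstate(divide="ignore"):
                logz = np.log(np.abs((x - c) / a))
            return -np.logaddexp(0.0, 2.0 * b * logz)
        with np.errstate(divide="ignore"):
            return np.log(self(x))

    def to_dict(self):
        return {"family": self.family,
                "params": [v.hex() for v in self.params],
                "shoulder": self.shoulder}

    @classmethod
    def from_dict(cls, d):
        return cls(d["family"],
                   np.array([float.fromhex(v) for v in d["params"]]),
                   d.get("shoulder"))


def _ramp_up(x, foot, peak):
    """Rising ramp: 0 at foot, 1 at peak; zero width becomes a step at peak."""
    if peak > foot:
        return (x - foot) / (peak - foot)
    return np.where(x >= peak, np.inf, -np.inf)


def _ramp_down(x, peak, foot):
    """Falling ramp: 1 at peak, 0 at foot; zero width becomes a step."""
    if foot > peak:
        return (foot - x) / (foot - peak)
    return np.where(x <= peak, np.inf, -np.inf)


def mf_eval(mf: MembershipFunction, x):
    """Functional alias for evaluating a membership function."""
    return mf(x)


@dataclass
class RuleBase:
    """Per-input MF lists plus antecedent index tuples (one MF per input)."""

    input_mfs: list            # list over inputs of list[MembershipFunction]
    rules: list                # list of tuples, len == number of inputs

    def __post_init__(self):
        if not self.rules:
            raise ValueError("rule list must be nonempty")
        if len(set(map(tuple, self.rules))) != len(self.rules):
            raise ValueError("duplicate rules")
        p = len(self.input_mfs)
        for r in self.rules:
            if len(r) != p or any(not 0 <= k < len(self.input_mfs[i])
                                  for i, k in enumerate(r)):
                raise ValueError(f"rule {r} references invalid MF indices")

    @property
    def n_inputs(self) -> int:
        return len(self.input_mfs)

    @property
    def n_rules(self) -> int:
        return len(self.rules)


@dataclass
class ANFISModel:
    rulebase: RuleBase
    consequents: np.ndarray          # (R, p+1), last column is the intercept
    config: ANFISConfig
    training_log: list = field(default_factory=list)

    @property
    def n_rules(self):
        return self.rulebase.n_rules

    @property
    def n_inputs(self):
        return self.rulebase.n_inputs


def _grid_mfs(lo: float, hi: float, m: int, family: str) -> list:
    """Evenly spaced MFs over [lo, hi] with ~0.5 crossings at midpoints."""
    if hi <= lo:
        raise ValueError("each input needs max > min")
    if m == 1:
        centers = [0.5 * (lo + hi)]
        delta = hi - lo
    else:
        centers = np.linspace(lo, hi, m)
        delta = (hi - lo) / (m - 1)
    mfs = []
    for k, c in enumerate(centers):
        left_sh = "left" if (k == 0 and m > 1) else None
        right_sh = "right" if (k == m - 1 and m > 1) else None
        sh = left_sh or right_sh
        if family == "gaussian":
            sigma = delta / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            mfs.append(MembershipFunction("gaussian", [c, sigma]))
        elif family == "gbell":
            mfs.append(MembershipFunction("gbell", [delta / 2.0, 2.0, c]))
        elif family == "triangular":
            mfs.append(MembershipFunction(
                "triangular", [c - delta, c, c + delta], shoulder=sh))
        else:
            mfs.append(MembershipFunction(
                "trapezoidal",
                [c - 0.75 * delta, c - 0.25 * delta,
                 c + 0.25 * delta, c + 0.75 * delta], shoulder=sh))
    return mfs


def init_grid(X: np.ndarray, config: ANFISConfig) -> RuleBase:
    """Build a rule base from data: full grid partition or scatter partition.

    Grid mode enumerates mfs_per_input**p rules and refuses when p exceeds
    ``max_grid_inputs``; scatter mode places one rule per seeded cluster of
    the input rows.
    """
    X = np.atleast_2d(np.asarray(X, float))
    p = X.shape[1]
    m = config.mfs_per_input
    if config.rule_generation == "grid":
        if p > config.max_grid_inputs:
            raise ValueError(
                f"grid partition of {p} inputs x {m} MFs would create "
                f"{m ** p} rules; use rule_generation='scatter' or reduce "
                f"inputs (max_grid_inputs={config.max_grid_inputs})")
        input_mfs = [_grid_mfs(X[:, i].min(), X[:, i].max(), m,
                               config.mf_family) for i in range(p)]
        rules = list(itertools.product(range(m), repeat=p))
        return RuleBase(input_mfs, rules)
    return _init_scatter(X, config)


def _init_scatter(X: np.ndarray, config: ANFISConfig) -> RuleBase:
    """One rule per data cluster; each rule owns one MF per input."""
    from . import lvq  # local import: rule centers via vector quantization

    p = X.shape[1]
    R = min(config.scatter_rules, X.shape[0])
    cfg = lvq.LVQConfig(J=R, mode="unsupervised_vq", epochs=20,
                        seed=config.seed, n_init=2)
    model = lvq.fit(X, cfg)
    assignments, sizes = lvq.assign_clusters(model, X)
    spans = X.max(axis=0) - X.min(axis=0)
    input_mfs: list = [[] for _ in range(p)]
    kept = [j for j in range(R) if sizes[j] > 0]
    for j in kept:
        rows = X[assignments == j]
        for i in range(p):
            c = float(model.prototypes[j, i])
            sig = float(rows[:, i].std())
            sig = max(sig, 1e-6 * max(spans[i], 1.0), 1e-12)
            if config.mf_family == "gaussian":
                mf = MembershipFunction("gaussian", [c, sig])
            elif config.mf_family == "gbell":
                mf = MembershipFunction("gbell", [sig * np.sqrt(2 * np.log(2)),
                                                  2.0, c])
            elif config.mf_family == "triangular":
                mf = MembershipFunction("triangular", [c - 3 * sig, c, c + 3 * sig])
            else:
                mf = MembershipFunction(
                    "trapezoidal", [c - 3 * sig, c - sig, c + sig, c + 3 * sig])
            input_mfs[i].append(mf)
    rules = [tuple([idx] * p) for idx in range(len(kept))]
    return RuleBase(input_mfs, rules)


def _membership_matrices(rulebase: RuleBase, X: np.ndarray) -> list:
    """Per input i: (n, m_i) matrix of membership degrees."""
    return [np.column_stack([mf(X[:, i]) for mf in mfs])
            for i, mfs in enumerate(rulebase.input_mfs)]


def firing_strengths(rulebase: RuleBase, X: np.ndarray) -> np.ndarray:
    """(n, R) product-t-norm firing strengths."""
    X = np.atleast_2d(np.asarray(X, float))
    M = _membership_matrices(rulebase, X)
    W = np.ones((X.shape[0], rulebase.n_rules))
    for r, rule in enumerate(rulebase.rules):
        for i, k in enumerate(rule):
            W[:, r] *= M[i][:, k]
    return W


def normalized_firing(rulebase: RuleBase, X: np.ndarray) -> np.ndarray:
    """(n, R) layer-3 normalized firing strengths, computed in log space.

    Products of many memberships underflow double precision for tail
    queries; normalization only needs relative strengths, so each row is
    shifted by its log-maximum before exponentiation. Rows where every rule
    has zero membership (possible outside triangular/trapezoidal support)
    raise :class:`DegenerateCoverageError`.
    """
    X = np.atleast_2d(np.asarray(X, float))
    logW = np.zeros((X.shape[0], rulebase.n_rules))
    logM = [np.column_stack([mf.log_eval(X[:, i]) for mf in mfs])
            for i, mfs in enumerate(rulebase.input_mfs)]
    for r, rule in enumerate(rulebase.rules):
        for i, k in enumerate(rule):
            logW[:, r] += logM[i][:, k]
    top = logW.max(axis=1)
    if np.any(np.isneginf(top)):
        bad = int(np.flatnonzero(np.isneginf(top))[0])
        raise DegenerateCoverageError(
            f"no rule fires for row {bad}; query outside the membership "
            f"grid's support")
    Wn = np.exp(logW - top[:, None])
    return Wn / Wn.sum(axis=1, keepdims=True)


def _predict_batch(model: ANFISModel, X: np.ndarray,
                   consequents: np.ndarray | None = None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    C = model.consequents if consequents is None else consequents
    Wn = normalized_firing(model.rulebase, X)
    Xa = np.column_stack([X, np.ones(X.shape[0])])
    F = Xa @ C.T                                  # (n, R) rule outputs
    return (Wn * F).sum(axis=1)


def predict(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Network output for each row of X."""
    return _predict_batch(model, X)


def forward(model: ANFISModel, x: np.ndarray):
    """Layer-by-layer evaluation for one query.

    Returns (firing strengths, normalized strengths, output).
    """
    x = np.asarray(x, float).reshape(1, -1)
    W = firing_strengths(model.rulebase, x)[0]
    normalized = normalized_firing(model.rulebase, x)[0]
    xa = np.append(x[0], 1.0)
    output = float(normalized @ (model.consequents @ xa))
    return W, normalized, output


def lse_consequents(model: ANFISModel, X: np.ndarray, y: np.ndarray,
                    ridge: float | None = None) -> np.ndarray:
    """Ridge least-squares solve for the consequent matrix, premises fixed.

    Row i of the design matrix concatenates normalized_r(x_i) * [x_i, 1]
    over rules r. With ridge=0 and full column rank this is the global SSE
    minimizer; rank-deficient unridged systems fall back to the minimum-norm
    solution with a warning.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    ridge = model.config.lse_ridge if ridge is None else ridge
    n, p = X.shape
    R = model.n_rules
    Wn = normalized_firing(model.rulebase, X)
    Xa = np.column_stack([X, np.ones(n)])
    A = (Wn[:, :, None] * Xa[:, None, :]).reshape(n, R * (p + 1))
    if ridge > 0:
        A_aug = np.vstack([A, np.sqrt(ridge) * np.eye(A.shape[1])])
        y_aug = np.concatenate([y, np.zeros(A.shape[1])])
    else:
        A_aug, y_aug = A, y
    beta, _, rank, _ = scipy.linalg.lstsq(A_aug, y_aug, lapack_driver="gelsd")
    if ridge == 0 and rank < A.shape[1]:
        warnings.warn("rank-deficient consequent system; "
                      "returning the minimum-norm solution")
    return beta.reshape(R, p + 1)


def _sse(model, X, y):
    return float(np.sum((_predict_batch(model, X) - y) ** 2))


def _mf_param_grads(mf: MembershipFunction, x: np.ndarray) -> np.ndarray:
    """d mu / d params at each x, shape (len(x), n_params).

    Piecewise-linear families use subgradients that are zero at kinks and on
    shoulder plateaus.
    """
    p = mf.params
    g = np.zeros((x.shape[0], len(p)))
    if mf.family == "gaussian":
        c, sig = p
        mu = mf(x)
        g[:, 0] = mu * (x - c) / sig ** 2
        g[:, 1] = mu * (x - c) ** 2 / sig ** 3
        return g
    if mf.family == "gbell":
        a, b, c = p
        z = (x - c) / a
        az = np.abs(z)
        t = az ** (2 * b)
        mu = 1.0 / (1.0 + t)
        nz = az > 1e-300
        g[:, 0] = mu ** 2 * 2 * b * t / a
        g[nz, 2] = mu[nz] ** 2 * 2 * b * t[nz] / (x[nz] - c)
        g[nz, 1] = -(mu[nz] ** 2) * 2 * t[nz] * np.log(az[nz])
        return g
    if mf.family == "triangular":
        a, b, c = p
        rising = (x > a) & (x < b)
        falling = (x > b) & (x < c)
        if mf.shoulder == "left":
            rising[:] = False
        if mf.shoulder == "right":
            falling[:] = False
        if b > a:
            g[rising, 0] = (x[rising] - b) / (b - a) ** 2
            g[rising, 1] = -(x[rising] - a) / (b - a) ** 2
        if c > b:
            g[falling, 1] = (c - x[falling]) / (c - b) ** 2
            g[falling, 2] = (x[falling] - b) / (c - b) ** 2
        return g
    # trapezoidal
    a, b, c, d = p
    rising = (x > a) & (x < b)
    falling = (x > c) & (x < d)
    if mf.shoulder == "left":
        rising[:] = False
    if mf.shoulder == "right":
        falling[:] = False
    if b > a:
        g[rising, 0] = (x[rising] - b) / (b - a) ** 2
        g[rising, 1] = -(x[rising] - a) / (b - a) ** 2
    if d > c:
        g[falling, 2] = (d - x[falling]) / (d - c) ** 2
        g[falling, 3] = (x[falling] - c) / (d - c) ** 2
    return g


def premise_gradients(model: ANFISModel, X: np.ndarray, y: np.ndarray) -> list:
    """dSSE/d(MF params), as nested lists matching rulebase.input_mfs."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    rb = model.rulebase
    R = rb.n_rules
    M = _membership_matrices(rb, X)
    W = np.ones((X.shape[0], R))
    for r, rule in enumerate(rb.rules):
        for i, k in enumerate(rule):
            W[:, r] *= M[i][:, k]
    S = W.sum(axis=1)
    # rows whose firing underflows carry no usable premise signal; drop them
    keep = S > 0
    X, y, W, S, M = X[keep], y[keep], W[keep], S[keep], [m[keep] for m in M]
    n, p = X.shape
    Xa = np.column_stack([X, np.ones(n)])
    F = Xa @ model.consequents.T
    yhat = (W * F).sum(axis=1) / S
    resid = yhat - y
    # product over the other inputs, computed directly so mu=0 is safe
    prod_others = np.ones((n, R, p))
    for r, rule in enumerate(rb.rules):
        for i in range(p):
            for i2, k2 in enumerate(rule):
                if i2 != i:
                    prod_others[:, r, i] *= M[i2][:, k2]
    dE_dW = 2.0 * resid[:, None] * (F - yhat[:, None]) / S[:, None]  # (n, R)
    grads = []
    for i, mfs in enumerate(rb.input_mfs):
        gi = []
        for k, mf in enumerate(mfs):
            dmu = _mf_param_grads(mf, X[:, i])          # (n, q)
            coef = np.zeros(n)
            for r, rule in enumerate(rb.rules):
                if rule[i] == k:
                    coef += dE_dW[:, r] * prod_others[:, r, i]
            gi.append(coef @ dmu)
        grads.append(gi)
    return grads


def _repair(family: str, params: np.ndarray, shoulder: str | None,
            span: float) -> MembershipFunction:
    """Restore family constraints after a gradient step (sort-and-clip)."""
    floor = max(1e-6 * span, 1e-12)
    p = np.asarray(params, float).copy()
    if family in ("triangular", "trapezoidal"):
        p = np.sort(p)
    elif family == "gbell":
        p[0] = max(p[0], floor)
        p[1] = max(p[1], 1e-3)
    else:
        p[1] = max(p[1], floor)
    return MembershipFunction(family, p, shoulder)


def premise_step(model: ANFISModel, X: np.ndarray, y: np.ndarray,
                 step: float) -> ANFISModel:
    """One batch gradient-descent step on the MF parameters (repaired).

    Returns a new model sharing the consequents. Non-finite gradients skip
    the step with a warning; step=0 is the identity.
    """
    if step == 0:
        return model
    X = np.atleast_2d(np.asarray(X, float))
    spans = X.max(axis=0) - X.min(axis=0)
    grads = premise_gradients(model, X, y)
    flat = np.concatenate([g for gi in grads for g in gi])
    if not np.all(np.isfinite(flat)):
        warnings.warn("non-finite premise gradient; step skipped")
        return model
    new_inputs = []
    for i, mfs in enumerate(model.rulebase.input_mfs):
        new_mfs = []
        for k, mf in enumerate(mfs):
            p_new = mf.params - step * grads[i][k]
            new_mfs.append(_repair(mf.family, p_new, mf.shoulder,
                                   max(spans[i], 1.0)))
        new_inputs.append(new_mfs)
    rb = RuleBase(new_inputs, list(model.rulebase.rules))
    return ANFISModel(rb, model.consequents.copy(), model.config,
                      list(model.training_log))


def fit_hybrid(X: np.ndarray, y: np.ndarray, config: ANFISConfig,
               rulebase: RuleBase | None = None) -> ANFISModel:
    """Hybrid training: per epoch, an LSE consequent solve then one premise
    gradient step with halving on SSE increase. The per-epoch training RMSE
    log is non-increasing; a final LSE solve leaves the consequents optimal
    for the final premises.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape
    rb = rulebase or init_grid(X, config)
    if n < rb.n_rules:
        warnings.warn(f"only n={n} rows for {rb.n_rules} rules; "
                      "consequents may be underdetermined")
    model = ANFISModel(rb, np.zeros((rb.n_rules, p + 1)), config)
    step = config.premise_step
    for _ in range(config.epochs):
        model.consequents = lse_consequents(model, X, y)
        sse = _sse(model, X, y)
        model.training_log.append(np.sqrt(sse / n))
        trial_step = step
        for _ in range(12):
            cand = premise_step(model, X, y, trial_step)
            if _sse(cand, X, y) <= sse:
                cand.training_log = model.training_log
                model = cand
                break
            trial_step /= 2.0
        # if every halved step increased SSE the premises stay put
    model.consequents = lse_consequents(model, X, y)
    model.training_log.append(np.sqrt(_sse(model, X, y) / n))
    return model


def save_model(model: ANFISModel, path) -> None:
    """Versioned structured-text serialization, round-trip exact."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": "anfis",
        "config": vars(model.config),
        "input_mfs": [[mf.to_dict() for mf in mfs]
                      for mfs in model.rulebase.input_mfs],
        "rules": [list(r) for r in model.rulebase.rules],
        "consequents": [[v.hex() for v in row] for row in model.consequents],
        "training_log": model.training_log,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> ANFISModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "anfis":
        raise ValueError("not an ANFIS model file")
    rb = RuleBase(
        [[MembershipFunction.from_dict(d) for d in mfs]
         for mfs in payload["input_mfs"]],
        [tuple(r) for r in payload["rules"]],
    )
    return ANFISModel(
        rulebase=rb,
        consequents=np.array([[float.fromhex(v) for v in row]
                              for row in payload["consequents"]]),
        config=ANFISConfig(**payload["config"]),
        training_log=payload["training_log"],
    )
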