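"""Learning vector quantization: LVQ1, OLVQ1 and unsupervised quantization.

Prototype (codebook) vectors partition feature space into Voronoi cells. In
the supervised modes each prototype carries a class label and is attracted to
same-class samples and repelled from other-class samples. OLVQ1 replaces the
global learning rate with a per-prototype rate

    eta_j(t) = min(eta_j(t-1) / (s(t) * eta_j(t-1) + 1), eta_max)

where s(t) = +1 when winner and sample agree and -1 otherwise. The
``unsupervised_vq`` modes drop labels and always attract the winner (s = +1),
which is online vector quantization; this is how the combined pipeline
segments unlabelled vocal-feature data into clusters.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MODES = ("lvq1_supervised", "olvq1_supervised",
         "unsupervised_vq", "unsupervised_vq_global")
SUPERVISED_MODES = ("lvq1_supervised", "olvq1_supervised")

MODEL_FORMAT_VERSION = 1


@dataclass
class LVQConfig:
    """Training configuration for an LVQ codebook.

    J : number of prototypes (default 9, the cluster count used for the
        telemonitoring data). eta0 / eta_max : initial and maximum learning
        rate in (0, 1]. ``init`` selects prototype initialization:
    "kmeanspp" (distance-weighted seeded sampling of data rows, default) or
    "sample" (uniform seeded sampling of J distinct rows). ``n_init``
    restarts are run and the codebook with lowest mean quantization error is
    kept; restarts guard against initial codebooks that leave a well-separated
    cluster without a prototype.
    """

    J: int = 9
    mode: str = "unsupervised_vq"
    eta0: float = 0.3
    eta_max: float = 0.3
    epochs: int = 100
    schedule: str = "linear"
    seed: int = 0
    init: str = "kmeanspp"
    n_init: int = 4

    def __post_init__(self):
        if not (0 < self.eta0 <= self.eta_max <= 1):
            raise ValueError("need 0 < eta0 <= eta_max <= 1")
        if self.J < 1 or self.epochs < 1 or self.n_init < 1:
            raise ValueError("J, epochs and n_init must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.init not in ("kmeanspp", "sample"):
            raise ValueError("init must be 'kmeanspp' or 'sample'")


@dataclass
class LVQModel:
    """A trained codebook: prototype positions, optional labels and rates."""

    prototypes: np.ndarray            # (J, d)
    config: LVQConfig
    labels: np.ndarray | None = None  # (J,) ints, supervised modes only
    rates: np.ndarray | None = None   # (J,) per-prototype rates, OLVQ1-style
    training_log: list = field(default_factory=list)

    @property
    def J(self) -> int:
        return self.prototypes.shape[0]

    @property
    def d(self) -> int:
        return self.prototypes.shape[1]


def distances(x: np.ndarray, model: LVQModel) -> np.ndarray:
    """Euclidean distance from x to every prototype, in prototype order."""
    x = np.asarray(x, float)
    if x.shape != (model.d,):
        raise ValueError(f"x has shape {x.shape}, prototypes have d={model.d}")
    return np.linalg.norm(model.prototypes - x, axis=1)


def winner(x: np.ndarray, model: LVQModel) -> int:
    """Index of the nearest prototype; ties break to the lowest index."""
    return int(np.argmin(distances(x, model)))


def lvq1_step(model: LVQModel, x: np.ndarray, label: int, eta: float) -> LVQModel:
    """One LVQ1 update: attract the winner on label match, repel on mismatch.

    Non-winning prototypes are unchanged. Mutates and returns ``model``.
    """
    if model.labels is None:
        raise ValueError("lvq1_step requires a supervised (labelled) model")
    if label is None:
        raise ValueError("supervised update needs a labelled sample")
    if not 0 <= eta <= 1:
        raise ValueError("eta must lie in [0, 1]")
    j = winner(x, model)
    sign = 1.0 if model.labels[j] == label else -1.0
    model.prototypes[j] += sign * eta * (np.asarray(x, float) - model.prototypes[j])
    return model


def olvq1_rate_update(prev_rate: float, s: int, eta_max: float) -> float:
    """Per-prototype rate recursion eta <- min(eta / (s*eta + 1), eta_max).

    Strictly decreases for s=+1; increases (capped at eta_max) for s=-1.
    """
    if s not in (1, -1):
        raise ValueError("s must be +1 or -1")
    if not 0 < prev_rate <= eta_max:
        raise ValueError("prev_rate must lie in (0, eta_max]")
    denom = s * prev_rate + 1.0
    if denom <= 0:
        raise ValueError("degenerate rate update: s*eta + 1 <= 0")
    return min(prev_rate / denom, eta_max)


def _init_prototypes(X: np.ndarray, J: int, method: str,
                     rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    if method == "sample":
        return X[rng.choice(n, size=J, replace=False)].copy()
    # distance-weighted (k-means++ style) seeded sampling of data rows
    chosen = [int(rng.integers(n))]
    d2 = np.sum((X - X[chosen[0]]) ** 2, axis=1)
    for _ in range(1, J):
        total = d2.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(n), chosen)
            chosen.append(int(rng.choice(remaining)))
        else:
            chosen.append(int(rng.choice(n, p=d2 / total)))
        d2 = np.minimum(d2, np.sum((X - X[chosen[-1]]) ** 2, axis=1))
    return X[chosen].copy()


def _run_training(X, labels, config: LVQConfig, rng) -> LVQModel:
    n = X.shape[0]
    protos = _init_prototypes(X, config.J, config.init, rng)
    if config.mode in SUPERVISED_MODES:
        # prototype labels come from the rows chosen at initialization:
        # relabel by nearest data row
        proto_labels = np.empty(config.J, dtype=int)
        for j in range(config.J):
            proto_labels[j] = labels[np.argmin(
                np.sum((X - protos[j]) ** 2, axis=1))]
    else:
        proto_labels = None
    rates = np.full(config.J, config.eta0)
    per_prototype = config.mode in ("olvq1_supervised", "unsupervised_vq")

    total_steps = config.epochs * n
    log = []
    t = 0
    for _ in range(config.epochs):
        qerr = 0.0
        for i in rng.permutation(n):
            x = X[i]
            dists = np.linalg.norm(protos - x, axis=1)
            j = int(np.argmin(dists))
            qerr += dists[j]
            if config.mode in SUPERVISED_MODES:
                s = 1 if proto_labels[j] == labels[i] else -1
            else:
                s = 1
            if per_prototype:
                rates[j] = olvq1_rate_update(rates[j], s, config.eta_max)
                eta = rates[j]
            else:
                eta = config.eta0 * max(0.0, 1.0 - t / total_steps)
            protos[j] += s * eta * (x - protos[j])
            t += 1
        log.append(qerr / n)
    return LVQModel(prototypes=protos, config=config, labels=proto_labels,
                    rates=rates if per_prototype else None, training_log=log)


def fit(data, config: LVQConfig, labels=None) -> LVQModel:
    """Train an LVQ codebook on a FeatureTable or raw (n, d) matrix.

    Runs ``config.n_init`` seeded restarts and keeps the model with the
    lowest final mean quantization error. Identical (data, config) pairs
    yield bit-identical models.
    """
    X = np.asarray(getattr(data, "features", data), float)
    if X.ndim != 2:
        raise ValueError("data must be an (n, d) matrix or FeatureTable")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    n = X.shape[0]
    if n < config.J:
        raise ValueError(f"need n >= J prototypes, got n={n}, J={config.J}")
    if config.mode in SUPERVISED_MODES:
        if labels is None:
            raise ValueError(f"mode {config.mode!r} requires labels")
        labels = np.asarray(labels, dtype=int)
        if labels.shape[0] != n:
            raise ValueError("labels length must equal n")

    master = np.random.default_rng(config.seed)
    best = None
    for _ in range(config.n_init):
        model = _run_training(X, labels, config,
                              np.random.default_rng(master.integers(2**31)))
        if best is None or model.training_log[-1] < best.training_log[-1]:
            best = model
    return best


def assign_clusters(model: LVQModel, data) -> tuple[np.ndarray, np.ndarray]:
    """Assign every row to its winning prototype. Sizes sum to n."""
    X = np.asarray(getattr(data, "features", data), float)
    d2 = ((X[:, None, :] - model.prototypes[None, :, :]) ** 2).sum(axis=2)
    assignments = np.argmin(d2, axis=1)
    sizes = np.bincount(assignments, minlength=model.J)
    return assignments, sizes


def centroid_table(model: LVQModel, data) -> np.ndarray:
    """Per-cluster feature means, (J, d). Empty clusters yield NaN rows."""
    X = np.asarray(getattr(data, "features", data), float)
    assignments, sizes = assign_clusters(model, X)
    out = np.full((model.J, model.d), np.nan)
    for j in range(model.J):
        if sizes[j] > 0:
            out[j] = X[assignments == j].mean(axis=0)
        else:
            warnings.warn(f"cluster {j} is empty; centroid undefined")
    return out


def save_model(model: LVQModel, path) -> None:
    """Serialize the codebook as versioned JSON text (round-trip exact)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": "lvq",
        "config": vars(model.config),
        "prototypes": [[v.hex() for v in row] for row in model.prototypes],
        "labels": None if model.labels is None else model.labels.tolist(),
        "rates": None if model.rates is None
                 else [v.hex() for v in model.rates],
        "training_log": model.training_log,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> LVQModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "lvq":
        raise ValueError("not an LVQ model file")
    return LVQModel(
        prototypes=np.array([[float.fromhex(v) for v in row]
                             for row in payload["prototypes"]]),
        config=LVQConfig(**payload["config"]),
        labels=None if payload["labels"] is None
               else np.asarray(payload["labels"], int),
        rates=None if payload["rates"] is None
              else np.array([float.fromhex(v) for v in payload["rates"]]),
        training_log=payload["training_log"],
    )
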