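"""Seeded generators of cluster-structured regression data with known truth.

These stand in for the telemonitoring recordings in all core tests: K
well-separated Gaussian feature blobs, each with its own input -> output map
(a linear map or a small Takagi-Sugeno system) plus additive Gaussian output
noise. The ground-truth record returned alongside the table carries the
cluster labels, generator parameters and noiseless outputs, so recovery
tests can compare against the Bayes-optimal RMSE (= noise_sd).

``make_telemonitoring_like`` draws a table whose 16 features match the
published per-feature moments of the UCI Parkinsons Telemonitoring data
(truncated Gaussians, diagonal covariance) with two pseudo-UPDRS targets
from a hidden nine-regime generator — a smoke-test stand-in, not a
simulation of real voice physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from . import anfis
from .data_io import FeatureTable


@dataclass
class SyntheticSpec:
    """Study conditions for a cluster-structured regression dataset.

    center_separation / cluster_sd is the separability ratio; at >= 6 the
    blobs are essentially non-overlapping and prototype clustering should
    recover memberships almost perfectly.
    """

    K: int = 3
    d: int = 2
    n_per_cluster: int = 650
    center_separation: float = 12.0
    cluster_sd: float = 1.0
    generator: str = "sugeno"        # nonlinear per-cluster map; or "linear"
    noise_sd: float = 0.5
    seed: int = 0
    covariance: np.ndarray | None = None   # optional d x d within-cluster cov

    def __post_init__(self):
        if self.K < 1 or self.n_per_cluster < 1 or self.noise_sd < 0:
            raise ValueError("need K >= 1, n_per_cluster >= 1, noise_sd >= 0")
        if self.d < 1 or self.cluster_sd <= 0 or self.center_separation < 0:
            raise ValueError("need d >= 1, cluster_sd > 0, separation >= 0")
        if self.generator not in ("linear", "sugeno"):
            raise ValueError("generator must be 'linear' or 'sugeno'")

    @property
    def separability_ratio(self) -> float:
        return self.center_separation / self.cluster_sd


@dataclass
class GroundTruth:
    labels: np.ndarray              # (n,) true cluster of each row
    centers: np.ndarray             # (K, d)
    generators: list                # per-cluster generator description
    noiseless: np.ndarray           # (n,) outputs before noise
    bayes_rmse: float               # = noise_sd


def _draw_centers(K, d, separation, rng) -> np.ndarray:
    """Seeded rejection sampling of K centers at pairwise distance >= separation."""
    if K == 1:
        return np.zeros((1, d))
    box = separation * (K ** (1.0 / d) + 1.0)
    centers = [rng.uniform(0, box, size=d)]
    for _ in range(10_000):
        if len(centers) == K:
            break
        cand = rng.uniform(0, box, size=d)
        if min(np.linalg.norm(cand - c) for c in centers) >= separation:
            centers.append(cand)
    if len(centers) < K:
        raise RuntimeError("could not place centers; lower the separation")
    return np.array(centers)


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw a cluster-structured table and its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    centers = _draw_centers(spec.K, spec.d, spec.center_separation, rng)
    n = spec.K * spec.n_per_cluster
    labels = np.repeat(np.arange(spec.K), spec.n_per_cluster)
    if spec.covariance is not None:
        L = np.linalg.cholesky(np.asarray(spec.covariance, float))
        noise = rng.standard_normal((n, spec.d)) @ L.T
    else:
        noise = spec.cluster_sd * rng.standard_normal((n, spec.d))
    X = centers[labels] + noise

    generators = []
    y_clean = np.empty(n)
    for k in range(spec.K):
        rows = labels == k
        if spec.generator == "linear":
            w = rng.uniform(-2.0, 2.0, size=spec.d)
            b = 20.0 * k + rng.uniform(-2.0, 2.0)
            y_clean[rows] = X[rows] @ w + b
            generators.append({"kind": "linear", "w": w, "b": b})
        else:
            lo = centers[k] - 3 * spec.cluster_sd
            hi = centers[k] + 3 * spec.cluster_sd
            cfg = anfis.ANFISConfig(mfs_per_input=2, seed=int(rng.integers(2**31)))
            model = make_sugeno_system(list(zip(lo, hi)), cfg,
                                       seed=cfg.seed, offset=20.0 * k)
            y_clean[rows] = anfis.predict(model, X[rows])
            generators.append({"kind": "sugeno", "model": model})
    y = y_clean + spec.noise_sd * rng.standard_normal(n)

    table = FeatureTable(
        features=X, targets=y,
        feature_names=[f"x{i + 1}" for i in range(spec.d)],
        target_names=["y"],
        subject_id=labels.copy(),
    )
    truth = GroundTruth(labels=labels, centers=centers, generators=generators,
                        noiseless=y_clean, bayes_rmse=spec.noise_sd)
    return table, truth


def make_sugeno_system(input_ranges, config: anfis.ANFISConfig, seed: int,
                       consequent_scale: float = 2.0,
                       offset: float = 0.0) -> anfis.ANFISModel:
    """A random first-order Sugeno system with grid membership functions.

    The MF grid spans each input's given (lo, hi) range exactly, so a model
    fit to data covering the same range starts from identical premises —
    the recovery-test oracle.
    """
    rng = np.random.default_rng(seed)
    corners = np.array(input_ranges, float)        # (p, 2)
    X_span = np.vstack([corners[:, 0], corners[:, 1]])
    rb = anfis.init_grid(X_span, config)
    p = corners.shape[0]
    C = rng.uniform(-consequent_scale, consequent_scale,
                    size=(rb.n_rules, p + 1))
    C[:, -1] += offset
    return anfis.ANFISModel(rb, C, config)


def sample_sugeno(model: anfis.ANFISModel, input_ranges, n: int,
                  noise_sd: float, seed: int,
                  include_endpoints: bool = True):
    """Draw (X, y, y_clean) uniformly over the system's input box.

    With ``include_endpoints`` the box corners are inserted so the sample's
    per-input min/max equal the generator's MF grid ends — grid
    initialization on this data then reproduces the generator's premises.
    """
    rng = np.random.default_rng(seed)
    corners = np.array(input_ranges, float)
    p = corners.shape[0]
    X = rng.uniform(corners[:, 0], corners[:, 1], size=(n, p))
    if include_endpoints and n >= 2:
        X[0] = corners[:, 0]
        X[1] = corners[:, 1]
    y_clean = anfis.predict(model, X)
    y = y_clean + noise_sd * rng.standard_normal(n)
    return X, y, y_clean


# Published per-feature summary moments of the UCI telemonitoring data
# (min, max, mean, sd), used as moment targets for the smoke-test generator.
TELEMONITORING_MOMENTS: dict = {
    "Jitter(%)":      (8e-4, 0.1, 0.006, 0.006),
    "Jitter(Abs)":    (2e-6, 4e-4, 4e-5, 3e-5),
    "Jitter:RAP":     (3e-4, 0.057, 0.003, 0.003),
    "Jitter:PPQ5":    (4e-4, 0.069, 0.003, 0.004),
    "Jitter:DDP":     (10e-4, 0.173, 0.009, 0.009),
    "Shimmer":        (0.003, 0.269, 0.034, 0.026),
    "Shimmer(dB)":    (0.026, 2.107, 0.311, 0.230),
    "Shimmer:APQ3":   (0.002, 0.163, 0.017, 0.013),
    "Shimmer:APQ5":   (0.002, 0.167, 0.020, 0.017),
    "Shimmer:APQ11":  (0.003, 0.276, 0.028, 0.020),
    "Shimmer:DDA":    (0.005, 0.488, 0.052, 0.040),
    "NHR":            (3e-4, 0.749, 0.032, 0.060),
    "HNR":            (1.659, 37.875, 21.679, 4.291),
    "RPDE":           (0.151, 0.966, 0.541, 0.101),
    "DFA":            (0.514, 0.866, 0.653, 0.071),
    "PPE":            (0.022, 0.732, 0.220, 0.092),
}


def make_telemonitoring_like(seed: int, n: int = 5875,
                             n_subjects: int = 42) -> FeatureTable:
    """A telemonitoring-shaped table: 16 features moment-matched to the
    published summary statistics (independent truncated Gaussians) and two
    pseudo-UPDRS targets driven by a hidden nine-regime map of the features.

    Useful for CLI smoke tests and pipeline exercises without any download;
    it does not reproduce the real data's feature correlations.
    """
    rng = np.random.default_rng(seed)
    names = list(TELEMONITORING_MOMENTS)
    X = np.empty((n, len(names)))
    for j, name in enumerate(names):
        lo, hi, mean, sd = TELEMONITORING_MOMENTS[name]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        X[:, j] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                random_state=rng)

    # hidden 9-regime target generator on standardized features
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    hnr_z = Z[:, names.index("HNR")]
    regime = np.clip(np.digitize(hnr_z, np.quantile(hnr_z, np.linspace(
        0, 1, 10)[1:-1])), 0, 8)
    w = rng.uniform(-1.5, 1.5, size=Z.shape[1])
    offsets = rng.uniform(-4, 4, size=9)
    motor = 21.0 + 3.0 * (Z @ w) / np.sqrt(Z.shape[1]) + offsets[regime] \
        + 0.8 * rng.standard_normal(n)
    motor = np.clip(motor, 5.0, 41.0)
    total = np.clip(1.3 * motor + 1.5 + 0.8 * rng.standard_normal(n),
                    7.0, 55.0)

    subj = np.sort(rng.integers(0, n_subjects, size=n)) + 1
    subj_age = rng.integers(36, 86, size=n_subjects)
    subj_sex = np.array([0] * 28 + [1] * (n_subjects - 28))[:n_subjects]
    test_time = rng.uniform(0, 180, size=n)
    return FeatureTable(
        features=X,
        targets=np.column_stack([motor, total]),
        feature_names=names, target_names=["motor", "total"],
        subject_id=subj, age=subj_age[subj - 1], sex=subj_sex[subj - 1],
        test_time=test_time,
    )
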