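"""The combined method: prototype clustering + one ANFIS expert per cluster.

``fit_combined`` quantizes the training rows with OLVQ1-style vector
quantization, trains a first-order Sugeno fuzzy system on each sufficiently
large cluster, and merges undersized clusters into their nearest neighbour
(the consequent least-squares solve needs more rows than coefficients).
Queries are routed to the nearest prototype's expert. ``crossvalidate`` and
``compare_methods`` implement the seeded k-fold protocol (whole-pipeline
refits per fold, so no information leaks from test rows into clustering)
and report per-fold and averaged RMSE / R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import anfis, lvq
from .data_io import FeatureTable, Scaler, scale_features
from .metrics import kfold_indices, r_squared, rmse

logger = logging.getLogger(__name__)

METHODS = ("anfis", "lvq1_anfis", "olvq1_anfis")


@dataclass
class CombinedModel:
    """An LVQ codebook plus one trained ANFIS expert per surviving cluster.

    ``route`` maps every prototype index to the expert key that serves its
    Voronoi cell (merged clusters point at their merge target).
    """

    lvq_model: lvq.LVQModel
    experts: dict
    route: dict
    scaler: Scaler | None = None
    target_name: str | None = None


def _extract(data, target):
    if isinstance(data, FeatureTable):
        return data.features, data.target(target)
    X, y = data
    return np.atleast_2d(np.asarray(X, float)), np.asarray(y, float)


def _effective_anfis_cfg(cfg: anfis.ANFISConfig, p: int) -> anfis.ANFISConfig:
    if cfg.rule_generation == "grid" and p > cfg.max_grid_inputs:
        logger.warning(
            "grid partition infeasible for %d inputs (%d rules); "
            "falling back to scatter partitioning", p, cfg.mfs_per_input ** p)
        return replace(cfg, rule_generation="scatter")
    return cfg


def _rule_count(cfg: anfis.ANFISConfig, p: int) -> int:
    if cfg.rule_generation == "grid":
        return cfg.mfs_per_input ** p
    return cfg.scatter_rules


def _adapt_to_cluster(cfg: anfis.ANFISConfig, n_rows: int,
                      p: int) -> anfis.ANFISConfig:
    """Shrink an expert's partition until the consequent solve is well posed.

    The least-squares stage estimates R*(p+1) coefficients; an expert keeps
    the configured granularity only when it has at least ten rows per
    coefficient (the usual one-in-ten sizing rule), otherwise membership
    functions (or scatter rules) are reduced, bottoming out at a single
    rule — a plain local linear model.
    """
    def ok(rules):
        return 10 * rules * (p + 1) <= n_rows

    if cfg.rule_generation == "grid":
        m = cfg.mfs_per_input
        while m > 1 and not ok(m ** p):
            m -= 1
        if m != cfg.mfs_per_input:
            logger.info("cluster with %d rows: grid reduced to %d MFs/input",
                        n_rows, m)
        return cfg if m == cfg.mfs_per_input else replace(cfg, mfs_per_input=m)
    R = cfg.scatter_rules
    while R > 1 and not ok(R):
        R -= 1
    return cfg if R == cfg.scatter_rules else replace(cfg, scatter_rules=R)


def fit_combined(data, lvq_cfg: lvq.LVQConfig, anfis_cfg: anfis.ANFISConfig,
                 target: str | None = None, min_cluster_size: int | None = None,
                 scale: str = "none") -> CombinedModel:
    """Cluster the rows, then train one ANFIS expert per (merged) cluster."""
    X, y = _extract(data, target)
    scaler = None
    if scale != "none":
        tbl = FeatureTable(X, y, [f"f{i}" for i in range(X.shape[1])], ["y"])
        tbl, scaler = scale_features(tbl, scale)
        X = tbl.features
    p = X.shape[1]
    anfis_cfg = _effective_anfis_cfg(anfis_cfg, p)
    if min_cluster_size is None:
        min_cluster_size = max(30, 3 * _rule_count(anfis_cfg, p))

    model = lvq.fit(X, lvq_cfg)
    assignments, sizes = lvq.assign_clusters(model, X)
    if X.shape[0] < min_cluster_size:
        raise ValueError(
            f"all clusters below the minimum expert size {min_cluster_size}")

    # merge undersized clusters into their nearest surviving neighbour
    groups = {j: [j] for j in range(model.J) if sizes[j] > 0}
    gsize = {j: int(sizes[j]) for j in groups}
    while len(groups) > 1 and min(gsize.values()) < min_cluster_size:
        small = min(gsize, key=lambda j: (gsize[j], j))
        others = [j for j in groups if j != small]
        dists = [np.min([
            np.linalg.norm(model.prototypes[a] - model.prototypes[b])
            for a in groups[small] for b in groups[j]]) for j in others]
        tgt = others[int(np.argmin(dists))]
        groups[tgt] += groups[small]
        gsize[tgt] += gsize[small]
        del groups[small], gsize[small]

    route = {}
    for leader, members in groups.items():
        for m in members:
            route[m] = leader
    # empty clusters route to the nearest surviving prototype
    leaders = list(groups)
    for j in range(model.J):
        if j not in route:
            d = [np.linalg.norm(model.prototypes[j] - model.prototypes[l])
                 for l in leaders]
            route[j] = leaders[int(np.argmin(d))]

    experts = {}
    for leader, members in sorted(groups.items()):
        rows = np.isin(assignments, members)
        cfg = replace(anfis_cfg, seed=(anfis_cfg.seed + leader) % (2**31))
        cfg = _adapt_to_cluster(cfg, int(rows.sum()), p)
        experts[leader] = anfis.fit_hybrid(X[rows], y[rows], cfg)
    return CombinedModel(model, experts, route, scaler=scaler,
                         target_name=target)


def predict_combined(model: CombinedModel, X, missing: str = "raise") -> np.ndarray:
    """Route each query to its nearest prototype's expert and evaluate it.

    ``missing="nan"`` returns NaN for queries outside an expert's membership
    support instead of raising.
    """
    X = np.atleast_2d(np.asarray(getattr(X, "features", X), float))
    if not np.all(np.isfinite(X)):
        raise ValueError("queries must be finite")
    if model.scaler is not None:
        X = model.scaler.transform(X)
    assignments, _ = lvq.assign_clusters(model.lvq_model, X)
    out = np.full(X.shape[0], np.nan)
    for j in np.unique(assignments):
        expert = model.experts[model.route[int(j)]]
        rows = assignments == j
        try:
            out[rows] = anfis.predict(expert, X[rows])
        except anfis.DegenerateCoverageError:
            if missing == "raise":
                raise anfis.DegenerateCoverageError(
                    f"degenerate coverage in expert of cluster {int(j)}")
            for i in np.flatnonzero(rows):       # salvage covered rows
                try:
                    out[i] = anfis.predict(expert, X[i:i + 1])[0]
                except anfis.DegenerateCoverageError:
                    pass
    return out


@dataclass
class EvalReport:
    """Per-fold and averaged metrics for one method on one target."""

    method: str
    target: str
    fold_rmse: list
    fold_r2: list
    n_failures: int = 0
    per_cluster: dict | None = None
    mean_rmse: float = field(init=False)
    mean_r2: float = field(init=False)

    def __post_init__(self):
        self.mean_rmse = float(np.mean(self.fold_rmse))
        self.mean_r2 = float(np.mean(self.fold_r2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "method": self.method, "target": self.target,
            "RMSE": self.mean_rmse, "R2": self.mean_r2,
            "folds": len(self.fold_rmse), "failures": self.n_failures,
        }])


def make_fitter(spec: dict):
    """Turn a declarative method spec into a (name, fit_fn) pair.

    ``fit_fn(X, y) -> predict_fn`` where ``predict_fn(X, missing)`` returns
    predictions (NaN marks uncovered rows when missing="nan").
    """
    method = spec["method"]
    name = spec.get("name", method)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    anfis_cfg = spec.get("anfis", anfis.ANFISConfig())
    if method == "anfis":
        def fit_fn(X, y):
            cfg = _effective_anfis_cfg(anfis_cfg, X.shape[1])
            model = anfis.fit_hybrid(X, y, cfg)

            def predict_fn(Xq, missing="raise"):
                if missing == "nan":
                    out = np.full(len(Xq), np.nan)
                    for i in range(len(Xq)):
                        try:
                            out[i] = anfis.predict(model, Xq[i:i + 1])[0]
                        except anfis.DegenerateCoverageError:
                            pass
                    return out
                return anfis.predict(model, Xq)
            predict_fn.model = model
            return predict_fn
        return name, fit_fn

    base_lvq = spec.get("lvq", lvq.LVQConfig())
    mode = "unsupervised_vq" if method == "olvq1_anfis" else "unsupervised_vq_global"
    lvq_cfg = replace(base_lvq, mode=mode)

    def fit_fn(X, y):
        model = fit_combined((X, y), lvq_cfg, anfis_cfg,
                             min_cluster_size=spec.get("min_cluster_size"))

        def predict_fn(Xq, missing="raise"):
            return predict_combined(model, Xq, missing=missing)
        predict_fn.model = model
        return predict_fn
    return name, fit_fn


def crossvalidate(data, method, k: int = 10, seed: int = 0,
                  target: str | None = None, folds=None) -> EvalReport:
    """Seeded k-fold evaluation: refit the whole pipeline on each train part.

    ``method`` is a declarative spec dict (see :func:`make_fitter`) or a
    ready-made (name, fit_fn) pair. Rows a fold's model cannot cover are
    counted as failures and excluded from that fold's metrics.
    """
    X, y = _extract(data, target)
    name, fit_fn = method if isinstance(method, tuple) else make_fitter(method)
    folds = folds if folds is not None else kfold_indices(len(y), k, seed)
    fold_rmse, fold_r2, failures = [], [], 0
    cluster_resid: dict = {}
    for test_idx in folds:
        mask = np.ones(len(y), bool)
        mask[test_idx] = False
        predict_fn = fit_fn(X[mask], y[mask])
        preds = predict_fn(X[test_idx], missing="nan")
        ok = np.isfinite(preds)
        failures += int((~ok).sum())
        fold_rmse.append(rmse(y[test_idx][ok], preds[ok]))
        fold_r2.append(r_squared(y[test_idx][ok], preds[ok]))
        model = getattr(predict_fn, "model", None)
        if isinstance(model, CombinedModel):
            assign, _ = lvq.assign_clusters(model.lvq_model, X[test_idx])
            for j in np.unique(assign):
                key = model.route[int(j)]
                rows = (assign == j) & ok
                cluster_resid.setdefault(key, []).extend(
                    (y[test_idx][rows] - preds[rows]).tolist())
    per_cluster = None
    if cluster_resid:
        per_cluster = {int(j): float(np.sqrt(np.mean(np.square(r))))
                       for j, r in sorted(cluster_resid.items())}
    return EvalReport(method=name, target=target or "y",
                      fold_rmse=fold_rmse, fold_r2=fold_r2,
                      n_failures=failures, per_cluster=per_cluster)


def compare_methods(data, specs: list, k: int = 10, seed: int = 0,
                    target: str | None = None) -> list[EvalReport]:
    """Evaluate several method specs on identical folds (paired comparison)."""
    X, y = _extract(data, target)
    folds = kfold_indices(len(y), k, seed)
    return [crossvalidate((X, y), spec, k=k, seed=seed,
                          target=target, folds=folds) for spec in specs]


def report_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Stack reports into a comparison table (method, target, RMSE, R2)."""
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)
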