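"""Reading, writing and summarising telemonitoring-style feature tables.

The reference dialect is the UCI Parkinsons Telemonitoring CSV: one row per
voice recording with subject metadata, two continuous UPDRS targets and 16
dysphonia measures. Any delimited file with a header can be read by supplying
a custom column dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Logical-role -> column-name mapping for the UCI header.
UCI_DIALECT: dict = {
    "subject_id": "subject#",
    "age": "age",
    "sex": "sex",
    "test_time": "test_time",
    "motor": "motor_UPDRS",
    "total": "total_UPDRS",
    "features": [
        "Jitter(%)", "Jitter(Abs)", "Jitter:RAP", "Jitter:PPQ5", "Jitter:DDP",
        "Shimmer", "Shimmer(dB)", "Shimmer:APQ3", "Shimmer:APQ5",
        "Shimmer:APQ11", "Shimmer:DDA", "NHR", "HNR", "RPDE", "DFA", "PPE",
    ],
}


class FormatError(ValueError):
    """The file does not match the declared column dialect."""


class ParseError(ValueError):
    """A numeric column contains a non-numeric cell."""


@dataclass
class FeatureTable:
    """In-memory exchange object: feature matrix, target(s) and row metadata.

    ``targets`` is ``(n,)`` for a single target or ``(n, t)`` with matching
    ``target_names``. Rows are kept in file order.
    """

    features: np.ndarray
    targets: np.ndarray
    feature_names: list[str]
    target_names: list[str]
    subject_id: np.ndarray = field(default=None)
    age: np.ndarray = field(default=None)
    sex: np.ndarray = field(default=None)
    test_time: np.ndarray = field(default=None)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValueError("FeatureTable needs n > 0 rows and d > 0 features")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature_names must be unique and match d")
        if self.targets.shape[0] != n:
            raise ValueError("targets length must equal number of rows")
        if self.targets.ndim == 2 and self.targets.shape[1] != len(self.target_names):
            raise ValueError("target_names must match target columns")
        for name in ("subject_id", "age", "sex", "test_time"):
            v = getattr(self, name)
            if v is None:
                setattr(self, name, np.zeros(n))
            elif len(np.asarray(v)) != n:
                raise ValueError(f"{name} length must equal number of rows")
            else:
                setattr(self, name, np.asarray(v))

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def target(self, name: str | None = None) -> np.ndarray:
        """Return a single target column as a flat vector."""
        if self.targets.ndim == 1:
            return self.targets
        if name is None:
            raise ValueError(f"table has targets {self.target_names}; pick one")
        return self.targets[:, self.target_names.index(name)]

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            features=self.features[idx],
            targets=self.targets[idx],
            feature_names=list(self.feature_names),
            target_names=list(self.target_names),
            subject_id=self.subject_id[idx],
            age=self.age[idx],
            sex=self.sex[idx],
            test_time=self.test_time[idx],
        )


def load_table(path, dialect: dict | None = None, target: str = "both",
               delimiter: str = ",") -> FeatureTable:
    """Read a delimited telemonitoring-style file into a :class:`FeatureTable`.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.
    dialect : dict, optional
        Role -> column-name mapping (see :data:`UCI_DIALECT`, the default).
    target : {"motor", "total", "both"}
        Which UPDRS column(s) to expose as the regression target.
    """
    dialect = dialect or UCI_DIALECT
    df = pd.read_csv(path, sep=delimiter)
    df.columns = [c.strip() for c in df.columns]

    wanted = [dialect[k] for k in ("subject_id", "age", "sex", "test_time")]
    if target in ("motor", "both"):
        wanted.append(dialect["motor"])
    if target in ("total", "both"):
        wanted.append(dialect["total"])
    if target not in ("motor", "total", "both"):
        raise ValueError(f"unknown target {target!r}")
    wanted += list(dialect["features"])
    for col in wanted:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")

    numeric_cols = list(dialect["features"])
    if target in ("motor", "both"):
        numeric_cols.append(dialect["motor"])
    if target in ("total", "both"):
        numeric_cols.append(dialect["total"])
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row}")
        df[col] = coerced

    missing = df[wanted].isna().any(axis=1)
    if missing.any():
        dropped = np.flatnonzero(missing.to_numpy()).tolist()
        logger.warning("dropping %d rows with missing cells: %s",
                       len(dropped), dropped[:20])
        df = df.loc[~missing]
    if len(df) == 0:
        raise ValueError("no complete rows remain after missing-value filter")

    if target == "both":
        targets = df[[dialect["motor"], dialect["total"]]].to_numpy(float)
        target_names = ["motor", "total"]
    else:
        targets = df[dialect[target]].to_numpy(float)
        target_names = [target]

    return FeatureTable(
        features=df[dialect["features"]].to_numpy(float),
        targets=targets,
        feature_names=list(dialect["features"]),
        target_names=target_names,
        subject_id=df[dialect["subject_id"]].to_numpy(),
        age=df[dialect["age"]].to_numpy(),
        sex=df[dialect["sex"]].to_numpy(),
        test_time=df[dialect["test_time"]].to_numpy(),
    )


def write_table(table: FeatureTable, path, dialect: dict | None = None,
                delimiter: str = ",") -> None:
    """Write a FeatureTable back out in the (default UCI) dialect."""
    dialect = dialect or UCI_DIALECT
    cols = {
        dialect["subject_id"]: table.subject_id,
        dialect["age"]: table.age,
        dialect["sex"]: table.sex,
        dialect["test_time"]: table.test_time,
    }
    if table.targets.ndim == 1:
        cols[dialect[table.target_names[0]]] = table.targets
    else:
        for j, name in enumerate(table.target_names):
            cols[dialect[name]] = table.targets[:, j]
    for j, name in enumerate(table.feature_names):
        cols[name] = table.features[:, j]
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)


def summarize(table: FeatureTable) -> pd.DataFrame:
    """Per-feature min / max / mean / sd descriptive statistics.

    The standard deviation uses the sample convention (n-1 denominator).
    """
    if table.n < 2:
        raise ValueError("sd is undefined for n < 2")
    X = table.features
    return pd.DataFrame(
        {
            "Min": X.min(axis=0),
            "Max": X.max(axis=0),
            "Mean": X.mean(axis=0),
            "SD": X.std(axis=0, ddof=1),
        },
        index=table.feature_names,
    )


@dataclass
class Scaler:
    """Invertible per-feature scaler (z-score or min-max)."""

    method: str
    shift: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.shift) / self.scale

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) * self.scale + self.shift

    def to_dict(self) -> dict:
        return {"method": self.method,
                "shift": self.shift.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(d["method"], np.asarray(d["shift"], float),
                   np.asarray(d["scale"], float))


def scale_features(table: FeatureTable, method: str = "none"):
    """Return a (scaled table, fitted scaler) pair. ``none`` is the identity."""
    X = table.features
    if method == "none":
        scaler = Scaler("none", np.zeros(table.d), np.ones(table.d))
    elif method == "zscore":
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance feature under zscore: {table.feature_names[zero[0]]!r}")
        scaler = Scaler("zscore", X.mean(axis=0), sd)
    elif method == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        rng = hi - lo
        rng = np.where(rng == 0, 1.0, rng)
        scaler = Scaler("minmax", lo, rng)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return replace(table, features=scaler.transform(X)), scaler
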