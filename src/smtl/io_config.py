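"""Feature-table I/O, experiment configuration, and reproducible randomness.

The pipeline starts from a samples-by-features numeric table with a binary
class label per sample and a per-feature modality tag (e.g. "MRI", "PET",
"CSF").  This module loads and validates that table, fits/applies per-feature
z-scoring with training-fold statistics only, and derives named random
substreams from a single master seed so that every stage is reproducible in
isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class TableFormatError(ValueError):
    """Raised when a feature table file violates the expected layout."""


class ConfigurationError(ValueError):
    """Raised for inconsistent configuration (e.g. unmapped features)."""


# ---------------------------------------------------------------------------
# Randomness plumbing


def component_rng(master_seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from the master seed.

    The component name is hashed (CRC32, stable across platforms and runs)
    into a spawn key, so each named stage draws from an independent stream
    and can be reproduced without running the stages before it.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


def component_seed(master_seed: int, name: str) -> int:
    """A 31-bit integer seed for APIs that take plain int seeds."""
    return int(component_rng(master_seed, name).integers(2**31))


# ---------------------------------------------------------------------------
# Feature table


@dataclass
class FeatureTable:
    """N samples by D features with binary labels and modality tags.

    ``labels`` take values in {+1, -1}; ``modality_of`` maps each feature
    index to its modality name.
    """

    sample_ids: list[str]
    X: np.ndarray
    labels: np.ndarray
    modality_of: dict[int, str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.X.shape
        if n < 2:
            raise TableFormatError(f"need at least 2 samples, got {n}")
        if d < 1:
            raise TableFormatError("need at least 1 feature")
        if len(self.sample_ids) != n:
            raise TableFormatError("sample_ids length mismatch")
        if len(self.feature_names) != d:
            raise TableFormatError("feature_names length mismatch")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise TableFormatError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        vals = set(np.unique(self.labels).tolist())
        if vals != {-1, 1}:
            raise TableFormatError(
                f"labels must contain both +1 and -1, got {sorted(vals)}"
            )
        if set(self.modality_of) != set(range(d)):
            missing = sorted(set(range(d)) - set(self.modality_of))
            raise ConfigurationError(
                f"features without a modality tag: {missing[:5]}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {+1: int((self.labels == 1).sum()), -1: int((self.labels == -1).sum())}

    def modality_indices(self) -> dict[str, np.ndarray]:
        """Feature indices grouped by modality, preserving column order."""
        out: dict[str, list[int]] = {}
        for j in range(self.n_features):
            out.setdefault(self.modality_of[j], []).append(j)
        return {m: np.asarray(idx, dtype=int) for m, idx in out.items()}

    def subset_samples(self, index: np.ndarray) -> "FeatureTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in index],
            X=self.X[index],
            labels=self.labels[index],
            modality_of=dict(self.modality_of),
            feature_names=list(self.feature_names),
        )

    def subset_features(self, index: np.ndarray) -> "FeatureTable":
        index = np.asarray(index, dtype=int)
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            X=self.X[:, index],
            labels=self.labels.copy(),
            modality_of={k: self.modality_of[j] for k, j in enumerate(index)},
            feature_names=[self.feature_names[j] for j in index],
        )

    def restrict_modalities(self, modalities: list[str]) -> "FeatureTable":
        """Keep only features of the given modalities (concatenated in
        original column order)."""
        keep = [j for j in range(self.n_features) if self.modality_of[j] in modalities]
        if not keep:
            raise ConfigurationError(f"no features in modalities {modalities}")
        return self.subset_features(np.asarray(keep))


def _read_modality_map(modality_map, feature_names: list[str]) -> dict[int, str]:
    if isinstance(modality_map, (str, Path)):
        p = Path(modality_map)
        if p.suffix.lower() == ".json":
            by_name = json.loads(p.read_text())
        else:
            df = pd.read_csv(p)
            if df.shape[1] != 2:
                raise ConfigurationError(
                    "modality map CSV must have exactly two columns "
                    "(feature, modality)"
                )
            by_name = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    else:
        by_name = dict(modality_map)
    out = {}
    for j, name in enumerate(feature_names):
        if name not in by_name:
            raise ConfigurationError(f"feature {name!r} missing from modality map")
        out[j] = str(by_name[name])
    return out


def load_feature_table(
    path,
    modality_map,
    label_column: str = "label",
    sample_id_column: str | None = "sample_id",
    positive_class=None,
) -> FeatureTable:
    """Load a CSV/TSV feature table and map its labels to {+1, -1}.

    ``positive_class`` names the label value mapped to +1 (by convention the
    disease-ward class of the comparison, e.g. AD in AD vs. NC).  When
    ``None``, the first label value encountered in file order is positive.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if label_column not in df.columns:
        raise TableFormatError(f"label column {label_column!r} not in header")
    if sample_id_column is not None and sample_id_column in df.columns:
        sample_ids = df[sample_id_column].astype(str).tolist()
        df = df.drop(columns=[sample_id_column])
    else:
        sample_ids = [f"s{i}" for i in range(len(df))]

    raw_labels = df[label_column]
    df = df.drop(columns=[label_column])
    feature_names = [str(c) for c in df.columns]

    for col in feature_names:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"missing or non-numeric cell at row {row} "
                f"(sample {sample_ids[row]!r}), column {col!r}"
            )
        df[col] = numeric

    uniq = list(dict.fromkeys(raw_labels.tolist()))  # file order, de-duplicated
    if len(uniq) != 2:
        raise TableFormatError(
            f"label column must have exactly two distinct values, got {uniq}"
        )
    if positive_class is None:
        positive_class = uniq[0]
    if positive_class not in uniq:
        # tolerate string/number mismatches coming from CLI flags
        by_str = {str(u): u for u in uniq}
        if str(positive_class) in by_str:
            positive_class = by_str[str(positive_class)]
        else:
            raise ConfigurationError(
                f"positive class {positive_class!r} not among labels {uniq}"
            )
    labels = np.where(raw_labels.to_numpy() == positive_class, 1, -1)

    modality_of = _read_modality_map(modality_map, feature_names)
    return FeatureTable(sample_ids, df.to_numpy(dtype=float), labels,
                        modality_of, feature_names)


def write_feature_table(
    table: FeatureTable,
    path,
    modality_path=None,
    label_names: dict[int, str] | None = None,
) -> None:
    """Write a table as CSV/TSV (plus an optional JSON modality sidecar)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.DataFrame(table.X, columns=table.feature_names)
    df.insert(0, "sample_id", table.sample_ids)
    if label_names is None:
        df["label"] = table.labels
    else:
        df["label"] = [label_names[int(v)] for v in table.labels]
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    if modality_path is not None:
        by_name = {table.feature_names[j]: m for j, m in table.modality_of.items()}
        Path(modality_path).write_text(json.dumps(by_name, indent=1))


# ---------------------------------------------------------------------------
# Standardization (training-fold statistics only)


@dataclass
class Standardizer:
    mean_: np.ndarray
    scale_: np.ndarray


def zscore_fit(X_train: np.ndarray) -> Standardizer:
    """Fit per-feature mean and scale on training rows.

    Constant columns get scale 1 so they pass through centered without a
    division error.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return Standardizer(mean_=mean, scale_=scale)


def zscore_apply(std: Standardizer, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != std.mean_.shape[0]:
        raise ValueError(
            f"dimension mismatch: standardizer fitted on {std.mean_.shape[0]} "
            f"features, got {X.shape[1]}"
        )
    return (X - std.mean_) / std.scale_


# ---------------------------------------------------------------------------
# Experiment configuration


_DEFAULT_LAMBDA_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5)


@dataclass
class ExperimentConfig:
    """Hyperparameter grids and protocol settings for the nested-CV pipeline.

    Defaults are the published protocol: K in 1..5 subclasses per class, SVM
    soft margin C in {2^-10 .. 2^5}, nine-point sparsity grids, 10 outer and
    5 inner stratified folds, and a 0.1 step for the multi-kernel modality
    weight lattice.  Sparsity values are interpreted as fractions of the
    training set's critical penalty (the smallest penalty that zeroes every
    weight), which makes one grid meaningful across data scales.
    """

    K_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    C_grid: tuple[float, ...] = tuple(2.0**p for p in range(-10, 6))
    lambda1_grid: tuple[float, ...] = _DEFAULT_LAMBDA_GRID
    lambda2_grid: tuple[float, ...] = _DEFAULT_LAMBDA_GRID
    n_outer_folds: int = 10
    n_inner_folds: int = 5
    modality_weight_step: float = 0.1
    master_seed: int = 0
    selection_tolerance: float = 1e-6
    max_iter: int = 1000
    rel_tol: float = 1e-6
    standardize: bool = True
    independent_K: bool = False  # search K(+) and K(-) separately if True

    def __post_init__(self) -> None:
        for name in ("K_grid", "C_grid", "lambda1_grid", "lambda2_grid"):
            vals = tuple(getattr(self, name))
            setattr(self, name, vals)
            if not vals or any(v <= 0 for v in vals):
                raise ConfigurationError(f"{name} must be non-empty and positive")
        if not (0 < self.modality_weight_step <= 1):
            raise ConfigurationError("modality_weight_step must be in (0, 1]")
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ConfigurationError("need at least 2 folds at each level")

    @classmethod
    def reduced(cls, **overrides) -> "ExperimentConfig":
        """A small-grid configuration for desk-scale simulation studies:
        K in {1,2,3}, three sparsity values, three C values."""
        base = dict(
            K_grid=(1, 2, 3),
            lambda1_grid=(0.05, 0.15, 0.3),
            lambda2_grid=(0.05, 0.15, 0.3),
            C_grid=(0.25, 1.0, 4.0),
            rel_tol=1e-5,
            max_iter=500,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    def as_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d
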