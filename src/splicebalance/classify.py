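"""Randomized decision-tree classification of tumour samples.

Assesses the diagnostic information carried by each of four data types —
gene expression (GE), exon expression (EE), splicing index (SI), and the
SI of genes *not* differentially expressed between the classes
(SI_nonDE, which isolates pure splicing information) — by repeatedly
(default 1000 iterations) drawing a random feature subset, splitting the
samples 2/3 train : 1/3 test, fitting a binary decision tree and scoring
sensitivity (positive-class recall) and specificity (negative-class
recall) on the held-out third.

Splits are stratified by class: with very small negative groups (e.g.
9 normal-tissue samples) an unstratified one-third test fold frequently
contains no negatives, leaving specificity undefined.  Iterations whose
test fold still lacks a class are redrawn and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DataError

DATA_TYPES = ("GE", "EE", "SI", "SI_nonDE")


@dataclass
class ClassificationConfig:
    data_type: str = "SI"
    n_features_grid: list[int] = field(default_factory=lambda: [10, 100, 1000])
    n_iterations: int = 1000
    train_fraction: float = 2.0 / 3.0
    positive_label: str = "basal"
    seed: int = 0

    def validate(self):
        if self.data_type not in DATA_TYPES:
            raise ConfigurationError(f"unknown data_type {self.data_type!r}")
        if any(n < 1 for n in self.n_features_grid):
            raise ConfigurationError("n_features must be positive")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must be in (0, 1)")


def build_si_nonDE_features(
    si_matrix: pd.DataFrame,
    ge_table: pd.DataFrame,
    annotation: pd.DataFrame,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Restrict an SI matrix to probes of non-differentially-expressed genes.

    Keeps probes whose gene has GE q-value greater than ``q_threshold``
    (i.e. no evidence of whole-gene differential expression between the
    classes), so the remaining features carry splicing information only.
    """
    gene_of = annotation.loc[si_matrix.index, "gene_id"]
    missing = set(gene_of) - set(ge_table.index)
    if missing:
        raise DataError(f"genes missing from GE table: {sorted(missing)[:10]}")
    non_de = set(ge_table.index[ge_table["q"] > q_threshold])
    keep = gene_of.isin(non_de)
    if not keep.any():
        raise DataError(
            "no probes left after the non-DE filter; raise q_threshold or check inputs"
        )
    return si_matrix.loc[keep]


def _stratified_split(labels: np.ndarray, train_fraction: float, rng):
    """Per-class random 2/3-1/3 split; returns (train_idx, test_idx)."""
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.asarray(train), np.asarray(test)


def run_classification_experiment(
    matrix: pd.DataFrame,
    labels,
    config: ClassificationConfig,
) -> pd.DataFrame:
    """Run the randomized-tree experiment over the feature-count grid.

    Per iteration: draw ``n`` features uniformly without replacement,
    stratified train/test split, fit an unpruned CART tree (Gini
    impurity, minimum leaf size 2), and score the held-out samples.
    Returns one summary row per ``n`` with mean sensitivity/specificity
    and normal-approximation 95% confidence intervals over iterations.
    """
    config.validate()
    y = pd.Series(np.asarray(labels), index=matrix.columns)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise DataError(f"two-class labels required, got {classes}")
    if config.positive_label not in classes:
        raise ConfigurationError(f"positive_label {config.positive_label!r} not in labels")
    y_bin = (y == config.positive_label).to_numpy()
    values = matrix.to_numpy(dtype=float).T  # samples x features
    n_feat_avail = values.shape[1]
    rng = np.random.default_rng(config.seed)

    rows = []
    for n_features in config.n_features_grid:
        if n_features > n_feat_avail:
            raise ConfigurationError(
                f"n_features={n_features} exceeds available features ({n_feat_avail})"
            )
        sens = np.empty(config.n_iterations)
        spec = np.empty(config.n_iterations)
        redraws = 0
        it = 0
        while it < config.n_iterations:
            feats = rng.choice(n_feat_avail, size=n_features, replace=False)
            train, test = _stratified_split(y_bin, config.train_fraction, rng)
            y_test = y_bin[test]
            if y_test.all() or not y_test.any():
                redraws += 1
                continue
            tree = DecisionTreeClassifier(
                criterion="gini",
                min_samples_leaf=2,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(values[np.ix_(train, feats)], y_bin[train])
            pred = tree.predict(values[np.ix_(test, feats)])
            sens[it] = np.mean(pred[y_test])
            spec[it] = np.mean(~pred[~y_test])
            it += 1
        half_s = 1.96 * sens.std(ddof=1) / np.sqrt(config.n_iterations)
        half_p = 1.96 * spec.std(ddof=1) / np.sqrt(config.n_iterations)
        rows.append(
            {
                "data_type": config.data_type,
                "n_features": n_features,
                "iterations": config.n_iterations,
                "redraws": redraws,
                "sensitivity_mean": sens.mean(),
                "sensitivity_ci_lo": sens.mean() - half_s,
                "sensitivity_ci_hi": sens.mean() + half_s,
                "specificity_mean": spec.mean(),
                "specificity_ci_lo": spec.mean() - half_p,
                "specificity_ci_hi": spec.mean() + half_p,
            }
        )
    return pd.DataFrame(rows)
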