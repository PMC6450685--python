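"""Nine-way Gaussian Naive Bayes population decoding with column-normalized
confusion matrices and the diagonal-significance test.

The decoder is written from scratch (per-class feature means and variances,
log-posterior argmax with ties broken by fixed panel order); scikit-learn
serves only as an independent cross-check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .ensembles import RESPONSE_WINDOW
from .stats import benjamini_hochberg, wilcoxon_signed_rank
from .types import TrialTensor

__all__ = [
    "GaussianNBModel", "fit_gaussian_nb", "trial_features",
    "cross_validated_confusion", "ConfusionMatrix", "diagonal_significance",
]

_VAR_FLOOR_REL = 1e-6


@dataclass
class GaussianNBModel:
    classes: tuple[str, ...]
    means: np.ndarray        # classes x features
    variances: np.ndarray    # classes x features (floored)
    priors: np.ndarray       # classes

    def log_posterior(self, x: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior, samples x classes."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        ll = -0.5 * (np.log(2.0 * np.pi * self.variances)[None, :, :]
                     + (x[:, None, :] - self.means[None, :, :]) ** 2
                     / self.variances[None, :, :]).sum(axis=2)
        return ll + np.log(self.priors)[None, :]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class labels; argmax ties resolve to the earliest class in
        ``classes`` (fixed panel order)."""
        lp = self.log_posterior(x)
        return np.asarray(self.classes)[np.argmax(lp, axis=1)]


def fit_gaussian_nb(features: np.ndarray, labels,
                    class_order: tuple[str, ...] | None = None) -> GaussianNBModel:
    """Per-class Gaussian fit with a variance floor of 1e-6 x pooled variance."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = tuple(class_order) if class_order is not None \
        else tuple(dict.fromkeys(y.tolist()))
    means, variances, priors = [], [], []
    pooled = float(np.mean(x.var(axis=0))) if x.size else 1.0
    floor = max(_VAR_FLOOR_REL * pooled, 1e-12)
    for c in classes:
        rows = x[y == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has {rows.shape[0]} trials; need >= 2")
        means.append(rows.mean(axis=0))
        variances.append(np.maximum(rows.var(axis=0), floor))
        priors.append(rows.shape[0] / x.shape[0])
    return GaussianNBModel(classes=classes, means=np.array(means),
                           variances=np.array(variances), priors=np.array(priors))


def trial_features(tensor: TrialTensor,
                   response_window: tuple[float, float] = RESPONSE_WINDOW
                   ) -> np.ndarray:
    """Decoder features: per-trial mean response-window z per neuron."""
    if not tensor.zscored:
        raise ValueError("trial_features expects a z-scored TrialTensor")
    sl = tensor.frames_for(*response_window)
    return tensor.values[:, :, sl].mean(axis=2)


@dataclass
class ConfusionMatrix:
    """Rows = decoded label, columns = actual label, entries in % with every
    column summing to 100."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    session_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix must be square over the labels")
        if np.any(m < 0):
            raise ValueError("confusion entries must be >= 0")
        sums = m.sum(axis=0)
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError("columns must each sum to 100%")
        self.matrix = m

    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))


def _stratified_folds(labels: np.ndarray, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold id per trial; each class's trials are shuffled and dealt
    round-robin so every fold sees every class."""
    folds = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ValueError(f"class {c!r} has {idx.size} trials; need >= {k} folds")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def cross_validated_confusion(tensor: TrialTensor, k_folds: int = 5,
                              n_repeats: int = 10, seed: int = 0,
                              class_order: tuple[str, ...] | None = None,
                              response_window: tuple[float, float] = RESPONSE_WINDOW,
                              session_id: str = "") -> ConfusionMatrix:
    """Stratified k-fold (x repeats) Gaussian NB decoding of the stimulus
    panel; held-out prediction counts are column-normalized to percent."""
    x = trial_features(tensor, response_window)
    y = np.asarray(tensor.trial_labels)
    classes = tuple(class_order) if class_order is not None \
        else tuple(dict.fromkeys(y.tolist()))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    rng = substream(seed, "decoder", session_id)
    for rep in range(n_repeats):
        folds = _stratified_folds(y, k_folds, rng)
        for k in range(k_folds):
            test = folds == k
            model = fit_gaussian_nb(x[~test], y[~test], class_order=classes)
            pred = model.predict(x[test])
            for p, a in zip(pred, y[test]):
                counts[index[p], index[a]] += 1
    col = counts.sum(axis=0)
    if np.any(col == 0):
        raise ValueError("a class received no held-out predictions")
    return ConfusionMatrix(matrix=100.0 * counts / col[None, :], labels=classes,
                           session_id=session_id)


def diagonal_significance(confusions: list[ConfusionMatrix],
                          q: float = 0.05) -> pd.DataFrame:
    """Fig-style diagonal test: for every actual-stimulus column, paired
    one-sided Wilcoxon signed-rank of the diagonal entry against each
    off-diagonal entry across sessions, BH-corrected over all comparisons;
    a column is significant iff all its comparisons reject.

    Returns one row per (column, off-diagonal row) comparison plus the
    per-column verdict in ``column_significant``.
    """
    if len(confusions) < 5:
        raise ValueError(f"need >= 5 session confusion matrices, got {len(confusions)}")
    labels = confusions[0].labels
    if any(c.labels != labels for c in confusions):
        raise ValueError("confusion matrices must share a label order")
    stack = np.stack([c.matrix for c in confusions])     # sessions x rows x cols
    rows = []
    pvals = []
    for j, col_label in enumerate(labels):
        diag = stack[:, j, j]
        for i, row_label in enumerate(labels):
            if i == j:
                continue
            res = wilcoxon_signed_rank(diag - stack[:, i, j], sided="one")
            rows.append({"column": col_label, "off_diagonal": row_label,
                         "statistic": res.statistic, "p_value": res.p_value})
            pvals.append(res.p_value)
    reject, adj = benjamini_hochberg(pvals, q)
    out = pd.DataFrame(rows)
    out["q_value"] = adj
    out["reject"] = reject
    verdict = out.groupby("column", sort=False)["reject"].all()
    out["column_significant"] = out["column"].map(verdict)
    return out
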