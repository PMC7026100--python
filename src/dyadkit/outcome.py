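"""Outcome classification: PCA + decision stump under leave-one-out.

The cohort is small (tens of dyads) and the feature table wide (21
hand-movement descriptors per camera/sequence plus 16 speech features),
so the classifier is deliberately minimal: features are mean-imputed and
z-scored, reduced by PCA to the smallest number of components reaching
the variance budget, and classified by a decision stump — a one-split
tree over a single (component) axis — evaluated by leave-one-out
cross-validation.  To avoid information leakage, imputation,
standardization, PCA and the stump are all refit inside every fold; a
config switch reproduces the laxer protocol of fitting PCA once.

Feature-level interpretation uses point-biserial Pearson correlations
of each *raw* feature with the binary class, ranked by |r| — the
machinery behind a "best features" table.

Usage follows the statsmodels pattern::

    model = DyadOutcomeModel(features_df, labels)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .config import RunConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class StandardizeTransform:
    """Training-fold means/SDs for imputation and z-scoring.

    Missing values are replaced by the training-fold mean; zero-variance
    features get SD 1 so they pass through centered.  Applying the
    transform to a held-out row uses training statistics only.
    """

    means: pd.Series
    sds: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        filled = table.fillna(self.means)
        return (filled - self.means) / self.sds


def impute_and_standardize(table: pd.DataFrame, training_rows=None
                           ) -> tuple[pd.DataFrame, StandardizeTransform]:
    """Fit the transform on ``training_rows`` and apply it to the table."""
    train = table if training_rows is None else table.loc[training_rows]
    if len(train) == 0:
        raise ValueError("empty training fold")
    means = train.mean()
    means = means.fillna(0.0)  # all-missing column: impute 0, SD 1
    sds = train.std(ddof=0)
    zero_var = ~(sds > 0)
    if zero_var.any():
        logger.info("zero-variance features: %s",
                    list(sds.index[zero_var.fillna(True)]))
    sds = sds.where(sds > 0, 1.0).fillna(1.0)
    transform = StandardizeTransform(means, sds)
    return transform.apply(table), transform


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAProjection:
    components: np.ndarray          # (k, d), orthonormal rows
    explained_variance: np.ndarray  # all d eigenvalues
    n_components: int
    mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.components.T


def fit_pca(X: np.ndarray, variance_kept: float = 0.95) -> PCAProjection:
    """PCA keeping the smallest k with cumulative explained variance
    at least ``variance_kept``.

    Components follow a deterministic sign convention: the
    largest-magnitude loading of each component is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    pca = PCA(n_components=None, svd_solver="full").fit(X)
    comps = pca.components_
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), variance_kept - 1e-12) + 1)
    k = min(k, comps.shape[0])
    return PCAProjection(components=comps[:k],
                         explained_variance=pca.explained_variance_,
                         n_components=k, mean=pca.mean_)


# ---------------------------------------------------------------------------
# decision stump


@dataclass(frozen=True)
class StumpModel:
    """Single-feature threshold classifier.

    ``polarity`` "greater" predicts class 1 where the feature exceeds
    the threshold; "lessOrEqual" predicts class 1 at or below it.  A
    degenerate fit (single-class training data, or no split beating the
    majority) falls back to the constant majority class.
    """

    feature: int
    threshold: float
    polarity: str               # "greater" | "lessOrEqual" | "constant"
    majority: int
    training_error: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.polarity == "constant":
            return np.full(X.shape[0], self.majority, dtype=int)
        v = X[:, self.feature]
        if self.polarity == "greater":
            return (v > self.threshold).astype(int)
        return (v <= self.threshold).astype(int)


_POLARITIES = ("greater", "lessOrEqual")


def fit_stump(X: np.ndarray, y: np.ndarray) -> StumpModel:
    """Exhaustive decision-stump search minimizing 0-1 training error.

    Candidate thresholds are midpoints of consecutive sorted distinct
    values of each feature.  Ties break toward the lower feature index,
    then the lower threshold, then the "greater" polarity, so the fit
    is fully reproducible.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    counts = np.bincount(y, minlength=2)
    majority = int(np.argmax(counts))
    best = StumpModel(feature=-1, threshold=np.nan, polarity="constant",
                      majority=majority, training_error=int(n - counts.max()))
    if counts.min() == 0:
        return best
    best_key = (best.training_error, d, np.inf, 2)
    for j in range(d):
        distinct = np.unique(X[:, j])
        if len(distinct) < 2:
            continue
        thresholds = (distinct[:-1] + distinct[1:]) / 2.0
        for thr in thresholds:
            above = X[:, j] > thr
            err_greater = int(np.sum(above != (y == 1)))
            for p_idx, (polarity, err) in enumerate(
                    zip(_POLARITIES, (err_greater, n - err_greater))):
                key = (err, j, thr, p_idx)
                if key < best_key:
                    best_key = key
                    best = StumpModel(feature=j, threshold=float(thr),
                                      polarity=polarity, majority=majority,
                                      training_error=err)
    return best


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassificationResult:
    """Per-dyad LOO predictions with the confusion matrix."""

    classes: tuple[str, str]
    predictions: pd.Series          # predicted class labels per dyad
    confusion_matrix: np.ndarray    # rows = true class, cols = predicted
    accuracy: float

    @property
    def n(self) -> int:
        return int(self.confusion_matrix.sum())


def _encode_labels(labels: pd.Series) -> tuple[np.ndarray, tuple[str, str]]:
    classes = tuple(sorted(pd.unique(labels.astype(str))))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y = (labels.astype(str) == classes[1]).to_numpy().astype(int)
    return y, classes


def loo_evaluate(table: pd.DataFrame, labels: pd.Series,
                 config: RunConfig | None = None) -> ClassificationResult:
    """Leave-one-out evaluation of the impute → z-score → PCA → stump chain.

    With the default ``pca_outside_loo=False`` every preprocessing step
    is refit on the n-1 training rows of each fold.  Row order does not
    affect the predictions.
    """
    config = config or RunConfig()
    if len(table) < 3:
        raise ValueError("need at least 3 dyads for leave-one-out")
    if config.drop_incomplete:
        keep = table.notna().all(axis=1)
        table, labels = table.loc[keep], labels.loc[keep]
    y, classes = _encode_labels(labels)
    n = len(table)

    shared_pca = shared_transform = None
    if config.pca_outside_loo:
        z_all, shared_transform = impute_and_standardize(table)
        shared_pca = fit_pca(z_all.to_numpy(), config.pca_variance_kept)

    preds = np.empty(n, dtype=int)
    for i in range(n):
        train_mask = np.ones(n, dtype=bool)
        train_mask[i] = False
        train_idx = table.index[train_mask]
        if config.pca_outside_loo:
            z = shared_transform.apply(table)
            proj = shared_pca
        else:
            z, transform = impute_and_standardize(table, train_idx)
            proj = fit_pca(z.loc[train_idx].to_numpy(),
                           config.pca_variance_kept)
        train_X = proj.transform(z.loc[train_idx].to_numpy())
        stump = fit_stump(train_X, y[train_mask])
        held = proj.transform(z.to_numpy()[[i]])
        preds[i] = int(stump.predict(held)[0])

    cm = np.zeros((2, 2), dtype=int)
    for yi, pi in zip(y, preds):
        cm[yi, pi] += 1
    accuracy = float(np.trace(cm)) / n
    predictions = pd.Series([classes[p] for p in preds], index=table.index,
                            name="predicted")
    return ClassificationResult(classes=classes, predictions=predictions,
                                confusion_matrix=cm, accuracy=accuracy)


def feature_class_correlations(table: pd.DataFrame, labels: pd.Series,
                               modality: dict[str, str] | None = None
                               ) -> list[dict]:
    """Point-biserial Pearson correlation of each raw feature with the class.

    Computed per feature over the rows where it is non-missing, with the
    two-sided p-value from the t-distribution; ranked by |r|.  Raw
    p-values are reported (matching a best-features table); a
    Benjamini-Hochberg column is added for reference.  Constant features
    are excluded.
    """
    y, classes = _encode_labels(labels)
    y = pd.Series(y, index=table.index)
    rows = []
    for feature in table.columns:
        v = table[feature]
        ok = v.notna()
        if ok.sum() < 3 or v[ok].nunique() < 2 or y[ok].nunique() < 2:
            logger.info("skipping constant/short feature %r", feature)
            continue
        r, p = sps.pearsonr(v[ok], y[ok])
        rows.append({"feature": feature, "r": float(r), "p": float(p),
                     "n": int(ok.sum()),
                     "modality": (modality or {}).get(feature, "")})
    rows.sort(key=lambda d: (-abs(d["r"]), d["feature"]))
    if rows:
        p_bh = sps.false_discovery_control([d["p"] for d in rows], method="bh")
        for d, q in zip(rows, p_bh):
            d["p_bh"] = float(q)
    return rows


def accuracy_from_counts(n_total: int, n_errors: int) -> float:
    """Accuracy percentage from error counts, to two decimals.

    51 dyads with 12 errors gives 76.47; 32 with 6 gives 81.25.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_errors <= n_total:
        raise ValueError("n_errors must lie in [0, n_total]")
    return round(100.0 * (n_total - n_errors) / n_total, 2)


# ---------------------------------------------------------------------------
# model / results objects


class DyadOutcomeModel:
    """Outcome classification model over a dyads-by-features table.

    Parameters
    ----------
    features : DataFrame
        One row per dyad, named feature columns, NaN = missing.
    labels : Series
        Binary group label per dyad (e.g. TD vs WS, or WS+ vs WS-).
    config : RunConfig, optional
    modality : dict, optional
        Feature name → modality tag ("Audio, infant", "Video, infant",
        ...) used in the report.
    """

    def __init__(self, features: pd.DataFrame, labels: pd.Series,
                 config: RunConfig | None = None,
                 modality: dict[str, str] | None = None):
        if len(features) != len(labels):
            raise ValueError("features and labels must align")
        if len(features) < 2 or features.shape[1] < 1:
            raise ValueError("need at least 2 dyads and 1 feature")
        self.features = features
        self.labels = labels.reindex(features.index)
        self.config = config or RunConfig()
        self.modality = modality or {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "group",
                       **kwargs) -> "DyadOutcomeModel":
        features = df.drop(columns=[label_col]).select_dtypes("number")
        return cls(features, df[label_col], **kwargs)

    def fit(self) -> "DyadOutcomeResults":
        """Run LOO evaluation, feature correlations and the full-data stump."""
        result = loo_evaluate(self.features, self.labels, self.config)
        correlations = feature_class_correlations(
            self.features, self.labels, self.modality)
        y, _ = _encode_labels(self.labels)
        z, _t = impute_and_standardize(self.features)
        proj = fit_pca(z.to_numpy(), self.config.pca_variance_kept)
        stump = fit_stump(proj.transform(z.to_numpy()), y)
        return DyadOutcomeResults(model=self, loo=result,
                                  correlations=correlations,
                                  pca=proj, stump=stump)


@dataclass
class DyadOutcomeResults:
    """Fitted results: LOO performance, feature ranking, final stump."""

    model: DyadOutcomeModel
    loo: ClassificationResult
    correlations: list[dict]
    pca: PCAProjection
    stump: StumpModel

    @property
    def accuracy(self) -> float:
        return self.loo.accuracy

    @property
    def accuracy_percent(self) -> float:
        n = self.loo.n
        return accuracy_from_counts(n, n - int(np.trace(self.loo.confusion_matrix)))

    @property
    def confusion_matrix(self) -> np.ndarray:
        return self.loo.confusion_matrix

    def summary(self, top: int = 10) -> str:
        c0, c1 = self.loo.classes
        cm = self.loo.confusion_matrix
        lines = [
            "Dyad outcome classification (decision stump, leave-one-out)",
            "=" * 60,
            f"dyads: {self.loo.n}    classes: {c0} vs {c1}",
            f"PCA components kept: {self.pca.n_components} "
            f"(variance budget {self.model.config.pca_variance_kept:.2f})",
            f"LOO accuracy: {self.accuracy_percent:.2f}%",
            "",
            "confusion matrix (rows = true, cols = predicted)",
            f"{'':>12}{c0:>10}{c1:>10}",
            f"{c0:>12}{cm[0, 0]:>10d}{cm[0, 1]:>10d}",
            f"{c1:>12}{cm[1, 0]:>10d}{cm[1, 1]:>10d}",
            "",
            f"top features by |point-biserial r| (class 1 = {c1})",
            f"{'feature':<32}{'modality':<16}{'r':>8}{'p':>10}",
        ]
        for d in self.correlations[:top]:
            lines.append(f"{d['feature']:<32}{d['modality']:<16}"
                         f"{d['r']:>8.2f}{d['p']:>10.3g}")
        return "\n".join(lines)

    def save_report(self, path) -> dict:
        from .io import write_report
        return write_report(self.loo, self.correlations, path)
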