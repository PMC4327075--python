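"""Smellprint statistics: PCA, two-class LDA, Wilks'-lambda MANOVA, t-tests.

A *smellprint* is the collective response of the seven-sensor array to one
sample — here a vector of one (or all three) extracted features per sensor,
in sensor-major order.  The multivariate methods below are implemented
directly from their definitions (covariance eigendecomposition, scatter
matrices, determinants) so that they can be checked against brute-force
and closed-form oracles; scipy supplies only the t and F distribution
functions.

* PCA: eigendecomposition of the sample covariance of the mean-centered
  data, components ordered by decreasing eigenvalue, with a deterministic
  sign convention (the largest-magnitude loading element is positive).
* LDA (two classes): Fisher discriminant ``w = Sigma^-1 (mu_1 - mu_0)``
  with the pooled within-class covariance; the decision threshold is the
  midpoint of the projected class means shifted by the log prior ratio.
  A small ridge is added when the scatter matrix is singular (e.g. 21
  features against 48 training points).
* Wilks' lambda: ``det(E) / det(E + H)`` from the within- and
  between-group cross-product matrices, with Rao's F approximation for
  degrees of freedom and p-value.
* Two-sample t: pooled-variance Student's t with a two-sided p.

Percentages are kept unrounded internally; the report layer rounds to one
decimal, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .device import FeatureSelection
from .features import FeatureVector

__all__ = [
    "Smellprint",
    "PcaResult",
    "LdaModel",
    "ClassificationReport",
    "ManovaResult",
    "TTestResult",
    "AnalysisError",
    "build_smellprints",
    "pca_scores",
    "lda_fit",
    "lda_predict",
    "split_train_validation",
    "confusion_metrics",
    "wilks_lambda",
    "two_sample_t",
    "round_half_away",
]


class AnalysisError(ValueError):
    """Invalid input to a statistical routine."""


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (89.583 -> 89.6 at one decimal)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


# -- smellprints -------------------------------------------------------------

_FEATURE_NAMES = {
    FeatureSelection.AREA: ("area",),
    FeatureSelection.RELATIVE: ("relative",),
    FeatureSelection.SLOPE: ("slope",),
    FeatureSelection.ALL: ("area", "slope", "relative"),
}


@dataclass(frozen=True)
class Smellprint:
    """One measurement's feature vector across the array, sensor-major.

    ``columns`` documents the ordering as "s<id>:<feature>" strings.
    """

    label: str
    values: np.ndarray
    columns: tuple[str, ...]


def build_smellprints(
    measurements: Sequence[tuple[str, FeatureVector]],
    feature: FeatureSelection = FeatureSelection.AREA,
) -> list[Smellprint]:
    """Assemble smellprints from labelled feature vectors.

    Sensor-major ordering: for ALL, sensor 1's (area, slope, relative)
    triple precedes sensor 2's, giving a 21-vector for seven sensors.
    """
    if not measurements:
        raise AnalysisError("no measurements given")
    names = _FEATURE_NAMES[feature]
    sensor_ids = measurements[0][1].sensor_ids
    columns = tuple(f"s{i}:{f}" for i in sensor_ids for f in names)
    out = []
    for label, fv in measurements:
        if fv.sensor_ids != sensor_ids:
            raise AnalysisError(
                f"inconsistent sensor sets: {fv.sensor_ids} vs {sensor_ids}"
            )
        per_feature = {f: fv.values(f) for f in names}
        values = np.array([per_feature[f][k] for k in range(len(sensor_ids)) for f in names])
        out.append(Smellprint(label=label, values=values, columns=columns))
    return out


# -- PCA ---------------------------------------------------------------------

@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray  # n x p
    loadings: np.ndarray  # p x p, columns are components
    explained_variance: np.ndarray  # eigenvalues, decreasing
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_scores(X: np.ndarray, *, autoscale: bool = False) -> PcaResult:
    """Principal component analysis of the rows of ``X``.

    Covariance PCA by default (``autoscale=True`` divides each column by
    its standard deviation first).  Components are ordered by decreasing
    eigenvalue; each loading column is signed so its largest-magnitude
    element is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise AnalysisError("PCA needs a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    if autoscale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest |loading| element of each component positive
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    total = eigval.sum()
    ratio = eigval / total if total > 0 else np.zeros_like(eigval)
    return PcaResult(
        scores=Xc @ eigvec,
        loadings=eigvec,
        explained_variance=eigval,
        explained_variance_ratio=ratio,
        mean=mean,
    )


# -- LDA ---------------------------------------------------------------------

@dataclass(frozen=True)
class LdaModel:
    classes: tuple  # (negative, positive) in sorted label order
    w: np.ndarray  # discriminant direction Sigma^-1 (mu_pos - mu_neg)
    threshold: float  # assign positive class when x @ w > threshold
    means: np.ndarray  # 2 x p class means, rows in ``classes`` order
    ridge: float  # ridge actually added to the pooled covariance


def lda_fit(X_train: np.ndarray, y_train: Sequence) -> LdaModel:
    """Fit a two-class Fisher/Gaussian LDA with pooled covariance.

    Priors are the training class proportions.  When the pooled covariance
    is singular, a ridge ``1e-8 * trace(Sigma) / p`` is added.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) != 2:
        raise AnalysisError(f"LDA needs exactly 2 classes in training data, got {classes}")
    masks = [y == c for c in classes]
    n = np.array([m.sum() for m in masks])
    p = X.shape[1]
    if X.shape[0] < 3 or n.min() < 1:
        raise AnalysisError("too few training samples")
    means = np.vstack([X[m].mean(axis=0) for m in masks])
    Sw = np.zeros((p, p))
    for m, mu in zip(masks, means):
        d = X[m] - mu
        Sw += d.T @ d
    sigma = Sw / (X.shape[0] - 2)  # pooled within-class covariance
    ridge = 0.0
    try:
        w = np.linalg.solve(sigma, means[1] - means[0])
        # reject solutions from a numerically singular system
        if not np.all(np.isfinite(w)) or np.linalg.cond(sigma) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(sigma) / p
        if ridge <= 0:
            ridge = 1e-12
        w = np.linalg.solve(sigma + ridge * np.eye(p), means[1] - means[0])
    priors = n / n.sum()
    threshold = 0.5 * float(w @ (means[0] + means[1])) + float(np.log(priors[0] / priors[1]))
    return LdaModel(classes=classes, w=w, threshold=threshold, means=means, ridge=ridge)


def lda_predict(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Assign each row of ``X`` to a class by side of the threshold."""
    z = np.asarray(X, dtype=float) @ model.w
    return np.where(z > model.threshold, model.classes[1], model.classes[0])


def split_train_validation(
    n: int, fraction: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive split of range(n); train size floor(n*fraction)."""
    if n < 2:
        raise AnalysisError("need at least 2 samples to split")
    if not (0.0 < fraction < 1.0):
        raise AnalysisError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(np.floor(n * fraction))
    return np.sort(perm[:k]), np.sort(perm[k:])


# -- confusion metrics -------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    """2x2 confusion counts (rows predicted, cols actual; negative class
    first) with derived rates in percent, unrounded."""

    confusion: np.ndarray
    correct_rate_pct: float
    false_positive_pct: float
    false_negative_pct: float

    def summary(self, labels: tuple[str, str] = ("healthy", "diseased")) -> str:
        c = self.confusion
        neg, pos = labels
        lines = [
            f"{'':>20s}  actual {neg:>8s}  actual {pos:>8s}",
            f"{'predicted ' + neg:>20s}  {c[0, 0]:>15d}  {c[0, 1]:>15d}",
            f"{'predicted ' + pos:>20s}  {c[1, 0]:>15d}  {c[1, 1]:>15d}",
            f"correct classification rate: {round_half_away(self.correct_rate_pct):.1f}%",
            f"false positive rate: {round_half_away(self.false_positive_pct):.1f}%",
            f"false negative rate: {round_half_away(self.false_negative_pct):.1f}%",
        ]
        return "\n".join(lines)


def confusion_metrics(confusion: np.ndarray) -> ClassificationReport:
    """Rates from a 2x2 confusion table (rows predicted, cols actual).

    Convention: index 0 is the negative class (healthy), index 1 positive
    (diseased).  False positive = actual-negative predicted positive;
    false negative = actual-positive predicted negative.  The three
    percentages sum to exactly 100.
    """
    c = np.asarray(confusion)
    if c.shape != (2, 2):
        raise AnalysisError(f"confusion must be 2x2, got {c.shape}")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
        raise AnalysisError("confusion counts must be non-negative integers")
    total = int(c.sum())
    if total == 0:
        raise AnalysisError("confusion table is empty")
    correct = 100.0 * (c[0, 0] + c[1, 1]) / total
    fp = 100.0 * c[1, 0] / total
    fn = 100.0 * c[0, 1] / total
    return ClassificationReport(
        confusion=c, correct_rate_pct=correct,
        false_positive_pct=fp, false_negative_pct=fn,
    )


def confusion_from_labels(
    y_true: Sequence, y_pred: Sequence, classes: tuple
) -> np.ndarray:
    """2x2 counts (rows predicted, cols actual) for the given class order."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    c = np.zeros((2, 2), dtype=int)
    for i, pred_c in enumerate(classes):
        for j, true_c in enumerate(classes):
            c[i, j] = int(np.sum((y_pred == pred_c) & (y_true == true_c)))
    return c


# -- MANOVA (Wilks' lambda) --------------------------------------------------

@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    approx_F: float
    df1: float
    df2: float
    p_value: float


def wilks_lambda(groups: Sequence[np.ndarray]) -> ManovaResult:
    """One-way MANOVA via Wilks' lambda with Rao's F approximation.

    ``groups`` is a list of (n_g x p) matrices.  Lambda = det(E)/det(E+H)
    with E the pooled within-group and H the between-group cross-product
    matrices.
    """
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    k = len(mats)
    if k < 2:
        raise AnalysisError("need at least 2 groups")
    p = mats[0].shape[1]
    if any(m.shape[1] != p for m in mats):
        raise AnalysisError("groups must share the same number of variables")
    ns = np.array([m.shape[0] for m in mats])
    N = int(ns.sum())
    if N <= p + k:
        raise AnalysisError(f"total n={N} must exceed p+k={p + k}")
    grand = np.vstack(mats).mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for m, n_g in zip(mats, ns):
        mu = m.mean(axis=0)
        d = m - mu
        E += d.T @ d
        dm = (mu - grand)[:, None]
        H += n_g * (dm @ dm.T)
    det_E = np.linalg.det(E)
    det_T = np.linalg.det(E + H)
    if det_E <= 0 or not np.isfinite(det_E):
        raise AnalysisError(
            "within-group cross-product matrix is singular; reduce the number "
            "of variables or add observations"
        )
    lam = float(det_E / det_T)
    lam = min(max(lam, 0.0), 1.0)
    # Rao's approximation
    nu_h = k - 1
    nu_e = N - k
    denom = p * p + nu_h * nu_h - 5
    t = np.sqrt((p * p * nu_h * nu_h - 4) / denom) if denom > 0 else 1.0
    df1 = p * nu_h
    df2 = (nu_e + nu_h - (p + nu_h + 1) / 2.0) * t - (p * nu_h - 2) / 2.0
    root = lam ** (1.0 / t)
    F = (1.0 - root) / root * df2 / df1 if root > 0 else np.inf
    p_value = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return ManovaResult(
        wilks_lambda=lam, approx_F=float(F), df1=float(df1), df2=float(df2),
        p_value=p_value,
    )


# -- two-sample t ------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool


def two_sample_t(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> TTestResult:
    """Pooled-variance Student's t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("each sample needs at least 2 observations")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if se == 0:
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    else:
        t = (a.mean() - b.mean()) / se
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TTestResult(t=float(t), df=float(df), p=p, significant=bool(p < alpha))
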