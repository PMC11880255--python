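"""Time-resolved MVPA: sliding per-timepoint LDA decoding of condition.

Per subject, the channel vector at each timepoint is classified with a
least-squares LDA whose pooled within-class covariance is shrunk by the
analytic Ledoit-Wolf blend toward a scaled identity. Performance is
ROC-AUC under repeated stratified 5-fold cross-validation (20 repetitions,
100 folds per timepoint). Group inference bootstraps the pooled
subject x fold AUC collection (5,000 Monte-Carlo resamples) and compares
the lower CI bound against the upper CI bound of a label-independent dummy
baseline. Classifier weights are inverted into Haufe activation patterns
(pattern = Sigma_x w / w' Sigma_x w) and masked where the bootstrap CI of
the evoked contrast excludes zero.

The class coding is fixed package-wide: positive decision scores and
positive patterns align with the suboptimal condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from robot_erp.cluster_stats import ContrastStack
from robot_erp.montage_io import EpochSet

POSITIVE_CLASS = "suboptimal"


# ---------------------------------------------------------------------------
# covariance shrinkage and LDA
# ---------------------------------------------------------------------------


def ledoit_wolf_cov(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Ledoit-Wolf shrinkage covariance of centered data.

    Returns (Sigma_hat, delta) with
    Sigma_hat = (1 - delta) S + delta (trace(S)/p) I and the analytically
    optimal delta clipped to [0, 1]; S is the biased (1/n) sample
    covariance of the column-centered input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    S, delta, mu = _lw_batch(X[None])
    return S[0] * (1 - delta[0]) + delta[0] * mu[0] * np.eye(X.shape[1]), \
        float(delta[0])


def _lw_batch(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Ledoit-Wolf over a (T, n, p) stack of datasets.

    Returns (S, delta, mu): biased sample covariances, shrinkage
    intensities and identity scales mu = trace(S)/p.
    """
    T, n, p = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    S = np.einsum("tnp,tnq->tpq", Xc, Xc) / n
    mu = np.trace(S, axis1=1, axis2=2) / p
    d2 = np.sum((S - mu[:, None, None] * np.eye(p)) ** 2, axis=(1, 2)) / p
    # E ||x x' - S||^2 / n: sum_k (||x_k||^2)^2 / n^2 - ||S||^2 / n
    sq = np.sum(Xc**2, axis=2)  # (T, n)
    b2 = (np.sum(sq**2, axis=1) / n**2 - np.sum(S**2, axis=(1, 2)) / n) / p
    b2 = np.minimum(np.maximum(b2, 0.0), d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(d2 > 0, b2 / d2, 0.0)
    return S, np.clip(delta, 0.0, 1.0), mu


def _fit_lda_batch(X: np.ndarray, y: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Fit shrinkage LDA independently at every timepoint.

    X: (n, T, p) feature stack, y: binary labels (1 = positive class).
    Returns (w, b): weights (T, p) and intercepts (T,) such that
    score = x . w + b is 0 at the midpoint of the projected class means.
    """
    y = np.asarray(y)
    m1 = X[y == 1].mean(axis=0)  # (T, p)
    m0 = X[y == 0].mean(axis=0)
    resid = np.concatenate([X[y == 1] - m1[None], X[y == 0] - m0[None]],
                           axis=0)
    resid = np.swapaxes(resid, 0, 1)  # (T, n, p)
    S, delta, mu = _lw_batch(resid)
    p = X.shape[2]
    eye = np.eye(p)
    sigma = (1 - delta)[:, None, None] * S \
        + (delta * mu)[:, None, None] * eye[None]
    w = np.linalg.solve(sigma, (m1 - m0)[..., None])[..., 0]  # (T, p)
    b = -np.einsum("tp,tp->t", w, (m1 + m0) / 2)
    return w, b


def lda_train(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrinkage LDA on a single feature matrix.

    y may be strings ({"optimal", "suboptimal"}) or 0/1; the positive class
    (scores > 0) is "suboptimal" / 1.
    """
    yb = binarize_labels(y)
    if len(np.unique(yb)) != 2:
        raise ValueError("both classes must be present")
    w, b = _fit_lda_batch(np.asarray(X, dtype=float)[:, None, :], yb)
    return w[0], float(b[0])


def binarize_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return (y == POSITIVE_CLASS).astype(int)
    return y.astype(int)


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based (Mann-Whitney, tie-corrected) ROC area."""
    yb = binarize_labels(y)
    if len(np.unique(yb)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(yb, scores))


def _auc_batch(scores: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Column-wise AUC of a (n, T) score matrix via rank statistics."""
    from scipy.stats import rankdata

    n1 = int(yb.sum())
    n0 = yb.size - n1
    ranks = rankdata(scores, axis=0)
    r1 = ranks[yb == 1].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


# ---------------------------------------------------------------------------
# cross-validation scaffolding
# ---------------------------------------------------------------------------


def cv_folds(y: np.ndarray, n_splits: int, n_repeats: int,
             seed: int | None) -> list[tuple[np.ndarray, np.ndarray]]:
    yb = binarize_labels(y)
    if min(np.bincount(yb)) < n_splits:
        raise ValueError("fewer samples in a class than CV splits")
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                 random_state=seed)
    return [(tr, te) for tr, te in cv.split(np.zeros_like(yb), yb)]


@dataclass
class DecodingCurve:
    scores: np.ndarray  # (folds, timepoints) AUC
    times: np.ndarray  # s
    boot_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    boot_lo: np.ndarray = field(default=None)  # type: ignore[assignment]
    boot_hi: np.ndarray = field(default=None)  # type: ignore[assignment]
    dummy_mean: float = np.nan
    dummy_hi: float = np.nan
    sig_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    weights: np.ndarray = field(default=None)  # (T, channels) fold-averaged

    @property
    def peak_time(self) -> float:
        return peak_time(self)

    def to_dict(self) -> dict:
        d = {
            "times_s": self.times.tolist(),
            "boot_mean": self.boot_mean.tolist(),
            "boot_lo": self.boot_lo.tolist(),
            "boot_hi": self.boot_hi.tolist(),
            "dummy_mean": float(self.dummy_mean),
            "dummy_hi": float(self.dummy_hi),
            "sig_mask": self.sig_mask.astype(bool).tolist(),
            "peak_time_s": float(self.peak_time),
            "n_folds": int(self.scores.shape[0]),
        }
        return d


@dataclass
class PatternMap:
    patterns: np.ndarray  # (channels, timepoints)
    mask: np.ndarray | None = None  # (channels, timepoints) bool
    times: np.ndarray | None = None
    channels: list[str] = field(default_factory=list)


def sliding_decode(epochs: EpochSet, n_splits: int = 5, n_repeats: int = 20,
                   seed: int | None = 0) -> DecodingCurve:
    """Per-timepoint repeated stratified CV decoding of condition.

    Returns the (folds, timepoints) AUC matrix plus the across-fold average
    LDA weight per timepoint (for pattern inversion). Bootstrap statistics
    are attached by :func:`finalize_curve` (or at the group level).
    """
    X = np.transpose(epochs.data, (0, 2, 1))  # (n, T, C)
    yb = binarize_labels(epochs.labels)
    counts = np.bincount(yb, minlength=2)
    if counts.min() < 10:
        raise ValueError("need at least 10 epochs per class")
    folds = cv_folds(yb, n_splits, n_repeats, seed)
    n_folds, T = len(folds), X.shape[1]
    scores = np.empty((n_folds, T))
    wsum = np.zeros((T, X.shape[2]))
    for k, (tr, te) in enumerate(folds):
        w, b = _fit_lda_batch(X[tr], yb[tr])
        dec = np.einsum("ntp,tp->nt", X[te], w) + b[None]
        scores[k] = _auc_batch(dec, yb[te])
        wsum += w
    return DecodingCurve(scores=scores, times=epochs.times,
                         weights=wsum / n_folds)


def bootstrap_ci(values: np.ndarray, n_boot: int = 5000,
                 seed: int | None = 0,
                 ci: float = 95.0) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean: (mean, lo, hi)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return float(v.mean()), float(lo), float(hi)


def _bootstrap_columns(values: np.ndarray, n_boot: int, seed: int | None,
                       ci: float = 95.0
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise bootstrap of the mean for a (n, T) matrix, resampling
    rows (one shared resampling scheme across columns)."""
    rng = np.random.default_rng(seed)
    n, T = values.shape
    mean = values.mean(axis=0)
    boots = np.empty((n_boot, T), dtype=np.float32)
    chunk = max(1, int(5e6 // max(n * T, 1)))
    for s in range(0, n_boot, chunk):
        e = min(s + chunk, n_boot)
        idx = rng.integers(0, n, size=(e - s, n))
        boots[s:e] = values[idx].mean(axis=1)
    q = [(100 - ci) / 2, 100 - (100 - ci) / 2]
    los, his = np.percentile(boots, q, axis=0)
    return mean, los, his


def dummy_scores(epochs_or_labels, n_splits: int = 5, n_repeats: int = 20,
                 seed: int | None = 0) -> np.ndarray:
    """Chance-level baseline: per fold, decision scores drawn independently
    of the test labels; AUC computed identically to the real decoder.
    Returns a (folds,) AUC collection."""
    labels = (epochs_or_labels.labels
              if isinstance(epochs_or_labels, EpochSet) else epochs_or_labels)
    yb = binarize_labels(np.asarray(labels))
    folds = cv_folds(yb, n_splits, n_repeats, seed)
    rng = np.random.default_rng(None if seed is None else seed + 101)
    out = np.empty(len(folds))
    for k, (_, te) in enumerate(folds):
        out[k] = _auc_batch(rng.standard_normal((te.size, 1)), yb[te])[0]
    return out


def finalize_curve(curve: DecodingCurve, dummy: np.ndarray,
                   n_boot: int = 5000, seed: int | None = 0) -> DecodingCurve:
    """Attach bootstrap statistics and the significance mask to a curve.

    ``dummy`` is the pooled dummy-AUC collection; its bootstrap upper CI
    bound (a scalar, the average dummy performance) gates significance.
    """
    mean, lo, hi = _bootstrap_columns(curve.scores, n_boot, seed)
    dmean, _, dhi = bootstrap_ci(
        dummy, n_boot=n_boot, seed=None if seed is None else seed + 1)
    curve.boot_mean, curve.boot_lo, curve.boot_hi = mean, lo, hi
    curve.dummy_mean, curve.dummy_hi = dmean, dhi
    curve.sig_mask = significance_mask(curve)
    return curve


def significance_mask(curve: DecodingCurve) -> np.ndarray:
    """Timepoints where the decoder's lower CI bound exceeds the dummy's
    upper CI bound."""
    return curve.boot_lo > curve.dummy_hi


def peak_time(curve: DecodingCurve) -> float:
    """Time of maximum bootstrap-mean AUC (fold-mean fallback); earliest
    timepoint on ties."""
    y = curve.boot_mean if curve.boot_mean is not None \
        else curve.scores.mean(axis=0)
    return float(curve.times[int(np.argmax(y))])


def group_curve(curves: list[DecodingCurve], dummies: list[np.ndarray],
                n_boot: int = 5000, seed: int | None = 0) -> DecodingCurve:
    """Pool fold scores across subjects ("across participants and folds")
    into one group-level curve with bootstrap statistics."""
    scores = np.concatenate([c.scores for c in curves], axis=0)
    pooled = DecodingCurve(scores=scores, times=curves[0].times)
    return finalize_curve(pooled, np.concatenate(dummies), n_boot=n_boot,
                          seed=seed)


# ---------------------------------------------------------------------------
# activation patterns
# ---------------------------------------------------------------------------


def haufe_patterns(epochs: EpochSet, weights: np.ndarray) -> PatternMap:
    """Invert decoder weights into forward-model activation patterns.

    pattern_t = Sigma_x(t) w_t / (w_t' Sigma_x(t) w_t), with Sigma_x(t) the
    feature covariance over all epochs at timepoint t. Positive pattern
    values align with the suboptimal class.
    """
    X = np.transpose(epochs.data, (0, 2, 1))  # (n, T, C)
    Xc = X - X.mean(axis=0, keepdims=True)
    T = X.shape[1]
    pats = np.empty((X.shape[2], T))
    for t in range(T):
        cov = Xc[:, t, :].T @ Xc[:, t, :] / (X.shape[0] - 1)
        sw = cov @ weights[t]
        denom = float(weights[t] @ sw)
        if denom <= 0:
            raise ValueError(f"undefined pattern at timepoint {t} "
                             "(zero projected variance)")
        pats[:, t] = sw / denom
    return PatternMap(patterns=pats, times=epochs.times,
                      channels=list(epochs.channels))


def mask_patterns(patterns: PatternMap, contrasts: ContrastStack,
                  n_boot: int = 5000, seed: int | None = 0) -> PatternMap:
    """Mask patterns where the bootstrap CI of the subject-mean evoked
    contrast excludes zero."""
    x = contrasts.data  # (S, C, T)
    S = x.shape[0]
    rng = np.random.default_rng(seed)
    chunk = max(1, int(5e7 // max(S * x.shape[1] * x.shape[2], 1)))
    boots = np.empty((n_boot,) + x.shape[1:], dtype=np.float32)
    for s in range(0, n_boot, chunk):
        e = min(s + chunk, n_boot)
        idx = rng.integers(0, S, size=(e - s, S))
        boots[s:e] = x[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    mask = (lo > 0) | (hi < 0)
    return PatternMap(patterns=patterns.patterns, mask=mask,
                      times=patterns.times, channels=patterns.channels)
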