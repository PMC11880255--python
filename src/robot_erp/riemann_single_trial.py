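"""Single-trial interval decoding via Riemannian geometry of covariances.

Per time interval: trials are cropped, xDAWN spatial filters are fit on the
training split (generalized eigenproblem of evoked-signal variance against
total single-trial variance, per class), super-trial covariance matrices
are built by stacking the two filtered class-evoked prototypes with the
filtered trial, and the SPD matrices are projected into the tangent space
at their affine-invariant geometric mean. A plain (pooled-covariance,
unshrunk) LDA classifies the tangent vectors; performance is ROC-AUC under
repeated stratified cross-validation, bootstrapped across subjects and
folds.

All estimation steps (filters, prototypes, geometric mean) use the
training split only; applying them to held-out trials is the only contact
with test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from scipy.linalg import eigh

from robot_erp.montage_io import EpochSet
from robot_erp.temporal_decoding import (
    _auc_batch,
    binarize_labels,
    bootstrap_ci,
    cv_folds,
)

DEFAULT_INTERVALS = ((0.0, 0.75), (0.75, 1.35), (1.35, 2.0))


@dataclass
class SPDSet:
    matrices: np.ndarray  # (trials, d, d)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        m = self.matrices
        if np.abs(m - np.swapaxes(m, -1, -2)).max() > 1e-10:
            raise ValueError("matrices not symmetric")
        if np.linalg.eigvalsh(m).min() <= 0:
            raise ValueError("matrices not positive definite")

    def __len__(self) -> int:
        return self.matrices.shape[0]

    @property
    def d(self) -> int:
        return self.matrices.shape[1]


@dataclass
class IntervalResult:
    intervals: list[tuple[float, float]]
    train_scores: list[np.ndarray]  # per interval, pooled fold AUCs
    test_scores: list[np.ndarray]
    train_stats: list[tuple[float, float, float]]  # (mean, lo, hi)
    test_stats: list[tuple[float, float, float]]
    dummy_test_stats: tuple[float, float, float] | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "intervals_s": [[float(a), float(b)] for a, b in self.intervals],
            "seed": self.seed,
            "per_interval": [
                {
                    "interval_s": [float(a), float(b)],
                    "train_auc_mean": tr[0], "train_auc_ci": [tr[1], tr[2]],
                    "test_auc_mean": te[0], "test_auc_ci": [te[1], te[2]],
                }
                for (a, b), tr, te in zip(self.intervals, self.train_stats,
                                          self.test_stats)
            ],
        }
        if self.dummy_test_stats is not None:
            d = self.dummy_test_stats
            out["dummy_test_auc_mean"] = d[0]
            out["dummy_test_auc_ci"] = [d[1], d[2]]
        return out


# ---------------------------------------------------------------------------
# xDAWN
# ---------------------------------------------------------------------------


def _reg(C: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    d = C.shape[0]
    return C + eps * (np.trace(C) / d + 1e-30) * np.eye(d)


def xdawn_filters(data: np.ndarray, labels: np.ndarray,
                  n_filters: int = 4) -> dict[int, np.ndarray]:
    """Per-class xDAWN spatial filters.

    data: (trials, channels, time). For each class, solves the generalized
    eigenproblem of the class-evoked covariance against the pooled
    single-trial covariance and keeps the ``n_filters`` leading unit-norm
    eigenvectors (rows of the returned (n_filters, channels) matrices).
    """
    yb = binarize_labels(labels)
    if min(np.bincount(yb, minlength=2)) < 2:
        raise ValueError("need at least 2 trials per class")
    X = np.asarray(data, dtype=float)
    n, C, T = X.shape
    # total single-trial covariance over the concatenated time axis,
    # computed without materializing the (C, n*T) copy
    grand = X.mean(axis=(0, 2))
    nt = n * T
    Cx = np.einsum("nct,ndt->cd", X, X, optimize=True)
    Cx = (Cx - nt * np.outer(grand, grand)) / (nt - 1)
    Cx = _reg(Cx)
    out = {}
    for cls in (0, 1):
        ev = X[yb == cls].mean(axis=0)
        ev = ev - ev.mean(axis=1, keepdims=True)
        Cs = ev @ ev.T / (T - 1)
        vals, vecs = eigh(Cs, Cx)
        order = np.argsort(vals)[::-1][:n_filters]
        W = vecs[:, order].T
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        out[cls] = W
    return out


def supertrial_covariances(data: np.ndarray, filters: dict[int, np.ndarray],
                           prototypes: dict[int, np.ndarray],
                           trial_class_for_filter: int = 1) -> SPDSet:
    """Covariances of xDAWN super-trials.

    Each super-trial stacks the filtered class-0 evoked prototype, the
    filtered class-1 evoked prototype, and the trial filtered with the
    class-``trial_class_for_filter`` filters (d = 3 x n_filters rows), and
    takes the sample covariance over time (1/(T-1)); a tiny
    trace-proportional ridge restores positive definiteness if needed.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[2] < 2:
        raise ValueError("need at least 2 time samples")
    P0 = filters[0] @ prototypes[0]
    P1 = filters[1] @ prototypes[1]
    Wt = filters[trial_class_for_filter]
    n, _, T = X.shape
    proto = np.vstack([P0, P1])  # (2f, T)
    trials = np.einsum("fc,nct->nft", Wt, X, optimize=True)  # (n, f, T)
    S = np.concatenate([np.broadcast_to(proto, (n,) + proto.shape), trials],
                       axis=1)  # (n, 3f, T)
    S = S - S.mean(axis=2, keepdims=True)
    covs = np.einsum("nit,njt->nij", S, S, optimize=True) / (T - 1)
    covs = 0.5 * (covs + np.swapaxes(covs, -1, -2))
    # restore strict positive definiteness where time-rank is short
    tr = np.trace(covs, axis1=1, axis2=2)
    d = covs.shape[1]
    bad = np.linalg.eigvalsh(covs)[:, 0] <= 1e-12 * tr
    if bad.any():
        covs[bad] += ((1e-8 + 1e-12) * tr[bad] / d)[:, None, None] * np.eye(d)
    return SPDSet(matrices=covs)


# ---------------------------------------------------------------------------
# SPD geometry
# ---------------------------------------------------------------------------


def _sqrt_and_inv_sqrt(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(M)
    if vals.min() <= 0:
        raise ValueError("matrix not positive definite")
    s = np.sqrt(vals)
    return (vecs * s) @ vecs.T, (vecs / s) @ vecs.T


def _logm_spd_batch(Ms: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(Ms)
    if vals.min() <= 0:
        raise ValueError("matrix not positive definite")
    lv = np.log(vals)
    return np.einsum("...ij,...j,...kj->...ik", vecs, lv, vecs)


def riemannian_mean(spds: SPDSet, tol: float = 1e-8,
                    max_iter: int = 50) -> np.ndarray:
    """Affine-invariant geometric mean by fixed-point iteration.

    M <- M^1/2 exp(mean_i log(M^-1/2 C_i M^-1/2)) M^1/2, initialized at the
    arithmetic mean, stopped when ||mean log||_F < tol.
    """
    C = spds.matrices
    if len(spds) == 0:
        raise ValueError("empty SPD set")
    if len(spds) == 1:
        return C[0].copy()
    M = C.mean(axis=0)
    prev = np.inf
    for _ in range(max_iter):
        Msq, Misq = _sqrt_and_inv_sqrt(M)
        whitened = Misq @ C @ Misq
        whitened = 0.5 * (whitened + np.swapaxes(whitened, -1, -2))
        L = _logm_spd_batch(whitened).mean(axis=0)
        resid = np.linalg.norm(L)
        vals, vecs = np.linalg.eigh(L)
        expL = (vecs * np.exp(vals)) @ vecs.T
        M = Msq @ expL @ Msq
        M = 0.5 * (M + M.T)
        if resid < tol:
            return M
        if resid < 1e-6 and resid >= 0.5 * prev:
            # numerically negligible residual that has stopped improving:
            # the fixed point has reached the floating-point floor for
            # ill-conditioned inputs
            return M
        prev = resid
    raise RuntimeError(
        f"geometric mean did not converge in {max_iter} iterations "
        f"(residual {resid:.3g})"
    )


def tangent_project(spds: SPDSet, reference: np.ndarray) -> np.ndarray:
    """Tangent-space vectors at ``reference``.

    v_i = vech(log(R^-1/2 C_i R^-1/2)) with off-diagonal entries scaled by
    sqrt(2), so ||v_i|| equals the affine-invariant geodesic distance from
    the reference.
    """
    _, Risq = _sqrt_and_inv_sqrt(np.asarray(reference, dtype=float))
    whitened = Risq @ spds.matrices @ Risq
    whitened = 0.5 * (whitened + np.swapaxes(whitened, -1, -2))
    logs = _logm_spd_batch(whitened)
    d = logs.shape[-1]
    iu = np.triu_indices(d)
    scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return logs[:, iu[0], iu[1]] * scale[None, :]


def geodesic_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant distance ||log(A^-1/2 B A^-1/2)||_F."""
    _, Aisq = _sqrt_and_inv_sqrt(A)
    W = Aisq @ B @ Aisq
    return float(np.linalg.norm(_logm_spd_batch(0.5 * (W + W.T)[None])[0]))


# ---------------------------------------------------------------------------
# interval decoding
# ---------------------------------------------------------------------------


def crop_interval(epochs: EpochSet, start: float, end: float) -> np.ndarray:
    """Half-open [start, end) crop of the epoch data, seconds after onset."""
    times = epochs.times
    if start < times[0] - 1e-9 or end > times[-1] + 1.0 / epochs.srate + 1e-9:
        raise ValueError(f"interval ({start}, {end}) outside epoch bounds")
    sel = (times >= start - 1e-9) & (times < end - 1e-9)
    return epochs.data[:, :, sel]


def _fit_fold(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
              n_filters: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit xDAWN + prototypes + geometric mean on the training trials only,
    then produce tangent vectors for train and test."""
    filters = xdawn_filters(Xtr, ytr, n_filters=n_filters)
    prototypes = {cls: Xtr[ytr == cls].mean(axis=0) for cls in (0, 1)}
    cov_tr = supertrial_covariances(Xtr, filters, prototypes)
    ref = riemannian_mean(cov_tr)
    cov_te = supertrial_covariances(Xte, filters, prototypes)
    return tangent_project(cov_tr, ref), tangent_project(cov_te, ref)


def interval_decode(epochs: EpochSet,
                    intervals=DEFAULT_INTERVALS,
                    n_splits: int = 5, n_repeats: int = 20,
                    n_filters: int = 4, seed: int | None = 0,
                    n_boot: int = 5000) -> IntervalResult:
    """Riemannian single-trial decoding per time interval (one subject)."""
    ivs = [(float(a), float(b)) for a, b in intervals]
    for a, b in ivs:
        if b <= a:
            raise ValueError("interval end must exceed start")
    yb = binarize_labels(epochs.labels)
    folds = cv_folds(yb, n_splits, n_repeats, seed)
    train_scores, test_scores, train_stats, test_stats = [], [], [], []
    for a, b in ivs:
        X = crop_interval(epochs, a, b)
        tr_auc = np.empty(len(folds))
        te_auc = np.empty(len(folds))
        for k, (tr, te) in enumerate(folds):
            Vtr, Vte = _fit_fold(X[tr], yb[tr], X[te], n_filters)
            clf = LinearDiscriminantAnalysis()
            clf.fit(Vtr, yb[tr])
            tr_auc[k] = _auc_batch(clf.decision_function(Vtr)[:, None],
                                   yb[tr])[0]
            te_auc[k] = _auc_batch(clf.decision_function(Vte)[:, None],
                                   yb[te])[0]
        train_scores.append(tr_auc)
        test_scores.append(te_auc)
        train_stats.append(bootstrap_ci(tr_auc, n_boot=n_boot, seed=seed))
        test_stats.append(bootstrap_ci(te_auc, n_boot=n_boot, seed=seed))
    return IntervalResult(intervals=ivs, train_scores=train_scores,
                          test_scores=test_scores, train_stats=train_stats,
                          test_stats=test_stats, seed=seed)


def group_interval_result(results: list[IntervalResult],
                          n_boot: int = 5000,
                          seed: int | None = 0) -> IntervalResult:
    """Pool fold scores across subjects and re-bootstrap."""
    ivs = results[0].intervals
    train_scores, test_scores, train_stats, test_stats = [], [], [], []
    for i in range(len(ivs)):
        tr = np.concatenate([r.train_scores[i] for r in results])
        te = np.concatenate([r.test_scores[i] for r in results])
        train_scores.append(tr)
        test_scores.append(te)
        train_stats.append(bootstrap_ci(tr, n_boot=n_boot, seed=seed))
        test_stats.append(bootstrap_ci(te, n_boot=n_boot, seed=seed))
    return IntervalResult(intervals=ivs, train_scores=train_scores,
                          test_scores=test_scores, train_stats=train_stats,
                          test_stats=test_stats, seed=seed)
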