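"""Mass-univariate spatiotemporal cluster-mass permutation statistics.

Subject-wise condition contrasts (suboptimal - optimal evoked response; the
sign convention is standardized package-wide) are tested against zero with
a one-sample t statistic per (channel, time) sample. Supra-threshold samples
of equal sign that are contiguous - adjacent in time on the same channel, or
on spatially adjacent channels at the same time - form clusters whose summed
t is the cluster mass. Family-wise error is controlled by the permutation
distribution of the maximum absolute cluster mass under per-subject sign
flips (the exchangeability transformation of a paired design), two-tailed.

p-values are +1-corrected Monte-Carlo estimates, never exactly zero. An
exhaustive 2^n sign-pattern enumeration is provided as an independent
oracle for small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from robot_erp.montage_io import EpochSet


@dataclass
class ContrastStack:
    """Per-subject evoked contrast maps: (subjects, channels, time)."""

    data: np.ndarray
    srate: float
    tmin: float
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("need a (subjects>=2, channels, time) stack")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in contrast stack")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


@dataclass
class Cluster:
    members: list[tuple[int, int]]  # (channel, time) indices
    mass: float
    sign: int
    p: float = np.nan

    @property
    def channels(self) -> set[int]:
        return {c for c, _ in self.members}

    @property
    def times(self) -> set[int]:
        return {t for _, t in self.members}


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold: float
    null_max_mass: np.ndarray
    n_permutations: int
    seed: int | None
    srate: float = np.nan
    tmin: float = np.nan
    channels: list[str] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]

    def to_dict(self) -> dict:
        def cl(c: Cluster) -> dict:
            d = {
                "members": [[int(a), int(b)] for a, b in sorted(c.members)],
                "mass": float(c.mass),
                "sign": int(c.sign),
                "p": float(c.p),
                "n_channels": len(c.channels),
            }
            if np.isfinite(self.srate):
                d["times_s"] = sorted(
                    {round(self.tmin + t / self.srate, 6) for t in c.times}
                )
            if self.channels:
                d["channel_labels"] = sorted(
                    {self.channels[ch] for ch in c.channels}
                )
            return d

        return {
            "contrast_convention": "suboptimal_minus_optimal",
            "threshold": float(self.threshold),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
            "alpha": self.alpha,
            "clusters": [cl(c) for c in self.clusters],
            "n_significant": len(self.significant),
        }


def contrast_stack(subject_epochs: list[EpochSet]) -> ContrastStack:
    """Build the subject-wise suboptimal-minus-optimal evoked contrast."""
    maps = []
    first = subject_epochs[0]
    for ep in subject_epochs:
        sub = ep.data[ep.labels == "suboptimal"].mean(axis=0)
        opt = ep.data[ep.labels == "optimal"].mean(axis=0)
        maps.append(sub - opt)
    return ContrastStack(data=np.stack(maps), srate=first.srate,
                         tmin=first.tmin, channels=list(first.channels))


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------


def t_map(contrasts: ContrastStack) -> np.ndarray:
    """One-sample t of the contrast against zero, per (channel, time)."""
    x = contrasts.data
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(mean)
    ok = sd > 0
    if not ok.all():
        import warnings

        warnings.warn("zero-variance samples in contrast; t set to 0 there")
    out[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return out


def forming_threshold(n_subjects: int, alpha: float = 0.05) -> float:
    """Two-tailed Student-t quantile at the cluster-forming alpha."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    return float(t_dist.ppf(1 - alpha / 2, df=n_subjects - 1))


# ---------------------------------------------------------------------------
# spatiotemporal connectivity machinery
# ---------------------------------------------------------------------------


class _Lattice:
    """Edge list of the (channel x time) spatiotemporal graph: temporal
    edges along each channel plus spatial edges between adjacent channels
    at equal time (no diagonal space-time edges)."""

    def __init__(self, adjacency: np.ndarray, n_times: int):
        n_chan = adjacency.shape[0]
        self.n_chan, self.n_times = n_chan, n_times
        nodes = np.arange(n_chan * n_times).reshape(n_chan, n_times)
        e0 = [nodes[:, :-1].ravel()]
        e1 = [nodes[:, 1:].ravel()]
        ai, aj = np.nonzero(np.triu(adjacency, k=1))
        if ai.size:
            e0.append(nodes[ai].ravel())
            e1.append(nodes[aj].ravel())
        self.e0 = np.concatenate(e0)
        self.e1 = np.concatenate(e1)
        self.n_nodes = n_chan * n_times

    def cluster_masses(self, tvals: np.ndarray, threshold: float
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Masses and component labels of same-sign supra-threshold
        clusters of a flattened t map; returns (masses, labels) where
        labels[i] is the component id of node i (only meaningful at
        supra-threshold nodes) and masses is indexed by component id
        (NaN for components without supra-threshold members)."""
        flat = tvals.ravel()
        pos = flat > threshold
        neg = flat < -threshold
        mask = pos | neg
        same = (pos[self.e0] & pos[self.e1]) | (neg[self.e0] & neg[self.e1])
        g = sparse.coo_matrix(
            (np.ones(same.sum(), dtype=np.int8),
             (self.e0[same], self.e1[same])),
            shape=(self.n_nodes, self.n_nodes),
        )
        _, labels = connected_components(g, directed=False)
        masses = np.bincount(labels[mask], weights=flat[mask],
                             minlength=labels.max() + 1)
        counts = np.bincount(labels[mask], minlength=labels.max() + 1)
        masses = np.where(counts > 0, masses, np.nan)
        return masses, labels

    def max_abs_mass(self, tvals: np.ndarray, threshold: float) -> float:
        masses, _ = self.cluster_masses(tvals, threshold)
        finite = masses[np.isfinite(masses)]
        return float(np.abs(finite).max()) if finite.size else 0.0


def find_clusters(tvals: np.ndarray, adjacency: np.ndarray,
                  threshold: float) -> list[Cluster]:
    """Connected same-sign supra-threshold clusters with their masses."""
    if adjacency.shape[0] != tvals.shape[0]:
        raise ValueError("adjacency size does not match channel count")
    lat = _Lattice(adjacency, tvals.shape[1])
    masses, labels = lat.cluster_masses(tvals, threshold)
    flat = tvals.ravel()
    mask = np.abs(flat) > threshold
    clusters = []
    for comp in np.unique(labels[mask]):
        nodes = np.flatnonzero((labels == comp) & mask)
        members = [(int(i // tvals.shape[1]), int(i % tvals.shape[1]))
                   for i in nodes]
        mass = float(flat[nodes].sum())
        clusters.append(Cluster(members=members, mass=mass,
                                sign=int(np.sign(mass))))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def _null_from_signs(contrasts: ContrastStack, adjacency: np.ndarray,
                     threshold: float, signs: np.ndarray) -> np.ndarray:
    """Max |cluster mass| for each row of a (n_draws, n_subjects) sign
    matrix. t maps for all draws come from one matrix product: sign flips
    leave per-sample sums of squares unchanged."""
    x = contrasts.data
    n_subj = x.shape[0]
    shape = x.shape[1:]
    X = x.reshape(n_subj, -1)
    ssq = np.einsum("sf,sf->f", X, X)
    lat = _Lattice(adjacency, shape[1])
    out = np.empty(signs.shape[0])
    means = signs @ X / n_subj
    for k in range(signs.shape[0]):
        mean = means[k]
        var = (ssq - n_subj * mean**2) / (n_subj - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = np.where(var > 0, mean / np.sqrt(var / n_subj), 0.0)
        out[k] = lat.max_abs_mass(tv.reshape(shape), threshold)
    return out


def permutation_null(contrasts: ContrastStack, adjacency: np.ndarray,
                     threshold: float, n_permutations: int = 1000,
                     seed: int | None = 0) -> np.ndarray:
    """Monte-Carlo null distribution of the max |cluster mass| under
    per-subject sign flips."""
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_permutations, contrasts.n_subjects))
    signs = signs * 2.0 - 1.0
    return _null_from_signs(contrasts, adjacency, threshold, signs)


def exact_null(contrasts: ContrastStack, adjacency: np.ndarray,
               threshold: float) -> np.ndarray:
    """Exhaustive null over all 2^n sign patterns (oracle; n <= 14)."""
    n = contrasts.n_subjects
    if n > 14:
        raise ValueError("exact enumeration limited to 14 subjects")
    bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
    signs = bits * 2.0 - 1.0
    return _null_from_signs(contrasts, adjacency, threshold, signs)


def p_values(clusters: list[Cluster], null_max_mass: np.ndarray,
             *, threshold: float, t_vals: np.ndarray | None = None,
             n_permutations: int | None = None, seed: int | None = None,
             srate: float = np.nan, tmin: float = np.nan,
             channels: list[str] | None = None,
             alpha: float = 0.05) -> ClusterReport:
    """Attach +1-corrected permutation p-values to observed clusters."""
    null = np.asarray(null_max_mass, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    n_perm = n_permutations if n_permutations is not None else null.size
    out = []
    for c in clusters:
        count = int(np.sum(null >= abs(c.mass)))
        out.append(Cluster(members=list(c.members), mass=c.mass, sign=c.sign,
                           p=(1 + count) / (1 + null.size)))
    return ClusterReport(
        clusters=out,
        t_map=t_vals if t_vals is not None else np.zeros((0, 0)),
        threshold=threshold, null_max_mass=null, n_permutations=n_perm,
        seed=seed, srate=srate, tmin=tmin, channels=channels or [],
        alpha=alpha,
    )


def cluster_test(contrasts: ContrastStack, adjacency: np.ndarray,
                 alpha: float = 0.05, cluster_alpha: float = 0.05,
                 n_permutations: int = 1000,
                 seed: int | None = 0) -> ClusterReport:
    """Full spatiotemporal cluster-mass permutation test."""
    thr = forming_threshold(contrasts.n_subjects, alpha=cluster_alpha)
    tv = t_map(contrasts)
    clusters = find_clusters(tv, adjacency, thr)
    null = permutation_null(contrasts, adjacency, thr,
                            n_permutations=n_permutations, seed=seed)
    return p_values(clusters, null, threshold=thr, t_vals=tv,
                    n_permutations=n_permutations, seed=seed,
                    srate=contrasts.srate, tmin=contrasts.tmin,
                    channels=list(contrasts.channels), alpha=alpha)
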