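"""Continuous-recording -> clean epoch preprocessing.

Canonical order: detrend -> bandpass (0.2-10 Hz, 4th-order Butterworth,
zero-phase) -> epoch (-0.2..2.0 s) -> downsample to 250 Hz -> per-epoch
bad-channel cleaning -> baseline correction on the 200 ms pre-stimulus
window -> condition-count equalization.

The artifact-rejection stage is a deliberately simple surrogate for
ICA-based cleaning: a virtual EOG channel (mean of Fp1/Fp2) is recorded in
the log, and per-epoch channels that are robust outliers in amplitude range
or variance are replaced by spherical-spline interpolation. This deviation
from ICA-based pipelines is flagged in the rejection log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from robot_erp.montage_io import EpochSet, Montage, RawRecording


def detrend(raw: RawRecording) -> RawRecording:
    """Remove the per-channel least-squares linear trend."""
    if raw.data.shape[1] < 2:
        raise ValueError("detrend requires at least 2 samples")
    data = signal.detrend(raw.data, axis=1, type="linear")
    return RawRecording(data=data, srate=raw.srate, events=list(raw.events),
                        channels=list(raw.channels))


def bandpass(raw: RawRecording, low: float = 0.2, high: float = 10.0,
             order: int = 4) -> RawRecording:
    """Zero-phase Butterworth bandpass (forward-backward second-order
    sections). Effective attenuation is the single-pass magnitude squared."""
    nyq = raw.srate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) for srate {raw.srate}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=raw.srate,
                        output="sos")
    data = signal.sosfiltfilt(sos, raw.data, axis=1)
    return RawRecording(data=data, srate=raw.srate, events=list(raw.events),
                        channels=list(raw.channels))


def epoch(raw: RawRecording, tmin: float = -0.2, tmax: float = 2.0,
          subject: str = "unknown") -> EpochSet:
    """Cut fixed-length epochs around each event; events whose window falls
    outside the recording are dropped with a warning."""
    n_times = int(round((tmax - tmin) * raw.srate))
    offset = int(round(tmin * raw.srate))
    segs, labels, dropped = [], [], 0
    for sample, label in raw.events:
        i0 = sample + offset
        i1 = i0 + n_times
        if i0 < 0 or i1 > raw.data.shape[1]:
            dropped += 1
            continue
        segs.append(raw.data[:, i0:i1])
        labels.append(label)
    if dropped:
        warnings.warn(f"dropped {dropped} events with out-of-range epoch windows")
    if not segs:
        raise ValueError("no valid events to epoch")
    return EpochSet(data=np.stack(segs), srate=raw.srate, tmin=tmin,
                    labels=np.array(labels), subject=subject,
                    unit="potential_uV", channels=list(raw.channels))


def downsample(epochs: EpochSet, target: float) -> EpochSet:
    """Anti-aliased polyphase resampling of every epoch to ``target`` Hz."""
    if target > epochs.srate:
        raise ValueError("target rate above current rate")
    if target < 20.0:
        raise ValueError("target rate below twice the 10 Hz passband edge")
    if target == epochs.srate:
        return epochs
    frac = Fraction(target / epochs.srate).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator,
                                axis=2)
    return epochs.copy_with(data=data, srate=target)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the per-epoch, per-channel mean of the pre-stimulus window
    [tmin, 0)."""
    if epochs.tmin > -0.2 + 1e-9:
        raise ValueError("baseline correction needs >= 200 ms pre-stimulus data")
    n_pre = int(round(-epochs.tmin * epochs.srate))
    if n_pre < 1:
        raise ValueError("no pre-stimulus samples")
    base = epochs.data[:, :, :n_pre].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


# ---------------------------------------------------------------------------
# bad-channel cleaning (spline interpolation)
# ---------------------------------------------------------------------------


@dataclass
class RejectionLog:
    virtual_eog: np.ndarray | None = None
    interpolated: list[tuple[int, int]] = field(default_factory=list)  # (epoch, channel)
    dropped_epochs: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "interpolated": [[int(e), int(c)] for e, c in self.interpolated],
            "dropped_epochs": [int(e) for e in self.dropped_epochs],
            "notes": list(self.notes),
            "n_interpolated": len(self.interpolated),
        }


def spline_interpolate_channels(montage: Montage, data: np.ndarray,
                                bad: np.ndarray,
                                G: np.ndarray | None = None) -> np.ndarray:
    """Replace channels listed in ``bad`` by spherical-spline predictions
    from the remaining channels (Perrin interpolation, m=4 stiffness via the
    same g-kernel as the CSD transform). ``G`` may be a precomputed spline
    kernel matrix for the montage."""
    from robot_erp.csd_transform import g_matrix

    good = np.setdiff1d(np.arange(montage.n_channels), bad)
    if good.size < 4:
        raise ValueError("too few good channels for spline interpolation")
    if G is None:
        cos_all = np.clip(montage.positions @ montage.positions.T, -1, 1)
        G = g_matrix(cos_all, m=4, n_terms=50)
    Ggg = G[np.ix_(good, good)] + 1e-5 * np.eye(good.size)
    Gbg = G[np.ix_(bad, good)]
    # constrained spline fit: [Ggg 1; 1' 0][c; mu] = [v; 0]
    n = good.size
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = Ggg
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.zeros((n + 1, data.shape[1]))
    rhs[:n] = data[good]
    sol = np.linalg.solve(A, rhs)
    c, mu = sol[:n], sol[n]
    out = data.copy()
    out[bad] = Gbg @ c + mu[None, :]
    return out


def clean_epochs(epochs: EpochSet, montage: Montage, z_thresh: float = 3.0,
                 max_bad_fraction: float = 0.2) -> tuple[EpochSet, RejectionLog]:
    """Per-epoch robust bad-channel detection and spline interpolation.

    A channel is bad within an epoch when its amplitude range or variance
    deviates from the cross-channel median by more than ``z_thresh`` robust
    (median/MAD) z-scores. Epochs with more than ``max_bad_fraction`` bad
    channels are dropped.
    """
    if epochs.channels and list(epochs.channels) != list(montage.labels):
        raise ValueError("epoch channels do not match the montage")
    log = RejectionLog()
    if "Fp1" in montage.labels and "Fp2" in montage.labels:
        i1, i2 = montage.index("Fp1"), montage.index("Fp2")
        log.virtual_eog = epochs.data[:, [i1, i2], :].mean(axis=1)
        log.notes.append("virtual EOG = mean(Fp1, Fp2) stored")
    log.notes.append(
        "artifact rejection is a threshold/interpolation surrogate, not ICA"
    )

    rng_feat = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (ep, ch)
    var_feat = epochs.data.var(axis=2)

    def robust_z(x: np.ndarray, axis: int) -> np.ndarray:
        med = np.median(x, axis=axis, keepdims=True)
        mad = np.median(np.abs(x - med), axis=axis, keepdims=True)
        mad = np.where(mad < 1e-30, 1.0, mad)
        return (x - med) / (1.4826 * mad)

    # outlier in either direction: across channels within the epoch, or
    # across epochs within the channel (the latter catches epochs where a
    # majority of channels is corrupted and the per-epoch median is useless)
    bad = np.zeros(rng_feat.shape, dtype=bool)
    for feat in (rng_feat, var_feat):
        bad |= np.abs(robust_z(feat, axis=1)) > z_thresh
        if epochs.n_epochs >= 16:
            bad |= np.abs(robust_z(feat, axis=0)) > z_thresh

    from robot_erp.csd_transform import g_matrix

    cos_all = np.clip(montage.positions @ montage.positions.T, -1, 1)
    G = g_matrix(cos_all, m=4, n_terms=50)
    keep, new_data = [], []
    for ep in range(epochs.n_epochs):
        bad_ch = np.flatnonzero(bad[ep])
        if bad_ch.size > max_bad_fraction * epochs.n_channels:
            log.dropped_epochs.append(ep)
            continue
        d = epochs.data[ep]
        if bad_ch.size:
            d = spline_interpolate_channels(montage, d, bad_ch, G=G)
            log.interpolated.extend((ep, int(c)) for c in bad_ch)
        keep.append(ep)
        new_data.append(d)
    if not keep:
        raise ValueError("all epochs rejected")
    return (
        epochs.copy_with(data=np.stack(new_data),
                         labels=epochs.labels[np.array(keep)]),
        log,
    )


# ---------------------------------------------------------------------------
# condition equalization
# ---------------------------------------------------------------------------


def _best_monotone_match(maj_pos: np.ndarray, min_pos: np.ndarray) -> np.ndarray:
    """Indices into maj_pos of the order-preserving subset of size
    len(min_pos) minimizing sum |maj_pos[j_i] - min_pos[i]|; earliest-index
    choice on ties (dynamic program)."""
    n_maj, n_min = len(maj_pos), len(min_pos)
    INF = np.inf
    # cost[i][j]: best cost matching first i minority epochs using majority
    # epochs from index >= j is computed backwards; we keep choice table.
    cost = np.full((n_min + 1, n_maj + 1), INF)
    cost[n_min, :] = 0.0
    choice = np.full((n_min, n_maj), -1, dtype=int)
    for i in range(n_min - 1, -1, -1):
        # matching minority i needs a majority index j with enough left over
        for j in range(n_maj - (n_min - i), -1, -1):
            take = abs(maj_pos[j] - min_pos[i]) + cost[i + 1, j + 1]
            skip = cost[i, j + 1]
            # prefer taking the earliest majority index on ties
            if take <= skip:
                cost[i, j] = take
                choice[i, j] = j
            else:
                cost[i, j] = skip
                choice[i, j] = -1
    picks = np.empty(n_min, dtype=int)
    j = 0
    for i in range(n_min):
        while choice[i, j] == -1:
            j += 1
        picks[i] = j
        j += 1
    return picks


def equalize_counts(epochs: EpochSet) -> EpochSet:
    """Drop majority-condition epochs so both conditions have equal counts,
    choosing the kept majority epochs to minimize the summed rank-position
    discrepancy against the minority sequence (deterministic)."""
    labs = epochs.labels
    conds = sorted(set(labs.tolist()))
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    idx_a = np.flatnonzero(labs == conds[0])
    idx_b = np.flatnonzero(labs == conds[1])
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("a condition has zero epochs")
    if idx_a.size == idx_b.size:
        return epochs
    if idx_a.size > idx_b.size:
        maj, mino = idx_a, idx_b
    else:
        maj, mino = idx_b, idx_a
    picks = _best_monotone_match(maj.astype(float), mino.astype(float))
    keep = np.sort(np.concatenate([mino, maj[picks]]))
    return epochs.copy_with(data=epochs.data[keep], labels=labs[keep])


# ---------------------------------------------------------------------------
# canonical chain
# ---------------------------------------------------------------------------


def preprocess_raw(raw: RawRecording, montage: Montage, *,
                   low: float = 0.2, high: float = 10.0, order: int = 4,
                   tmin: float = -0.2, tmax: float = 2.0,
                   target_srate: float = 250.0, z_thresh: float = 3.0,
                   subject: str = "unknown",
                   equalize: bool = True) -> tuple[EpochSet, RejectionLog]:
    """Run the full canonical preprocessing chain on one recording."""
    r = detrend(raw)
    r = bandpass(r, low=low, high=high, order=order)
    ep = epoch(r, tmin=tmin, tmax=tmax, subject=subject)
    ep = downsample(ep, target_srate)
    ep, log = clean_epochs(ep, montage, z_thresh=z_thresh)
    ep = baseline_correct(ep)
    if equalize:
        ep = equalize_counts(ep)
    return ep, log
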