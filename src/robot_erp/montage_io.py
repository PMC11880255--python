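"""Electrode geometry, channel adjacency, and raw/epoch file I/O.

The 64-channel study montage uses idealized spherical 10-10 coordinates
constructed from the standard arc-fraction rules of the extended 10-20
system (midline nasion-inion arc divided in 10% steps, the circumferential
ring at the 10% level, intermediate electrodes by great-circle interpolation
between the midline and ring electrode of the same row). Coordinates are
unit vectors in head frame: +x right, +y anterior, +z up, Cz at the vertex.
"""

from __future__ import annotations

import configparser
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

EPOCHS_SCHEMA_VERSION = 1

# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class Montage:
    """Ordered electrode labels with unit-sphere positions."""

    labels: list[str]
    positions: np.ndarray  # (n, 3), unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class RawRecording:
    """Continuous multichannel recording in microvolts."""

    data: np.ndarray  # (channels, samples), uV
    srate: float
    events: list[tuple[int, str]]  # (sample index, condition label)
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        idx = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.data.shape[1]):
            raise ValueError("event sample index outside data range")


@dataclass
class EpochSet:
    """Epoched trials: (epochs, channels, time)."""

    data: np.ndarray
    srate: float
    tmin: float  # epoch start relative to stimulus onset, s
    labels: np.ndarray  # per-epoch condition strings
    subject: str = "unknown"
    unit: str = "potential_uV"  # or "csd"
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs, channels, time)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per epoch required")
        if self.unit not in ("potential_uV", "csd"):
            raise ValueError(f"unknown unit tag {self.unit!r}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.srate

    def copy_with(self, **kw) -> "EpochSet":
        out = dict(
            data=self.data,
            srate=self.srate,
            tmin=self.tmin,
            labels=self.labels,
            subject=self.subject,
            unit=self.unit,
            channels=list(self.channels),
        )
        out.update(kw)
        return EpochSet(**out)


# ---------------------------------------------------------------------------
# idealized 10-10 montage construction
# ---------------------------------------------------------------------------

# label list of the study cap (actiCAP 64, ground FPz, reference FCz), with
# the midline AFz included so every row of the extended 10-20 grid is
# complete.
STUDY64_LABELS = [
    "Fp1", "Fp2", "Fz", "AF3", "AF4", "AF7", "AF8", "AFz",
    "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8",
    "FC1", "FC2", "FC3", "FC4", "FC5", "FC6",
    "FT7", "FT8", "FT9", "FT10",
    "Cz", "C1", "C2", "C3", "C4", "C5", "C6",
    "T7", "T8",
    "CPz", "CP1", "CP2", "CP3", "CP4", "CP5", "CP6",
    "TP7", "TP8", "TP9", "TP10",
    "Pz", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
    "POz", "PO3", "PO4", "PO7", "PO8",
    "Oz", "O1", "O2", "Iz",
]


def _sph(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector from polar angle theta (from vertex) and azimuth phi
    (0 = anterior midline, positive toward the right ear)."""
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Great-circle interpolation between unit vectors a and b."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def _build_study64_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}

    # Midline: nasion-inion arc in 10% steps of 180 deg. Anterior azimuth 0,
    # posterior azimuth 180. Cz sits exactly at the vertex.
    midline = {
        "Fpz": (72.0, 0.0), "AFz": (54.0, 0.0), "Fz": (36.0, 0.0),
        "FCz": (18.0, 0.0), "Cz": (0.0, 0.0), "CPz": (18.0, 180.0),
        "Pz": (36.0, 180.0), "POz": (54.0, 180.0), "Oz": (72.0, 180.0),
        "Iz": (90.0, 180.0),
    }
    for lab, (th, ph) in midline.items():
        pos[lab] = _sph(th, ph)

    # Circumferential ring at polar angle 72 deg, azimuth steps of 18 deg.
    ring = {
        "Fp1": -18, "Fp2": 18, "AF7": -36, "AF8": 36, "F7": -54, "F8": 54,
        "FT7": -72, "FT8": 72, "T7": -90, "T8": 90, "TP7": -108, "TP8": 108,
        "P7": -126, "P8": 126, "PO7": -144, "PO8": 144, "O1": -162, "O2": 162,
    }
    for lab, ph in ring.items():
        pos[lab] = _sph(72.0, float(ph))

    # Inferior ring (10% below the main ring) for FT9/FT10, TP9/TP10.
    for lab, ph in {"FT9": -72, "FT10": 72, "TP9": -108, "TP10": 108}.items():
        pos[lab] = _sph(90.0, float(ph))

    # Intermediate electrodes: great-circle interpolation between the row's
    # midline electrode and its ring electrode; indices 1/3/5 at 25/50/75%.
    rows = {
        "AF": ("AFz", "AF7", "AF8", {"3": 0.5}),
        "F": ("Fz", "F7", "F8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "FC": ("FCz", "FT7", "FT8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "C": ("Cz", "T7", "T8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "CP": ("CPz", "TP7", "TP8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "P": ("Pz", "P7", "P8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "PO": ("POz", "PO7", "PO8", {"3": 0.5}),
    }
    for row, (mid, left, right, fracs) in rows.items():
        for idx, t in fracs.items():
            odd = int(idx)
            pos[f"{row}{odd}"] = _slerp(pos[mid], pos[left], t)
            pos[f"{row}{odd + 1}"] = _slerp(pos[mid], pos[right], t)

    return pos


def load_standard_montage(name: str) -> Montage:
    """Return a packaged montage by identifier.

    Only ``"study64"`` is known: the 64-channel extended 10-20 cap of the
    study, with idealized spherical coordinates.
    """
    if name != "study64":
        raise ValueError(f"unknown montage {name!r}")
    pos = _build_study64_positions()
    arr = np.array([pos[lab] for lab in STUDY64_LABELS])
    arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    return Montage(labels=list(STUDY64_LABELS), positions=arr)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


def azimuthal_projection(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection about the vertex (+z pole).

    Radius = polar angle, azimuth preserved; distances from the pole are
    exact, so neighborhood structure near the cap is faithful.
    """
    p = np.asarray(positions, dtype=float)
    theta = np.arccos(np.clip(p[:, 2], -1.0, 1.0))
    az = np.arctan2(p[:, 0], p[:, 1])
    return np.column_stack([theta * np.sin(az), theta * np.cos(az)])


def adjacency(montage: Montage) -> np.ndarray:
    """Channel adjacency via Delaunay triangulation of the 2-D projection.

    Parameter-free and guaranteed connected: the triangulation of the
    projected electrode cloud is a planar connected graph.
    """
    from scipy.spatial import Delaunay, QhullError

    n = montage.n_channels
    if n < 4:
        raise ValueError("adjacency requires at least 4 channels")
    pts = azimuthal_projection(montage.positions)
    try:
        tri = Delaunay(pts)
    except QhullError as err:  # pragma: no cover - degenerate geometry
        raise ValueError(f"degenerate electrode geometry: {err}") from err
    adj = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            adj[a, b] = adj[b, a] = True
    np.fill_diagonal(adj, False)
    return adj


# ---------------------------------------------------------------------------
# BrainVision I/O
# ---------------------------------------------------------------------------


def _parse_vhdr(header_path: str) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False)
    with open(header_path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    # headers start with a non-INI magic line; drop anything before the
    # first section
    start = text.find("[")
    cp.read_string(text[start:])
    return cp


def read_brainvision(header_path: str) -> RawRecording:
    """Read a BrainVision triplet (.vhdr/.vmrk/.eeg) into a RawRecording.

    Supports the common layout: multiplexed binary, IEEE float32 or int16
    with per-channel resolution. Stimulus markers become events labelled by
    their marker description.
    """
    cp = _parse_vhdr(header_path)
    common = cp["Common Infos"]
    base = os.path.dirname(os.path.abspath(header_path))
    data_file = os.path.join(base, common["DataFile"])
    marker_file = os.path.join(base, common["MarkerFile"])
    for f in (data_file, marker_file):
        if not os.path.exists(f):
            raise FileNotFoundError(f"companion file missing: {f}")
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY data format supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation supported")
    n_chan = int(common["NumberOfChannels"])
    srate = 1e6 / float(common["SamplingInterval"])  # interval is in us

    fmt = cp["Binary Infos"]["BinaryFormat"].upper()
    labels: list[str] = []
    resolutions = np.ones(n_chan)
    ch = cp["Channel Infos"]
    for i in range(n_chan):
        parts = ch[f"Ch{i + 1}"].split(",")
        labels.append(parts[0])
        if len(parts) > 2 and parts[2].strip():
            resolutions[i] = float(parts[2])

    raw_bytes = np.fromfile(data_file, dtype=np.uint8)
    if fmt == "IEEE_FLOAT_32":
        flat = raw_bytes.view("<f4").astype(float)
        scale = np.ones(n_chan)
    elif fmt == "INT_16":
        flat = raw_bytes.view("<i2").astype(float)
        scale = resolutions
    else:
        raise ValueError(f"unsupported binary format {fmt!r}")
    if flat.size % n_chan:
        raise ValueError("data file size not a multiple of the channel count")
    data = flat.reshape(-1, n_chan).T * scale[:, None]

    events: list[tuple[int, str]] = []
    mcp = _parse_vhdr(marker_file)
    mk = mcp["Marker Infos"]
    for key in sorted(mk, key=lambda k: int(k[2:])):
        parts = mk[key].split(",")
        mtype, desc, pos = parts[0], parts[1], int(parts[2])
        if mtype.strip().lower() != "stimulus":
            continue
        sample = pos - 1  # marker positions are 1-based
        if not (0 <= sample < data.shape[1]):
            raise ValueError(f"marker at sample {sample} outside data range")
        events.append((sample, desc.strip()))
    events.sort(key=lambda e: e[0])
    return RawRecording(data=data, srate=srate, events=events, channels=labels)


def write_brainvision(raw: RawRecording, header_path: str) -> None:
    """Write a RawRecording as a float32 multiplexed BrainVision triplet."""
    base, _ = os.path.splitext(header_path)
    name = os.path.basename(base)
    eeg_file, vmrk_file = base + ".eeg", base + ".vmrk"
    n_chan = raw.data.shape[0]
    channels = raw.channels or [f"Ch{i + 1}" for i in range(n_chan)]
    with open(header_path, "w", encoding="utf-8") as fh:
        fh.write("BrainVision Data Exchange Header File Version 1.0\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={name}.eeg\nMarkerFile={name}.vmrk\n")
        fh.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        fh.write(f"NumberOfChannels={n_chan}\n")
        fh.write(f"SamplingInterval={1e6 / raw.srate:.6f}\n")
        fh.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n")
        fh.write("[Channel Infos]\n")
        for i, lab in enumerate(channels):
            fh.write(f"Ch{i + 1}={lab},,1,µV\n")
    raw.data.T.astype("<f4").tofile(eeg_file)
    with open(vmrk_file, "w", encoding="utf-8") as fh:
        fh.write("BrainVision Data Exchange Marker File Version 1.0\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={name}.eeg\n")
        fh.write("[Marker Infos]\n")
        fh.write(f"Mk1=New Segment,,1,1,0\n")
        for k, (sample, label) in enumerate(raw.events, start=2):
            fh.write(f"Mk{k}=Stimulus,{label},{sample + 1},1,0\n")


# ---------------------------------------------------------------------------
# HDF5 epoch container
# ---------------------------------------------------------------------------


def save_epochs(epochs: EpochSet, path: str) -> None:
    """Write an EpochSet to an HDF5 container.

    Layout: datasets ``data`` (epochs x channels x time, float64) and
    ``labels`` (UTF-8 strings); attributes ``schema_version``, ``srate``,
    ``tmin``, ``unit``, ``subject`` and ``channels``.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = EPOCHS_SCHEMA_VERSION
        f.attrs["srate"] = float(epochs.srate)
        f.attrs["tmin"] = float(epochs.tmin)
        f.attrs["unit"] = epochs.unit
        f.attrs["subject"] = str(epochs.subject)
        f.attrs["channels"] = [str(c) for c in epochs.channels]
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "labels", data=np.array([str(x) for x in epochs.labels], dtype=object),
            dtype=h5py.string_dtype("utf-8"),
        )


def load_epochs(path: str) -> EpochSet:
    """Inverse of :func:`save_epochs`; errors on schema-version mismatch."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != EPOCHS_SCHEMA_VERSION:
            raise ValueError(
                f"epoch container schema version {version} != "
                f"{EPOCHS_SCHEMA_VERSION}"
            )
        labels = np.array([s.decode() if isinstance(s, bytes) else str(s)
                           for s in f["labels"][()]])
        return EpochSet(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            tmin=float(f.attrs["tmin"]),
            labels=labels,
            subject=str(f.attrs["subject"]),
            unit=str(f.attrs["unit"]),
            channels=[str(c) for c in f.attrs["channels"]],
        )
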