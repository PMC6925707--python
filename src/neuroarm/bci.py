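"""Motor-imagery EEG classification pipeline.

The pipeline mirrors a classical band-power BCI: 19-channel 10-20 recordings
at 1000 Hz are notch/band-pass filtered (zero-phase), surface-Laplacian
referenced, and cut into 4-s stimulus-locked epochs.  Discriminative
(channel, frequency-band) features are picked from r-squared maps (squared
point-biserial correlation between per-epoch band power and the binary
condition label), band powers form the feature vectors, and three pairwise
linear discriminants (left-hand imagery vs right-hand imagery, each vs
rest) vote: each pairwise model takes the mode over overlapping 2-s
subepochs, and the epoch receives the class named by at least two of the
three models (otherwise it is rejected, which the controllers treat as
rest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "CHANNELS_10_20",
    "LAPLACIAN_NEIGHBORS",
    "CLASSES",
    "EEGRecording",
    "Epoch",
    "FeatureDef",
    "PairwiseLDA",
    "ConsensusClassifier",
    "notch_filter",
    "bandpass_filter",
    "laplacian_filter",
    "preprocess",
    "epochs_from_events",
    "make_subepochs",
    "band_power",
    "epoch_bin_powers",
    "r2_from_powers",
    "r2_map",
    "R2_BIN_STARTS",
    "select_features",
    "train_pairwise",
    "train_consensus",
    "train_consensus_from_features",
    "decide_from_features",
    "classify_epoch",
    "score_session",
    "cross_validated_accuracy",
    "save_recording",
    "load_recording",
]

#: the 19-channel 10-20 montage, in recording order
CHANNELS_10_20 = [
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Cz", "Fz", "Pz",
]

#: small-Laplacian neighbor table for the 19-channel montage (configuration,
#: not physiology: nearest electrodes available in this cap)
LAPLACIAN_NEIGHBORS: dict[str, list[str]] = {
    "FP1": ["FP2", "F7", "F3"],
    "FP2": ["FP1", "F8", "F4"],
    "F3": ["FP1", "F7", "C3", "Fz"],
    "F4": ["FP2", "F8", "C4", "Fz"],
    "C3": ["F3", "P3", "T3", "Cz"],
    "C4": ["F4", "P4", "T4", "Cz"],
    "P3": ["C3", "T5", "O1", "Pz"],
    "P4": ["C4", "T6", "O2", "Pz"],
    "O1": ["P3", "T5", "O2"],
    "O2": ["P4", "T6", "O1"],
    "F7": ["FP1", "F3", "T3"],
    "F8": ["FP2", "F4", "T4"],
    "T3": ["F7", "C3", "T5"],
    "T4": ["F8", "C4", "T6"],
    "T5": ["T3", "P3", "O1"],
    "T6": ["T4", "P4", "O2"],
    "Cz": ["C3", "C4", "Fz", "Pz"],
    "Fz": ["F3", "F4", "Cz"],
    "Pz": ["P3", "P4", "Cz", "O1", "O2"],
}

#: class code mapping: I = 1, 2, 3
CLASSES = {1: "LHIM", 2: "rest", 3: "RHIM"}
CLASS_CODES = {v: k for k, v in CLASSES.items()}


@dataclass
class EEGRecording:
    """channels x samples matrix in microvolts with an event table.

    ``events`` is a DataFrame with columns ``onset_s``, ``duration_s``,
    ``label`` (and optionally ``trial``).
    """

    data: np.ndarray
    fs: float = 1000.0
    channel_labels: list[str] = field(default_factory=lambda: list(CHANNELS_10_20))
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["onset_s", "duration_s", "label"]))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if set(self.channel_labels) != set(CHANNELS_10_20):
            raise ValueError("channel labels must be the 19-channel 10-20 montage")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if len(self.events) and (self.events["onset_s"].min() < 0
                                 or self.events["onset_s"].max() > self.duration_s):
            raise ValueError("event onsets must lie within the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError as err:
            raise KeyError(f"unknown channel {label!r}") from err


@dataclass
class Epoch:
    """Stimulus-locked segment: channels x samples, with its class label."""

    data: np.ndarray
    label: str
    onset: float = 0.0
    fs: float = 1000.0
    channel_labels: list[str] = field(default_factory=lambda: list(CHANNELS_10_20))
    trial: int = 0

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError as err:
            raise KeyError(f"unknown channel {label!r}") from err


@dataclass(frozen=True)
class FeatureDef:
    """One feature: band power (microvolt^2) of ``channel`` in [lo, hi] Hz."""

    channel: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi <= 70.0 + 1e-9):
            raise ValueError("feature bands must lie within 1-70 Hz")

    def __str__(self) -> str:
        return f"{self.channel} ({self.lo:g}-{self.hi:g})"


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def _check_band(band: tuple[float, float], fs: float) -> None:
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2})")


def bandpass_filter(data: np.ndarray, band: tuple[float, float], fs: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    _check_band(band, fs)
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def notch_filter(data: np.ndarray, freq: float, fs: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch (power-line removal)."""
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.filtfilt(b, a, data, axis=-1)


def laplacian_filter(data: np.ndarray, channel_labels: Sequence[str],
                     neighbors: dict[str, list[str]] | None = None) -> np.ndarray:
    """Surface Laplacian: each channel minus the mean of its montage neighbors."""
    neighbors = neighbors or LAPLACIAN_NEIGHBORS
    idx = {c: i for i, c in enumerate(channel_labels)}
    out = np.empty_like(data)
    for i, ch in enumerate(channel_labels):
        nb = [idx[n] for n in neighbors.get(ch, []) if n in idx]
        out[i] = data[i] - data[nb].mean(axis=0) if nb else data[i]
    return out


def preprocess(rec: EEGRecording, band: tuple[float, float] = (1.0, 100.0),
               notch: float | None = 60.0, laplacian: bool = True) -> EEGRecording:
    """Standard conditioning: Laplacian reference, notch, zero-phase band-pass."""
    _check_band(band, rec.fs)
    data = rec.data
    if laplacian:
        data = laplacian_filter(data, rec.channel_labels)
    if notch is not None:
        data = notch_filter(data, notch, rec.fs)
    data = bandpass_filter(data, band, rec.fs)
    return EEGRecording(data, rec.fs, list(rec.channel_labels), rec.events.copy())


# --------------------------------------------------------------------------
# epoching and features
# --------------------------------------------------------------------------

def epochs_from_events(rec: EEGRecording, duration_s: float = 4.0,
                       labels: Sequence[str] = ("LHIM", "rest", "RHIM")) -> list[Epoch]:
    """Cut stimulus-locked epochs for the given class labels."""
    out = []
    for _, ev in rec.events.iterrows():
        if ev["label"] not in labels:
            continue
        i0 = int(round(ev["onset_s"] * rec.fs))
        i1 = i0 + int(round(duration_s * rec.fs))
        if i1 > rec.n_samples:
            continue
        out.append(Epoch(rec.data[:, i0:i1], ev["label"], float(ev["onset_s"]),
                         rec.fs, list(rec.channel_labels),
                         trial=int(ev["trial"]) if "trial" in ev else 0))
    return out


def make_subepochs(epoch: Epoch, window: float = 2.0, stride: float = 0.0625) -> list[Epoch]:
    """Overlapping windows fully inside the epoch: count = floor((T-w)/s) + 1."""
    if stride <= 0:
        raise ValueError("stride must be positive")
    if window > epoch.duration_s + 1e-12:
        raise ValueError("subepoch window exceeds epoch duration")
    n = int(np.floor((epoch.duration_s - window) / stride + 1e-9)) + 1
    w = int(round(window * epoch.fs))
    out = []
    for k in range(n):
        i0 = int(round(k * stride * epoch.fs))
        out.append(Epoch(epoch.data[:, i0:i0 + w], epoch.label,
                         epoch.onset + k * stride, epoch.fs,
                         list(epoch.channel_labels), epoch.trial))
    return out


def band_power(epoch: Epoch, fdef: FeatureDef) -> float:
    """Mean squared amplitude of the band-filtered channel (microvolt^2)."""
    x = epoch.channel(fdef.channel)
    y = bandpass_filter(x, (fdef.lo, fdef.hi), epoch.fs)
    return float(np.mean(y ** 2))


#: lower edges of the 2-Hz analysis bins, 1-69 Hz
R2_BIN_STARTS = np.arange(1.0, 69.0, 2.0)


def epoch_bin_powers(epochs: Sequence[Epoch]) -> np.ndarray:
    """(n_epochs, n_channels, n_bins) band powers from per-epoch periodograms."""
    n_ch = len(epochs[0].channel_labels)
    fs = epochs[0].fs
    nper = min(int(fs), epochs[0].data.shape[1])
    powers = np.empty((len(epochs), n_ch, len(R2_BIN_STARTS)))
    for i, ep in enumerate(epochs):
        f, psd = sps.welch(ep.data, fs=fs, nperseg=nper, axis=-1)
        df = f[1] - f[0]
        for j, lo in enumerate(R2_BIN_STARTS):
            sel = (f >= lo) & (f < lo + 2.0)
            powers[i, :, j] = psd[:, sel].sum(axis=-1) * df
    return powers


def r2_from_powers(powers: np.ndarray, labels: Sequence[str],
                   pair: tuple[str, str]) -> np.ndarray:
    """r-squared map from precomputed (n_epochs, channels, bins) powers."""
    labels = np.asarray(labels)
    keep = np.isin(labels, pair)
    y = (labels[keep] == pair[1]).astype(float)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("both conditions need at least 2 epochs")
    X = powers[keep]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = np.einsum("nij,n->ij", Xc, yc)
    den = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r ** 2


def r2_map(epochs: Sequence[Epoch], pair: tuple[str, str]) -> np.ndarray:
    """Squared point-biserial correlation map, channels x 2-Hz bins.

    Each cell correlates per-epoch band power with the binary condition
    label over the epochs belonging to the two conditions in ``pair``.
    """
    return r2_from_powers(epoch_bin_powers(epochs),
                          [ep.label for ep in epochs], pair)


def select_features(r2: np.ndarray, k: int = 4,
                    channel_labels: Sequence[str] = CHANNELS_10_20) -> list[FeatureDef]:
    """Top-k (channel, bin) cells by r-squared, merging adjacent bins per channel.

    Ties break deterministically by channel order, then frequency.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_ch, n_bins = r2.shape
    if k > r2.size:
        raise ValueError("k exceeds the number of map cells")
    cells = [(-r2[c, b], c, b) for c in range(n_ch) for b in range(n_bins)]
    cells.sort()
    chosen = cells[:k]
    by_channel: dict[int, list[int]] = {}
    for _, c, b in chosen:
        by_channel.setdefault(c, []).append(b)
    feats = []
    for c in sorted(by_channel):
        bins = sorted(by_channel[c])
        start = prev = bins[0]
        for b in bins[1:] + [None]:
            if b is not None and b == prev + 1:
                prev = b
                continue
            lo = R2_BIN_STARTS[start]
            hi = R2_BIN_STARTS[prev] + 2.0
            feats.append(FeatureDef(channel_labels[c], lo, hi))
            if b is not None:
                start = prev = b
    return feats


# --------------------------------------------------------------------------
# LDA and consensus
# --------------------------------------------------------------------------

@dataclass
class PairwiseLDA:
    """Two-class linear discriminant: w proportional to pooled-Sigma^-1 (mu1-mu0),
    threshold at the projected midpoint of the class means."""

    pair: tuple[str, str]
    w: np.ndarray
    b: float

    def decide(self, X: np.ndarray) -> list[str]:
        X = np.atleast_2d(X)
        s = X @ self.w + self.b
        # ties (score exactly 0) go to the first-listed class
        return [self.pair[1] if v > 0 else self.pair[0] for v in s]


def train_pairwise(X: np.ndarray, labels: Sequence[str],
                   pair: tuple[str, str], cond_limit: float = 1e8) -> PairwiseLDA:
    """Closed-form LDA fit with ridge shrinkage for ill-conditioned covariance."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    X0, X1 = X[labels == pair[0]], X[labels == pair[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("both classes need at least 2 samples")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (len(X) - 2)
    S = np.atleast_2d(S)
    if not np.all(np.isfinite(S)) or np.linalg.cond(S) > cond_limit:
        ridge = max(np.trace(S) / S.shape[0] * 1e-4, 1e-12)
        S = S + np.eye(S.shape[0]) * ridge
    w = np.linalg.solve(S, mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return PairwiseLDA(pair, w, b)


PAIRS = (("LHIM", "RHIM"), ("LHIM", "rest"), ("RHIM", "rest"))


@dataclass
class ConsensusClassifier:
    """Three pairwise discriminants + subepoch voting + 2-of-3 consensus."""

    features: list[FeatureDef]
    discriminants: dict[tuple[str, str], PairwiseLDA]
    window: float = 2.0
    stride: float = 0.0625
    log_power: bool = False

    def feature_matrix(self, epochs: Sequence[Epoch]) -> np.ndarray:
        """(n_epochs, n_subepochs, n_features) subepoch band powers."""
        rows = []
        for ep in epochs:
            subs = make_subepochs(ep, self.window, self.stride)
            w = subs[0].data.shape[1]
            feat = np.empty((len(subs), len(self.features)))
            for j, fd in enumerate(self.features):
                y = bandpass_filter(ep.channel(fd.channel), (fd.lo, fd.hi), ep.fs)
                for i, sub in enumerate(subs):
                    i0 = int(round((sub.onset - ep.onset) * ep.fs))
                    feat[i, j] = np.mean(y[i0:i0 + w] ** 2)
            rows.append(np.log(feat + 1e-12) if self.log_power else feat)
        return np.stack(rows)

    def to_json_dict(self) -> dict:
        return {
            "features": [{"channel": f.channel, "lo": f.lo, "hi": f.hi}
                         for f in self.features],
            "discriminants": {
                "|".join(p): {"w": d.w.tolist(), "b": d.b}
                for p, d in self.discriminants.items()
            },
            "window": self.window,
            "stride": self.stride,
            "log_power": self.log_power,
        }

    @staticmethod
    def from_json_dict(d: dict) -> "ConsensusClassifier":
        feats = [FeatureDef(**f) for f in d["features"]]
        disc = {}
        for key, dd in d["discriminants"].items():
            pair = tuple(key.split("|"))
            disc[pair] = PairwiseLDA(pair, np.array(dd["w"]), float(dd["b"]))
        return ConsensusClassifier(feats, disc, d["window"], d["stride"],
                                   d.get("log_power", False))


def _mode_decision(decisions: Sequence[str], pair: tuple[str, str]) -> str:
    counts = {pair[0]: 0, pair[1]: 0}
    for d in decisions:
        counts[d] += 1
    # tie toward the first-listed class of the pair
    return pair[1] if counts[pair[1]] > counts[pair[0]] else pair[0]


def train_consensus_from_features(F: np.ndarray, labels: Sequence[str],
                                  features: list[FeatureDef],
                                  window: float = 2.0, stride: float = 0.0625,
                                  log_power: bool = False) -> ConsensusClassifier:
    """Fit the three pairwise discriminants on a precomputed
    (n_epochs, n_subepochs, n_features) array of subepoch band powers."""
    clf = ConsensusClassifier(features, {}, window, stride, log_power)
    rep = np.repeat(list(labels), F.shape[1])
    X = F.reshape(-1, F.shape[2])
    for pair in PAIRS:
        sel = np.isin(rep, pair)
        clf.discriminants[pair] = train_pairwise(X[sel], rep[sel], pair)
    return clf


def train_consensus(epochs: Sequence[Epoch], features: list[FeatureDef],
                    window: float = 2.0, stride: float = 0.0625,
                    log_power: bool = False) -> ConsensusClassifier:
    """Fit the three pairwise discriminants on subepoch feature vectors."""
    clf = ConsensusClassifier(features, {}, window, stride, log_power)
    F = clf.feature_matrix(epochs)
    return train_consensus_from_features(F, [ep.label for ep in epochs],
                                         features, window, stride, log_power)


def decide_from_features(clf: ConsensusClassifier, Fi: np.ndarray) -> str:
    """Consensus decision for one epoch's (n_subepochs, n_features) array."""
    modes = []
    for pair in PAIRS:
        decisions = clf.discriminants[pair].decide(Fi)
        modes.append(_mode_decision(decisions, pair))
    votes: dict[str, int] = {}
    for m in modes:
        votes[m] = votes.get(m, 0) + 1
    if max(votes.values()) < 2:
        return "reject"
    return max(votes, key=votes.get)


def classify_epoch(clf: ConsensusClassifier, epoch: Epoch) -> str:
    """Consensus decision: the class named by >= 2 pairwise modes, else 'reject'."""
    if epoch.duration_s < clf.window - 1e-9:
        raise ValueError("epoch shorter than the subepoch window")
    return decide_from_features(clf, clf.feature_matrix([epoch])[0])


def cross_validated_accuracy(epochs: Sequence[Epoch], features: list[FeatureDef],
                             n_folds: int | None = None,
                             reject_as: str = "rest",
                             per_class: bool = False):
    """Trial-grouped cross-validated consensus accuracy (fraction correct).

    Folds follow the ``trial`` field when present (leave-one-trial-out),
    otherwise ``n_folds`` contiguous blocks.  With ``per_class`` also
    returns a dict of per-class accuracies.
    """
    trials = sorted({ep.trial for ep in epochs})
    if len(trials) > 1 and n_folds is None:
        folds = [[i for i, ep in enumerate(epochs) if ep.trial == t] for t in trials]
    else:
        k = n_folds or 5
        idx = np.arange(len(epochs))
        folds = [list(f) for f in np.array_split(idx, k)]
    tmp = ConsensusClassifier(features, {})
    F = tmp.feature_matrix(epochs)
    labels = [ep.label for ep in epochs]
    hits: dict[str, list[int]] = {}
    for test in folds:
        train = [i for i in range(len(epochs)) if i not in set(test)]
        clf = train_consensus_from_features(
            F[train], [labels[i] for i in train], features)
        for i in test:
            lab = decide_from_features(clf, F[i])
            if lab == "reject":
                lab = reject_as
            hits.setdefault(labels[i], []).append(int(lab == labels[i]))
    acc = float(np.mean([h for v in hits.values() for h in v]))
    if per_class:
        return acc, {c: float(np.mean(v)) for c, v in sorted(hits.items())}
    return acc


# --------------------------------------------------------------------------
# session scoring
# --------------------------------------------------------------------------

def score_session(true_or_intended: Sequence[str], decisions: Sequence[str],
                  protocol: Literal["cued", "uncued_pc", "uncued_gs"] = "cued",
                  context: Sequence[dict] | None = None) -> float:
    """Session performance as a percentage.

    cued / uncued_gs: percent agreement between the instructed (or intended)
    and classified stimulus types.  uncued_pc: percent of stimuli whose
    resulting action reduced the effector-target distance or completed a
    needed axis change (``context`` supplies per-stimulus step outcomes with
    boolean fields ``reduced_distance`` and ``completed_needed_axis_change``).
    """
    if protocol in ("cued", "uncued_gs"):
        a, b = list(true_or_intended), list(decisions)
        if len(a) != len(b):
            raise ValueError("label sequences must have equal length")
        if not a:
            raise ValueError("empty session")
        return 100.0 * float(np.mean([x == y for x, y in zip(a, b)]))
    if protocol == "uncued_pc":
        if context is None:
            raise ValueError("uncued_pc scoring requires step outcomes")
        ok = [bool(c.get("reduced_distance") or c.get("completed_needed_axis_change"))
              for c in context]
        if not ok:
            raise ValueError("empty session")
        return 100.0 * float(np.mean(ok))
    raise ValueError(f"unknown protocol {protocol!r}")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def save_recording(rec: EEGRecording, prefix: str | Path) -> None:
    """Write <prefix>.dat (channels x samples, whitespace-delimited),
    <prefix>.json sidecar and <prefix>_events.csv."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".dat"), rec.data, fmt="%.6g")
    prefix.with_suffix(".json").write_text(json.dumps(
        {"fs": rec.fs, "channel_labels": rec.channel_labels}))
    rec.events.to_csv(f"{prefix}_events.csv", index=False)


def load_recording(prefix: str | Path) -> EEGRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.loadtxt(prefix.with_suffix(".dat"))
    ev_path = Path(f"{prefix}_events.csv")
    events = pd.read_csv(ev_path) if ev_path.exists() else pd.DataFrame(
        columns=["onset_s", "duration_s", "label"])
    return EEGRecording(data, meta["fs"], meta["channel_labels"], events)
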