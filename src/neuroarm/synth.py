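"""Synthetic study data: EEG sessions and tabletop camera scenes.

The EEG generator emulates the experimental protocols (15-s baseline, 2-s
prestimulus cue, 4-s stimuli, randomized class order with fixed per-class
counts) on a 19-channel 10-20 montage at 1000 Hz.  Signals are pink (1/f)
background noise plus a 10-Hz mu rhythm at the central electrodes whose
amplitude drops contralaterally during imagined hand movement
(event-related desynchronization), plus a stimulus-locked positive
P300-like deflection at O1/O2/Pz whose amplitude and latency drift
linearly with trial repetition (the mental-fatigue signature).

The scene generator renders the 400x400 mm marker-delimited table plane
through a ground-truth projective camera, producing a 640x480 RGB image
plus a JSON-able ground-truth record of every centroid.

Every generator is a pure function of (spec, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .bci import CHANNELS_10_20, EEGRecording
from .vision import MARKER_WORLD_MM, Homography, table_to_robot

__all__ = [
    "ProtocolSpec",
    "SubjectParams",
    "PROTOCOLS",
    "gen_protocol",
    "gen_eeg_session",
    "pink_noise",
    "default_camera_homography",
    "gen_scene",
]

TrialType = Literal["training", "cued_pc", "uncued_pc", "cued_gs", "uncued_gs"]


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and stimulus-count layout of one trial (one protocol run)."""

    trial_type: TrialType = "training"
    baseline_s: float = 15.0
    prestimulus_s: float = 2.0
    stimulus_s: float = 4.0
    isi_range_s: tuple[float, float] = (2.0, 4.0)
    counts: dict = field(default_factory=lambda: {"LHIM": 10, "rest": 10, "RHIM": 10})

    @property
    def n_stimuli(self) -> int:
        return sum(self.counts.values())


#: protocol presets with the study's stimulus counts and interstimulus gaps
PROTOCOLS: dict[str, ProtocolSpec] = {
    "training": ProtocolSpec("training"),
    "cued_pc": ProtocolSpec("cued_pc", counts={"LHIM": 5, "rest": 5, "RHIM": 5}),
    "uncued_pc": ProtocolSpec("uncued_pc", counts={"imagine": 20}),
    # goal-selection prestimulus: 2-s cross + 1-s beep; manipulation happens
    # in the long 27-29 s interstimulus gap
    "cued_gs": ProtocolSpec("cued_gs", prestimulus_s=3.0, isi_range_s=(27.0, 29.0),
                            counts={"LHIM": 5, "rest": 5, "RHIM": 5}),
    "uncued_gs": ProtocolSpec("uncued_gs", prestimulus_s=3.0, isi_range_s=(27.0, 29.0),
                              counts={"imagine": 15}),
}


@dataclass(frozen=True)
class SubjectParams:
    """Synthetic-subject signal model.

    erd_depth: fractional mu-power drop during imagery (0-1); applied to C3
    for right-hand imagery and C4 for left-hand imagery (contralateral).
    p300_*: baseline amplitude (microvolt) / latency (ms) and their linear
    per-trial-repetition slopes.  noise_sd: pink-noise RMS per channel.
    """

    erd_depth: float = 0.5
    mu_amp_uv: float = 10.0
    noise_sd_uv: float = 5.0
    p300_amp0_uv: float = 5.0
    p300_amp_slope_uv: float = 0.0
    p300_lat0_ms: float = 350.0
    p300_lat_slope_ms: float = 0.0
    p300_width_ms: float = 60.0  # FWHM of the Gaussian deflection
    erd_ramp_s: float = 0.25

    def __post_init__(self):
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must be in [0, 1]")


ERD_CHANNEL = {"RHIM": "C3", "LHIM": "C4"}
P300_CHANNELS = ("O1", "O2", "Pz")

_P300_BAND = (1.0, 10.0)
_template_cache: dict = {}


def _p300_template(fs: float, width_ms: float) -> tuple[np.ndarray, int]:
    """Unit-peak P300-like deflection: a Gaussian of the given FWHM,
    band-limited to 1-10 Hz so its peak amplitude is what a standard ERP
    band-pass preserves.  Returns (waveform, index of the peak sample)."""
    key = (fs, width_ms)
    if key not in _template_cache:
        from .bci import bandpass_filter

        sigma = width_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        half = int(round(0.6 * fs))
        t = (np.arange(2 * half + 1) - half) / fs
        g = np.exp(-0.5 * (t / sigma) ** 2)
        g1 = bandpass_filter(g, _P300_BAND, fs)
        # normalize so that one further pass of the standard ERP band-pass
        # (as applied at extraction time) leaves a unit peak
        g2 = bandpass_filter(g1, _P300_BAND, fs)
        k = int(np.argmax(g2))
        _template_cache[key] = (g1 / g2[k], k)
    return _template_cache[key]


def _add_p300(data: np.ndarray, onsets_s: Sequence[float], amp: float,
              lat_s: float, width_ms: float, fs: float,
              channel_rows: Sequence[int]) -> None:
    tmpl, k = _p300_template(fs, width_ms)
    n = data.shape[1]
    for onset in onsets_s:
        i_peak = int(round((onset + lat_s) * fs))
        lo, hi = i_peak - k, i_peak - k + len(tmpl)
        s0, s1 = max(lo, 0), min(hi, n)
        if s0 >= s1:
            continue
        seg = tmpl[s0 - lo:s1 - lo] * amp
        for r in channel_rows:
            data[r, s0:s1] += seg


def gen_protocol(spec: ProtocolSpec, seed: int,
                 class_sequence: Sequence[str] | None = None) -> pd.DataFrame:
    """Randomized event table with exact per-class counts and protocol timing.

    ``class_sequence`` overrides the randomized order (used for scripted
    uncued sessions where a policy decides each intent).
    """
    rng = np.random.default_rng(seed)
    if class_sequence is None:
        labels = [c for c, n in spec.counts.items() for _ in range(n)]
        rng.shuffle(labels)
    else:
        labels = list(class_sequence)
    t = spec.baseline_s
    rows = []
    for lab in labels:
        t += spec.prestimulus_s
        rows.append({"onset_s": round(t, 6), "duration_s": spec.stimulus_s, "label": lab})
        t += spec.stimulus_s
        t += float(rng.uniform(*spec.isi_range_s))
    return pd.DataFrame(rows)


def pink_noise(shape: tuple[int, ...], rng: np.random.Generator,
               rms: float = 1.0) -> np.ndarray:
    """1/f-amplitude noise along the last axis, scaled to the given RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    X = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    y = np.fft.irfft(X * scale, n=n, axis=-1)
    cur = np.sqrt(np.mean(y ** 2, axis=-1, keepdims=True))
    return y * (rms / np.maximum(cur, 1e-30))


def gen_eeg_session(spec: ProtocolSpec, params: SubjectParams, seed: int,
                    trial_index: int = 0, fs: float = 1000.0,
                    class_sequence: Sequence[str] | None = None) -> EEGRecording:
    """One protocol run as a 19 x N microvolt recording with embedded events.

    ``trial_index`` (0-based repetition within a session) drives the linear
    P300 amplitude/latency drift.  For 'imagine' protocols supply
    ``class_sequence`` with the intended classes; events keep those labels.
    """
    events = gen_protocol(spec, seed, class_sequence)
    last = events.iloc[-1]
    total_s = float(last["onset_s"] + last["duration_s"] + spec.isi_range_s[1] + 1.0)
    n = int(round(total_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence((seed, trial_index, 7919)))
    n_ch = len(CHANNELS_10_20)
    data = pink_noise((n_ch, n), rng, rms=params.noise_sd_uv)
    t = np.arange(n) / fs

    # mu rhythm at the central electrodes, with contralateral ERD during MI
    mu_phase = rng.uniform(0, 2 * np.pi, size=2)
    for k, ch in enumerate(("C3", "C4")):
        env = np.ones(n)
        for _, ev in events.iterrows():
            if ERD_CHANNEL.get(ev["label"]) != ch:
                continue
            env *= 1.0 - (1.0 - np.sqrt(1.0 - params.erd_depth)) * _window(
                t, ev["onset_s"], ev["duration_s"], params.erd_ramp_s)
        idx = CHANNELS_10_20.index(ch)
        data[idx] += params.mu_amp_uv * env * np.sin(2 * np.pi * 10.0 * t + mu_phase[k])

    # stimulus-locked P300-like deflection with per-trial drift
    amp = params.p300_amp0_uv + params.p300_amp_slope_uv * trial_index
    lat = (params.p300_lat0_ms + params.p300_lat_slope_ms * trial_index) / 1000.0
    _add_p300(data, events["onset_s"].to_numpy(), amp, lat,
              params.p300_width_ms, fs,
              [CHANNELS_10_20.index(c) for c in P300_CHANNELS])

    events = events.assign(trial=trial_index)
    return EEGRecording(data, fs, list(CHANNELS_10_20), events)


def gen_stimulus_block(spec: ProtocolSpec, params: SubjectParams, label: str,
                       trial_index: int, rng: np.random.Generator,
                       fs: float = 1000.0) -> tuple[np.ndarray, float]:
    """One prestimulus+stimulus+interstimulus block for online simulation.

    Returns ``(data, onset_s)`` where ``onset_s`` is the stimulus onset
    within the block.  Used by the uncued session drivers, where each
    intent is decided only after the previous stimulus was classified, so
    the recording is assembled block by block.
    """
    isi = float(rng.uniform(*spec.isi_range_s))
    total = spec.prestimulus_s + spec.stimulus_s + isi
    n = int(round(total * fs))
    data = pink_noise((len(CHANNELS_10_20), n), rng, rms=params.noise_sd_uv)
    t = np.arange(n) / fs
    onset = spec.prestimulus_s
    for k, ch in enumerate(("C3", "C4")):
        env = np.ones(n)
        if ERD_CHANNEL.get(label) == ch:
            env -= (1.0 - np.sqrt(1.0 - params.erd_depth)) * _window(
                t, onset, spec.stimulus_s, params.erd_ramp_s)
        idx = CHANNELS_10_20.index(ch)
        data[idx] += params.mu_amp_uv * env * np.sin(
            2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
    amp = params.p300_amp0_uv + params.p300_amp_slope_uv * trial_index
    lat = (params.p300_lat0_ms + params.p300_lat_slope_ms * trial_index) / 1000.0
    _add_p300(data, [onset], amp, lat, params.p300_width_ms, fs,
              [CHANNELS_10_20.index(c) for c in P300_CHANNELS])
    return data, onset


def _window(t: np.ndarray, onset: float, dur: float, ramp: float) -> np.ndarray:
    """Unit window over [onset, onset+dur] with raised-cosine ramps."""
    w = np.zeros_like(t)
    core = (t >= onset + ramp) & (t <= onset + dur - ramp)
    w[core] = 1.0
    up = (t >= onset) & (t < onset + ramp)
    w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - onset) / ramp))
    dn = (t > onset + dur - ramp) & (t <= onset + dur)
    w[dn] = 0.5 * (1 - np.cos(np.pi * (onset + dur - t[dn]) / ramp))
    return w


# --------------------------------------------------------------------------
# camera scenes
# --------------------------------------------------------------------------

def default_camera_homography() -> Homography:
    """Ground-truth table(mm) -> image(px) map for a fixed oblique camera.

    The camera sits behind the robot edge of the table, elevated and tilted
    roughly 35 degrees from the vertical, mimicking a webcam on a small
    tripod; chosen once so the whole 400x400 mm plane falls inside the
    640x480 frame.
    """
    C = np.array([200.0, 2060.0, 1680.0])  # camera center, mm
    look = np.array([200.0, 180.0, 0.0]) - C
    z = look / np.linalg.norm(look)
    x = np.array([-1.0, 0.0, 0.0])  # u axis (flipped so table +x maps rightward)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    t = -R @ C
    f = 2850.0
    K = np.array([[f, 0, 320.0], [0, f, 240.0], [0, 0, 1.0]])
    P = K @ np.column_stack([R[:, 0], R[:, 1], t])  # plane z=0
    return Homography(P)


# render colors (RGB, 0-255)
_PALETTE = {
    "table": (255, 255, 255),
    "background": (120, 120, 120),
    "cyan": (0, 255, 255),
    "orange": (255, 150, 0),
    "magenta": (255, 0, 255),
    "yellow": (255, 255, 0),
    "blue": (0, 70, 255),
    "green": (0, 190, 0),
    "red": (230, 0, 0),
}

DISK_RADIUS_MM = 13.0
DISK_HEIGHT_MM = 6.0
TARGET_RADIUS_MM = 42.0
MARKER_SIZE_MM = 30.0


def gen_scene(disk_table: tuple[float, float] | None = (200.0, 200.0),
              targets_table: dict[str, tuple[float, float]] | None = None,
              camera: Homography | None = None,
              noise_sd: float = 0.0, seed: int = 0,
              shape: tuple[int, int] = (480, 640),
              omit_markers: Sequence[str] = ()) -> tuple[np.ndarray, dict]:
    """Render the table scene and return (uint8 RGB image, ground truth).

    Items must lie inside the 400x400 mm plane.  Gaussian pixel noise with
    standard deviation ``noise_sd`` (on the 0-1 intensity scale) is added
    when nonzero.  The ground-truth dict records image/table/robot
    coordinates of every centroid.
    """
    if targets_table is None:
        targets_table = {"green": (100.0, 120.0), "red": (300.0, 120.0)}
    H = camera or default_camera_homography()
    for name, p in {"disk": disk_table, **targets_table}.items():
        if p is None:
            continue
        if not (0 <= p[0] <= 400 and 0 <= p[1] <= 400):
            raise ValueError(f"item {name} outside the 400x400 mm plane")

    h, w = shape
    vv, uu = np.mgrid[0:h, 0:w]
    pix = np.stack([uu.ravel(), vv.ravel(), np.ones(h * w)])
    Hinv = np.linalg.inv(H.H)
    world = Hinv @ pix
    x = (world[0] / world[2]).reshape(h, w)
    y = (world[1] / world[2]).reshape(h, w)
    behind = world[2].reshape(h, w) * H.H[2, 2] < 0  # points behind the camera

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = _PALETTE["background"]
    on_table = (x >= 0) & (x <= 400) & (y >= 0) & (y <= 400) & ~behind
    img[on_table] = _PALETTE["table"]

    def paint_disk(center, radius, color):
        m = ((x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius ** 2) & ~behind
        img[m] = _PALETTE[color]

    for color, p in targets_table.items():
        paint_disk(p, TARGET_RADIUS_MM, color)
    if disk_table is not None:
        paint_disk(disk_table, DISK_RADIUS_MM, "blue")
    half = MARKER_SIZE_MM / 2.0
    for color, (cx, cy) in MARKER_WORLD_MM.items():
        if color in omit_markers:
            continue
        m = (np.abs(x - cx) <= half) & (np.abs(y - cy) <= half) & ~behind
        img[m] = _PALETTE[color]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = img.astype(float) / 255.0 + rng.normal(0, noise_sd, img.shape)
        img = (np.clip(noisy, 0, 1) * 255).round().astype(np.uint8)

    def record(p):
        if p is None:
            return None
        uvw = H.H @ np.array([p[0], p[1], 1.0])
        return {
            "table_mm": [float(p[0]), float(p[1])],
            "robot_mm": [float(v) for v in table_to_robot(np.asarray(p))],
            "img_px": [float(uvw[0] / uvw[2]), float(uvw[1] / uvw[2])],
        }

    truth = {
        "markers": {c: record(p) for c, p in MARKER_WORLD_MM.items()
                    if c not in omit_markers},
        "disk": record(disk_table),
        "targets": {c: record(p) for c, p in targets_table.items()},
        "homography_table_to_image": H.H.tolist(),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return img, truth
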