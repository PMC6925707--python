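"""P300 feature extraction and the ANOVA fatigue analysis.

Stimulus-locked 1-s epochs (200 ms pre to 800 ms post stimulus) are
averaged per trial, baseline-corrected by the prestimulus mean, band-pass
filtered at 1-10 Hz (zero phase), and reduced to two features: the
amplitude of the most positive peak in the 200-500 ms window and its
latency.  A decreasing amplitude and increasing latency across trial
repetitions index growing mental fatigue.

The statistics mirror the study design: per-subject one-way ANOVAs
(factor: trial repetition) per channel and feature, and a two-way balanced
fixed-effects ANOVA (trial repetition x channel, sessions as replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .bci import EEGRecording, bandpass_filter

__all__ = [
    "P300Features",
    "AnovaTable",
    "erp_p300",
    "anova_oneway",
    "anova_twoway",
]

SEARCH_WINDOW_MS = (200.0, 500.0)
EPOCH_SPAN_MS = (-200.0, 800.0)


@dataclass(frozen=True)
class P300Features:
    """Per-trial P300 summary: peak amplitude (microvolt) and latency (ms)."""

    amplitude: float
    latency: float
    channel: str
    trial: int = 0
    session: int = 0


@dataclass
class AnovaTable:
    """F, p, degrees of freedom and sums of squares per factor."""

    factors: dict  # name -> {"F", "p", "df", "ss"}
    ss_error: float
    df_error: int
    ss_total: float

    def as_frame(self) -> pd.DataFrame:
        rows = [{"factor": k, **v} for k, v in self.factors.items()]
        rows.append({"factor": "error", "F": np.nan, "p": np.nan,
                     "df": self.df_error, "ss": self.ss_error})
        return pd.DataFrame(rows)


def erp_p300(rec: EEGRecording, channel: str,
             baseline_correct: bool = True,
             band: tuple[float, float] = (1.0, 10.0)) -> P300Features:
    """P300 amplitude/latency of one trial recording on one channel.

    Averages the stimulus-locked epochs of all events in the recording,
    baseline-corrects by the -200-0 ms mean, filters 1-10 Hz (zero-phase,
    4th order), and takes the most positive value in the 200-500 ms
    post-stimulus window (the window maximum; for a flat signal the first
    window sample is reported by convention).
    """
    if len(rec.events) == 0:
        raise ValueError("recording has no events")
    x = rec.channel(channel)
    fs = rec.fs
    pre = int(round(-EPOCH_SPAN_MS[0] / 1000.0 * fs))
    post = int(round(EPOCH_SPAN_MS[1] / 1000.0 * fs))
    segs = []
    for onset in rec.events["onset_s"]:
        i = int(round(onset * fs))
        if i - pre < 0 or i + post > rec.n_samples:
            continue
        segs.append(x[i - pre:i + post])
    if not segs:
        raise ValueError("no event fits inside the recording")
    avg = np.mean(segs, axis=0)
    if baseline_correct:
        avg = avg - avg[:pre].mean()
    avg = bandpass_filter(avg, band, fs)
    t_ms = (np.arange(len(avg)) - pre) / fs * 1000.0
    win = (t_ms >= SEARCH_WINDOW_MS[0]) & (t_ms <= SEARCH_WINDOW_MS[1])
    idx = np.flatnonzero(win)
    k = idx[np.argmax(avg[idx])]
    trial = int(rec.events["trial"].iloc[0]) if "trial" in rec.events else 0
    return P300Features(float(avg[k]), float(t_ms[k]), channel, trial=trial)


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------

def anova_oneway(groups: list[np.ndarray]) -> AnovaTable:
    """Classical one-way fixed-effects decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = 0.0 if ss_between <= 1e-300 else np.inf
    else:
        F = (ss_between / df_b) / ms_w
    p = float(spstats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaTable(
        factors={"group": {"F": float(F), "p": p, "df": df_b, "ss": float(ss_between)}},
        ss_error=float(ss_within), df_error=df_w,
        ss_total=float(((allv - grand) ** 2).sum()))


def anova_twoway(values: np.ndarray) -> AnovaTable:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``values`` has shape (levels_A, levels_B, replicates), replicates >= 2.
    In the fatigue analysis A is trial repetition (5 levels), B is channel
    (O1, O2, Pz) and the replicates are the three sessions.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3:
        raise ValueError("expected a balanced factorA x factorB x replicate array")
    a, b, r = v.shape
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")
    grand = v.mean()
    mean_a = v.mean(axis=(1, 2))
    mean_b = v.mean(axis=(0, 2))
    mean_ab = v.mean(axis=2)
    ss_a = b * r * ((mean_a - grand) ** 2).sum()
    ss_b = a * r * ((mean_b - grand) ** 2).sum()
    ss_ab = r * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_err = ((v - mean_ab[:, :, None]) ** 2).sum()
    ss_tot = ((v - grand) ** 2).sum()
    df = {"A": a - 1, "B": b - 1, "AB": (a - 1) * (b - 1)}
    df_err = a * b * (r - 1)
    ms_err = ss_err / df_err
    factors = {}
    for name, ss, d in (("trial", ss_a, df["A"]), ("channel", ss_b, df["B"]),
                        ("interaction", ss_ab, df["AB"])):
        if ms_err == 0:
            F = 0.0 if ss <= 1e-300 else np.inf
        else:
            F = (ss / d) / ms_err
        p = float(spstats.f.sf(F, d, df_err)) if np.isfinite(F) else 0.0
        factors[name] = {"F": float(F), "p": p, "df": d, "ss": float(ss)}
    return AnovaTable(factors=factors, ss_error=float(ss_err),
                      df_error=df_err, ss_total=float(ss_tot))
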