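"""End-to-end session drivers wiring the modules into the three study stages.

``run_training_session`` generates the training repetitions, builds the
r-squared maps, selects features, fits the pairwise-LDA consensus
classifier and reports cross-validated accuracy.  ``run_uncued_session``
simulates self-paced operation: a scripted intent policy stands in for the
volunteer, each intent is synthesized as EEG, classified, and fed to the
process-control or goal-selection controller; per-trial P300 features are
extracted along the way.  ``fatigue_analysis`` pools sessions into the
one-way and two-way ANOVA layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from . import bci, control, p300, synth
from .bci import (
    CHANNELS_10_20,
    ConsensusClassifier,
    EEGRecording,
    Epoch,
    FeatureDef,
    decide_from_features,
    epochs_from_events,
    select_features,
    train_consensus,
)
from .control import (
    ProcessControlState,
    StepOutcome,
    goal_selection_action,
    plan_pick_and_place,
    process_control_step,
)
from .kinematics import RobotModel
from .p300 import P300Features, anova_oneway, anova_twoway, erp_p300
from .synth import PROTOCOLS, SubjectParams, gen_eeg_session
from .vision import TableScene, robot_to_table

__all__ = [
    "SessionReport",
    "train_from_epochs",
    "run_training_session",
    "greedy_pc_policy",
    "run_uncued_session",
    "fatigue_analysis",
]

P300_CHANNELS = ("O1", "O2", "Pz")


@dataclass
class SessionReport:
    """Per-session summary: performance, features, P300 trends."""

    mode: str
    seed: int
    session: int = 0
    performance_pct: float = np.nan
    per_trial_pct: list[float] = field(default_factory=list)
    per_class_pct: dict = field(default_factory=dict)
    features: list[str] = field(default_factory=list)
    p300: list[P300Features] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def mean_sd(self) -> tuple[float, float]:
        a = np.asarray(self.per_trial_pct, dtype=float)
        if a.size == 0:
            return self.performance_pct, np.nan
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "session": self.session,
            "performance_pct": self.performance_pct,
            "per_trial_pct": self.per_trial_pct,
            "per_class_pct": self.per_class_pct,
            "features": self.features,
            "p300": [
                {"amplitude_uV": f.amplitude, "latency_ms": f.latency,
                 "channel": f.channel, "trial": f.trial, "session": f.session}
                for f in self.p300
            ],
            "extras": self.extras,
        }

    @staticmethod
    def from_json_dict(d: dict) -> "SessionReport":
        r = SessionReport(d["mode"], d["seed"], d["session"],
                          d["performance_pct"], list(d["per_trial_pct"]),
                          dict(d["per_class_pct"]), list(d["features"]),
                          extras=dict(d.get("extras", {})))
        r.p300 = [P300Features(f["amplitude_uV"], f["latency_ms"], f["channel"],
                               f["trial"], f["session"]) for f in d["p300"]]
        return r


def _select_from_powers(powers: np.ndarray, labels: Sequence[str],
                        k_features: int) -> list[FeatureDef]:
    """Top-k features from the element-wise max of the three pairwise maps."""
    maps = [bci.r2_from_powers(powers, labels, pair) for pair in bci.PAIRS]
    return select_features(np.maximum.reduce(maps), k=k_features)


def train_from_epochs(epochs: Sequence[Epoch], k_features: int = 4
                      ) -> tuple[ConsensusClassifier, list[FeatureDef]]:
    """Feature selection (max over the three pairwise r-squared maps) + fit."""
    powers = bci.epoch_bin_powers(epochs)
    features = _select_from_powers(powers, [ep.label for ep in epochs], k_features)
    clf = train_consensus(epochs, features)
    return clf, features


def nested_cv_accuracy(epochs: Sequence[Epoch], k_features: int = 4,
                       reject_as: str = "rest") -> tuple[float, dict]:
    """Leave-one-trial-out consensus accuracy with feature selection nested
    inside each fold (no selection leakage into the held-out trial)."""
    labels = [ep.label for ep in epochs]
    powers = bci.epoch_bin_powers(epochs)
    trials = sorted({ep.trial for ep in epochs})
    if len(trials) > 1:
        folds = [[i for i, ep in enumerate(epochs) if ep.trial == t] for t in trials]
    else:
        folds = [list(f) for f in np.array_split(np.arange(len(epochs)), 5)]
    feat_cache: dict[FeatureDef, np.ndarray] = {}

    def featmat(feats, idx):
        cols = []
        for fd in feats:
            if fd not in feat_cache:
                tmp = ConsensusClassifier([fd], {})
                feat_cache[fd] = tmp.feature_matrix(epochs)[:, :, 0]
            cols.append(feat_cache[fd][idx])
        return np.stack(cols, axis=-1)  # (len(idx), subs, feats)

    hits: dict[str, list[int]] = {}
    for test in folds:
        train = [i for i in range(len(epochs)) if i not in set(test)]
        feats = _select_from_powers(powers[train], [labels[i] for i in train],
                                    k_features)
        clf = bci.train_consensus_from_features(
            featmat(feats, train), [labels[i] for i in train], feats)
        Ftest = featmat(feats, test)
        for j, i in enumerate(test):
            lab = decide_from_features(clf, Ftest[j])
            if lab == "reject":
                lab = reject_as
            hits.setdefault(labels[i], []).append(int(lab == labels[i]))
    acc = float(np.mean([h for v in hits.values() for h in v]))
    return acc, {c: float(np.mean(v)) for c, v in sorted(hits.items())}


def run_training_session(params: SubjectParams, seed: int, n_trials: int = 5,
                         k_features: int = 4, session: int = 0) -> SessionReport:
    """Generate the training repetitions and evaluate the consensus classifier.

    Accuracy is epoch-level, leave-one-trial-out cross-validated with
    per-fold feature selection; the reported classifier and feature set are
    refit on all epochs.
    """
    spec = PROTOCOLS["training"]
    epochs: list[Epoch] = []
    for t in range(n_trials):
        rec = gen_eeg_session(spec, params, seed=seed * 1000 + t, trial_index=t)
        epochs.extend(epochs_from_events(rec))
    clf, features = train_from_epochs(epochs, k_features)
    acc, per_class = nested_cv_accuracy(epochs, k_features)
    report = SessionReport(
        mode="training", seed=seed, session=session,
        performance_pct=100.0 * acc,
        per_class_pct={c: 100.0 * v for c, v in per_class.items()},
        features=[str(f) for f in features],
    )
    report.extras["classifier"] = clf.to_json_dict()
    report.extras["n_epochs"] = len(epochs)
    return report


# --------------------------------------------------------------------------
# scripted intent policies
# --------------------------------------------------------------------------

def greedy_pc_policy(state: ProcessControlState) -> str:
    """Intend the command that best approaches the target.

    If a ±10 mm move on the active axis reduces the distance, intend the
    better of LHIM/RHIM; otherwise intend rest (twice in a row cycles to a
    more useful axis).
    """
    best, best_d = "rest", state.distance_to_target
    for lab, delta in (("RHIM", control.STEP_MM), ("LHIM", -control.STEP_MM)):
        p = np.array(state.effector, dtype=float)
        p[control._AXIS_IDX[state.axis]] += delta
        d = float(np.linalg.norm(p - np.array(state.target)))
        if d < best_d - 1e-12:
            best, best_d = lab, d
    return best


def _random_gs_scene(rng: np.random.Generator) -> TableScene:
    """A synthetic goal-selection scene with items inside the reachable zone."""
    y = rng.uniform(160.0, 270.0)
    dx = rng.uniform(-80.0, 80.0)
    gap = rng.uniform(60.0, 110.0)
    cx = rng.uniform(-60.0, 60.0)
    disk_r = np.array([dx, y])
    left_r = np.array([cx - gap, rng.uniform(160.0, 270.0)])
    right_r = np.array([cx + gap, rng.uniform(160.0, 270.0)])
    img, truth = synth.gen_scene(
        disk_table=tuple(robot_to_table(disk_r)),
        targets_table={"green": tuple(robot_to_table(left_r)),
                       "red": tuple(robot_to_table(right_r))})
    from .vision import locate_scene
    return locate_scene(img)


def run_uncued_session(mode: Literal["process_control", "goal_selection"],
                       params: SubjectParams, clf: ConsensusClassifier,
                       seed: int, n_trials: int = 5, session: int = 0,
                       policy: Callable[..., str] | None = None,
                       model: RobotModel | None = None,
                       plan_tasks: bool = False) -> SessionReport:
    """Simulate one uncued (self-paced) session of ``n_trials`` repetitions.

    Each stimulus is decided by the scripted ``policy`` (defaults: greedy
    distance reduction for process control, a seeded random choice for goal
    selection), synthesized as an EEG block, classified by ``clf``, and
    executed by the corresponding controller.  Scoring follows the study
    definitions: percent of useful process-control commands, percent of
    intent/classification coincidences for goal selection.  P300 amplitude
    and latency are extracted per trial repetition from the assembled
    blocks at O1, O2 and Pz.
    """
    spec = PROTOCOLS["uncued_pc" if mode == "process_control" else "uncued_gs"]
    model = model or RobotModel()
    rng = np.random.default_rng(np.random.SeedSequence((seed, session, 104729)))
    report = SessionReport(mode=mode, seed=seed, session=session)
    fs = 1000.0
    trial_scores = []
    trajectories = []
    for t in range(n_trials):
        blocks, events, onset_acc = [], [], spec.baseline_s
        blocks.append(synth.pink_noise((len(CHANNELS_10_20),
                                        int(spec.baseline_s * fs)), rng,
                                       rms=params.noise_sd_uv))
        state = ProcessControlState()
        outcomes: list[StepOutcome] = []
        intents, decisions = [], []
        for _ in range(spec.n_stimuli):
            if policy is not None:
                intent = policy(state) if mode == "process_control" else policy(rng)
            elif mode == "process_control":
                intent = greedy_pc_policy(state)
            else:
                intent = str(rng.choice(["LHIM", "rest", "RHIM"]))
            data, onset_in_block = synth.gen_stimulus_block(
                spec, params, intent, t, rng, fs)
            i0 = int(round(onset_in_block * fs))
            i1 = i0 + int(round(spec.stimulus_s * fs))
            ep = Epoch(data[:, i0:i1], intent, fs=fs)
            decided = decide_from_features(clf, clf.feature_matrix([ep])[0])
            intents.append(intent)
            decisions.append("rest" if decided == "reject" else decided)
            if mode == "process_control":
                before = state.distance_to_target
                could_reduce = control._axis_can_reduce(state)
                nxt = process_control_step(state, decisions[-1], model)
                outcomes.append(StepOutcome(
                    state=nxt,
                    reduced_distance=nxt.distance_to_target < before - 1e-12,
                    axis_changed=nxt.axis != state.axis,
                    completed_needed_axis_change=(nxt.axis != state.axis)
                    and not could_reduce))
                state = nxt
            elif plan_tasks:
                scene = _random_gs_scene(rng)
                action = goal_selection_action(scene, decisions[-1])
                if action != "hold":
                    plan_pick_and_place(scene, action, model)
            events.append({"onset_s": onset_acc + onset_in_block,
                           "duration_s": spec.stimulus_s, "label": intent,
                           "decision": decisions[-1], "trial": t})
            onset_acc += data.shape[1] / fs
            blocks.append(data)
        rec = EEGRecording(np.concatenate(blocks, axis=1), fs,
                           list(CHANNELS_10_20), pd.DataFrame(events))
        for ch in P300_CHANNELS:
            f = erp_p300(rec, ch)
            report.p300.append(P300Features(f.amplitude, f.latency, ch,
                                            trial=t, session=session))
        if mode == "process_control":
            score = bci.score_session(intents, decisions, "uncued_pc",
                                      [o.as_dict() for o in outcomes])
            trajectories.append({"final_distance_mm": state.distance_to_target,
                                 "final_effector": list(state.effector)})
        else:
            score = bci.score_session(intents, decisions, "uncued_gs")
        trial_scores.append(score)
    report.per_trial_pct = trial_scores
    report.performance_pct = float(np.mean(trial_scores))
    if trajectories:
        report.extras["trajectories"] = trajectories
    return report


def fatigue_analysis(reports: Sequence[SessionReport]) -> dict:
    """Pool uncued sessions into the P300 ANOVA layout.

    Two-way: trial repetition x channel with sessions as replicates (one
    table for amplitude, one for latency).  One-way: per channel, factor
    trial repetition, values pooled across sessions.
    """
    feats = [f for r in reports for f in r.p300]
    trials = sorted({f.trial for f in feats})
    sessions = sorted({f.session for f in feats})
    chans = list(P300_CHANNELS)

    def cube(attr):
        v = np.full((len(trials), len(chans), len(sessions)), np.nan)
        for f in feats:
            v[trials.index(f.trial), chans.index(f.channel),
              sessions.index(f.session)] = getattr(f, attr)
        if np.isnan(v).any():
            raise ValueError("unbalanced P300 layout: missing cells")
        return v

    out = {"two_way": {}, "one_way": {}}
    for attr in ("amplitude", "latency"):
        out["two_way"][attr] = anova_twoway(cube(attr))
        out["one_way"][attr] = {}
        for ch in chans:
            groups = [
                np.array([f2.amplitude if attr == "amplitude" else f2.latency
                          for f2 in feats if f2.channel == ch and f2.trial == t])
                for t in trials
            ]
            out["one_way"][attr][ch] = anova_oneway(groups)
    return out
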