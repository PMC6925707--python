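"""Simulate a self-paced process-control session: ±10 mm moves toward a target.

A scripted greedy "user" intends whichever command brings the effector
closer to the target at [0, 300, -49] mm (resting twice to switch axes when
the current one is exhausted).  Each intent becomes synthetic EEG, is
classified, and drives the controller; performance is the percentage of
stimuli that reduced the distance or completed a needed axis change.
"""

from neuroarm.app import run_training_session, run_uncued_session
from neuroarm.bci import ConsensusClassifier
from neuroarm.synth import SubjectParams

params = SubjectParams(erd_depth=0.6, p300_amp_slope_uv=-0.4,
                       p300_lat_slope_ms=12.0)
training = run_training_session(params, seed=21, n_trials=2)
clf = ConsensusClassifier.from_json_dict(training.extras["classifier"])

session = run_uncued_session("process_control", params, clf, seed=21, n_trials=2)
print(f"training accuracy    : {training.performance_pct:.1f} %")
print(f"session performance  : {session.performance_pct:.1f} % useful commands")
for k, traj in enumerate(session.extras["trajectories"]):
    print(f"  trial {k}: final distance to target "
          f"{traj['final_distance_mm']:.1f} mm (started at 363.3 mm)")
print("\nP300 features per trial (fatigue drifts downward/later):")
for f in session.p300:
    if f.channel == "Pz":
        print(f"  trial {f.trial}: amplitude {f.amplitude:.2f} uV, "
          f"latency {f.latency:.0f} ms")
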