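"""Track a synthetic wildlife sequence and score it.

Generates a 3-animal, 200-frame scenario with a mildly unreliable detector
(10% misses, 0.1 false positives per frame, 2 px box jitter, noisy re-ID
embeddings), runs the tracker, and prints CLEAR-MOT and identity metrics.
"""

from wildtrack import RunConfig, evaluate, report_table
from wildtrack.synthetic import ScenarioConfig, generate_scenario
from wildtrack.tracker import run

scenario = generate_scenario(ScenarioConfig(n_objects=3, n_frames=200, seed=42))
config = RunConfig(embedding_dim=scenario.config.embedding_dim)

trajectories = run(scenario.detections_by_frame(), config)
report = evaluate(
    scenario.ground_truth,
    trajectories.records,
    start_frame=max(scenario.confirmed_from.values()),  # skip confirmation warm-up
    name="synthetic",
)

print(report_table([report], overall=False).to_string(index=False))
print(
    f"\n{len(trajectories.records)} output records for "
    f"{len({r.identity for r in trajectories.records})} identities. "
    "MOTA near 100 means few misses/false alarms survived tracking; "
    "IDF1 near 100 means each animal kept one identity throughout."
)
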