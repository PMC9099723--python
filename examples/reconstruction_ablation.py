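"""Show what trajectory reconstruction buys when the detector blacks out.

Uses the central-gaps condition: a clean detector except for runs of up to 4
consecutive missed frames, always while the animal is inside the central
region of the frame.  The tracker is run twice on identical input —
reconstruction off, then on — and scored against the same ground truth.
"""

from wildtrack.ablation import ablation_table, compare_reconstruction
from wildtrack.scenarios import central_gap_scenario

scenario, config = central_gap_scenario(seed=1)
reports = compare_reconstruction(scenario, config)

print(ablation_table(reports).to_string(index=False))
print(
    "\nEvery gap frame is a false negative without reconstruction; "
    "re-emitting the last box while the animal sits in the central region "
    "recovers them all here (gaps are shorter than the 5-frame cap), so FN "
    "drops to 0 and MOTA rises accordingly."
)
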