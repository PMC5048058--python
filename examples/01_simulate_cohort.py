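"""Generate a synthetic two-device cohort and write it in the CSV dialects.

Each participant gets a research-grade (waist accelerometer, counts+steps)
and a consumer (wrist tracker, steps+METs+intensity) minute stream on one
grid, plus a self-reported exercise journal with small boundary jitter.
"""

from actisync import DeviceBiasModel, SimulationConfig, generate_cohort, write_cohort

config = SimulationConfig(n_participants=3, n_days=7, seed=42)
participants, truth = generate_cohort(config)  # default consumer bias model

write_cohort(participants, truth, "scratch/example_cohort")

p = participants[0]
print(f"participants: {len(participants)}, minutes each: {len(p.research)}")
print(f"{p.participant_id} journal ({len(p.journal)} reported bouts):")
print(p.journal.to_string(index=False))
worn = truth.participants[0].minutes["true_state"].gt(0).mean()
print(f"fraction of minutes truly worn: {worn:.2f}")
print("Files written to scratch/example_cohort/ — the same dialects the readers consume.")
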