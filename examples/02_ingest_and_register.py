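"""Read both device exports from CSV and register them on a common grid.

Registration intersects the two observation spans; minutes present on one
device only are excluded and the load reports say what was zero-filled.
"""

from actisync import (
    DeviceBiasModel,
    SimulationConfig,
    generate_cohort,
    read_consumer_export,
    read_research_export,
    register,
    write_cohort,
)

# build a tiny cohort on disk first
participants, truth = generate_cohort(SimulationConfig(n_participants=1, n_days=3, seed=7))
write_cohort(participants, truth, "scratch/example_ingest")

research = read_research_export("scratch/example_ingest/P01_research.csv", epoch_seconds=60)
consumer = read_consumer_export("scratch/example_ingest/P01_consumer.csv", met_scale=10)
print(f"research: {len(research)} minutes, {research.report.n_filled} gap-filled")
print(f"consumer: {len(consumer)} minutes, {consumer.report.n_filled} gap-filled")

reg = register(research, consumer)
print(f"registered common grid: {reg.minutes[0]} .. {reg.minutes[-1]} ({len(reg.minutes)} minutes)")
print("joint_wear is the AND of the two wear masks (still all-wear before screening):",
      int(reg.joint_wear.sum()), "minutes")
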