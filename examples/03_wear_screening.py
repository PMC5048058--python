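"""Nonwear detection and valid-day screening.

A run of >= 60 consecutive zero minutes on either device is nonwear; a day
needs >= 480 joint-wear minutes (8 waking hours) to enter the day-level
analysis.
"""

from actisync import (
    SimulationConfig,
    WearCriteria,
    apply_joint_exclusion,
    generate_cohort,
    register,
    screen_valid_days,
    wear_report,
)

participants, _ = generate_cohort(SimulationConfig(n_participants=1, n_days=7, seed=3))
p = participants[0]

reg = apply_joint_exclusion(register(p.research, p.consumer), WearCriteria())
reg.valid_days = screen_valid_days(reg)

report = wear_report(reg)
print(report.to_string())
print(f"\nvalid days: {sorted(reg.valid_days)}")
print("Each row tallies per-device and joint wear minutes; valid=1 means the")
print("day clears the 8-hour joint-wear minimum and enters the analysis.")
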