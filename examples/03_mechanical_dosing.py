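"""Two-seeding mechanical dosing: priming duration controls the fate.

Cells are cultured on a stiff 30 kPa substrate for a variable priming
duration and then re-seeded onto a soft substrate.  Short priming lets the
second substrate decide; long priming commits the remembered (osteogenic)
fate regardless of the second substrate.
"""

from mscfate import DosingSchedule, classify_fate, fate_map, run_two_seeding

# A single dosing run with a dense trajectory:
schedule = DosingSchedule(first_S_kpa=30.0, first_duration=50.0,
                          second_S_kpa=0.4)
trajectory = run_two_seeding(schedule)
call = classify_fate(trajectory)
print(f"prime 30 kPa for 50, re-seed at 0.4 kPa -> {call.lineage}")
print(f"  final marker levels: "
      f"{ {g: round(v, 3) for g, v in call.marker_levels.items()} }")

# A fate map over priming durations and second-seeding stiffness values.
# Note the staged progression with increasing duration, and that the number
# of reachable fates shrinks as the second substrate stiffens (4 -> 3 -> 2).
table = fate_map([30.0], [0.0, 0.5, 1.0, 2.0, 3.0, 50.0], [0.4, 0.9, 12.0])
print("\n", table[["first_duration", "second_S_kPa", "lineage"]]
      .pivot(index="first_duration", columns="second_S_kPa",
             values="lineage").to_string())
table.to_csv("fate_map.csv", index=False)
print("\nwrote fate_map.csv")
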