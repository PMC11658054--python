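"""Generate a small synthetic colony and write it to CSV.

Builds a 40-worker observation-hive day (two nurse cohorts plus a forager
cohort), writes trajectories.csv / bees.csv / ground-truth sidecars, and
prints the population structure.  The ground-truth files record what the
generator planted (queen movement states, community membership, ages) so
downstream estimators can be validated against them.
"""

from pathlib import Path

from queenrelay import ColonyConfig, generate_colony_day, write_dataset

cfg = ColonyConfig(
    cohort_schedule=((0, 14), (10, 13), (12, 13)),
    day_length_s=1200.0,          # a 20-minute excerpt of the day
    comb_width=40.0, comb_height=28.0,
    broodnest_centres=((14.0, 14.0, 0), (14.0, 14.0, 1)),
    broodnest_radius=12.0,
    seed=42,
)
day = 14
traj, bees, truth = generate_colony_day(cfg, day)

out = Path("scratch/example_colony")
write_dataset(traj, bees, truth, out)

n_frames = traj.groupby("bee_id").size()
print(f"wrote {out}/trajectories.csv with {len(traj)} rows "
      f"({len(n_frames)} bees x {n_frames.iloc[0]} frames)")
print("\npopulation by planted community:")
print(truth.workers["community"].value_counts().to_string())
print("\nqueen time stationary:",
      f"{(truth.queen_states['queen_state'] == 'S').mean():.0%}",
      "(the chain's long-run S share is 60%)")
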