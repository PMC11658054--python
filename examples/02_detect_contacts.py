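"""Detect transmission-relevant contacts from trajectories.

A contact frame is one where the head half of a bee's trapezoidal body
outline overlaps a nestmate's outline; side-by-side or tail-to-tail
proximity never counts.  Consecutive contact frames merge into contact
intervals, and per-contact inspection fractions record who was inspecting
whom (the inspector is the pheromone receiver).
"""

from queenrelay import ColonyConfig, detect_contacts, generate_colony_day

cfg = ColonyConfig(
    cohort_schedule=((0, 10), (10, 10)),
    day_length_s=600.0,
    comb_width=30.0, comb_height=20.0,
    broodnest_centres=((10.0, 10.0, 0), (10.0, 10.0, 1)),
    broodnest_radius=8.0,
    seed=7,
)
traj, bees, _ = generate_colony_day(cfg, 12)
contacts = detect_contacts(traj, bees, frame_rate=cfg.frame_rate)

dur = contacts["t_end_s"] - contacts["t_start_s"]
queen_mask = (contacts["i"] == "queen") | (contacts["j"] == "queen")
print(f"{len(contacts)} contacts in a {cfg.day_length_s/60:.0f}-minute scene")
print(f"  queen-worker: {queen_mask.sum()}, worker-worker: {(~queen_mask).sum()}")
print(f"  mean duration {dur.mean():.1f} s (queen contacts: "
      f"{dur[queen_mask].mean():.1f} s)")
print("\nlongest contact:")
print(contacts.loc[dur.idxmax()].to_string())
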