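"""Simulate a small plate recording and inspect the ground truth.

One row of 12 moderately active larvae with strong stimulus following is
simulated over a shortened assay (2 blank + 10 stimulus periods of 2 minutes
each) and the per-frame ground truth is summarized.
"""

from plateomr import (
    LarvaParams,
    PeriodSchedule,
    default_periods,
    simulate_experiment,
    standard_layout,
)

layout = standard_layout(n_plates=1, rows_per_plate=1, wells_per_row=12)
schedule = PeriodSchedule(period_length=120.0, periods=default_periods(2, 10))
params = LarvaParams(p_move=0.5, optomotor_gain=0.8)

exp = simulate_experiment(layout, schedule, params, seed=42)
truth = exp.truth_table()

moved = truth[truth.frame > 0]
print(f"simulated {len(exp.wells)} larvae over {exp.n_frames} frames")
print(f"fraction of intervals with movement: {moved.moved.mean():.3f} "
      f"(generating p_move = {params.p_move})")
frame = exp.frame(150)  # a stimulus-on frame
print(f"rendered frame shape: {frame.shape}, dtype {frame.dtype}")
print("per-larva mean |y| position (mm):",
      truth.groupby("col").y_mm.apply(lambda s: s.abs().mean()).round(2).tolist())
# The moved fraction tracks p_move because each interval is an independent
# Bernoulli draw; |y| stays below the 1.575 mm swimmable radius.
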