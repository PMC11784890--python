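"""Compare how fast each box loss converges under gradient descent.

100 seeded random boxes are regressed onto random targets with a constant
step; the table reports the median number of steps until IoU >= 0.99 and
the fraction of trials that never get there (orbiting instead of settling).
"""

from cropdet.convergence import format_summary, loss_convergence_sim

summaries = loss_convergence_sim(n_trials=100, step_size=0.05, seed=0)
print(format_summary(summaries))
print()
by_name = {s.loss_name: s for s in summaries}
print(f"SIMIoU settles (median {by_name['simiou'].median_steps:.0f} steps, "
      f"{100 * by_name['simiou'].failure_rate:.0f}% failures) where GIoU "
      f"mostly orbits the optimum ({100 * by_name['giou'].failure_rate:.0f}% "
      "failures): its corner-distance term vanishes smoothly at the "
      "optimum, so a fixed step can come to rest.")
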