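"""Half-life estimation from transcription-shutoff time courses.

After a transcription block, ln(abundance) declines linearly with time;
the fit is anchored at the t0-normalized value 1 and the half-life is
ln(2) over the decay rate.
"""

from rbpreg.decay import compare_half_lives, estimate_half_life, series_from_frame
from rbpreg.synthetic_data import SimulationConfig, simulate_decay

cfg = SimulationConfig(seed=41)
df, truth = simulate_decay(cfg, cfg.rng())
series = {s.condition_id: s for s in series_from_frame(df)}

for cond, s in series.items():
    fit = estimate_half_life(s)
    print(f"{cond}: T1/2 = {fit.half_life:.2f} hr "
          f"(truth {truth[cond]} hr, r^2 = {fit.r_squared:.3f})")

for clone in ("WT6", "WT10", "MUT3"):
    comp = compare_half_lives(series[f"{clone}_Ctrl"], series[f"{clone}_Dox"],
                              seed=41)
    print(f"{clone}: Dox/Ctrl half-life ratio {comp.fold_change:.2f} "
          f"[{comp.ci_low:.2f}, {comp.ci_high:.2f}]")
print("-> induction stabilizes the transcript ~4-fold in WT6 and ~2-fold in")
print("   WT10, while the truncated mutant leaves the half-life unchanged.")
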