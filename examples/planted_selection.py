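"""Recover a sparse planted linear signal among thousands of noise columns.

Builds a 500 x 2,000 dataset where only columns x3 and x17 drive the
outcome (slopes 1.5 and -1.0, Gaussian noise sd 0.5), runs the selection
at default thresholds, and prints what was accepted and why.
"""

import minlinmo as mm

truth = mm.SyntheticTruth(support=[3, 17], effects=[1.5, -1.0], noise_sd=0.5)
m, y, _ = mm.generate_planted(500, 2000, truth, seed=42)

trace = mm.run_selection(m, y)

print(f"queue held {len(trace.queue)} candidates "
      f"(of {m.n_predictors} screened)")
for step in trace.steps[:6]:
    print(f"  {step.column_name:>6}  |r|={step.abs_corr_outcome:.3f}  "
          f"{step.decision}")
n_rej = len(trace.steps) - trace.n_accepted
print(f"  ... {n_rej} candidates rejected in total")
print(f"final model: intercept {trace.final_model.intercept:+.4f}")
for name, slope in trace.final_model.terms:
    print(f"  {name:>6}  slope {slope:+.4f}")
print(f"adjusted R2 {trace.final_model.adjusted_r2_final:.4f}")
print()
print("The two planted columns are recovered with slopes near the true")
print("(1.5, -1.0); every noise column that slipped past screening was")
print("rejected by the residual-correlation or adjusted-R2 gate.")
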