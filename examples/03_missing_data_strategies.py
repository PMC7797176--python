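"""Compare the three missing-data strategies on one simulated cohort.

Forward filling carries the last observation; linear filling interpolates
between observations; model filling lets the recurrent model impute from
all features jointly.  On a 300-subject cohort with 30% of entries missing
at random, the integrative strategy should match or beat forward filling.
"""

import adprog as ap

maes = ap.run_fill_comparison(seed=0, n_subjects=300)
print("held-out forecast MAE over all continuous markers (z-units):")
print(f"  model filling   {maes['model']:.4f}")
print(f"  forward filling {maes['forward']:.4f}")
winner = "model" if maes["model"] <= maes["forward"] else "forward"
print(f"\nLower is better; here {winner} filling wins. Model filling exploits"
      "\ncross-feature correlation (an observed cognitive score informs the"
      "\nimputed MRI volume), which per-feature carry-forward cannot.")
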