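"""Parameter recovery: simulate with the reference estimates, refit, compare.

Runs a reduced version of the headline-recovery experiment for the
affirmation model (2 replicates to keep this quick; the standard run
uses 5) and prints bias, RMSE, and interval coverage per coefficient.
"""

from tcnet.experiments import HEADLINE_COEFS, headline_recovery
from tcnet.reference import reference_interval

report = headline_recovery("affirmation", seed=0, horizon=200, replicates=2,
                           iterations=800, burn_in=300)
agg = report.aggregate()
print(agg.to_string(index=False))
print()
for coef in HEADLINE_COEFS["affirmation"]:
    mean, lo, hi = reference_interval("affirmation", coef)
    print(f"{coef}: generating value {mean:+.2f}, reference 95% interval "
          f"({lo:+.2f}, {hi:+.2f})")
print("\n'coverage' is the share of replicates whose 95% posterior interval")
print("covers the generating value; bias and RMSE are on the probit scale.")
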