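"""Link per-patient TF activity to survival.

Simulates 300 patients whose hazard increases e-fold per unit of TF03
activity, screens each TF with a median-split log-rank test, then lets
a bidirectional stepwise-AIC Cox search pick the joint model.
"""

import math

from tftea.personalized import SampleActivityMatrix
from tftea.simulate import simulate_survival_data
from tftea.survival import cox_stepwise, logrank_screen

candidates = [f"TF{i:02d}" for i in range(1, 7)]
X, clinical = simulate_survival_data(300, candidates, {"TF03": 1.0}, seed=5)
mat = SampleActivityMatrix(activity=X, p=X * math.nan, adj_p=X * math.nan)

print("log-rank screen (high vs low activity at the median):")
for r in logrank_screen(mat, clinical, min_events=10):
    print(f"  {r.tf_name}: chi2 = {r.logrank_stat:6.2f}, adj p = {r.adj_p:.2e}, "
          f"worse survival in the {r.worse_group}-activity group")

model = cox_stepwise(mat, clinical)
print()
print(f"stepwise Cox selected: {model.selected_variables} "
      f"(AIC {model.aic:.1f} vs null {model.null_aic:.1f})")
print(model.coefficients.round(3).to_string())
print()
print("the TF03 coefficient is the log hazard ratio per activity unit;")
print("its recovery near the simulated value of 1.0 validates the search.")
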