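"""First-order molecular-weight decay, in vivo vs in vitro.

Generates retention series anchored at the 6-month follow-up values
(61.8% in vivo, 68.5% in vitro), fits the rate constant per environment
and predicts the retention trajectory.
"""

import numpy as np

from stentdeg import fit_first_order, generate_mw_series, predict_retention

observations = generate_mw_series(times=(1.0, 3.0, 6.0), noise_sd=0.0)
for env in ("in_vivo", "in_vitro"):
    model = fit_first_order([o for o in observations if o.environment == env])
    print(f"{env:9s}: k = {model.rate_constant:.5f} /month")
    for t in (0.0, 1.0, 3.0, 6.0, 12.0):
        print(f"   t = {t:4.1f} mo -> Mw retention {predict_retention(model, t):.3f}")

print(
    "\nThe in vivo rate is slightly higher (61.8% vs 68.5% retained at"
    "\n6 months); both environments lose molecular weight long before the"
    "\nscaffold loses measurable radial strength."
)
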