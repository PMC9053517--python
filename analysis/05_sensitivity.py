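#!/usr/bin/env python
"""Sensitivity procedures: carrier test, extreme-progressor trimming, LEDD.

Runs the carrier-status association with and without trimming the 5% fastest
and slowest progressors, and the medication-masking experiment in which the
motor examination is attenuated by levodopa-equivalent dose and then
reconstructed with the true attenuation coefficient.
"""

import logging

from pdprog import experiments

logging.basicConfig(level=logging.WARNING)

res = experiments.carrier_trim_trial(seed=20)
full, trimmed = res["full"], res["trimmed"]
print("carrier status vs cognitive progression score:")
print(f"  full cohort : beta={full.beta:.3f} se={full.se:.3f} P={full.p:.2e} n={full.n}")
print(f"  5%-trimmed  : beta={trimmed.beta:.3f} se={trimmed.se:.3f} P={trimmed.p:.2e} n={trimmed.n}")
print("  (same sign, attenuated magnitude is the expected pattern)")

res = experiments.ledd_sensitivity_trial(seed=20)
print("\nmotor-exam slope vs truth correlation under medication masking:")
print(f"  untreated scenario      : r = {res['corr_untreated']:.3f}")
print(f"  treated, unadjusted     : r = {res['corr_masked']:.3f}")
print(f"  treated, LEDD-adjusted  : r = {res['corr_adjusted']:.3f}")
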