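"""Derived decision metrics at the reference parameters.

Tabulates, per stimulus set: the weight balance omega-/omega+, the
noise-free subunits-to-threshold counts, the raw |theta/omega| ratios and
the noise-to-signal ratios sigma/|omega|.  Key findings printed below: ten
consecutive heterospecific subunits fix a rejection without noise, while 29
onset-9dB subunits are needed for a positive decision; the noise exceeds
every weight (NSR > 1.6), most dramatically for the positive subunits.
"""
from pathlib import Path

import songdrift as sd

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = sd.REFERENCE_PARAMS
table = sd.set_metrics_table(sd.SET_PAIRS, params)
table.to_csv(OUT / "set_metrics.csv", index=False)

print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print("subunits to lower threshold (dorsatus):",
      sd.subunits_to_threshold(params.weights["dorsatus"], params.theta_minus))
print("subunits to lower threshold (mollis):  ",
      sd.subunits_to_threshold(params.weights["mollis"], params.theta_minus))
print("subunits to upper threshold (onset9dB):",
      sd.subunits_to_threshold(params.weights["onset9dB"], params.theta_plus))
print("block threshold ratio |theta+/omega+|: ",
      sd.threshold_ratio(params.weights["block"], params.theta_plus))
print("omega-/omega+ (onset set):             ",
      round(sd.weight_ratio(params.weights["onset3dB_pause4ms"],
                            params.weights["onset9dB"]), 1))
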