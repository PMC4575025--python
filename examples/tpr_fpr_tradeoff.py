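"""Trace the FPR/TPR trade-off across candidate scan intervals.

Malignant nodules carry growth rates drawn from lognormal(ln 0.015, 0.83)
(fit to a published 120-case histogram); measurement noise blurs that
distribution with a Gaussian kernel of SD a*sqrt(2)/dt.  Short intervals
inflate both the stable-nodule FPR and the blurring loss of TPR; long
intervals approach the pure lognormal ceiling.
"""

from vctgrowth import (
    DEFAULT_MALIGNANT_MODEL,
    DEFAULT_WINDOW,
    rate_curve,
    tpr_pure,
)

curve = rate_curve(
    0.057, DEFAULT_MALIGNANT_MODEL, DEFAULT_WINDOW, list(range(30, 181, 15))
)
print("interval_d   FPR      TPR")
for pt in curve:
    print(f"{pt.delta_t:8.0f}   {pt.fpr:.4f}   {pt.tpr:.4f}")
ceiling = tpr_pure(DEFAULT_MALIGNANT_MODEL, DEFAULT_WINDOW)
print(f"TPR ceiling (no blurring): {ceiling:.4f}")
print("-> about 31% of malignancies fall outside the 30-400-day doubling-"
      "time band no matter how long one waits; the scan interval only "
      "controls how much measurement noise adds to that.")
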