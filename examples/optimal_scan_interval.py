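"""Find the shortest follow-up interval keeping the false-positive rate under 5%.

A stable nodule's apparent growth rate between two scans is pure
measurement noise: k ~ N(0, a*sqrt(2)/dt).  The probability that it lands
in the malignancy band (doubling time 30-400 days) is the false-positive
rate; lengthening the scan interval narrows the noise and shrinks the FPR.
The result is independent of nodule size.
"""

from vctgrowth import DEFAULT_WINDOW, optimal_interval, stable_fpr

a = 0.057  # proportional-error slope of the volumetric-CT system

print(f"decision band: {DEFAULT_WINDOW.k_low:.5f} < k < "
      f"{DEFAULT_WINDOW.k_high:.5f} per day "
      f"(doubling time {DEFAULT_WINDOW.dt_min:.0f}-{DEFAULT_WINDOW.dt_max:.0f} d)")

for dt in (30, 60, 81, 120, 180):
    print(f"  FPR at {dt:3d} days: {stable_fpr(dt, a):.4f}")

best = optimal_interval(a, alpha=0.05)
print(f"optimal interval: {best} days "
      f"(FPR = {stable_fpr(best, a):.4f} < 0.05; "
      f"one day earlier it is {stable_fpr(best - 1, a):.4f})")
print("-> scanning earlier than this risks mistaking measurement noise in "
      "a stable nodule for malignant growth more than 5% of the time.")
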