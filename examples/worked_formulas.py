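"""Closed-form worked examples: heritability, accuracy and SE calculators.

Reproduces published scalar calculations for dairy cattle, pigs and broiler
chickens directly from the formulas — no data needed.
"""

import math

import predslice as ps

cases = [
    ("Holsteins / milk", 0.55, 580_000, 15_000, 381_000),
    ("Pigs / fitness", 0.09, 12_000, 5_000, 2_000),
    ("Pigs / growth", 0.36, 20_000, 5_000, 11_000),
    # the chicken study reports accuracy 0.58 under an assumed h2 of 0.30;
    # the unreported predictivity is recovered as acc * sqrt(h2)
    ("Chicken / growth", 0.58 * math.sqrt(0.30), 100_000, 5_000, 40_000),
]

print(f"{'data set':<20} {'c':>6} {'h2_hat':>7} {'SE':>8} {'acc':>6}")
for name, c, n_ref, me, n_val in cases:
    est = ps.h2_from_predictivity(c, n_ref, me, n_validation=n_val)
    acc = ps.acc_from_predictivity(c, est.h2)
    print(f"{name:<20} {c:6.3f} {est.h2:7.3f} {est.se:8.5f} {acc.acc:6.2f}")

print()
print("SE(acc) at h2=0.25, n=1600:", ps.se_accuracy(0.25, 1600))
print("SE(r_g) at h2=0.25, acc=0.5, n=1600:", ps.se_gencorr(0.25, 0.5, 1600))
print("min reference size, Me=15000, h2=0.05:",
      ps.min_reference_size(15_000, 0.05))
# h2_hat is the heritability implied by the observed predictive ability given
# the reference size and the number of independent chromosome segments Me;
# the SE shrinks as the validation population grows.
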