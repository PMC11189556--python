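"""A-priori power analysis for the two-arm comparison.

Two-sided two-sample t-test under the noncentral-t distribution: required
per-group n at 95% power for medium (d=0.5) and large (d=0.8) effects, and
achieved power at the feasibility-capped 70 per group.
"""

from eftrial import PowerSpec, power_two_sample

for d in (0.5, 0.8):
    sol = power_two_sample(PowerSpec(d=d, power=0.95), "n")
    print(f"d={d}: {sol.n_per_group}/group ({2 * sol.n_per_group} total) "
          f"-> power {sol.power:.3f}")
for d in (0.5, 0.8):
    at70 = power_two_sample(PowerSpec(d=d, n_per_group=70), "power")
    print(f"d={d} at 70/group: power {100 * at70.power:.1f}%")
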