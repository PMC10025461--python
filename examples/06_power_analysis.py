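"""How many strides must be averaged to detect a gait change?

Given the stride-to-stride variability of a tracked quantity, a one-sample
t-test power calculation (noncentral t) gives the number of strides needed
to detect a specified difference.
"""
from gaitmesh import steps_needed

sd = 11.0      # mm, stride-to-stride variability of step length
delta = 10.0   # mm, difference worth detecting (1 cm)

n = steps_needed(sd_mm=sd, delta_mm=delta, alpha=0.05, power=0.8)
print(f"variability {sd:g} mm, target difference {delta:g} mm "
      f"-> {n} strides needed (alpha=0.05, power=0.8)")

for sd in (5.0, 11.0, 20.0):
    n = steps_needed(sd_mm=sd, delta_mm=10.0)
    print(f"  sd = {sd:4.1f} mm -> n = {n}")
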