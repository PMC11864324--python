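"""Critical loads from fitted response parameters.

The N critical load is the lognormal peak n1 (deposition above which the
response declines).  For a sigmoid S response the critical load is found by
inverting the sigmoid at a chosen fractional reduction f (5% for growth,
1% for survival by default).
"""

from treecl import critical_load_direct, critical_load_sigmoid, sulfur_sigmoid
from treecl.core import GrowthParams

params = GrowthParams(a=3.0, n1=8.7, s1=9.0, s2=2.0, s3=0.3)

cl_n = critical_load_direct(params, "N", endpoint="growth")
print(f"N critical load = n1 = {cl_n.value} kg N ha-1 yr-1 (basis {cl_n.basis})")

for f in (0.01, 0.05):
    cl_s = critical_load_sigmoid(params.s1, params.s2, params.s3, f,
                                 endpoint="growth")
    check = sulfur_sigmoid(cl_s.value, params.s1, params.s2, params.s3)
    print(f"S critical load at f = {f:.0%} reduction: "
          f"{cl_s.value:.3f} kg S ha-1 yr-1  "
          f"(sigmoid there = {check:.4f} = 1 - f)")

# a reduction deeper than the plateau allows is undefined, never clipped
deep = critical_load_sigmoid(9.0, 2.0, 0.3, 0.8)
print(f"f = 0.8 with plateau s3 = 0.3: value = {deep.value} ({deep.note})")
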