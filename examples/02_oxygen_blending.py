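"""FiO2 titration by static blending of the air and oxygen lines.

The two high-pressure lines each carry a needle valve; the flow-weighted
mix of compressed air (21 % O2) and pure oxygen spans the full 21–100 %
inspired-oxygen range.
"""

from ventsim import blend_fio2

print("air flow  O2 flow   FiO2")
for air, o2 in [(10.0, 0.0), (7.5, 2.5), (5.0, 5.0), (2.5, 7.5), (0.0, 10.0)]:
    f = blend_fio2(air, o2)
    print(f"  {air:5.1f}   {o2:5.1f}   {100 * f:5.1f} %")

print("\npure air gives 21 %, pure oxygen 100 %; equal flows give the")
print("arithmetic mean 60.5 %. A 40 % target (the in vivo setting) needs an")
share = (0.40 - 0.21) / 0.79
print(f"oxygen flow share of {100 * share:.1f} % of total inspiratory flow.")
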