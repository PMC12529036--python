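"""Characterize a perforated artificial-leaf film from its pore geometry.

Computes the theoretical anatomical maximum pore conductance under the
three end-correction conventions, then shows that any two columns predict
the third (the film thickness cancels in their ratio).
"""

from dyng import (
    N_NONE,
    N_ONE_END,
    N_TWO_END,
    PoreGeometry,
    invert_end_correction,
    theoretical_gpw,
)

# microscope characterization of a film: 2000 um2 mean pore area,
# 10 pores per mm2, 20 um thick polyethylene
geometry = dict(PA=2000e-12, PD=10e6, l=20e-6)

values = {}
for label, n in (("one-end (pi/4)", N_ONE_END), ("none (1)", N_NONE),
                 ("two-end (pi/2)", N_TWO_END)):
    values[n] = theoretical_gpw(PoreGeometry(**geometry, n=n))
    print(f"g_pw with {label:>14s} correction: {values[n]:.4f} mol m-2 s-1")

predicted = invert_end_correction(values[N_ONE_END], values[N_TWO_END])
print(f"\nn=1 value predicted from the other two columns: {predicted:.4f}")
print("Larger end corrections add vapor-shell resistance at the pore")
print("mouths, so the one-end column is always the largest; the agreement")
print("above shows the three columns are one two-parameter model.")
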