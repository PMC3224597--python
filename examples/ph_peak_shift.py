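"""Titration-driven peak positional variation.

A histidine-like singlet at 3.0 ppm with acid-limit position 3.12 ppm,
base-limit position 3.02 ppm and pKa 6.5 is shifted at a range of
sample pH values.  The apex slides logistically between the two limit
positions with its midpoint at pH == pKa, the behaviour real
pH-sensitive resonances show between their protonation states.
"""

import math

import numpy as np

import nmrmixsim as nms
from nmrmixsim.synthetic_standards import LorentzianSpec, MultipletShape, make_lorentzian_standard

params = nms.SimulationParameters(n_points=8192, snr=math.inf)
spec = LorentzianSpec(multiplets=[MultipletShape(centre=3.0, half_width=0.004)])
raw, _ = make_lorentzian_standard(spec, params.grid(), metabolite_id="histidine_like")
clean, _ = nms.preprocess_standard(raw, params)

table = [nms.Multiplet([3.0], pka=6.5, acid_limits=[3.12], base_limits=[3.02])]
print(f"{'pH':>5} {'predicted position':>20} {'observed apex':>15}")
for ph in (4.0, 5.5, 6.5, 7.5, 9.0):
    assignment = nms.make_shift_assignment(clean, table, params, ph, np.random.default_rng(0))
    eta = assignment.shifts[0].eta
    shifted = nms.shift_spectrum(clean, assignment, params)
    apex = float(shifted.ppm[np.argmax(shifted.intensity)])
    print(f"{ph:>5.1f} {3.0 + eta:>20.4f} {apex:>15.4f}")
print()
print("At pH 6.5 (= pKa) the peak sits at the midpoint (3.07 ppm); low pH")
print("drives it toward the base-limit position and high pH toward the")
print("acid-limit position, following the logistic titration curve.")
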