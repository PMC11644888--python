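"""Why a blink is visible in a resonance frequency.

The eye sits behind a small electrode on an eyeglass frame. Electrode and
eye form a capacitor whose dielectric stack changes when the eyelid (a thin,
highly polarizable layer) slides between them: closing the eye raises the
capacitance, which pulls the LC resonance frequency down. This script walks
through the numbers with the default geometry.
"""

import capblink as cb

model = cb.EyeDielectricModel()
circuit = cb.CircuitParams()

print("Dielectric stack (air gap / eyelid / eye tissue):")
print(f"  thicknesses d = {[f'{d*1e3:g} mm' for d in model.d]}")
print(f"  permittivities eps = {list(model.eps)}")
print(f"  plate area S = {model.plate_area*1e4:g} cm^2")

pair = cb.capacitance_pair(model)
print("\nEye capacitance:")
print(f"  open  (lid out of the gap): {pair.cx_open*1e12:.4f} pF")
print(f"  closed (lid in the gap):    {pair.cx_closed*1e12:.4f} pF")
print(f"  closed/open ratio:          {cb.capacitance_ratio(model):.4f}")

f_open, f_closed = cb.frequency_pair(circuit, model)
print(f"\nLC tank: L = {circuit.inductance*1e6:g} uH, C = {circuit.capacitance*1e12:g} pF")
print(f"  resonance, eye open:   {f_open:,.1f} Hz")
print(f"  resonance, eye closed: {f_closed:,.1f} Hz")
print(f"  blink dip:             {f_open - f_closed:,.1f} Hz "
      f"({(f_open - f_closed) / f_open * 1e6:.0f} ppm of the carrier)")
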