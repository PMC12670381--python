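"""Gas-phase unit conversions behind the guideline and emission numbers.

Air-quality guidelines quote NO2 both as mass concentrations and as mixing
ratios, and stove emission rates both volumetrically and by mass; all four
are linked by the ideal-gas molar volume at the 20 °C / 1 atm reference.
"""

from resno2.units import GasConditions, mlh_to_mgh, ugm3_to_ppbv

print("WHO long-term guideline:  10 µg/m³ =", round(ugm3_to_ppbv(10.0), 2), "ppbv")
print("WHO 1-h guideline:       200 µg/m³ =", round(ugm3_to_ppbv(200.0), 1), "ppbv (~100)")
print("Average burner emission:  25 mL/h  =", round(mlh_to_mgh(25.0), 1), "mg/h (rounds to 48)")

warm = GasConditions(temperature=298.15)
print("Same burner at 25 °C:     25 mL/h  =", round(mlh_to_mgh(25.0, warm), 1),
      "mg/h  (the 20 °C reference is what reproduces the conventional 48)")
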