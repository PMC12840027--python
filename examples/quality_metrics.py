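"""The quality formulas on small worked inputs.

Moisture-basis conversion, moisture ratio, drying rate, shrinkage,
color difference, and the yellowness index table for the dried product.
"""

from yubadry import (
    ColorLab,
    delta_e,
    drying_rate,
    moisture_ratio,
    shrinkage_rate,
    wb_to_db,
    yellowness_index,
)

m0 = wb_to_db(0.5664)
print(f"fresh moisture 56.64% w.b. = {m0:.4f} g water / g solids (d.b.)")
print(f"moisture ratio at half the initial content: {moisture_ratio(m0 / 2, m0):.2f}")
print(f"drying rate for 1.00 -> 0.90 g/g over 1 min: {drying_rate(1.0, 0.9, 10, 11):.3f} g/g/min")
print(f"shrinkage for 1000 -> 800 px projected area: {shrinkage_rate(1000, 800):.1f} %")
print(f"color difference fresh vs yellowed sample:  "
      f"{delta_e(ColorLab(81.5, -2.6, 2.6), ColorLab(80.7, -2.8, 5.7)):.2f}")

print("\nYellowness index YI = 142.86 * b* / L* per drying treatment:")
for name, L, b in [("60 degC", 80.68, 5.70), ("65 degC", 79.85, 5.26),
                   ("70 degC", 79.44, 5.61), ("controlled", 79.96, 6.28)]:
    print(f"  {name:>10}: L*={L:.2f}, b*={b:.2f} -> YI={yellowness_index(L, b):.2f}")
print("Higher YI = more yellow, the color consumers prefer in yuba sticks.")
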