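"""Absolute quantification by isotope dilution.

A calibration curve of standard/internal-standard area ratios gives a
response factor; an unknown's area ratio divided by that factor is its
on-column amount, converted to lesions per 1e9 nucleotides using the
UV-quantified total of canonical nucleotides.
"""

from adductomics import fit_response_factor, lesions_per_1e9, quantify_isotope_dilution

# calibration: (concentration fmol, std/IS area ratio)
points = [(0, 0.0), (1, 0.21), (2, 0.40), (5, 1.01), (10, 2.02)]
model = fit_response_factor(points, analyte="N2-CMdG")
print(f"response factor: {model.response_factor:.4f} ratio/fmol (R^2 = {model.r_squared:.4f})")

# an unknown sample injection
amount = quantify_isotope_dilution(analyte_area=8600, is_area=21000, model=model)
print(f"amount on column: {amount:.2f} fmol")

# ~1.8e-8 mol of canonical nucleotides per 10 ug DNA injection
nt_total = 1.82e-8
print(f"level: {lesions_per_1e9(amount, nt_total):.0f} lesions per 1e9 nt")

# At this nucleotide denominator, 3.8 fmol on column corresponds to
# ~209 lesions per 1e9 nt — the scale at which low-abundance DNA
# damage products occur in tissue genomes.
print(f"3.8 fmol -> {lesions_per_1e9(3.8, nt_total):.0f} per 1e9 nt")
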