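"""Build the stepped-MRM acquisition design.

An exhaustive neutral-loss screen for 2'-deoxynucleoside adducts: every
integer precursor from m/z 225 to 524 is paired with its -116 Da
product (loss of 2'-deoxyribose), split into six 50 Da injections.
"""

from adductomics import generate_stepped_mrm, neutral_loss_product

design = generate_stepped_mrm(start_mz=225, window_width=50,
                              n_injections=6, neutral_loss=116)

print(f"transitions: {len(design)}")
first, last = design.transitions[0], design.transitions[-1]
print(f"first: {first.precursor_mz}->{first.product_mz} (injection {first.injection_index})")
print(f"last:  {last.precursor_mz}->{last.product_mz} (injection {last.injection_index})")
print(f"non-canonical (monitored): {len(design.non_canonical())}")
print(f"N2-CMdG product ion: {neutral_loss_product(326, 116)}")

# The 300 transitions cover the nucleoside adduct mass range; the four
# canonical nucleosides (m/z 228, 243, 252, 268) are flagged so the
# screen ignores them, leaving 296 monitored adduct channels. The
# 326->210 pair is the transition on which N2-CMdG is discovered.
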