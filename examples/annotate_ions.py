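"""Annotate measured m/z features by accurate mass against the bundled list.

Three deprotonated ions ([M-H]-, the default adduct rule) are matched at
0.003 m/z tolerance: pyruvate, its phenylhydrazone derivative (alpha-keto
acids are derivatized during extraction, shifting the formula by
+C6H8N2 -H2O), and glucose with a small simulated mass error.
"""

from mixdeconv.annotate import PROTON_MASS, annotate_ions, formula_mass, load_reference_list

refs = load_reference_list()  # bundled metabolites + PHderiv_ entries

mz_values = [
    formula_mass("C3H4O3") - PROTON_MASS,            # pyruvate, exact
    formula_mass("C9H10N2O2") - PROTON_MASS,         # its phenylhydrazone
    formula_mass("C6H12O6") - PROTON_MASS + 0.0012,  # glucose, 1.2 mDa off
]
table = annotate_ions(mz_values, refs, tolerance=0.003, adduct="M-H")
print(table[["mz", "id", "name", "mass_error"]].round(5).to_string(index=False))

shift = formula_mass("C6H8N2") - formula_mass("H2O")
print(f"\nphenylhydrazone mass shift: +{shift:.4f} Da")
print("mass_error is measured minus expected m/z; every reference within the")
print("tolerance is reported, closest first, so isobaric matches stay visible.")
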