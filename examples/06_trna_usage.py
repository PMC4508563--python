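"""Detect a compensatory shift in tRNA anticodon-loop nucleotide usage.

Pseudouridine synthase A (TruA) modifies U at positions 38-40 of the
anticodon stem-loop.  A lineage that lost the gene can avoid unmodified U at
exactly the positions that are normally modified.  Here one synthetic group
is generated with strongly reduced T usage at TruA-target cells and compared
against a reference-like group.
"""

from panbin import compare_usage, generate_trna_set, usage_matrix

reduced_T = {"T": 0.1, "C": 0.55, "G": 0.25, "A": 0.1}
normal_T = {"T": 0.65, "C": 0.15, "G": 0.1, "A": 0.1}
uniform = {b: 0.25 for b in "ACGT"}

targets = ("Lys", "Met", "Phe")
spec_bins = {iso: {38: uniform, 39: reduced_T, 40: uniform} for iso in targets}
spec_ref = {iso: {38: uniform, 39: normal_T, 40: uniform} for iso in targets}

bins = usage_matrix(generate_trna_set(500, spec_bins, seed=1), group="genome bins")
ref = usage_matrix(generate_trna_set(500, spec_ref, seed=2), group="reference")

df = compare_usage(bins, ref, nucleotide="T", min_n=5)
print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

# delta = T frequency in the bins minus the reference; strongly negative
# values at position 39 of Lys/Met/Phe reproduce the planted compensatory
# shift (T replaced mostly by C, stabilizing the loop without modification).
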