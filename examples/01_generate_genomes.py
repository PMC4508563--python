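"""Generate a synthetic genome set with planted core/flexible structure.

Builds 6 proteomes with a 40-family core, 20 flexible families and 10% gene
dropout (simulated bin incompleteness), then summarizes what was planted.
"""

from panbin import GeneratorParams, generate_genome_set

params = GeneratorParams(
    n_genomes=6,
    n_core_families=40,
    n_flex_families=20,
    n_unique_per_genome=10,
    dropout_rate=0.1,
    within_family_identity=0.9,
    n_marker_families=20,
    mean_protein_len=150,
    seed=42,
)
proteomes, truth = generate_genome_set(params)

for p in proteomes:
    print(f"{p.genome_id}: {p.n_genes} genes")
print(f"planted families: {len(truth.family_class)} "
      f"({sum(c == 'CORE' for c in truth.family_class.values())} core)")
print(f"genes dropped by incompleteness: {len(truth.dropped_genes)}")

# Each genome carries every core family (minus dropout), about half of the
# flexible families, and its own unique genes; the truth table is the
# ground truth that ortholog inference is scored against.
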