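"""Pan-genome accumulation: add genomes in random orders, count new genes.

Counts use the looser pairwise criterion (>=50% positives over >50% of the
protein length) and are normalized by the median protein count of the
genomes included so far; power-regression curves are fitted to the means.
"""

from panbin import GeneratorParams, accumulate, fit_new_gene_curve, fit_pan_curve, generate_genome_set

params = GeneratorParams(
    n_genomes=6, n_core_families=30, n_flex_families=25, flex_presence_prob=0.4,
    n_unique_per_genome=12, mean_protein_len=120, n_marker_families=10, seed=3,
)
proteomes, _ = generate_genome_set(params)

curve = accumulate(proteomes, trials=100, seed=11, min_kmer_matches=2)
print(f"orders used: {curve.n_trials} (exhaustive when G! <= trials)")

steps, new_norm = curve.series("new", normalized=True)
for s, v in zip(steps, new_norm):
    print(f"step {s}: mean normalized new genes = {v:.3f}")

fit_new = fit_new_gene_curve(curve)
fit_pan = fit_pan_curve(curve)
print(f"new-gene curve  ~ {fit_new.amplitude:.3f} * n^{fit_new.exponent:.3f}")
print(f"pan-genome size ~ {fit_pan.amplitude:.1f} * n^{fit_pan.exponent:.3f}")

# A slowly decaying new-gene exponent (b well above -1) and a pan-genome
# exponent near +1 indicate an open pan-genome: each added genome keeps
# contributing a sizable fraction of novel genes.
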