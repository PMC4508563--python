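"""End-to-end orchestration: synthetic genome set -> all-vs-all alignment ->
ortholog table -> core/flexible partition + accumulation curves ->
CSCG completeness -> tRNA usage, under one validated configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import align, completeness, orthology, pangenome, seqio, synthetic, trna

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters in one namespace.

    Defaults are the analysis profile this package reproduces: 70% coverage
    and a 2-SD AAI window for orthology, 50% positives over >50% length for
    accumulation, core threshold 13/17 of the genome count, 100 accumulation
    trials, MCL inflation 2.0, 105 markers.
    """

    # generator
    n_genomes: int = 17
    n_core_families: int = 200
    n_flex_families: int = 150
    flex_presence_prob: float = 0.5
    n_unique_per_genome: int = 50
    mean_protein_len: int = 250
    len_dispersion: float = 0.3
    within_family_identity: float = 0.9
    dropout_rate: float = 0.0
    marker_count: int = 105
    # alignment
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    score_floor: float = 40.0
    min_kmer_matches: int = 2
    # orthology
    min_cov: float = 0.70
    aai_window: float = 2.0
    inflation: float = 2.0
    cov_mode: str = "both"
    # pan-genome
    sim_threshold: float = 50.0
    cov_threshold: float = 0.5
    core_min_fraction: float = 13.0 / 17.0
    trials: int = 100
    # signatures
    gc_window: int = 120
    gc_step: int = 30
    tetra_window: int = 5000
    # tRNA
    trna_min_n: int = 5
    trna_n_per_isotype: int = 200
    # global
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = seqio.read_config(path)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.core_min_fraction <= 1:
            raise ValueError("core_min_fraction must be in (0, 1]")
        if self.core_min_genomes > self.n_genomes:
            raise ValueError(
                f"core threshold {self.core_min_genomes} exceeds n_genomes {self.n_genomes}"
            )
        # delegate generator checks
        self.generator_params()

    @property
    def core_min_genomes(self) -> int:
        import math

        return math.ceil(self.core_min_fraction * self.n_genomes)

    def generator_params(self) -> synthetic.GeneratorParams:
        return synthetic.GeneratorParams(
            n_genomes=self.n_genomes,
            n_core_families=self.n_core_families,
            n_flex_families=self.n_flex_families,
            flex_presence_prob=self.flex_presence_prob,
            n_unique_per_genome=self.n_unique_per_genome,
            mean_protein_len=self.mean_protein_len,
            len_dispersion=self.len_dispersion,
            within_family_identity=self.within_family_identity,
            dropout_rate=self.dropout_rate,
            n_marker_families=self.marker_count,
            seed=stage_seed(self.seed, "synth"),
        )


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and the stage name, so
    stages can be rerun independently; always below 2**31."""
    h = zlib.crc32(f"{master_seed}:{stage}".encode())
    return int(h % (2**31 - 1))


def compute_pairwise_hits(
    proteomes: Sequence[seqio.Proteome], cfg: RunConfig
) -> Dict[Tuple[str, str], List[align.AlignmentHit]]:
    """All-vs-all hits for every ordered genome pair (each unordered pair is
    aligned once; the reverse direction reuses the alignment)."""
    hits: Dict[Tuple[str, str], List[align.AlignmentHit]] = {}
    for pa, pb in itertools.combinations(proteomes, 2):
        fwd = align.all_vs_all(
            pa, pb,
            matrix_name=cfg.matrix_name, gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend, score_floor=cfg.score_floor,
            min_kmer_matches=cfg.min_kmer_matches,
        )
        hits[(pa.genome_id, pb.genome_id)] = fwd
        hits[(pb.genome_id, pa.genome_id)] = [h.swapped() for h in fwd]
    return hits


def run_all(cfg: RunConfig, outdir) -> Dict:
    """Run every stage in dependency order, writing each stage's outputs and
    a manifest to ``outdir``.  Deterministic for a given (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config": dataclasses.asdict(cfg),
        "stages": [],
        "stage_seeds": {},
    }

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s complete: %s", stage, info)

    t0 = time.time()
    # 1. synthetic genome set
    params = cfg.generator_params()
    manifest["stage_seeds"]["synth"] = params.seed
    proteomes, truth = synthetic.generate_genome_set(params)
    for p in proteomes:
        seqio.write_fasta(p, outdir / f"{p.genome_id}.faa")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene\tfamily\tclass\tdropped\n")
        for gene, fam in sorted(truth.gene_to_family.items()):
            cls = truth.family_class.get(fam, synthetic.UNIQUE)
            fh.write(f"{gene}\t{fam}\t{cls}\t{int(gene in truth.dropped_genes)}\n")
    done("synth", n_genomes=len(proteomes), n_genes=sum(p.n_genes for p in proteomes))

    # 2. all-vs-all alignment
    hits = compute_pairwise_hits(proteomes, cfg)
    lengths = {r.id: len(r) for p in proteomes for r in p}
    for (ga, gb), hlist in hits.items():
        if ga < gb:
            align.write_hits_tsv(hlist, lengths, outdir / f"hits_{ga}_{gb}.tsv")
    done("align", n_pairs=len(hits) // 2, n_hits=sum(len(v) for v in hits.values()) // 2)

    # 3. orthology
    table, aai_records = orthology.infer_orthologs(
        proteomes, hits_by_pair=hits,
        min_cov=cfg.min_cov, aai_window=cfg.aai_window,
        inflation=cfg.inflation, cov_mode=cfg.cov_mode,
    )
    seqio.write_presence_matrix(table.presence_matrix(), outdir / "presence_matrix.tsv")
    orthology.aai_matrix(aai_records).to_csv(outdir / "aai_matrix.tsv", sep="\t")
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("family\tgenome\tgene\n")
        for fid in sorted(table.families):
            for g, gene in sorted(table.families[fid]):
                fh.write(f"{fid}\t{g}\t{gene}\n")
        for g, gene in sorted(table.singletons):
            fh.write(f"-\t{g}\t{gene}\n")
    with open(outdir / "multicopy_flags.tsv", "w") as fh:
        fh.write("family\tgenome\tcopies\n")
        for fid, g, c in orthology.flag_multicopy(table):
            fh.write(f"{fid}\t{g}\t{c}\n")
    done("ortho", n_families=len(table.families), n_singletons=len(table.singletons))

    # 4. partition + accumulation
    part = pangenome.partition(table, cfg.n_genomes, cfg.core_min_genomes)
    with open(outdir / "partition.json", "w") as fh:
        json.dump(
            {
                "core_min_genomes": part.core_min_genomes,
                "family_counts": part.class_family_counts(),
                "gene_counts": part.class_gene_counts(),
            },
            fh, indent=2,
        )
    pairwise = pangenome.PairwiseShared(
        proteomes, hits_by_pair=hits,
        sim_threshold=cfg.sim_threshold, cov_threshold=cfg.cov_threshold,
    )
    acc_seed = stage_seed(cfg.seed, "accumulate")
    manifest["stage_seeds"]["accumulate"] = acc_seed
    curve = pangenome.accumulate(
        proteomes, trials=cfg.trials, seed=acc_seed, pairwise=pairwise,
    )
    curve.stats.to_csv(outdir / "accumulation.tsv", sep="\t", index=False)
    fit_new = pangenome.fit_new_gene_curve(curve)
    fit_pan = pangenome.fit_pan_curve(curve)
    with open(outdir / "power_fits.json", "w") as fh:
        json.dump(
            {
                "new_genes_normalized": dataclasses.asdict(fit_new),
                "pan_total": dataclasses.asdict(fit_pan),
            },
            fh, indent=2,
        )
    done("pangenome", n_trials=curve.n_trials,
         new_gene_exponent=fit_new.exponent, pan_exponent=fit_pan.exponent)

    # 5. completeness
    marker_rows = synthetic.generate_marker_hits(truth, proteomes)
    reports = completeness.census_genomes(
        marker_rows, sorted(truth.marker_families),
        genome_ids=[p.genome_id for p in proteomes],
    )
    reference = proteomes[0].genome_id
    with open(outdir / "completeness.tsv", "w") as fh:
        fh.write("genome\tmarkers_found\tcompleteness_pct\trelative_completeness_pct\tmulticopy\n")
        for g, rep in reports.items():
            rel = completeness.relative_completeness_from_table(table, g, reference)
            fh.write(
                f"{g}\t{len(rep.markers_found)}\t{rep.completeness_pct}\t"
                f"{rel:.1f}\t{len(rep.markers_multicopy)}\n"
            )
    done("completeness", reference=reference)

    # 6. tRNA usage (synthetic set with a planted usage shift, vs uniform)
    trna_seed = stage_seed(cfg.seed, "trna")
    manifest["stage_seeds"]["trna"] = trna_seed
    uniform = {n: 0.25 for n in "ACGT"}
    shifted = {"T": 0.05, "C": 0.55, "G": 0.30, "A": 0.10}
    spec_bin = {iso: {38: shifted, 39: shifted, 40: uniform} for iso in ("Lys", "Met", "Phe")}
    spec_ref = {iso: {38: {"T": 0.55, "C": 0.2, "G": 0.15, "A": 0.1},
                      39: {"T": 0.55, "C": 0.2, "G": 0.15, "A": 0.1},
                      40: uniform}
                for iso in ("Lys", "Met", "Phe")}
    recs_bin = synthetic.generate_trna_set(cfg.trna_n_per_isotype, spec_bin, seed=trna_seed)
    recs_ref = synthetic.generate_trna_set(cfg.trna_n_per_isotype, spec_ref, seed=trna_seed + 1)
    m_bin = trna.usage_matrix(recs_bin, group="bins")
    m_ref = trna.usage_matrix(recs_ref, group="reference")
    cmp_df = trna.compare_usage(m_bin, m_ref, nucleotide="T", min_n=cfg.trna_min_n)
    m_bin.to_frame().to_csv(outdir / "trna_usage.tsv", sep="\t", index=False)
    cmp_df.to_csv(outdir / "trna_comparison.tsv", sep="\t", index=False)
    done("trna", n_cells=len(cmp_df))

    manifest["runtime_s"] = round(time.time() - t0, 2)
    manifest["input_checksums"] = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()[:16]
        for f in sorted(outdir.glob("*.faa"))
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
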