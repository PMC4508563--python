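"""Synthetic genome sets and tRNA sets with planted ground truth.

The generator emulates a set of reconstructed genome bins from a single
bacterial phylum: a core of gene families present in every genome, flexible
families present in a random subset of genomes, genome-unique genes, and a
per-gene dropout that simulates bin incompleteness (missing scaffolds).
Within a family, each genome's copy is derived from a common ancestral
protein by i.i.d. substitutions, so expected pairwise identity between any
two members is a controlled target.

Every emitted gene carries a truth label (its planted family or UNIQUE),
which downstream orthology/pan-genome stages are scored against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .seqio import Proteome, SequenceRecord, TRNARecord

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
UNIQUE = "UNIQUE"
CORE = "CORE"
FLEX = "FLEX"


@dataclass
class GeneratorParams:
    """Knobs of the planted-structure genome-set generator.

    Defaults mirror the comparison this package targets: 17 genome bins of a
    reduced-genome phylum, a conserved core of a few hundred families, a
    flexible complement of partially shared families plus genome-unique
    genes, and proteins averaging ~250 residues.
    """

    n_genomes: int = 17
    n_core_families: int = 200
    n_flex_families: int = 150
    flex_presence_prob: float = 0.5
    n_unique_per_genome: int = 50
    mean_protein_len: int = 250
    len_dispersion: float = 0.3
    within_family_identity: float = 0.9
    dropout_rate: float = 0.0
    n_marker_families: int = 105
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flex_presence_prob", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_genomes", "n_core_families", "n_flex_families",
                     "n_unique_per_genome", "mean_protein_len", "n_marker_families"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.2 < self.within_family_identity <= 1.0:
            raise ValueError("within_family_identity must be in (0.2, 1.0]")
        if self.n_marker_families > self.n_core_families:
            raise ValueError("n_marker_families cannot exceed n_core_families")


@dataclass
class SyntheticTruth:
    """Planted structure of a generated genome set."""

    gene_to_family: Dict[str, str]          # gene id -> family id or UNIQUE
    family_class: Dict[str, str]            # family id -> CORE | FLEX
    marker_families: Set[str]
    dropped_genes: Set[str]
    params: GeneratorParams
    gene_genome: Dict[str, str] = field(default_factory=dict)

    def surviving_genes(self) -> Set[str]:
        return set(self.gene_to_family) - self.dropped_genes


def substitution_probability(target_identity: float) -> float:
    """Per-copy substitution probability giving the target pairwise identity.

    Two copies independently mutated from an ancestor with per-site
    substitution probability p (uniform over the 19 alternatives) agree at a
    site with probability (1-p)^2 + p^2/19; solve for p.
    """
    t = target_identity
    # (20/19) p^2 - 2 p + (1 - t) = 0, take the root in [0, 1)
    a = 20.0 / 19.0
    disc = 4.0 - 4.0 * a * (1.0 - t)
    if disc < 0:
        raise ValueError(f"target identity {t} unreachable under this model")
    return (2.0 - math.sqrt(disc)) / (2.0 * a)


def _genome_rng(seed: int, genome_index: int) -> np.random.Generator:
    # keyed stream: adding genomes never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, genome_index)))


def _family_rng(seed: int, family_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2, family_index)))


def _draw_length(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return max(50, int(round(mean)))
    shape = 1.0 / dispersion**2
    scale = mean * dispersion**2
    return max(50, int(round(rng.gamma(shape, scale))))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p
    if hit.any():
        idx = np.flatnonzero(hit)
        for i in idx:
            choices = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
            arr[i] = rng.choice(choices)
    return "".join(arr)


def generate_genome_set(params: GeneratorParams) -> Tuple[List[Proteome], SyntheticTruth]:
    """Generate proteomes with a planted core/flexible/unique structure.

    Deterministic under ``params.seed``.  Raises if a genome ends up empty
    (e.g. dropout too aggressive for the gene counts).
    """
    p_sub = substitution_probability(params.within_family_identity)

    n_fam = params.n_core_families + params.n_flex_families
    fam_ids = [f"FAM{i:05d}" for i in range(n_fam)]
    family_class = {
        fid: (CORE if i < params.n_core_families else FLEX)
        for i, fid in enumerate(fam_ids)
    }
    # ancestral sequences, one keyed stream per family
    ancestors: Dict[str, str] = {}
    for i, fid in enumerate(fam_ids):
        frng = _family_rng(params.seed, i)
        length = _draw_length(frng, params.mean_protein_len, params.len_dispersion)
        ancestors[fid] = _random_protein(frng, length)

    master = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(0,)))
    core_ids = fam_ids[: params.n_core_families]
    marker_families = set(
        master.choice(np.array(core_ids), size=params.n_marker_families, replace=False)
    ) if params.n_marker_families else set()

    gene_to_family: Dict[str, str] = {}
    gene_genome: Dict[str, str] = {}
    dropped: Set[str] = set()
    proteomes: List[Proteome] = []

    for g in range(params.n_genomes):
        gid = f"G{g + 1:02d}"
        rng = _genome_rng(params.seed, g)
        genes: List[SequenceRecord] = []
        counter = 0
        for i, fid in enumerate(fam_ids):
            if family_class[fid] == FLEX and rng.random() >= params.flex_presence_prob:
                continue
            counter += 1
            gene_id = f"{gid}|g{counter:05d}"
            seq = _mutate(rng, ancestors[fid], p_sub)
            genes.append(SequenceRecord(id=gene_id, genome_id=gid, seq=seq))
            gene_to_family[gene_id] = fid
            gene_genome[gene_id] = gid
        for _ in range(params.n_unique_per_genome):
            counter += 1
            gene_id = f"{gid}|g{counter:05d}"
            length = _draw_length(rng, params.mean_protein_len, params.len_dispersion)
            genes.append(SequenceRecord(id=gene_id, genome_id=gid, seq=_random_protein(rng, length)))
            gene_to_family[gene_id] = UNIQUE
            gene_genome[gene_id] = gid
        # dropout simulates bin incompleteness
        kept: List[SequenceRecord] = []
        for rec in genes:
            if params.dropout_rate > 0 and rng.random() < params.dropout_rate:
                dropped.add(rec.id)
            else:
                kept.append(rec)
        if not kept:
            raise ValueError(f"genome {gid} is empty under these parameters")
        order = rng.permutation(len(kept))
        proteomes.append(Proteome(genome_id=gid, records=[kept[i] for i in order]))

    truth = SyntheticTruth(
        gene_to_family=gene_to_family,
        family_class=family_class,
        marker_families={str(m) for m in marker_families},
        dropped_genes=dropped,
        params=params,
        gene_genome=gene_genome,
    )
    return proteomes, truth


def generate_marker_hits(
    truth: SyntheticTruth,
    proteomes: Sequence[Proteome],
    inject_duplicates: Optional[Dict[str, Sequence[str]]] = None,
) -> List[Tuple[str, str, str]]:
    """Marker-hit rows (genome_id, gene_id, marker_family) for CSCG scoring.

    Every surviving member of a marker family yields one row.
    ``inject_duplicates`` maps genome_id -> marker families to duplicate
    (an extra synthetic hit row), for exercising contamination flags.
    """
    rows: List[Tuple[str, str, str]] = []
    for prot in proteomes:
        for rec in prot:
            fam = truth.gene_to_family.get(rec.id)
            if fam in truth.marker_families:
                rows.append((prot.genome_id, rec.id, fam))
    if inject_duplicates:
        for gid, fams in inject_duplicates.items():
            for fam in fams:
                rows.append((gid, f"{gid}|dup_{fam}", fam))
    return rows


# ---------------------------------------------------------------------------
# tRNA sets

# canonical anticodons (DNA alphabet) per isotype, standard genetic code
CANONICAL_ANTICODONS: Dict[str, List[str]] = {
    "Ala": ["AGC", "GGC", "CGC", "TGC"],
    "Arg": ["ACG", "GCG", "CCG", "TCG", "CCT", "TCT"],
    "Asn": ["GTT", "ATT"],
    "Asp": ["GTC", "ATC"],
    "Cys": ["GCA", "ACA"],
    "Gln": ["CTG", "TTG"],
    "Glu": ["CTC", "TTC"],
    "Gly": ["ACC", "GCC", "CCC", "TCC"],
    "His": ["GTG", "ATG"],
    "Ile": ["AAT", "GAT", "TAT"],
    "Leu": ["AAG", "GAG", "CAG", "TAG", "CAA", "TAA"],
    "Lys": ["CTT", "TTT"],
    "Met": ["CAT"],
    "Phe": ["GAA", "AAA"],
    "Pro": ["AGG", "GGG", "CGG", "TGG"],
    "Ser": ["AGA", "GGA", "CGA", "TGA", "ACT", "GCT"],
    "Thr": ["AGT", "GGT", "CGT", "TGT"],
    "Trp": ["CCA"],
    "Tyr": ["GTA", "ATA"],
    "Val": ["AAC", "GAC", "CAC", "TAC"],
}

# fixed 75-nt cloverleaf-like scaffold; anticodon occupies indices 33-35
# (standard positions 34-36), so positions 37..40 are indices 36..39
_TRNA_TEMPLATE = (
    "GGGGCTATAGCTCAGCTGGGAGAGCGCCTGCTT"  # 0..32  (acceptor stem + D arm)
    "NNN"                                # 33..35 anticodon
    "AAANN"                              # 36..40 pos 37 + loop positions 38/39/40 + 41
    "CTGGAGGTCCTGTGTTCGATCCACAGAGCCCCCA"  # remainder to 76
)
ANTICODON_OFFSET = 33
NUCS = np.array(list("ACGT"))
LOOP_POSITIONS = (38, 39, 40)


def generate_trna_set(
    n_per_isotype: int,
    usage_spec: Dict[str, Dict[int, Dict[str, float]]],
    seed: int = 0,
    genome_id: str = "SYN",
) -> List[TRNARecord]:
    """Generate tRNA-like records with controlled base usage at positions 38-40.

    ``usage_spec`` maps isotype -> position (38/39/40) -> nucleotide
    distribution over A/C/G/T.  Positions not given a distribution are
    sampled uniformly.  Isotypes are those listed in ``usage_spec``.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    records: List[TRNARecord] = []
    for isotype in sorted(usage_spec):
        spec = usage_spec[isotype]
        for pos, dist in spec.items():
            if pos not in LOOP_POSITIONS:
                raise ValueError(f"usage_spec position must be one of {LOOP_POSITIONS}, got {pos}")
            total = sum(dist.get(n, 0.0) for n in "ACGT")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"distribution for {isotype}/{pos} sums to {total}, expected 1"
                )
        anticodons = CANONICAL_ANTICODONS.get(isotype)
        if not anticodons:
            raise ValueError(f"unknown isotype {isotype!r}")
        for i in range(n_per_isotype):
            anticodon = anticodons[rng.integers(len(anticodons))]
            seq = list(_TRNA_TEMPLATE)
            seq[ANTICODON_OFFSET : ANTICODON_OFFSET + 3] = anticodon
            for pos in LOOP_POSITIONS:
                idx = ANTICODON_OFFSET + 4 + (pos - 38)
                dist = spec.get(pos)
                if dist is None:
                    seq[idx] = str(rng.choice(NUCS))
                else:
                    probs = np.array([dist.get(n, 0.0) for n in "ACGT"])
                    seq[idx] = str(rng.choice(NUCS, p=probs / probs.sum()))
            # fill any leftover Ns uniformly
            for j, c in enumerate(seq):
                if c == "N":
                    seq[j] = str(rng.choice(NUCS))
            records.append(
                TRNARecord(
                    genome_id=genome_id,
                    isotype=isotype,
                    anticodon=anticodon,
                    seq="".join(seq),
                    anticodon_start=ANTICODON_OFFSET,
                    strand="+",
                    scaffold=genome_id,
                    trna_number=i + 1,
                    begin=0,
                    end=len(_TRNA_TEMPLATE),
                    score=50.0,
                )
            )
    return records
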