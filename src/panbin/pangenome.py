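"""Core/flexible partitioning and pan-genome accumulation curves.

Two distinct criteria are used, mirroring the two protocols of the source
analysis pipeline:

* family partitioning works on the ortholog table (BBH + AAI + MCL, 70%
  coverage) and calls a family CORE when it is present in at least
  ``core_min_genomes`` genomes (default: ceil(13/17 * G));
* gene accumulation re-compares raw proteomes pairwise with the looser
  Tettelin-style thresholds (>=50% positives over >50% of the protein
  length), adding genomes one at a time in random order and normalizing
  each count by the median protein count of the genomes included so far.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .align import AlignmentHit, all_vs_all
from .orthology import OrthologTable
from .seqio import Proteome

logger = logging.getLogger(__name__)

CORE = "CORE"
SHARED_NON_CORE = "SHARED_NON_CORE"
UNIQUE = "UNIQUE"


@dataclass
class PartitionResult:
    """Core / shared-non-core / unique classification of an ortholog table."""

    family_class: Dict[str, str]          # family id -> class
    singleton_class: str                  # always UNIQUE, kept for clarity
    core_min_genomes: int
    n_genomes: int
    family_genes: Dict[str, int]          # family id -> gene count
    n_singletons: int

    def class_family_counts(self) -> Dict[str, int]:
        out = {CORE: 0, SHARED_NON_CORE: 0, UNIQUE: 0}
        for cls in self.family_class.values():
            out[cls] += 1
        return out

    def class_gene_counts(self) -> Dict[str, int]:
        out = {CORE: 0, SHARED_NON_CORE: 0, UNIQUE: 0}
        for fid, cls in self.family_class.items():
            out[cls] += self.family_genes[fid]
        out[UNIQUE] += self.n_singletons
        return out

    @property
    def n_genes(self) -> int:
        return sum(self.family_genes.values()) + self.n_singletons


def partition(
    table: OrthologTable,
    n_genomes: int,
    core_min_genomes: Optional[int] = None,
) -> PartitionResult:
    """Classify families by genome presence.

    CORE: present in >= core_min_genomes genomes (default ceil(13/17 * G),
    i.e. 13 when G = 17).  UNIQUE: confined to a single genome (including
    all singletons).  Everything else is SHARED_NON_CORE.
    """
    if core_min_genomes is None:
        core_min_genomes = math.ceil(13.0 / 17.0 * n_genomes)
    if core_min_genomes > n_genomes:
        raise ValueError(
            f"core_min_genomes ({core_min_genomes}) exceeds n_genomes ({n_genomes})"
        )
    family_class: Dict[str, str] = {}
    family_genes: Dict[str, int] = {}
    for fid, members in table.families.items():
        presence = len({g for g, _ in members})
        if presence >= core_min_genomes:
            family_class[fid] = CORE
        elif presence == 1:
            family_class[fid] = UNIQUE
        else:
            family_class[fid] = SHARED_NON_CORE
        family_genes[fid] = len(members)
    return PartitionResult(
        family_class=family_class,
        singleton_class=UNIQUE,
        core_min_genomes=core_min_genomes,
        n_genomes=n_genomes,
        family_genes=family_genes,
        n_singletons=len(table.singletons),
    )


# ---------------------------------------------------------------------------
# Accumulation


@dataclass
class PanGenomeCurve:
    """Per-step accumulation statistics over genome-order permutations."""

    steps: List[int]
    stats: pd.DataFrame       # columns: step, stat, raw_mean, raw_sd, norm_mean, norm_sd
    per_trial: pd.DataFrame   # columns: trial, step, stat, raw, norm
    trial_orders: List[Tuple[str, ...]]
    n_trials: int
    seed: Optional[int]

    def series(self, stat: str, normalized: bool = False) -> Tuple[np.ndarray, np.ndarray]:
        sub = self.stats[self.stats["stat"] == stat].sort_values("step")
        col = "norm_mean" if normalized else "raw_mean"
        return sub["step"].to_numpy(), sub[col].to_numpy()


@dataclass
class PowerFit:
    """Least-squares power-law fit y = a * x^b on log-log scale."""

    amplitude: float
    exponent: float
    rss: float
    n_points: int


def shared_with(
    gene_ids: Sequence[str],
    hits: Sequence[AlignmentHit],
    sim_threshold: float = 50.0,
    cov_threshold: float = 0.5,
) -> Set[str]:
    """Gene ids (queries) with at least one qualifying hit.

    Qualifying: percent positives >= sim_threshold and query coverage
    strictly greater than cov_threshold.
    """
    ok = set()
    for h in hits:
        if h.pct_positives >= sim_threshold and h.q_cov > cov_threshold:
            ok.add(h.query_id)
    return ok & set(gene_ids)


class PairwiseShared:
    """Precomputed per-ordered-genome-pair shared-gene sets.

    ``shared[(A, B)]`` is the set of genes of A with a qualifying hit in B,
    so accumulation trials reduce to set operations.
    """

    def __init__(
        self,
        proteomes: Sequence[Proteome],
        hits_by_pair: Optional[Mapping[Tuple[str, str], Sequence[AlignmentHit]]] = None,
        sim_threshold: float = 50.0,
        cov_threshold: float = 0.5,
        min_kmer_matches: int = 0,
        score_floor: float = 40.0,
    ) -> None:
        self.proteomes = {p.genome_id: p for p in proteomes}
        self.shared: Dict[Tuple[str, str], Set[str]] = {}
        ids = [p.genome_id for p in proteomes]
        for ga, gb in itertools.combinations(ids, 2):
            if hits_by_pair is not None:
                hits_ab = list(hits_by_pair.get((ga, gb), ()))
                hits_ba = list(hits_by_pair.get((gb, ga), ())) or [h.swapped() for h in hits_ab]
            else:
                hits_ab = all_vs_all(
                    self.proteomes[ga], self.proteomes[gb],
                    score_floor=score_floor, min_kmer_matches=min_kmer_matches,
                )
                hits_ba = [h.swapped() for h in hits_ab]
            self.shared[(ga, gb)] = shared_with(
                self.proteomes[ga].gene_ids(), hits_ab, sim_threshold, cov_threshold
            )
            self.shared[(gb, ga)] = shared_with(
                self.proteomes[gb].gene_ids(), hits_ba, sim_threshold, cov_threshold
            )

    def new_genes(self, added: str, prior: Sequence[str]) -> Set[str]:
        """Genes of the added genome shared with no prior genome."""
        genes = set(self.proteomes[added].gene_ids())
        for p in prior:
            genes -= self.shared[(added, p)]
        return genes


def _trial_orders(genome_ids: Sequence[str], trials: int, rng: np.random.Generator) -> List[Tuple[str, ...]]:
    g = len(genome_ids)
    total = math.factorial(g)
    if total <= trials:
        return [tuple(p) for p in itertools.permutations(genome_ids)]
    orders: Set[Tuple[str, ...]] = set()
    ids = np.array(genome_ids, dtype=object)
    while len(orders) < trials:
        orders.add(tuple(rng.permutation(ids)))
    return sorted(orders)  # deterministic order of the sampled set


def accumulate(
    proteomes: Sequence[Proteome],
    trials: int = 100,
    seed: Optional[int] = None,
    pairwise: Optional[PairwiseShared] = None,
    sim_threshold: float = 50.0,
    cov_threshold: float = 0.5,
    global_median: bool = False,
    min_kmer_matches: int = 0,
) -> PanGenomeCurve:
    """Tettelin-style accumulation over random genome orders.

    Genomes are added one at a time; per step the number of new genes
    (no qualifying hit in any prior genome), the cumulative pan-genome size
    and the number of first-genome genes shared with every genome so far are
    recorded, raw and divided by the median protein count of the genomes
    included up to that step (or the global median with
    ``global_median=True``).  Orders are distinct permutations sampled
    without replacement; when G! <= trials all permutations are used.
    """
    if len(proteomes) < 2:
        raise ValueError("accumulation needs at least 2 proteomes")
    if pairwise is None:
        pairwise = PairwiseShared(
            proteomes, sim_threshold=sim_threshold, cov_threshold=cov_threshold,
            min_kmer_matches=min_kmer_matches,
        )
    rng = np.random.default_rng(seed)
    genome_ids = [p.genome_id for p in proteomes]
    sizes = {p.genome_id: p.n_genes for p in proteomes}
    orders = _trial_orders(genome_ids, trials, rng)
    all_median = float(np.median([sizes[g] for g in genome_ids]))

    rows = []
    for t, order in enumerate(orders):
        first = order[0]
        pan = sizes[first]
        shared_set = set(pairwise.proteomes[first].gene_ids())
        for k, added in enumerate(order, start=1):
            included = order[:k]
            median = all_median if global_median else float(np.median([sizes[g] for g in included]))
            if k == 1:
                n_new = sizes[first]
                n_shared = sizes[first]
            else:
                new = pairwise.new_genes(added, included[:-1])
                n_new = len(new)
                pan += n_new
                shared_set &= pairwise.shared[(first, added)]
                n_shared = len(shared_set)
            for stat, raw in (("new", n_new), ("pan", pan), ("shared", n_shared)):
                rows.append(
                    {"trial": t, "step": k, "stat": stat, "raw": raw, "norm": raw / median}
                )
    per_trial = pd.DataFrame(rows)
    stats = (
        per_trial.groupby(["step", "stat"])
        .agg(raw_mean=("raw", "mean"), raw_sd=("raw", "std"),
             norm_mean=("norm", "mean"), norm_sd=("norm", "std"))
        .fillna(0.0)
        .reset_index()
    )
    return PanGenomeCurve(
        steps=sorted(per_trial["step"].unique()),
        stats=stats,
        per_trial=per_trial,
        trial_orders=orders,
        n_trials=len(orders),
        seed=seed,
    )


def fit_power(xs: Sequence[float], ys: Sequence[float]) -> PowerFit:
    """Least-squares fit of log y = log a + b log x.

    Exact on noiseless power-law input.  Raises on non-positive values,
    naming the offending index.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys):
        raise ValueError("xs and ys must have equal length")
    if len(xs) < 2:
        raise ValueError("power fit needs at least 2 points")
    for name, arr in (("x", xs), ("y", ys)):
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise ValueError(f"non-positive {name} value at index {bad[0]}")
    lx, ly = np.log(xs), np.log(ys)
    b, loga = np.polyfit(lx, ly, 1)
    resid = ly - (loga + b * lx)
    return PowerFit(
        amplitude=float(np.exp(loga)),
        exponent=float(b),
        rss=float(np.sum(resid**2)),
        n_points=len(xs),
    )


def fit_new_gene_curve(curve: PanGenomeCurve, include_step1: bool = False,
                       normalized: bool = True) -> PowerFit:
    """Power-regression fit to the mean new-gene curve.

    Step 1 is excluded by default: the first genome's full gene count is not
    an accumulation observation.
    """
    xs, ys = curve.series("new", normalized=normalized)
    if not include_step1:
        keep = xs >= 2
        xs, ys = xs[keep], ys[keep]
    return fit_power(xs, ys)


def fit_pan_curve(curve: PanGenomeCurve, normalized: bool = False) -> PowerFit:
    xs, ys = curve.series("pan", normalized=normalized)
    return fit_power(xs, ys)


# ---------------------------------------------------------------------------
# Category breakdown (Table-2-shaped)

COG_LETTERS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
MULTIPLE = "Multiple assignments"
UNASSIGNED = "Unassigned"


def category_breakdown(
    part: PartitionResult,
    table: OrthologTable,
    gene_categories: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Class x category gene counts from an external gene -> categories map.

    Genes with two or more categories are counted once under "Multiple
    assignments"; genes with none (or only unknown letters, which trigger a
    warning) under "Unassigned".  Row and column sums are appended.
    """
    import warnings

    gene_class: Dict[str, str] = {}
    for fid, members in table.families.items():
        for _, gene in members:
            gene_class[gene] = part.family_class[fid]
    for _, gene in table.singletons:
        gene_class[gene] = UNIQUE

    counts: Dict[str, Dict[str, int]] = {}
    for gene, cls in gene_class.items():
        cats = [c for c in gene_categories.get(gene, ())]
        known = []
        for c in cats:
            if c in COG_LETTERS:
                known.append(c)
            else:
                warnings.warn(f"unknown category letter {c!r} for gene {gene}; bucketed as Unassigned")
        if len(known) >= 2:
            key = MULTIPLE
        elif len(known) == 1:
            key = known[0]
        else:
            key = UNASSIGNED
        counts.setdefault(key, {CORE: 0, SHARED_NON_CORE: 0, UNIQUE: 0})[cls] += 1

    rows = sorted(k for k in counts if k not in (MULTIPLE, UNASSIGNED))
    rows += [k for k in (MULTIPLE, UNASSIGNED) if k in counts]
    df = pd.DataFrame(
        [[counts[r].get(c, 0) for c in (CORE, SHARED_NON_CORE, UNIQUE)] for r in rows],
        index=rows,
        columns=[CORE, SHARED_NON_CORE, UNIQUE],
    )
    df["Total"] = df.sum(axis=1)
    df.loc["Total"] = df.sum(axis=0)
    return df
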