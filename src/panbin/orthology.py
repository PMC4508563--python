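"""Ortholog family inference: reciprocal best hits, AAI-adaptive identity
filtering, similarity-graph construction and Markov clustering.

The per-genome-pair criterion is: a gene pair is a provisional ortholog pair
when each gene is the other's best-scoring hit and the alignment covers at
least ``min_cov`` of BOTH protein lengths; the mean and standard deviation
of the provisional pairs' percent identities define the genome pair's
average amino-acid identity (AAI), and pairs whose identity falls more than
``aai_window`` standard deviations BELOW the mean are discarded.  Accepted
pairs across all genome pairs form an undirected similarity graph that is
partitioned into families by the Markov Cluster (MCL) algorithm.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .align import AlignmentHit, all_vs_all
from .seqio import Proteome

logger = logging.getLogger(__name__)

GeneKey = Tuple[str, str]  # (genome_id, gene_id)


@dataclass
class GenomePairAAI:
    """Average amino-acid identity of one genome pair, from its BBH pairs."""

    genome_a: str
    genome_b: str
    mean_identity: float
    sd_identity: float
    n_pairs: int

    @property
    def defined(self) -> bool:
        return self.n_pairs >= 1


@dataclass
class OrthologTable:
    """Partition of all genes into multi-member families and singletons."""

    families: Dict[str, Set[GeneKey]]
    singletons: Set[GeneKey]
    converged: bool = True

    def __post_init__(self) -> None:
        for fid, members in self.families.items():
            if len(members) < 2:
                raise ValueError(f"family {fid} has fewer than 2 members")

    @property
    def n_genes(self) -> int:
        return sum(len(m) for m in self.families.values()) + len(self.singletons)

    @property
    def n_family_genes(self) -> int:
        return sum(len(m) for m in self.families.values())

    def family_presence(self, fid: str) -> int:
        """Number of distinct genomes with at least one member."""
        return len({g for g, _ in self.families[fid]})

    def gene_to_family(self) -> Dict[GeneKey, Optional[str]]:
        out: Dict[GeneKey, Optional[str]] = {}
        for fid, members in self.families.items():
            for key in members:
                out[key] = fid
        for key in self.singletons:
            out[key] = None
        return out

    def genome_family_complement(self, genome_id: str) -> Set[str]:
        """Family ids with at least one member in the given genome."""
        return {
            fid for fid, members in self.families.items()
            if any(g == genome_id for g, _ in members)
        }

    def presence_matrix(self) -> pd.DataFrame:
        """Families x genomes integer copy-count matrix."""
        genomes = sorted({g for m in self.families.values() for g, _ in m}
                         | {g for g, _ in self.singletons})
        data = {}
        for fid, members in sorted(self.families.items()):
            row = {g: 0 for g in genomes}
            for g, _ in members:
                row[g] += 1
            data[fid] = row
        return (
            pd.DataFrame.from_dict(data, orient="index")
            .reindex(columns=genomes)
            .fillna(0)
            .astype(int)
        )


# ---------------------------------------------------------------------------
# Best hits and BBH pairs


def best_hits(hits: Sequence[AlignmentHit]) -> Dict[str, AlignmentHit]:
    """Per query, the best-scoring hit.

    Ties on score are broken by higher percent identity, then by
    lexicographically smaller subject id, so the result is deterministic.
    """
    best: Dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (h.score, h.pct_identity, _NegStr(h.subject_id))
        key_cur = (cur.score, cur.pct_identity, _NegStr(cur.subject_id))
        if key_new > key_cur:
            best[h.query_id] = h
    return best


class _NegStr(str):
    """Orders strings in reverse, so 'smaller id wins' fits a max-compare."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def bbh_pairs(
    bh_ab: Mapping[str, AlignmentHit],
    bh_ba: Mapping[str, AlignmentHit],
    genome_a: str,
    genome_b: str,
    min_cov: float = 0.70,
    aai_window: float = 2.0,
    cov_mode: str = "both",
) -> Tuple[Dict[Tuple[str, str], AlignmentHit], GenomePairAAI]:
    """Reciprocal best hits of one genome pair with coverage and AAI filters.

    Stage 1: reciprocal pairs whose a->b hit covers >= ``min_cov`` of the
    protein length (both sequences by default, query only with
    cov_mode='query') form the provisional set.  Stage 2: the mean and
    population SD of provisional identities define the pair's AAI.
    Stage 3: pairs with identity below mean - aai_window*SD are removed.

    Returns accepted (gene_a, gene_b) -> hit, plus the AAI record.
    """
    if cov_mode not in ("both", "query"):
        raise ValueError(f"unknown cov_mode {cov_mode!r}")
    provisional: Dict[Tuple[str, str], AlignmentHit] = {}
    for qa, hit in bh_ab.items():
        back = bh_ba.get(hit.subject_id)
        if back is None or back.subject_id != qa:
            continue
        if cov_mode == "both":
            ok = hit.q_cov >= min_cov and hit.s_cov >= min_cov
        else:
            ok = hit.q_cov >= min_cov
        if ok:
            provisional[(qa, hit.subject_id)] = hit
    if not provisional:
        aai = GenomePairAAI(genome_a, genome_b, float("nan"), float("nan"), 0)
        logger.warning("no provisional BBH pairs for %s vs %s; AAI undefined", genome_a, genome_b)
        return {}, aai
    idents = np.array([h.pct_identity for h in provisional.values()])
    mean = float(idents.mean())
    sd = float(idents.std(ddof=0))
    cutoff = mean - aai_window * sd
    accepted = {
        pair: h for pair, h in provisional.items() if h.pct_identity >= cutoff
    }
    aai = GenomePairAAI(genome_a, genome_b, mean, sd, len(provisional))
    return accepted, aai


# ---------------------------------------------------------------------------
# Graph construction and MCL


def build_graph(
    pair_hits: Mapping[Tuple[GeneKey, GeneKey], AlignmentHit],
    all_genes: Iterable[GeneKey],
    weight: str = "identity",
) -> nx.Graph:
    """Undirected similarity graph over all genes.

    Edge weight is pct_identity/100 (default) or the raw alignment score.
    Genes without any accepted pair become isolated nodes.
    """
    G = nx.Graph()
    G.add_nodes_from(all_genes)
    for (ka, kb), hit in pair_hits.items():
        w = hit.pct_identity / 100.0 if weight == "identity" else hit.score
        G.add_edge(ka, kb, weight=w)
    return G


def _mcl_matrix(M: np.ndarray, inflation: float, max_iter: int,
                prune_threshold: float, tol: float) -> Tuple[np.ndarray, bool]:
    """Run MCL iterations on a column-stochastic matrix; returns (matrix, converged)."""
    for _ in range(max_iter):
        prev = M
        M = M @ M                      # expansion
        M = M ** inflation             # inflation
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if M.shape == prev.shape and np.abs(M - prev).max() < tol:
            return M, True
    return M, False


def _clusters_from_matrix(M: np.ndarray) -> List[Set[int]]:
    """Read clusters off attractor rows (nonzero diagonal), merging overlaps."""
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > 0]
    clusters: List[Set[int]] = []
    for i in attractors:
        members = set(np.flatnonzero(M[i] > 0)) | {i}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    # any node not claimed by an attractor row joins the cluster of its
    # strongest column entry (degenerate but possible after pruning)
    claimed = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in claimed:
            col = M[:, j]
            if col.max() > 0:
                owner = int(col.argmax())
                for c in clusters:
                    if owner in c:
                        c.add(j)
                        break
                else:
                    clusters.append({owner, j})
            else:
                clusters.append({j})
    return clusters


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    prune_threshold: float = 1e-5,
    tol: float = 1e-8,
) -> OrthologTable:
    """Markov clustering of the similarity graph into an ortholog table.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight (1.0 for isolated nodes) before column normalization.
    Clustering runs per connected component (equivalent to clustering the
    whole matrix: expansion and inflation never create cross-component
    entries) to keep the dense linear algebra small.  Non-convergence within
    ``max_iter`` on any component returns the current clustering with
    ``converged=False``.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    clusters: List[Set[GeneKey]] = []
    converged_all = True
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(set(nodes))
            continue
        idx = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        M = np.zeros((n, n))
        for u, v, data in graph.subgraph(comp).edges(data=True):
            w = data.get("weight", 1.0)
            M[idx[u], idx[v]] = w
            M[idx[v], idx[u]] = w
        loop = M.max(axis=0)
        loop[loop == 0] = 1.0
        np.fill_diagonal(M, loop)
        M = M / M.sum(axis=0)
        M, ok = _mcl_matrix(M, inflation, max_iter, prune_threshold, tol)
        if not ok:
            converged_all = False
            logger.warning("MCL did not converge on a %d-node component", n)
        for members in _clusters_from_matrix(M):
            clusters.append({nodes[i] for i in members})

    families: Dict[str, Set[GeneKey]] = {}
    singles: Set[GeneKey] = set()
    multi = [c for c in clusters if len(c) >= 2]
    # deterministic family ids: size desc, then smallest member id
    multi.sort(key=lambda c: (-len(c), min(c)))
    for i, c in enumerate(multi, start=1):
        families[f"F{i:05d}"] = c
    for c in clusters:
        if len(c) == 1:
            singles |= c
    return OrthologTable(families=families, singletons=singles, converged=converged_all)


def flag_multicopy(table: OrthologTable) -> List[Tuple[str, str, int]]:
    """All (family, genome, copy_count) with two or more members per genome."""
    flags: List[Tuple[str, str, int]] = []
    for fid in sorted(table.families):
        counts: Dict[str, int] = {}
        for g, _ in table.families[fid]:
            counts[g] = counts.get(g, 0) + 1
        for g, c in sorted(counts.items()):
            if c >= 2:
                flags.append((fid, g, c))
    return flags


# ---------------------------------------------------------------------------
# End-to-end orchestration over a genome set


def infer_orthologs(
    proteomes: Sequence[Proteome],
    hits_by_pair: Optional[Mapping[Tuple[str, str], Sequence[AlignmentHit]]] = None,
    min_cov: float = 0.70,
    aai_window: float = 2.0,
    inflation: float = 2.0,
    cov_mode: str = "both",
    min_kmer_matches: int = 0,
    score_floor: float = 40.0,
    weight: str = "identity",
) -> Tuple[OrthologTable, List[GenomePairAAI]]:
    """Full ortholog inference across a genome set.

    ``hits_by_pair`` maps ordered (genome_a, genome_b) pairs to alignment
    hits; when absent, the built-in aligner computes them (one unordered
    pair at a time, reusing each alignment for both directions).
    """
    by_id = {p.genome_id: p for p in proteomes}
    genome_ids = [p.genome_id for p in proteomes]
    accepted: Dict[Tuple[GeneKey, GeneKey], AlignmentHit] = {}
    aai_records: List[GenomePairAAI] = []
    for ga, gb in itertools.combinations(genome_ids, 2):
        if hits_by_pair is not None:
            hits_ab = list(hits_by_pair.get((ga, gb), ()))
            hits_ba = list(hits_by_pair.get((gb, ga), ()))
            if not hits_ba:
                hits_ba = [h.swapped() for h in hits_ab]
        else:
            hits_ab = all_vs_all(
                by_id[ga], by_id[gb],
                score_floor=score_floor, min_kmer_matches=min_kmer_matches,
            )
            hits_ba = [h.swapped() for h in hits_ab]
        pairs, aai = bbh_pairs(
            best_hits(hits_ab), best_hits(hits_ba), ga, gb,
            min_cov=min_cov, aai_window=aai_window, cov_mode=cov_mode,
        )
        aai_records.append(aai)
        for (a_gene, b_gene), hit in pairs.items():
            accepted[((ga, a_gene), (gb, b_gene))] = hit
    all_genes = [(p.genome_id, r.id) for p in proteomes for r in p]
    graph = build_graph(accepted, all_genes, weight=weight)
    table = mcl_cluster(graph, inflation=inflation)
    logger.info(
        "infer_orthologs: %d genes -> %d families (%d genes) + %d singletons",
        table.n_genes, len(table.families), table.n_family_genes, len(table.singletons),
    )
    return table, aai_records


def aai_matrix(aai_records: Sequence[GenomePairAAI]) -> pd.DataFrame:
    genomes = sorted({r.genome_a for r in aai_records} | {r.genome_b for r in aai_records})
    m = pd.DataFrame(np.nan, index=genomes, columns=genomes)
    for r in aai_records:
        m.loc[r.genome_a, r.genome_b] = r.mean_identity
        m.loc[r.genome_b, r.genome_a] = r.mean_identity
    return m
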