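"""Genome-bin quality from conserved single-copy genes (CSCGs).

A bin's completeness is the fraction of an expected marker set (105 CSCGs by
default) found at least once; markers found in multiple copies flag possible
contamination (misplaced scaffolds).  Relative completeness compares a bin's
ortholog-family complement against the complement of a designated reference
genome — useful when the lineage legitimately lacks some universal markers,
so absolute CSCG completeness underestimates how much of a typical genome of
the group was recovered.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .orthology import OrthologTable

logger = logging.getLogger(__name__)

DEFAULT_N_MARKERS = 105


@dataclass
class CSCGReport:
    """Marker census of one genome bin."""

    genome_id: str
    n_markers_expected: int
    markers_found: Set[str]
    markers_multicopy: Dict[str, int]
    relative_completeness_pct: Optional[float] = None

    def __post_init__(self) -> None:
        extra = set(self.markers_multicopy) - self.markers_found
        if extra:
            raise ValueError(f"multicopy markers not in found set: {sorted(extra)}")

    @property
    def completeness_raw(self) -> float:
        return 100.0 * len(self.markers_found) / self.n_markers_expected

    @property
    def completeness_pct(self) -> int:
        """Integer percent, rounded half away from zero."""
        return int(math.floor(self.completeness_raw + 0.5))


def score_completeness(
    marker_hits: Iterable[Tuple[str, str]],
    marker_set: Sequence[str],
    genome_id: str = "",
) -> CSCGReport:
    """Census one genome's marker hits against the expected marker set.

    ``marker_hits`` yields (gene_id, marker_id) rows for a single genome.
    Hits to markers outside ``marker_set`` are ignored with a warning.
    """
    expected = set(marker_set)
    if not expected:
        raise ValueError("marker set is empty")
    counts: Dict[str, int] = {}
    for gene_id, marker in marker_hits:
        if marker not in expected:
            warnings.warn(f"hit to marker {marker!r} outside the marker set; ignored")
            continue
        counts[marker] = counts.get(marker, 0) + 1
    found = set(counts)
    multi = {m: c for m, c in counts.items() if c >= 2}
    return CSCGReport(
        genome_id=genome_id,
        n_markers_expected=len(expected),
        markers_found=found,
        markers_multicopy=multi,
    )


def relative_completeness(
    genome_families: Set[str],
    reference_complement: Set[str],
) -> float:
    """Percent of the reference genome's family complement present in a bin.

    100 * |families of this genome  ∩  reference complement| / |reference|.
    The designated standard genome scores exactly 100 against itself.
    """
    if not reference_complement:
        raise ValueError("reference complement is empty")
    return 100.0 * len(genome_families & reference_complement) / len(reference_complement)


def relative_completeness_from_table(
    table: OrthologTable,
    genome_id: str,
    reference_genome_id: str,
) -> float:
    """Relative completeness of one genome against a reference, both read
    off an ortholog table's family complements."""
    ref = table.genome_family_complement(reference_genome_id)
    mine = table.genome_family_complement(genome_id)
    return relative_completeness(mine, ref)


def contamination_flags(report: CSCGReport) -> List[Tuple[str, int]]:
    """Markers present in two or more copies, highest count first."""
    return sorted(report.markers_multicopy.items(), key=lambda kv: (-kv[1], kv[0]))


def census_genomes(
    marker_rows: Iterable[Tuple[str, str, str]],
    marker_set: Sequence[str],
    genome_ids: Optional[Sequence[str]] = None,
) -> Dict[str, CSCGReport]:
    """Score every genome in a (genome_id, gene_id, marker_id) hit table.

    Genomes listed in ``genome_ids`` but absent from the table get an empty
    report (completeness 0).
    """
    by_genome: Dict[str, List[Tuple[str, str]]] = {}
    for genome, gene, marker in marker_rows:
        by_genome.setdefault(genome, []).append((gene, marker))
    if genome_ids:
        for g in genome_ids:
            by_genome.setdefault(g, [])
    return {
        g: score_completeness(rows, marker_set, genome_id=g)
        for g, rows in sorted(by_genome.items())
    }
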