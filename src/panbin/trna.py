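"""Nucleotide usage at tRNA anticodon-loop positions 38, 39 and 40.

Pseudouridine synthase A (TruA) modifies uridines at positions 38-40 of the
anticodon stem-loop.  Lineages that have lost the gene can compensate by
avoiding U (T in gene space) at exactly those positions of the isotypes that
are normally modified; this module computes the per-isotype usage matrices
and group-vs-group frequency differences that expose such a shift.

Positions are located by fixed offsets from the anticodon: with the
anticodon at standard positions 34-36, positions 38/39/40 are offsets
+4/+5/+6 from the anticodon start.  This is valid for canonical cloverleaf
tRNAs, where no length variation occurs between the anticodon and position
40; records too short for the offsets are skipped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import TRNARecord

logger = logging.getLogger(__name__)

LOOP_POSITIONS = (38, 39, 40)
NUCLEOTIDES = ("A", "C", "G", "T")
Cell = Tuple[str, int]  # (isotype, position)


def loop_positions(record: TRNARecord) -> Optional[Tuple[str, str, str]]:
    """Bases at standard positions 38, 39, 40, or None if the record is too
    short to carry them.  Raises if the stored anticodon disagrees with the
    sequence at the stated offset."""
    if record.anticodon_start is None or not record.seq:
        warnings.warn(f"record {record.genome_id}/{record.isotype} has no sequence; skipped")
        return None
    a = record.anticodon_start
    if record.seq[a : a + 3] != record.anticodon:
        raise ValueError(
            f"anticodon mismatch in {record.genome_id}/{record.isotype}: "
            f"sequence has {record.seq[a:a + 3]!r}, record says {record.anticodon!r}"
        )
    if a + 6 >= len(record.seq):
        warnings.warn(f"record {record.genome_id}/{record.isotype} too short for positions 38-40; skipped")
        return None
    return record.seq[a + 4], record.seq[a + 5], record.seq[a + 6]


@dataclass
class UsageMatrix:
    """Per-(isotype, position) nucleotide counts and frequencies for a group."""

    group: str
    counts: Dict[Cell, Dict[str, int]]

    def n(self, isotype: str, position: int) -> int:
        return sum(self.counts.get((isotype, position), {}).values())

    def frequency(self, isotype: str, position: int, nucleotide: str) -> float:
        cell = self.counts.get((isotype, position))
        if not cell:
            raise KeyError((isotype, position))
        total = sum(cell.values())
        return cell.get(nucleotide, 0) / total

    def cells(self) -> List[Cell]:
        return sorted(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (iso, pos), cell in sorted(self.counts.items()):
            total = sum(cell.values())
            row = {"group": self.group, "isotype": iso, "position": pos, "n": total}
            for nuc in NUCLEOTIDES:
                row[nuc] = cell.get(nuc, 0) / total if total else 0.0
            rows.append(row)
        return pd.DataFrame(rows)


def usage_matrix(records: Iterable[TRNARecord], group: str = "") -> UsageMatrix:
    """Pool usable records (across genomes) into per-(isotype, position)
    nucleotide counts.  Isotypes with zero usable records are omitted."""
    counts: Dict[Cell, Dict[str, int]] = {}
    n_usable = 0
    for rec in records:
        bases = loop_positions(rec)
        if bases is None:
            continue
        n_usable += 1
        for pos, base in zip(LOOP_POSITIONS, bases):
            cell = counts.setdefault((rec.isotype, pos), {})
            cell[base] = cell.get(base, 0) + 1
    if n_usable == 0:
        raise ValueError("no usable tRNA records")
    return UsageMatrix(group=group, counts=counts)


def usage_from_reference_table(df: pd.DataFrame, group: str = "reference") -> UsageMatrix:
    """Build a UsageMatrix from a pre-tabulated reference TSV.

    Expected columns: isotype, position, A, C, G, T.  Rows may carry counts
    or frequencies; frequency rows (sums within 1e-6 of 1) are scaled by a
    nominal n of 1000 so comparisons can apply their min-n mask.
    """
    counts: Dict[Cell, Dict[str, int]] = {}
    for _, row in df.iterrows():
        vals = {n: float(row[n]) for n in NUCLEOTIDES}
        total = sum(vals.values())
        if total <= 0:
            continue
        if abs(total - 1.0) < 1e-6:
            vals = {n: v * 1000 for n, v in vals.items()}
        counts[(str(row["isotype"]), int(row["position"]))] = {
            n: int(round(v)) for n, v in vals.items()
        }
    return UsageMatrix(group=group, counts=counts)


def compare_usage(
    matrix_a: UsageMatrix,
    matrix_b: UsageMatrix,
    nucleotide: str = "T",
    min_n: int = 5,
) -> pd.DataFrame:
    """Per shared (isotype, position) frequency difference freq_a - freq_b.

    Cells with fewer than ``min_n`` records in either group are masked
    (excluded).  Raises when the matrices share no cells at all.
    """
    shared = set(matrix_a.counts) & set(matrix_b.counts)
    if not shared:
        raise ValueError(f"matrices {matrix_a.group!r} and {matrix_b.group!r} share no cells")
    rows = []
    for iso, pos in sorted(shared):
        n_a, n_b = matrix_a.n(iso, pos), matrix_b.n(iso, pos)
        if n_a < min_n or n_b < min_n:
            continue
        fa = matrix_a.frequency(iso, pos, nucleotide)
        fb = matrix_b.frequency(iso, pos, nucleotide)
        rows.append(
            {"isotype": iso, "position": pos, "nucleotide": nucleotide,
             "freq_a": fa, "freq_b": fb, "delta": fa - fb, "n_a": n_a, "n_b": n_b}
        )
    return pd.DataFrame(rows)
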