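"""Composition and coverage signatures used for bin-consistency checks:
windowed %G+C, tetranucleotide frequency vectors, and scaffold mean coverage.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TETRAMERS: List[str] = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
_TETRA_INDEX = {t: i for i, t in enumerate(TETRAMERS)}


@dataclass
class WindowProfile:
    """Sliding-window statistic along one scaffold (starts are 0-based)."""

    scaffold_id: str
    window: int
    step: int
    values: List[Tuple[int, float]]
    statistic: str = "gc"

    def __post_init__(self) -> None:
        if not self.window >= self.step >= 1:
            raise ValueError("require window >= step >= 1")


def gc_windows(seq: str, window: int = 120, step: int = 30, scaffold_id: str = "") -> WindowProfile:
    """%G+C per fully contained window; N does not count in the denominator.

    Windows whose denominator is zero (all-N) get NaN.  A sequence shorter
    than the window yields an empty profile with a warning.
    """
    seq = seq.upper()
    values: List[Tuple[int, float]] = []
    if len(seq) < window:
        warnings.warn(f"sequence {scaffold_id or '<anon>'} shorter than window {window}; empty profile")
        return WindowProfile(scaffold_id, window, step, values)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    is_acgt = is_gc | (arr == b"A") | (arr == b"T")
    for start in range(0, len(seq) - window + 1, step):
        denom = int(is_acgt[start : start + window].sum())
        gc = int(is_gc[start : start + window].sum())
        values.append((start, 100.0 * gc / denom if denom else float("nan")))
    return WindowProfile(scaffold_id, window, step, values)


def tetra_freq(seq: str, window: int = 5000, scaffold_id: str = "") -> pd.DataFrame:
    """Overlapping 4-mer frequencies per window, tiled by ``window``.

    4-mers are counted within a window only (they do not span tile
    boundaries); the trailing partial window is kept when it is at least
    4 nt.  4-mers containing anything but ACGT are skipped; frequencies are
    counts normalized to sum to 1 per window (windows with zero valid 4-mers
    are dropped).  Counting is strand-specific over all 256 tetramers in
    lexicographic column order.
    """
    seq = seq.upper()
    rows = []
    starts = []
    for start in range(0, len(seq), window):
        chunk = seq[start : start + window]
        if len(chunk) < 4:
            break
        counts = np.zeros(256, dtype=float)
        for i in range(len(chunk) - 3):
            idx = _TETRA_INDEX.get(chunk[i : i + 4])
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        if total > 0:
            rows.append(counts / total)
            starts.append(start)
    df = pd.DataFrame(rows, columns=TETRAMERS)
    df.insert(0, "window_start", starts)
    if scaffold_id:
        df.insert(0, "scaffold", scaffold_id)
    return df


def canonical_tetra(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse the 256-dimensional profile to 136 reverse-complement pairs."""
    comp = str.maketrans("ACGT", "TGCA")
    seen = {}
    for t in TETRAMERS:
        rc = t.translate(comp)[::-1]
        key = min(t, rc)
        seen.setdefault(key, []).append(t)
    meta = df[[c for c in df.columns if c not in TETRAMERS]]
    collapsed = {
        key: df[list(set(members))].sum(axis=1) for key, members in sorted(seen.items())
    }
    return pd.concat([meta, pd.DataFrame(collapsed)], axis=1)


def mean_coverage(depths: Mapping[int, float], scaffold_length: int) -> float:
    """Mean per-base depth over a declared scaffold length.

    ``depths`` maps 0-based positions to depth; absent positions count as 0.
    Positions at or beyond the declared length are an error.
    """
    if scaffold_length <= 0:
        raise ValueError("scaffold_length must be positive")
    for pos in depths:
        if pos >= scaffold_length or pos < 0:
            raise ValueError(f"depth position {pos} outside scaffold of length {scaffold_length}")
    return float(sum(depths.values())) / scaffold_length
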