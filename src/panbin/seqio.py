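"""Readers and writers for the external formats the pipeline touches.

All coordinates are converted exactly once at the I/O boundary: files use
1-based inclusive coordinates (BLAST tabular, tRNAscan-SE), in-memory types
use 0-based half-open intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")

FASTA_WRAP = 60


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SequenceRecord:
    """One protein or nucleotide sequence with a stable identifier."""

    id: str
    genome_id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence for record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Proteome:
    """A genome's gene complement: ordered records with unique ids."""

    genome_id: str
    records: List[SequenceRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate gene id {dup!r} in genome {self.genome_id!r}")

    @property
    def n_genes(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == gene_id:
                return r
        raise KeyError(gene_id)

    def gene_ids(self) -> List[str]:
        return [r.id for r in self.records]


@dataclass
class TabularHit:
    """One row of 12-column BLAST tabular output (outfmt 6 dialect).

    Coordinates are kept 1-based inclusive, as in the file; they are a
    transport type, not used for arithmetic.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end in hit {self.query_id}->{self.subject_id}")
        if self.s_start > self.s_end:
            raise ValueError(f"s_start > s_end in hit {self.query_id}->{self.subject_id}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")


@dataclass
class TRNARecord:
    """A tRNA gene with its isotype, anticodon and (optionally) sequence.

    ``anticodon_start`` is the 0-based index of the anticodon within ``seq``
    (anticodon occupies standard positions 34-36 of the cloverleaf).
    Records parsed from a tRNAscan-SE table carry begin/end coordinates on
    the source scaffold (0-based half-open after normalization) but no
    sequence until one is attached.
    """

    genome_id: str
    isotype: str
    anticodon: str
    seq: str = ""
    anticodon_start: Optional[int] = None
    strand: str = "+"
    scaffold: str = ""
    trna_number: int = 0
    begin: Optional[int] = None
    end: Optional[int] = None
    score: float = 0.0

    def __post_init__(self) -> None:
        self.anticodon = self.anticodon.upper().replace("U", "T")
        self.seq = self.seq.upper().replace("U", "T")

    @property
    def usable(self) -> bool:
        """True when loop positions 38-40 can be read off the sequence."""
        return (
            bool(self.seq)
            and self.anticodon_start is not None
            and self.anticodon_start + 6 < len(self.seq)
        )


ISOTYPES = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "SeC", "Sup", "iMet", "fMet", "Undet",
}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, genome_id: Optional[str] = None, alphabet: str = "protein") -> Proteome:
    """Read a FASTA file into a :class:`Proteome`.

    ``genome_id`` defaults to the file stem.  Sequences are upper-cased;
    duplicate ids, empty files and illegal residues are rejected with
    distinct errors.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: malformed header (empty id)")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - allowed
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains illegal {alphabet} "
                f"residues {sorted(bad)}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, genome_id=gid, seq=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no records")
    logger.info("read_fasta: %s -> %d records (genome %s)", path, len(records), gid)
    return Proteome(genome_id=gid, records=records)


def write_fasta(proteome_or_records, path) -> None:
    """Write records to FASTA, wrapping sequence lines at 60 columns."""
    records = proteome_or_records.records if isinstance(proteome_or_records, Proteome) else proteome_or_records
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.seq), FASTA_WRAP):
                fh.write(r.seq[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (12-column outfmt-6 dialect)

_BLAST_COLS = [
    ("query_id", str), ("subject_id", str), ("pct_identity", float),
    ("aln_length", int), ("mismatches", int), ("gap_opens", int),
    ("q_start", int), ("q_end", int), ("s_start", int), ("s_end", int),
    ("evalue", float), ("bit_score", float),
]


def read_blast_tabular(path) -> List[TabularHit]:
    """Parse 12-column tab-separated hits; wrong column count names the line."""
    hits: List[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            kwargs = {name: conv(v) for (name, conv), v in zip(_BLAST_COLS, fields)}
            hits.append(TabularHit(**kwargs))
    return hits


def write_blast_tabular(hits: Iterable[TabularHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                        str(h.aln_length), str(h.mismatches), str(h.gap_opens),
                        str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                        f"{h.evalue:.2g}", f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# tRNAscan-SE tabular output

_TRNASCAN_HEADER = (
    "Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tInf\n"
    "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
    "--------\t------\t-----\t---\t----\t-----\t-----\t----\t-----\n"
)


def read_trnascan_table(path, genome_id: Optional[str] = None) -> List[TRNARecord]:
    """Parse tRNAscan-SE tabular output (3 header lines, 9 columns).

    Reverse-strand rows (begin > end on the scaffold) are flagged with
    strand='-' and their coordinates normalized to 0-based half-open with
    begin < end.  Unknown isotype strings are kept with isotype "Undet"
    and a warning.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    records: List[TRNARecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3 or not line.strip():
            continue
        fields = [f.strip() for f in line.rstrip("\n").split("\t")]
        if len(fields) < 9:
            raise FormatError(f"{path}: line {lineno}: expected 9 columns, got {len(fields)}")
        scaffold, num, begin, end, isotype, anticodon = fields[:6]
        score = float(fields[8])
        b, e = int(begin), int(end)
        if b <= e:
            strand = "+"
            begin0, end0 = b - 1, e  # 1-based inclusive -> 0-based half-open
        else:
            strand = "-"
            begin0, end0 = e - 1, b
        if isotype not in ISOTYPES:
            warnings.warn(f"{path}: line {lineno}: unknown isotype {isotype!r}, kept as Undet")
            isotype = "Undet"
        records.append(
            TRNARecord(
                genome_id=gid, isotype=isotype, anticodon=anticodon,
                strand=strand, scaffold=scaffold, trna_number=int(num),
                begin=begin0, end=end0, score=score,
            )
        )
    return records


def write_trnascan_table(records: Iterable[TRNARecord], path) -> None:
    """Write records in tRNAscan-SE tabular layout (1-based inclusive coords)."""
    with open(path, "w") as fh:
        fh.write(_TRNASCAN_HEADER)
        for r in records:
            begin0 = r.begin if r.begin is not None else 0
            end0 = r.end if r.end is not None else len(r.seq)
            if r.strand == "+":
                b, e = begin0 + 1, end0
            else:
                b, e = end0, begin0 + 1
            fh.write(
                "\t".join(
                    [
                        r.scaffold or r.genome_id, str(r.trna_number), str(b), str(e),
                        r.isotype, r.anticodon, "0", "0", f"{r.score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Per-base depth tables


def read_depth_table(path) -> Dict[str, Dict[int, float]]:
    """Read a 3-column (scaffold, 1-based position, depth) TSV.

    Returns per-scaffold sparse position->depth maps with 0-based positions.
    Positions absent from the table are depth 0 when averaging over a
    declared scaffold length (see :func:`panbin.signatures.mean_coverage`).
    """
    out: Dict[str, Dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            scaffold, pos, depth = fields[0], int(fields[1]), float(fields[2])
            if depth < 0:
                raise FormatError(f"{path}: line {lineno}: negative depth {depth}")
            out.setdefault(scaffold, {})[pos - 1] = depth
    return out


# ---------------------------------------------------------------------------
# Presence/absence matrices


def write_presence_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a families x genomes integer copy-count matrix as TSV."""
    matrix.to_csv(path, sep="\t", index_label="family")


def read_presence_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="family")


# ---------------------------------------------------------------------------
# Flat key/value run configuration


def read_config(path) -> Dict[str, object]:
    """Load a flat key/value config file (YAML dialect, no nesting)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key/value mapping")
    for k, v in data.items():
        if isinstance(v, (dict, list)):
            raise FormatError(f"{path}: config key {k!r} is nested; flat keys only")
    return data
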