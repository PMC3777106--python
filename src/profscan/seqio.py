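"""Reading, writing and manipulating DNA sequences and alignments.

Sequences are stored uppercase over the IUPAC nucleotide alphabet
(``ACGT`` plus the degenerate codes ``RYSWKMBDHVN``).  ``U`` is silently
mapped to ``T`` and lowercase input is uppercased; no soft-masking
semantics are attached to case.  Internally every coordinate is 0-based
half-open; user-facing report formatting (in :mod:`profscan.pipeline`)
converts to 1-based inclusive.

Degenerate codes are represented internally as 4-bit masks (A=1, C=2,
G=4, T=8); e.g. ``R = A|G = 5``.  This makes complementation a bit
reversal and lets emission tables be extended to all 15 codes without
special cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

GAP_CHARS = "-."

# 4-bit masks: A=1, C=2, G=4, T=8
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_ALPHABET = frozenset(IUPAC_CODES)

CODE_TO_MASK = {c: sum(_BASE_BITS[b] for b in bases) for c, bases in IUPAC_CODES.items()}
MASK_TO_CODE = {m: c for c, m in CODE_TO_MASK.items()}

# char -> mask lookup table for fast encoding (0 = invalid)
_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    _ENCODE_LUT[ord(_c)] = _m
    _ENCODE_LUT[ord(_c.lower())] = _m
_ENCODE_LUT[ord("U")] = CODE_TO_MASK["T"]
_ENCODE_LUT[ord("u")] = CODE_TO_MASK["T"]


def _revbits4(m: int) -> int:
    """Reverse the 4 bits of a base mask: complementation A<->T, C<->G."""
    return ((m & 1) << 3) | ((m & 2) << 1) | ((m & 4) >> 1) | ((m & 8) >> 3)


COMPLEMENT = {c: MASK_TO_CODE[_revbits4(m)] for c, m in CODE_TO_MASK.items()}
_COMP_LUT = str.maketrans(COMPLEMENT)

# mask -> complement mask, for encoded arrays
COMP_MASK = np.array([_revbits4(m) for m in range(16)], dtype=np.uint8)


class ParseError(ValueError):
    """Malformed sequence/alignment input."""


def clean_residues(s: str) -> str:
    """Uppercase, map U->T; raise on non-IUPAC symbols."""
    s = s.upper().replace("U", "T")
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise ParseError(f"non-IUPAC nucleotide symbol(s): {sorted(bad)}")
    return s


@dataclass
class SequenceRecord:
    """A named DNA sequence, with bookkeeping for windows and strand.

    ``source_offset`` is the 0-based offset of this record (or window cut
    from a larger record) within its parent sequence, on the plus strand.
    """

    id: str
    residues: str
    description: str = ""
    source_offset: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        self.residues = clean_residues(self.residues)
        if self.source_offset < 0:
            raise ValueError("source_offset must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """Residues as a uint8 array of 4-bit base masks."""
        return encode(self.residues)


def encode(s: str) -> np.ndarray:
    """Encode a DNA string as uint8 4-bit base masks (A=1,C=2,G=4,T=8)."""
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[arr]
    if np.any(codes == 0):
        i = int(np.argmax(codes == 0))
        raise ParseError(f"non-IUPAC symbol {s[i]!r} at position {i}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(MASK_TO_CODE[int(m)] for m in codes)


def revcomp(s: str) -> str:
    """Reverse complement, with IUPAC degenerate codes mapped correctly."""
    s = clean_residues(s)
    return s.translate(_COMP_LUT)[::-1]


@dataclass
class MultipleAlignment:
    """An MSA: ordered rows of (id, aligned string); gaps normalized to '-'."""

    rows: list[tuple[str, str]]
    rf: str | None = field(default=None)  # optional per-column reference annotation

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0][1])
        norm = []
        seen: set[str] = set()
        for rid, aligned in self.rows:
            if len(aligned) != ncol:
                raise ParseError(
                    f"ragged alignment: row {rid!r} has length "
                    f"{len(aligned)}, expected {ncol}"
                )
            if rid in seen:
                raise ParseError(f"duplicate alignment row id {rid!r}")
            seen.add(rid)
            a = aligned.upper().replace(".", "-").replace("U", "T")
            bad = set(a) - IUPAC_ALPHABET - {"-"}
            if bad:
                raise ParseError(f"row {rid!r}: non-IUPAC symbol(s) {sorted(bad)}")
            norm.append((rid, a))
        self.rows = norm
        self.n_columns = ncol

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def column(self, j: int) -> list[str]:
        return [aligned[j] for _, aligned in self.rows]

    def degapped(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(id=rid, residues=aligned.replace("-", ""))
            for rid, aligned in self.rows
        ]

    def subset(self, ids: list[str], drop_empty_columns: bool = True) -> "MultipleAlignment":
        keep = set(ids)
        rows = [(rid, a) for rid, a in self.rows if rid in keep]
        if drop_empty_columns:
            cols = [
                j for j in range(self.n_columns)
                if any(a[j] != "-" for _, a in rows)
            ]
            rows = [(rid, "".join(a[j] for j in cols)) for rid, a in rows]
            rf = "".join(self.rf[j] for j in cols) if self.rf else None
        else:
            rf = self.rf
        return MultipleAlignment(rows, rf=rf)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file; order preserved, residues validated.

    Duplicate ids are allowed but logged as a warning.  An empty file
    yields an empty list.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    seen: set[str] = set()

    def flush(lineno: int) -> None:
        nonlocal header, chunks, desc
        if header is None:
            return
        try:
            residues = clean_residues("".join(chunks))
        except ParseError as e:
            raise ParseError(f"{path}: record {header!r} (ends line {lineno}): {e}")
        if header in seen:
            logger.warning("duplicate FASTA id %r in %s", header, path)
        seen.add(header)
        records.append(SequenceRecord(id=header, residues=residues, description=desc))
        header, chunks, desc = None, [], ""

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(lineno - 1)
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line.strip())
        flush(lineno if records or header else 0)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_msa(path: str | Path, format: str = "stockholm") -> MultipleAlignment:
    """Read an MSA from Stockholm or aligned-FASTA (``afa``).

    '.' and '-' are both accepted as gaps and normalized to '-'.  A
    Stockholm ``#=GC RF`` line, if present, is kept as ``rf``.
    """
    if format not in ("stockholm", "afa"):
        raise ValueError(f"unknown alignment format {format!r} (expected 'stockholm' or 'afa')")
    bio_fmt = "stockholm" if format == "stockholm" else "fasta"
    try:
        aln = AlignIO.read(str(path), bio_fmt)
    except ValueError as e:
        raise ParseError(f"{path}: cannot parse as {format}: {e}") from e
    rows = [(rec.id, str(rec.seq)) for rec in aln]
    rf = None
    ca = getattr(aln, "column_annotations", None)
    if ca and "reference_annotation" in ca:
        rf = ca["reference_annotation"]
    return MultipleAlignment(rows, rf=rf)


def write_stockholm(msa: MultipleAlignment, path: str | Path) -> None:
    """Write a one-block Stockholm file (with #=GC RF if present)."""
    name_w = max(len(rid) for rid, _ in msa.rows)
    name_w = max(name_w, len("#=GC RF"))
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for rid, aligned in msa.rows:
            fh.write(f"{rid:<{name_w}} {aligned}\n")
        if msa.rf is not None:
            fh.write(f"{'#=GC RF':<{name_w}} {msa.rf}\n")
        fh.write("//\n")
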