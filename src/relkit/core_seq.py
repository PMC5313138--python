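"""Sequence data model and standard-format I/O shared by all pipeline stages.

Conventions
-----------
* Internal coordinates are 0-based half-open; externally reported positions
  are 1-based inclusive.
* Protein residues are upper-case over the 20 standard amino acids plus ``X``
  (unknown) and ``*`` (stop, as emitted by :func:`translate`).
* Nucleotide bases are upper-case over ``ACGTN``.  Circular sequences support
  index arithmetic modulo their length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio.Seq import Seq
from Bio import SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NUC_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class ProteinSeq:
    """An amino-acid sequence with a unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        bad = set(self.residues.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"illegal residue(s) {sorted(bad)} in protein {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NucSeq:
    """A nucleotide sequence, optionally circular."""

    id: str
    bases: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("nucleotide id must be non-empty")
        if len(self.bases) < 1:
            raise ValueError(f"empty nucleotide sequence {self.id!r}")
        bad = set(self.bases.upper()) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"illegal base(s) {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> str:
        """0-based half-open slice; wraps modulo length when circular."""
        n = len(self.bases)
        if not self.circular:
            if start < 0 or end > n or start > end:
                raise IndexError(
                    f"slice [{start}, {end}) out of bounds for linear "
                    f"sequence {self.id!r} of length {n}"
                )
            return self.bases[start:end]
        if end - start > n:
            raise IndexError("window longer than circular sequence")
        length = end - start
        start %= n
        stop = start + length
        if stop <= n:
            return self.bases[start:stop]
        return self.bases[start:] + self.bases[: stop - n]


class SequenceSet:
    """Ordered collection of sequences with unique ids."""

    def __init__(self, records: Iterable = (), source: str = "") -> None:
        self.source = source
        self._records = []
        self._by_id = {}
        for rec in records:
            self.add(rec)

    def add(self, rec) -> None:
        if rec.id in self._by_id:
            raise ValueError(f"duplicate id {rec.id!r} in sequence set")
        self._by_id[rec.id] = rec
        self._records.append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator:
        return iter(self._records)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self._by_id[key]
        return self._records[key]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        return SequenceSet((self._by_id[i] for i in ids), source=self.source)


@dataclass
class Msa:
    """Aligned rows of equal length with ``-`` as the gap symbol."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows:
            w = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != w:
                    raise ValueError(f"row {rid!r} has length {len(row)} != {w}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def read_fasta(path, alphabet: Literal["protein", "nucleotide"],
               circular: bool = False) -> SequenceSet:
    """Read a multi-record FASTA file.

    Whitespace inside sequence lines is stripped; case is preserved on read
    (validation is case-insensitive).  Malformed headers, illegal characters
    and duplicate ids raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUC_ALPHABET
    records: list = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if header in seen:
            raise ParseError(
                f"{path}:{header_line}: duplicate id {header!r}")
        seen.add(header)
        if alphabet == "protein":
            records.append(ProteinSeq(header, seq))
        else:
            records.append(NucSeq(header, seq, circular=circular))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}:{line_no}: empty FASTA header")
                header = name
                header_line = line_no
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{line_no}: sequence data before first header")
                bad = set(line.upper()) - allowed
                if bad:
                    raise ParseError(
                        f"{path}:{line_no}: illegal character(s) "
                        f"{sorted(bad)} for alphabet {alphabet!r}")
                chunks.append(line.upper())
        flush(header_line)
    return SequenceSet(records, source=str(path))


def write_fasta(seqs, path, width: int = 60) -> None:
    """Write sequences as FASTA with 60-column wrapping."""
    with open(path, "w") as fh:
        for rec in seqs:
            body = rec.residues if isinstance(rec, ProteinSeq) else rec.bases
            fh.write(f">{rec.id}\n")
            for i in range(0, len(body), width):
                fh.write(body[i:i + width] + "\n")


def read_genbank(path) -> tuple[NucSeq, list[dict]]:
    """Read a single-record GenBank file (read-only plasmid input).

    Returns the sequence (circular if the record topology says so) and a
    list of CDS feature dicts with 0-based half-open coordinates.
    """
    record = SeqIO.read(str(path), "genbank")
    circular = record.annotations.get("topology", "linear") == "circular"
    nuc = NucSeq(record.id, str(record.seq).upper(), circular=circular)
    feats = []
    for f in record.features:
        if f.type != "CDS":
            continue
        feats.append({
            "locus_tag": f.qualifiers.get("locus_tag", [""])[0],
            "protein_id": f.qualifiers.get("protein_id", [""])[0],
            "start": int(f.location.start),
            "end": int(f.location.end),
            "strand": "+" if f.location.strand != -1 else "-",
        })
    return nuc, feats


def reverse_complement(seq: NucSeq) -> NucSeq:
    """Watson-Crick reverse complement; N maps to N; circular flag kept."""
    return replace(seq, bases=seq.bases.translate(_COMPLEMENT)[::-1])


def translate(seq: NucSeq, frame: int = 0, strand: str = "+",
              code: int = 11) -> ProteinSeq:
    """Translate one reading frame (bacterial table 11 by default).

    The trailing partial codon is dropped and stop codons render as ``*``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0..2, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    bases = seq.bases if strand == "+" else reverse_complement(seq).bases
    sub = bases[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    aa = str(Seq(sub).translate(table=code)) if sub else ""
    return ProteinSeq(f"{seq.id}|{strand}{frame}", aa.replace("J", "X"))


def six_frame_translations(seq: NucSeq, code: int = 11) -> list[ProteinSeq]:
    return [translate(seq, f, s, code) for s in "+-" for f in (0, 1, 2)]


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return first - 1, last
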