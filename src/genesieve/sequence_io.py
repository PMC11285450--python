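"""Sequence containers, FASTA/FASTQ I/O and six-frame translation machinery.

Protein queries and raw reads are the two inputs of the pipeline; everything
downstream (translated search, read recovery, reconstruction) goes through the
:class:`SequenceRecord` / :class:`ReadRecord` types and the frame/strand
conventions defined here.

Frame convention: frame ``f`` on strand ``+`` starts translation at 0-based
nucleotide offset ``f - 1``; on strand ``-`` the offset is counted from the 5'
end of the reverse complement (the transeq convention), so exactly six
distinct frames exist per read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "SequenceRecord",
    "ReadRecord",
    "FrameSpec",
    "SequenceFormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "reverse_complement",
    "translate",
    "six_frame_translations",
    "SIX_FRAMES",
]


class SequenceFormatError(ValueError):
    """Raised on malformed sequence files or illegal residues/bases."""


# Amino-acid alphabet: the 20 standard residues, ambiguity codes B/Z/J,
# unknown 'X', stop '*', and '-' (uncovered position in reconstructions).
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZJXU*-")
_DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (translation table 1); any codon containing a
# character outside {A,C,G,T} translates to 'X' so that peptide coordinates
# stay aligned with nucleotide coordinates.
_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: dict[str, str] = dict(_TABLE1.forward_table)
_CODON_MAP.update({codon: "*" for codon in _TABLE1.stop_codons})


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence (typically a query such as a CD1 family member)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence record with empty id")
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues.upper()) - _AA_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"record {self.id!r} contains non-amino-acid characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReadRecord:
    """A raw sequencing read; qualities are Phred-scaled integers if present."""

    id: str
    bases: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("read with empty id")
        if len(self.bases) < 1:
            raise SequenceFormatError(f"read {self.id!r} has an empty sequence")
        object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - _DNA_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"read {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        if self.qualities is not None:
            object.__setattr__(self, "qualities", tuple(self.qualities))
            if len(self.qualities) != len(self.bases):
                raise SequenceFormatError(
                    f"read {self.id!r}: {len(self.qualities)} quality values for "
                    f"{len(self.bases)} bases"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def mean_quality(self) -> float | None:
        if not self.qualities:
            return None
        return sum(self.qualities) / len(self.qualities)


@dataclass(frozen=True, order=True)
class FrameSpec:
    """One of the six reading frames: strand '+'/'-' and frame 1-3."""

    strand: str
    frame: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.frame not in (1, 2, 3):
            raise ValueError(f"frame must be 1, 2 or 3, got {self.frame!r}")


SIX_FRAMES: tuple[FrameSpec, ...] = tuple(
    FrameSpec(strand, frame) for strand in "+-" for frame in (1, 2, 3)
)


def _check_path(path: str | os.PathLike) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    return p


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a protein FASTA file into :class:`SequenceRecord` objects.

    Raises :class:`SequenceFormatError` on an empty file or a header with no
    sequence, naming the offending record.
    """
    p = _check_path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(p), "fasta"):
        seq = str(rec.seq).replace(" ", "")
        if not seq:
            raise SequenceFormatError(f"record {rec.id!r} in {p} has no sequence")
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=seq, description=desc))
    if not records:
        raise SequenceFormatError(f"no FASTA records found in {p}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as single-line-sequence FASTA (round-trips exactly)."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(f"{header}\n{rec.residues}\n")


def read_fastq(
    path: str | os.PathLike, min_mean_quality: float | None = None
) -> list[ReadRecord]:
    """Parse Phred+33 FASTQ into :class:`ReadRecord` objects.

    ``min_mean_quality`` optionally drops reads whose mean base quality falls
    below the cutoff (off by default: no filter is applied).
    """
    p = _check_path(path)
    reads: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(p), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            read = ReadRecord(id=rec.id, bases=str(rec.seq), qualities=quals)
            if min_mean_quality is not None:
                mq = read.mean_quality()
                if mq is not None and mq < min_mean_quality:
                    continue
            reads.append(read)
    except ValueError as exc:  # biopython names the offending read
        raise SequenceFormatError(f"malformed FASTQ in {p}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            quals = read.qualities or tuple([40] * len(read.bases))
            qual_str = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual_str}\n")


def read_reads(path: str | os.PathLike) -> list[ReadRecord]:
    """Read a reads file in FASTQ or FASTA format (sniffed from first byte)."""
    p = _check_path(path)
    with open(p) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(p)
    reads = []
    for rec in SeqIO.parse(str(p), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise SequenceFormatError(f"record {rec.id!r} in {p} has no sequence")
        reads.append(ReadRecord(id=rec.id, bases=seq))
    return reads


def reverse_complement(bases: str) -> str:
    """Reverse complement over {A,C,G,T,N}; errors name the first bad offset."""
    upper = bases.upper()
    for i, b in enumerate(upper):
        if b not in _DNA_ALPHABET:
            raise SequenceFormatError(f"illegal base {b!r} at offset {i}")
    return upper.translate(_COMPLEMENT)[::-1]


def translate(bases: str, frame_spec: FrameSpec) -> str:
    """Translate ``bases`` in the given frame under the standard genetic code.

    Stops render as ``*``; codons containing ``N`` render as ``X``; trailing
    1-2 bases are dropped. A sequence shorter than one codon in the frame
    yields the empty peptide.
    """
    seq = bases.upper()
    if frame_spec.strand == "-":
        seq = reverse_complement(seq)
    seq = seq[frame_spec.frame - 1 :]
    n_codons = len(seq) // 3
    return "".join(
        _CODON_MAP.get(seq[3 * i : 3 * i + 3], "X") for i in range(n_codons)
    )


def six_frame_translations(bases: str) -> list[tuple[FrameSpec, str]]:
    """All six (frame, peptide) translations of a read, in canonical order."""
    return [(fs, translate(bases, fs)) for fs in SIX_FRAMES]
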