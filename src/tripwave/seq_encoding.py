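"""Sequence ingestion and binary indicator (Voss) encoding.

A DNA string is mapped to four binary tracks, one per nucleotide: track X
carries a 1 wherever the sequence has base X and 0 elsewhere.  All spectral
analysis downstream operates on these tracks.  Ambiguity codes (N, R, Y, ...)
contribute 0 to every track, so the four columns sum to 1 at unambiguous
positions and 0 at ambiguous ones.

Coordinates are 0-based half-open internally; BED input is taken as-is and
GFF3 (1-based closed) is converted on ingestion.  User-facing reports convert
back to 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes accepted after validation (uppercase).
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")


class SequenceError(ValueError):
    """Raised for unusable sequence input (empty, non-IUPAC residues)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated nucleotide sequence.

    Residues are stored uppercase; ``U`` is accepted and treated as ``T``
    for encoding purposes.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise SequenceError(f"sequence {self.id!r} is empty")
        res = self.residues.upper()
        bad = set(res) - IUPAC_CODES
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-IUPAC residues: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class IndicatorSet:
    """The four binary indicator tracks of one sequence.

    ``tracks`` is a (4, L) uint8 array in A, C, G, T row order.
    """

    seq_id: str
    tracks: np.ndarray

    def __post_init__(self) -> None:
        self.tracks = np.asarray(self.tracks, dtype=np.uint8)
        if self.tracks.ndim != 2 or self.tracks.shape[0] != 4:
            raise ValueError("tracks must have shape (4, L)")

    @property
    def length(self) -> int:
        return self.tracks.shape[1]

    def track(self, base: str) -> np.ndarray:
        return self.tracks[_BASE_INDEX[base.upper()]]

    def __getitem__(self, key: slice) -> "IndicatorSet":
        return IndicatorSet(self.seq_id, self.tracks[:, key])


@dataclass(frozen=True)
class AnnotationInterval:
    """A genomic interval (0-based half-open) attached to a sequence."""

    seq_id: str
    start: int
    end: int
    kind: Literal["exon", "CDS", "junction"] = "exon"
    strand: Literal["+", "-", "unknown"] = "unknown"
    name: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} < start {self.start} ({self.name or self.seq_id})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def encode_indicators(seq: NucleotideSequence | str, seq_id: str = "seq") -> IndicatorSet:
    """Map a sequence to its four binary indicator tracks.

    ``AGTCA`` becomes u_A = 10001, u_C = 00010, u_G = 01000, u_T = 00100.
    ``U`` counts as ``T``; every other ambiguity code yields 0 in all four
    tracks.
    """
    if isinstance(seq, str):
        seq = NucleotideSequence(seq_id, seq)
    arr = np.frombuffer(seq.residues.replace("U", "T").encode("ascii"), dtype=np.uint8)
    tracks = np.zeros((4, len(seq)), dtype=np.uint8)
    for i, base in enumerate(BASES):
        tracks[i] = arr == ord(base)
    return IndicatorSet(seq.id, tracks)


def decode_indicators(ind: IndicatorSet) -> str:
    """Inverse of :func:`encode_indicators` for unambiguous sequences.

    Positions with an all-zero column (ambiguity codes) decode to ``N``.
    """
    out = np.full(ind.length, ord("N"), dtype=np.uint8)
    for i, base in enumerate(BASES):
        out[ind.tracks[i] == 1] = ord(base)
    return out.tobytes().decode("ascii")


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read FASTA into validated sequences, order preserved, ids from headers."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        log.warning("FASTA file %s contains no records", path)
    return [NucleotideSequence(r.id, str(r.seq)) for r in records]


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s), 70):
                fh.write(s.residues[i : i + 70] + "\n")


def read_annotations(
    path: str | Path, fmt: Literal["BED", "GFF3"] | None = None
) -> list[AnnotationInterval]:
    """Read BED (0-based half-open) or GFF3 (1-based closed) intervals.

    Both are normalised to the internal 0-based half-open convention
    (pyranges performs the GFF3 shift).  ``fmt`` defaults to the file
    extension.
    """
    import pyranges

    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            fmt = "BED"
        elif suffix in (".gff", ".gff3"):
            fmt = "GFF3"
        else:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    if fmt == "BED":
        df = pyranges.read_bed(str(path)).df
    elif fmt == "GFF3":
        df = pyranges.read_gff3(str(path)).df
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    intervals: list[AnnotationInterval] = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "Strand", ".")
        kind_raw = str(getattr(row, "Feature", "exon")).lower()
        kind = "CDS" if kind_raw == "cds" else ("junction" if kind_raw == "junction" else "exon")
        start, end = int(row.Start), int(row.End)
        if start < 0:
            raise ValueError(f"negative coordinate in {path.name}: {start}")
        intervals.append(
            AnnotationInterval(
                seq_id=str(row.Chromosome),
                start=start,
                end=end,
                kind=kind,  # type: ignore[arg-type]
                strand=strand if strand in ("+", "-") else "unknown",
                name=str(getattr(row, "Name", "") or getattr(row, "ID", "") or ""),
            )
        )
    return intervals


def write_indicator_tsv(ind: IndicatorSet, path: str | Path) -> None:
    """Dump the four tracks as a 4-column TSV (debugging aid)."""
    import pandas as pd

    pd.DataFrame(
        {base: ind.tracks[i] for i, base in enumerate(BASES)}
    ).to_csv(path, sep="\t", index=False)
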