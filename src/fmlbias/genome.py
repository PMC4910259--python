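"""Reference-sequence access.

Two interchangeable accessors: an in-memory genome (synthetic fixtures,
tests) and a pyfaidx-backed FASTA genome.  All coordinates handed to an
accessor are 0-based half-open; query chromosome names are normalized
against the genome's own naming by stripping or adding a ``chr`` prefix.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping

from pyfaidx import Fasta


class UnknownChromosomeError(KeyError):
    """Raised when a chromosome cannot be resolved against the reference."""


def _normalize(name: str, known: Iterable[str]) -> str:
    known = set(known)
    if name in known:
        return name
    if name.startswith("chr") and name[3:] in known:
        return name[3:]
    if "chr" + name in known:
        return "chr" + name
    raise UnknownChromosomeError(
        f"chromosome {name!r} not present in reference (known: {sorted(known)})"
    )


class ReferenceGenome:
    """In-memory reference sequence keyed by chromosome name."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {c: s.upper() for c, s in sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def resolve_chrom(self, name: str) -> str:
        return _normalize(name, self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[self.resolve_chrom(chrom)])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence for the 0-based half-open interval [start, end)."""
        chrom = self.resolve_chrom(chrom)
        if start < 0 or end > len(self._seqs[chrom]):
            raise IndexError(
                f"[{start}, {end}) outside {chrom} (length {len(self._seqs[chrom])})"
            )
        return self._seqs[chrom][start:end]

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.fetch(chrom, pos - 1, pos)

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


class FastaGenome(ReferenceGenome):
    """FASTA-backed accessor (indexed on first open via pyfaidx)."""

    def __init__(self, path: str):
        self._fasta = Fasta(path, sequence_always_upper=True)
        self._lengths = {name: len(rec) for name, rec in self._fasta.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def resolve_chrom(self, name: str) -> str:
        return _normalize(name, self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[self.resolve_chrom(chrom)]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        chrom = self.resolve_chrom(chrom)
        if start < 0 or end > self._lengths[chrom]:
            raise IndexError(
                f"[{start}, {end}) outside {chrom} (length {self._lengths[chrom]})"
            )
        return self._fasta[chrom][start:end].seq

    def to_fasta(self, path: str, width: int = 70) -> None:  # pragma: no cover
        raise NotImplementedError("already backed by a FASTA file")
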