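"""Shared domain types, coordinate conventions, and mutation QC.

Conventions used throughout the package:

* internal coordinates are 0-based half-open (``GenomicInterval``);
* all files read or written use 1-based positions (VCF/TSV convention);
* ``ref``/``alt`` alleles are always expressed on the + strand of the
  reference, regardless of the strand of the element they fall in.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

from .genome import ReferenceGenome, UnknownChromosomeError

log = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

ELEMENT_TYPES = ("cds", "utr5", "utr3", "splice", "promoter", "lncrna")


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval; sorts by (chrom, start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end {self.end} must exceed start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomicElement:
    """A named, typed set of disjoint genomic segments tested as one unit.

    Segments are sorted and pairwise disjoint (overlapping same-type
    annotations are merged upstream), all on one chromosome and strand.
    """

    element_id: str
    symbol: str
    element_type: str
    segments: tuple[GenomicInterval, ...]
    strand: str = "."

    def __post_init__(self):
        if not self.segments:
            raise ValueError(f"{self.element_id}: element with no segments")
        segs = tuple(sorted(self.segments))
        object.__setattr__(self, "segments", segs)
        chroms = {s.chrom for s in segs}
        if len(chroms) != 1:
            raise ValueError(f"{self.element_id}: segments on multiple chromosomes")
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.element_id}: overlapping segments {a} / {b}")
        if self.length <= 0:  # unreachable given interval invariants, kept as guard
            raise ValueError(f"{self.element_id}: zero-length element")

    @property
    def chrom(self) -> str:
        return self.segments[0].chrom

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.segments)

    def covers(self, pos1: int) -> bool:
        """Whether the 1-based position falls inside any segment."""
        p0 = pos1 - 1
        return any(s.contains(p0) for s in self.segments)

    def positions(self) -> Iterator[int]:
        """All 1-based positions, in segment order."""
        for s in self.segments:
            yield from range(s.start + 1, s.end + 1)


@dataclass(frozen=True)
class Mutation:
    """A single-nucleotide somatic variant (+ strand alleles)."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not an SNV: {self.ref}>{self.alt}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} is not 1-based")


@dataclass
class MutationSet:
    mutations: list[Mutation]
    samples: set[str]
    provenance: str = ""

    def __post_init__(self):
        missing = {m.sample_id for m in self.mutations} - self.samples
        if missing:
            raise ValueError(f"mutations from samples not in set: {sorted(missing)}")

    @classmethod
    def from_mutations(cls, mutations: Iterable[Mutation], provenance: str = "",
                       samples: Optional[Iterable[str]] = None) -> "MutationSet":
        muts = list(mutations)
        sample_set = set(samples) if samples is not None else set()
        sample_set |= {m.sample_id for m in muts}
        return cls(muts, sample_set, provenance)

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[Mutation]:
        return iter(self.mutations)


@dataclass
class QCReport:
    """Counts of records dropped while validating a raw mutation table."""

    n_input: int = 0
    n_retained: int = 0
    non_snv: int = 0
    ref_mismatch: int = 0
    malformed: int = 0

    @property
    def n_dropped(self) -> int:
        return self.non_snv + self.ref_mismatch + self.malformed


@dataclass(frozen=True)
class FMBiasResult:
    """Per-element outcome of the FM-bias test."""

    element_id: str
    n_mutations: int
    n_samples: int
    observed_mean: float
    p_value: float
    q_value: Optional[float]
    n_iterations: int
    symbol: str = ""
    element_type: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.q_value is not None and self.q_value < self.p_value - 1e-12:
            raise ValueError(
                f"{self.element_id}: q {self.q_value} below p {self.p_value}"
            )

    def with_q(self, q: Optional[float]) -> "FMBiasResult":
        return replace(self, q_value=q)


class RawVariant(NamedTuple):
    """An unvalidated record as read from a mutation file (strings)."""

    chrom: str
    pos: str
    ref: str
    alt: str
    sample: str


def validate_mutations(
    raw_records: Iterable[RawVariant | Sequence[str]],
    genome: ReferenceGenome,
    provenance: str = "",
) -> tuple[MutationSet, QCReport]:
    """Filter raw records down to reference-matching SNVs.

    Indels/MNVs and records whose reported reference allele disagrees with
    the reference sequence are dropped and tallied in the QC report; a
    chromosome missing from the reference is a hard error.  Idempotent:
    revalidating an already-clean set changes nothing.
    """
    qc = QCReport()
    kept: list[Mutation] = []
    samples: set[str] = set()
    for rec in raw_records:
        qc.n_input += 1
        if isinstance(rec, Mutation):
            chrom_s, pos_s, ref, alt, sample = (
                rec.chrom, str(rec.pos), rec.ref, rec.alt, rec.sample_id,
            )
        else:
            chrom_s, pos_s, ref, alt, sample = (str(x) for x in rec)
        chrom = genome.resolve_chrom(chrom_s)  # UnknownChromosomeError propagates
        samples.add(sample)
        try:
            pos = int(pos_s)
            if pos < 1:
                raise ValueError
        except ValueError:
            qc.malformed += 1
            log.debug("malformed position %r at %s", pos_s, chrom)
            continue
        ref, alt = ref.upper(), alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
            qc.non_snv += 1
            continue
        if pos > genome.length(chrom) or genome.base(chrom, pos) != ref:
            qc.ref_mismatch += 1
            continue
        kept.append(Mutation(sample, chrom, pos, ref, alt))
    qc.n_retained = len(kept)
    if qc.n_dropped:
        log.info(
            "mutation QC: %d/%d retained (%d non-SNV, %d ref-mismatch, %d malformed)",
            qc.n_retained, qc.n_input, qc.non_snv, qc.ref_mismatch, qc.malformed,
        )
    return MutationSet(kept, samples, provenance), qc


# ---------------------------------------------------------------------------
# Mutation file I/O

_MUTATION_COLUMNS = ["CHROMOSOME", "POSITION", "REF", "ALT", "SAMPLE"]


def read_mutations_tsv(path: str) -> list[RawVariant]:
    """Read the tab-separated mutation dialect (header required)."""
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty mutation file")
        cols = {c.upper(): c for c in reader.fieldnames}
        missing = [c for c in _MUTATION_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for row in reader:
            records.append(
                RawVariant(
                    row[cols["CHROMOSOME"]], row[cols["POSITION"]],
                    row[cols["REF"]], row[cols["ALT"]], row[cols["SAMPLE"]],
                )
            )
    return records


def write_mutations_tsv(mutations: MutationSet, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MUTATION_COLUMNS)
        for m in mutations:
            writer.writerow([m.chrom, m.pos, m.ref, m.alt, m.sample_id])


def read_mutations_vcf(path: str, sample: Optional[str] = None) -> list[RawVariant]:
    """Minimal VCF reader: CHROM/POS/REF/first ALT.

    Sample attribution: genotype columns when present (every carrier of a
    non-reference genotype contributes one record), otherwise the ``sample``
    label (default: the file stem).
    """
    import pysam

    if sample is None:
        sample = path.rsplit("/", 1)[-1].split(".")[0]
    records: list[RawVariant] = []
    with pysam.VariantFile(path) as vcf:
        genotyped = list(vcf.header.samples)
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            if genotyped:
                for s in genotyped:
                    gt = rec.samples[s].get("GT")
                    if gt and any(a not in (None, 0) for a in gt):
                        records.append(RawVariant(rec.chrom, str(rec.pos), rec.ref, alt, s))
            else:
                records.append(RawVariant(rec.chrom, str(rec.pos), rec.ref, alt, sample))
    return records
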