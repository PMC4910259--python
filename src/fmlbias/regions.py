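"""Element catalog construction from a Gencode-style GTF.

Builds the six element classes under test — CDS, 5'/3' UTR, intronic splice
flanks, promoters, and lincRNA exons — applying the masking rules that keep
the classes non-redundant:

* same-gene, same-type annotations are merged;
* UTRs lose any base annotated anywhere as CDS and any base inside a short
  (10 bp) intronic splice site; 5' UTRs additionally lose 3' UTR overlaps;
* promoters (2500 bp upstream of the TSS of protein-coding genes) lose any
  base annotated anywhere as CDS, UTR, or short splice site;
* lincRNA exons lose the same CDS/UTR/short-splice bases;
* splice elements under test are the 50 bp at each end of protein-coding
  introns (clipped and merged for micro-introns).

"annotated anywhere" is global: any gene's CDS masks any gene's promoter.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils
from intervaltree import IntervalTree

from .core import ELEMENT_TYPES, GenomicElement, GenomicInterval
from .genome import ReferenceGenome

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Interval arithmetic (0-based half-open throughout)

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted disjoint cover; touching intervals (end == start) merge."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) != 1:
        raise ValueError(f"merge across chromosomes: {sorted(chroms)}")
    strands = {iv.strand for iv in ivs}
    strand = strands.pop() if len(strands) == 1 else "."
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, strand)
        else:
            merged.append(iv)
    return [GenomicInterval(iv.chrom, iv.start, iv.end, strand) for iv in merged]


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference a \\ b as disjoint intervals (both inputs disjoint/sorted)."""
    a = sorted(a)
    b = sorted(b)
    out: list[GenomicInterval] = []
    j = 0
    for iv in a:
        cur = iv.start
        while j < len(b) and (b[j].chrom < iv.chrom or
                              (b[j].chrom == iv.chrom and b[j].end <= cur)):
            j += 1
        k = j
        while k < len(b) and b[k].chrom == iv.chrom and b[k].start < iv.end:
            if b[k].start > cur:
                out.append(GenomicInterval(iv.chrom, cur, b[k].start, iv.strand))
            cur = max(cur, b[k].end)
            if cur >= iv.end:
                break
            k += 1
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, cur, iv.end, iv.strand))
    return out


def build_splice_regions(
    introns: Iterable[GenomicInterval], flank: int
) -> list[GenomicInterval]:
    """The first and last ``flank`` bp of each intron, merged.

    Introns shorter than 2x flank yield the whole intron once (no double
    counting).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    pieces: list[GenomicInterval] = []
    for iv in introns:
        if len(iv) <= 2 * flank:
            pieces.append(iv)
        else:
            pieces.append(GenomicInterval(iv.chrom, iv.start, iv.start + flank, iv.strand))
            pieces.append(GenomicInterval(iv.chrom, iv.end - flank, iv.end, iv.strand))
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in pieces:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        out.extend(merge_intervals(by_chrom[chrom]))
    return out


def build_promoters(
    tss_list: Iterable[tuple[str, int, str]],
    upstream: int,
    genome: ReferenceGenome,
) -> list[GenomicInterval]:
    """Windows of ``upstream`` bp upstream of each TSS (1-based), strand-aware.

    For a + strand TSS at 1-based t the window is 0-based [t-1-upstream, t-1);
    for - strand it is [t, t+upstream).  Windows are clipped at chromosome
    bounds; a TSS outside the chromosome is an error.
    """
    if upstream <= 0:
        raise ValueError("upstream must be positive")
    out = []
    for chrom, tss, strand in tss_list:
        chrom = genome.resolve_chrom(chrom)
        clen = genome.length(chrom)
        if not (1 <= tss <= clen):
            raise ValueError(f"TSS {chrom}:{tss} outside chromosome (length {clen})")
        if strand == "+":
            start, end = max(0, tss - 1 - upstream), tss - 1
        elif strand == "-":
            start, end = tss, min(clen, tss + upstream)
        else:
            raise ValueError(f"promoter requires a stranded TSS, got {strand!r}")
        if end > start:
            out.append(GenomicInterval(chrom, start, end, strand))
        else:
            log.warning("promoter window empty for TSS %s:%d (%s)", chrom, tss, strand)
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


# ---------------------------------------------------------------------------
# Catalog

@dataclass
class ElementCatalog:
    """Elements under test plus a position -> element-id interval index."""

    elements: dict[str, GenomicElement] = field(default_factory=dict)
    _index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def add(self, element: GenomicElement) -> None:
        if element.element_id in self.elements:
            raise ValueError(f"duplicate element id {element.element_id}")
        self.elements[element.element_id] = element
        tree = self._index.setdefault(element.chrom, IntervalTree())
        for seg in element.segments:
            tree.addi(seg.start, seg.end, element.element_id)

    def lookup(self, chrom: str, pos1: int) -> set[str]:
        """Element ids whose segments cover the 1-based position."""
        tree = self._index.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.at(pos1 - 1)}

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[GenomicElement]:
        return iter(self.elements.values())

    def __contains__(self, element_id: str) -> bool:
        return element_id in self.elements

    def __getitem__(self, element_id: str) -> GenomicElement:
        return self.elements[element_id]

    # -- BED-like TSV: one row per segment -------------------------------

    _COLUMNS = ["CHROM", "START", "END", "STRAND", "ELEMENT_ID", "ELEMENT_TYPE", "SYMBOL"]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self._COLUMNS) + "\n")
            for el in sorted(self.elements.values(), key=lambda e: e.element_id):
                for seg in el.segments:
                    fh.write(
                        f"{seg.chrom}\t{seg.start}\t{seg.end}\t{el.strand}\t"
                        f"{el.element_id}\t{el.element_type}\t{el.symbol}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str) -> "ElementCatalog":
        rows: dict[str, dict] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != cls._COLUMNS:
                raise ValueError(f"{path}: unexpected catalog header {header}")
            for line in fh:
                chrom, start, end, strand, eid, etype, symbol = line.rstrip("\n").split("\t")
                entry = rows.setdefault(
                    eid, {"strand": strand, "etype": etype, "symbol": symbol, "segs": []}
                )
                entry["segs"].append(GenomicInterval(chrom, int(start), int(end), strand))
        catalog = cls()
        for eid, entry in rows.items():
            catalog.add(
                GenomicElement(
                    eid, entry["symbol"], entry["etype"],
                    tuple(entry["segs"]), entry["strand"],
                )
            )
        return catalog


# ---------------------------------------------------------------------------
# GTF parsing

@dataclass
class RegionConfig:
    splice_flank: int = 50      # splice elements under test
    short_splice: int = 10      # intron-edge mask subtracted from UTR/promoter/lncRNA
    promoter_upstream: int = 2500
    element_types: tuple[str, ...] = ELEMENT_TYPES
    blacklist: frozenset[str] = frozenset()   # element ids, gene ids, or symbols
    protein_coding_biotypes: frozenset[str] = frozenset({"protein_coding"})
    lncrna_biotypes: frozenset[str] = frozenset({"lincRNA"})


@dataclass
class _Gene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    cds: list[GenomicInterval] = field(default_factory=list)
    utr: list[GenomicInterval] = field(default_factory=list)   # unclassified UTR features
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    exons_by_tx: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    cds_by_tx: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    tx_spans: list[GenomicInterval] = field(default_factory=list)


def _iter_gtf_lines(source) -> Iterator[str]:
    if isinstance(source, str):
        opener = gzip.open if source.endswith(".gz") else open
        with opener(source, "rt") as fh:
            yield from fh
    else:
        yield from source


def _attr(feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def parse_gtf(source, config: RegionConfig) -> tuple[dict[str, _Gene], dict[str, _Gene]]:
    """Collect per-gene structure for protein-coding and lincRNA genes.

    A feature counts only when both the gene and transcript biotypes carry
    the required annotation (Gencode ``gene_type``/``transcript_type``).
    """
    coding: dict[str, _Gene] = {}
    linc: dict[str, _Gene] = {}
    for line in _iter_gtf_lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        feat = gffutils.feature.feature_from_line(line, dialect=None)
        gene_type = _attr(feat, "gene_type") or _attr(feat, "gene_biotype")
        tx_type = _attr(feat, "transcript_type") or _attr(feat, "transcript_biotype")
        gene_id = _attr(feat, "gene_id")
        if gene_id is None:
            continue
        symbol = _attr(feat, "gene_name") or gene_id
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)

        if gene_type in config.protein_coding_biotypes:
            if feat.featuretype != "gene" and tx_type not in config.protein_coding_biotypes:
                continue
            gene = coding.setdefault(gene_id, _Gene(gene_id, symbol, feat.seqid, feat.strand))
            tx_id = _attr(feat, "transcript_id")
            if feat.featuretype == "CDS":
                gene.cds.append(iv)
                if tx_id:
                    gene.cds_by_tx.setdefault(tx_id, []).append(iv)
            elif feat.featuretype == "exon" and tx_id:
                gene.exons_by_tx.setdefault(tx_id, []).append(iv)
            elif feat.featuretype == "UTR":
                gene.utr.append(iv)
            elif feat.featuretype in ("five_prime_utr", "five_prime_UTR"):
                gene.utr5.append(iv)
            elif feat.featuretype in ("three_prime_utr", "three_prime_UTR"):
                gene.utr3.append(iv)
            elif feat.featuretype == "transcript":
                gene.tx_spans.append(iv)
        elif gene_type in config.lncrna_biotypes:
            if feat.featuretype != "gene" and tx_type not in config.lncrna_biotypes:
                continue
            gene = linc.setdefault(gene_id, _Gene(gene_id, symbol, feat.seqid, feat.strand))
            tx_id = _attr(feat, "transcript_id")
            if feat.featuretype == "exon" and tx_id:
                gene.exons_by_tx.setdefault(tx_id, []).append(iv)
    return coding, linc


def _classify_utrs(gene: _Gene) -> None:
    """Split plain Gencode ``UTR`` features into 5'/3' by CDS position."""
    if not gene.utr:
        return
    all_cds = merge_intervals(gene.cds) if gene.cds else []
    if not all_cds:
        log.warning("%s: UTR features but no CDS; skipped", gene.gene_id)
        gene.utr.clear()
        return
    cds_start, cds_end = all_cds[0].start, all_cds[-1].end
    for iv in gene.utr:
        left = iv.start < cds_start
        right = iv.end > cds_end
        if left and not right:
            (gene.utr5 if gene.strand == "+" else gene.utr3).append(iv)
        elif right and not left:
            (gene.utr3 if gene.strand == "+" else gene.utr5).append(iv)
        else:
            # fully inside the CDS span or spanning it: side is ambiguous
            log.warning("%s: UTR %s ambiguous against CDS span; skipped",
                        gene.gene_id, iv)
    gene.utr.clear()


def _gene_introns(gene: _Gene) -> list[GenomicInterval]:
    introns = []
    for exons in gene.exons_by_tx.values():
        exons = sorted(exons)
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                introns.append(GenomicInterval(a.chrom, a.end, b.start, gene.strand))
    return introns


def build_catalog(
    annotation,
    genome: ReferenceGenome,
    config: Optional[RegionConfig] = None,
) -> ElementCatalog:
    """Build the element catalog from a GTF path or iterable of GTF lines."""
    config = config or RegionConfig()
    coding, linc = parse_gtf(annotation, config)
    for gene in coding.values():
        _classify_utrs(gene)

    # global masks ("previously annotated" is genome-wide)
    def _merged_by_chrom(ivs: list[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
        by: dict[str, list[GenomicInterval]] = {}
        for iv in ivs:
            by.setdefault(iv.chrom, []).append(iv)
        return {c: merge_intervals(v) for c, v in by.items()}

    all_cds = _merged_by_chrom([iv for g in coding.values() for iv in g.cds])
    all_utr = _merged_by_chrom(
        [iv for g in coding.values() for iv in g.utr5 + g.utr3]
    )
    all_utr3 = _merged_by_chrom([iv for g in coding.values() for iv in g.utr3])
    all_introns = [iv for g in coding.values() for iv in _gene_introns(g)]
    short_splice = _merged_by_chrom(
        build_splice_regions(all_introns, config.short_splice) if all_introns else []
    )

    def _mask(ivs: list[GenomicInterval], *masks) -> list[GenomicInterval]:
        out = merge_intervals(ivs)
        chrom = out[0].chrom if out else None
        for mask in masks:
            if not out:
                break
            out = subtract_intervals(out, mask.get(chrom, []))
        return out

    catalog = ElementCatalog()

    def _emit(gene: _Gene, etype: str, segments: list[GenomicInterval]) -> None:
        eid = f"{gene.gene_id}:{etype}"
        if {eid, gene.gene_id, gene.symbol} & config.blacklist:
            log.info("%s: blacklisted", eid)
            return
        if not segments:
            log.info("%s: no bases survive masking; omitted", eid)
            return
        catalog.add(
            GenomicElement(eid, gene.symbol, etype, tuple(segments), gene.strand)
        )

    for gene in sorted(coding.values(), key=lambda g: g.gene_id):
        if "cds" in config.element_types and gene.cds:
            _emit(gene, "cds", merge_intervals(gene.cds))
        if "splice" in config.element_types:
            introns = _gene_introns(gene)
            if introns:
                _emit(gene, "splice", build_splice_regions(introns, config.splice_flank))
        if "utr5" in config.element_types and gene.utr5:
            _emit(gene, "utr5", _mask(gene.utr5, all_cds, short_splice, all_utr3))
        if "utr3" in config.element_types and gene.utr3:
            _emit(gene, "utr3", _mask(gene.utr3, all_cds, short_splice))
        if "promoter" in config.element_types and gene.tx_spans:
            # TSS = most 5' transcript start among protein-coding transcripts
            if gene.strand == "+":
                tss = min(iv.start for iv in gene.tx_spans) + 1
            else:
                tss = max(iv.end for iv in gene.tx_spans)
            windows = build_promoters(
                [(gene.chrom, tss, gene.strand)], config.promoter_upstream, genome
            )
            _emit(gene, "promoter", _mask(windows, all_cds, all_utr, short_splice))

    if "lncrna" in config.element_types:
        for gene in sorted(linc.values(), key=lambda g: g.gene_id):
            exons = [iv for exs in gene.exons_by_tx.values() for iv in exs]
            if exons:
                _emit(gene, "lncrna", _mask(exons, all_cds, all_utr, short_splice))

    return catalog
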