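"""Functional-impact score lookup and per-element substitution enumeration.

A score store answers "what is the impact score of chrom:pos ref>alt?" for
every possible single-nucleotide substitution in the tested elements.  Two
backends: a plain sorted TSV loaded into memory (toy/panel scale) and a
bgzip+tabix-indexed TSV accessed through pysam (genome scale, CADD-style).

``element_scores`` enumerates the complete substitution space of one
element — every (position, alt) with its score, trinucleotide channel, and
signature-weighted sampling probability — which is both the background
sampling pool and the normalizer of the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .core import BASES, GenomicElement
from .genome import ReferenceGenome
from .signature import CHANNEL_INDEX, ContextError, SignatureMatrix, canonical_channel

log = logging.getLogger(__name__)


class RefAltError(ValueError):
    """Queried alt equals the reference base — not a substitution."""


class SignatureMismatchError(RuntimeError):
    """Every possible substitution in the element has zero signature probability."""


class ScoreStore:
    """Interface: ``get`` returns the score or None (unscored), never a silent 0."""

    provider: str = "unknown"

    def get(self, chrom: str, pos: int, alt: str) -> Optional[float]:
        raise NotImplementedError

    def ref_at(self, chrom: str, pos: int) -> Optional[str]:
        """Reference allele recorded at a position, if known to the store."""
        return None


def get_score(store: ScoreStore, chrom: str, pos: int, alt: str) -> Optional[float]:
    """Score for a substitution; None signals an unscored position.

    Raises :class:`RefAltError` when the store knows the reference allele at
    ``pos`` and ``alt`` equals it (the query is not a substitution).
    """
    ref = store.ref_at(chrom, pos)
    if ref is not None and ref == alt.upper():
        raise RefAltError(f"{chrom}:{pos} alt {alt} equals the reference allele")
    return store.get(chrom, pos, alt)


class InMemoryScoreStore(ScoreStore):
    """Whole score table held in memory; suits element catalogs < ~10 Mb."""

    def __init__(self, provider: str = "synthetic"):
        self.provider = provider
        self._scores: dict[tuple[str, int, str], float] = {}
        self._refs: dict[tuple[str, int], str] = {}

    def add(self, chrom: str, pos: int, ref: str, alt: str, score: float) -> None:
        if not np.isfinite(score):
            raise ValueError(f"non-finite score at {chrom}:{pos} {ref}>{alt}")
        self._scores[(chrom, pos, alt)] = float(score)
        self._refs[(chrom, pos)] = ref

    def get(self, chrom: str, pos: int, alt: str) -> Optional[float]:
        return self._scores.get((chrom, pos, alt))

    def ref_at(self, chrom: str, pos: int) -> Optional[str]:
        return self._refs.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._scores)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, str, str, float]],
        provider: str = "synthetic",
    ) -> "InMemoryScoreStore":
        store = cls(provider)
        for chrom, pos, ref, alt, score in records:
            store.add(chrom, int(pos), ref, alt, float(score))
        return store

    @classmethod
    def from_tsv(
        cls, path: str, score_column: int = -1, provider: str = "cadd-like"
    ) -> "InMemoryScoreStore":
        """Load a CADD-style TSV: CHROM POS REF ALT [RAW] SCORE.

        ``score_column`` selects which trailing column holds the score
        (default: the last, i.e. the scaled score in CADD tables).
        """
        store = cls(provider)
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if fields[0].upper() in ("CHROM", "CHROMOSOME"):
                    continue
                chrom, pos, ref, alt = fields[:4]
                store.add(chrom, int(pos), ref.upper(), alt.upper(),
                          float(fields[score_column]))
        return store

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("CHROM\tPOS\tREF\tALT\tSCORE\n")
            for (chrom, pos, alt), score in sorted(self._scores.items()):
                fh.write(f"{chrom}\t{pos}\t{self._refs[(chrom, pos)]}\t{alt}\t{score:.6g}\n")


class TabixScoreStore(ScoreStore):
    """Random access into a bgzip-compressed, tabix-indexed score TSV.

    Expects 1-based positions in column 2 and CHROM/POS/REF/ALT leading
    columns; ``score_column`` selects the score field (default last).
    """

    def __init__(self, path: str, score_column: int = -1, provider: str = "cadd-like"):
        import pysam

        self.provider = provider
        self._tbx = pysam.TabixFile(path)
        self._score_column = score_column
        self._contigs = set(self._tbx.contigs)

    def _rows(self, chrom: str, pos: int):
        if chrom not in self._contigs:
            chrom = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
            if chrom not in self._contigs:
                return
        try:
            yield from self._tbx.fetch(chrom, pos - 1, pos)
        except ValueError:
            return

    def get(self, chrom: str, pos: int, alt: str) -> Optional[float]:
        for row in self._rows(chrom, pos):
            fields = row.split("\t")
            if int(fields[1]) == pos and fields[3].upper() == alt.upper():
                return float(fields[self._score_column])
        return None

    def ref_at(self, chrom: str, pos: int) -> Optional[str]:
        for row in self._rows(chrom, pos):
            fields = row.split("\t")
            if int(fields[1]) == pos:
                return fields[2].upper()
        return None


@dataclass
class ElementScoreVector:
    """All possible substitutions of one element, scored and weighted.

    Arrays are parallel; ``prob`` is the per-(position, alt) sampling
    probability, proportional to the signature probability of the entry's
    channel and normalized over the element.  Entries at unscored positions
    are absent (``n_unscored_positions`` tallies them).
    """

    element_id: str
    pos: np.ndarray          # 1-based positions, int64
    alt: np.ndarray          # alt alleles, '<U1'
    score: np.ndarray        # float64
    channel: np.ndarray      # channel index 0..95, or -1 when context unavailable
    prob: np.ndarray         # normalized sampling probabilities
    n_unscored_positions: int = 0

    def __len__(self) -> int:
        return len(self.pos)


class ElementScorer:
    """Caches the signature-independent per-element enumeration.

    The (position, alt, score, channel) arrays depend only on store and
    genome and are computed once per element; re-weighting under a
    different signature is a cheap array lookup.
    """

    def __init__(self, store: ScoreStore, genome: ReferenceGenome):
        self.store = store
        self.genome = genome
        self._cache: dict[str, tuple] = {}

    def _enumerate(self, element: GenomicElement):
        if element.element_id in self._cache:
            return self._cache[element.element_id]
        chrom = self.genome.resolve_chrom(element.chrom)
        clen = self.genome.length(chrom)
        pos_l, alt_l, score_l, chan_l = [], [], [], []
        n_unscored = 0
        for seg in element.segments:
            # fetch with 1 bp flanks for contexts, clipped at chromosome ends
            lo = max(0, seg.start - 1)
            hi = min(clen, seg.end + 1)
            seq = self.genome.fetch(chrom, lo, hi).upper()
            for pos0 in range(seg.start, seg.end):
                ref = seq[pos0 - lo]
                if ref not in BASES:
                    n_unscored += 1
                    continue
                ctx = seq[pos0 - lo - 1 : pos0 - lo + 2] if (pos0 > 0 and pos0 < clen - 1) else None
                scored_any = False
                for alt in BASES:
                    if alt == ref:
                        continue
                    s = self.store.get(chrom, pos0 + 1, alt)
                    if s is None:
                        continue
                    scored_any = True
                    if ctx is not None and len(ctx) == 3:
                        try:
                            chan = CHANNEL_INDEX[canonical_channel(ctx, alt)]
                        except ContextError:
                            chan = -1
                    else:
                        chan = -1
                    pos_l.append(pos0 + 1)
                    alt_l.append(alt)
                    score_l.append(s)
                    chan_l.append(chan)
                if not scored_any:
                    n_unscored += 1
        arrays = (
            np.asarray(pos_l, dtype=np.int64),
            np.asarray(alt_l, dtype="<U1"),
            np.asarray(score_l, dtype=np.float64),
            np.asarray(chan_l, dtype=np.int64),
            n_unscored,
        )
        self._cache[element.element_id] = arrays
        if n_unscored:
            log.info(
                "%s: %d position(s) without scores (incompletely scored element)",
                element.element_id, n_unscored,
            )
        return arrays

    def vector(
        self, element: GenomicElement, signature: SignatureMatrix
    ) -> ElementScoreVector:
        pos, alt, score, chan, n_unscored = self._enumerate(element)
        if len(pos) == 0:
            raise SignatureMismatchError(
                f"{element.element_id}: no scorable substitutions"
            )
        weights = np.where(chan >= 0, signature.probabilities[np.clip(chan, 0, None)], 0.0)
        total = weights.sum()
        if total <= 0:
            raise SignatureMismatchError(
                f"{element.element_id}: every possible substitution has zero "
                "signature probability; signature and data do not match"
            )
        return ElementScoreVector(
            element.element_id, pos, alt, score, chan, weights / total, n_unscored
        )

    def raw_weights(
        self, element: GenomicElement, signature: SignatureMatrix
    ) -> tuple[ElementScoreVector, np.ndarray]:
        """Vector plus unnormalized signature weights (for cross-element pooling)."""
        vec = self.vector(element, signature)
        weights = np.where(
            vec.channel >= 0,
            signature.probabilities[np.clip(vec.channel, 0, None)],
            0.0,
        )
        return vec, weights


def element_scores(
    store: ScoreStore,
    element: GenomicElement,
    signature: SignatureMatrix,
    genome: ReferenceGenome,
) -> ElementScoreVector:
    """One-shot enumeration of an element's substitution space (uncached)."""
    return ElementScorer(store, genome).vector(element, signature)
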