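"""Signature-preserving negative-control randomization.

Each mutation is repositioned uniformly among the positions of its 50-kb
window whose reference trinucleotide matches the mutation's
pyrimidine-collapsed context (either orientation), with the alternate
allele chosen to reproduce the same 96-channel class.  Per-sample mutation
counts and the channel count vector are preserved exactly, so the
randomized cohort is a faithful draw from the same mutational process with
positional information destroyed — the method's false-positive control.

Windows are fixed tiles of the chromosome (floor(pos0 / window)), making
the scheme deterministic and independent of mutation order; a
``centered=True`` option uses a +/- window/2 span around each mutation
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

from .core import COMPLEMENT, Mutation, MutationSet, reverse_complement
from .genome import ReferenceGenome
from .signature import ContextError, canonical_channel, trinucleotide_context

log = logging.getLogger(__name__)

_PYRIMIDINES = "CT"


@dataclass
class RandomizationReport:
    n_mutations: int = 0
    n_repositioned: int = 0
    n_kept_original: int = 0  # edge/ambiguous context or no in-window match


class _ContextFinder:
    """Caches, per (chrom, tile, collapsed context), the matching positions."""

    def __init__(self, genome: ReferenceGenome, window: int):
        self.genome = genome
        self.window = window
        self._cache: dict[tuple[str, int, str], np.ndarray] = {}
        self._seqs: dict[tuple[str, int], np.ndarray] = {}

    def _tile_seq(self, chrom: str, tile: int) -> tuple[np.ndarray, int]:
        key = (chrom, tile)
        if key not in self._seqs:
            start = tile * self.window
            end = min(self.genome.length(chrom), start + self.window)
            seq = self.genome.fetch(chrom, start, end).upper()
            self._seqs[key] = np.frombuffer(seq.encode(), dtype=np.uint8)
        return self._seqs[key], tile * self.window

    def matches(self, chrom: str, tile: int, context: str) -> np.ndarray:
        """1-based positions in the tile whose trinucleotide is ``context``
        or its reverse complement (genuine palindromes counted once)."""
        key = (chrom, tile, context)
        if key not in self._cache:
            arr, offset = self._tile_seq(chrom, tile)
            hits = []
            targets = {context, reverse_complement(context)}
            for t in targets:
                codes = np.frombuffer(t.encode(), dtype=np.uint8)
                m = (arr[:-2] == codes[0]) & (arr[1:-1] == codes[1]) & (arr[2:] == codes[2])
                hits.append(np.flatnonzero(m))
            centers = np.unique(np.concatenate(hits)) + 1  # center of the 3-mer
            # exclude centers whose context would spill over the tile into a
            # neighboring one? not needed: matches are fully inside the tile
            self._cache[key] = centers + offset + 1  # to 1-based genome coords
        return self._cache[key]


def randomize_dataset(
    mutations: MutationSet,
    genome: ReferenceGenome,
    window: int = 50_000,
    rng: Union[np.random.Generator, int, None] = None,
    centered: bool = False,
) -> tuple[MutationSet, RandomizationReport]:
    """Reposition every mutation within its window, preserving channels.

    Returns the randomized set (same samples, same per-sample counts) and a
    report.  Mutations without a usable context, or with no context match
    in their window, keep their original position.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    report = RandomizationReport(n_mutations=len(mutations))
    finder = None if centered else _ContextFinder(genome, window)
    out: list[Mutation] = []
    for m in mutations:
        chrom = genome.resolve_chrom(m.chrom)
        try:
            ctx = trinucleotide_context(genome, chrom, m.pos)
            channel_ctx = ctx if ctx[1] in _PYRIMIDINES else reverse_complement(ctx)
            # collapsed alt accompanying the collapsed context
            alt_pyr = m.alt if ctx[1] in _PYRIMIDINES else COMPLEMENT[m.alt]
            canonical_channel(ctx, m.alt)  # raises on ambiguous bases
        except (ContextError, KeyError):
            report.n_kept_original += 1
            out.append(Mutation(m.sample_id, chrom, m.pos, m.ref, m.alt))
            continue

        if centered:
            half = window // 2
            lo = max(0, m.pos - 1 - half)
            hi = min(genome.length(chrom), m.pos - 1 + half + 1)
            seq = genome.fetch(chrom, lo, hi).upper()
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            hits = []
            for t in {channel_ctx, reverse_complement(channel_ctx)}:
                codes = np.frombuffer(t.encode(), dtype=np.uint8)
                mask = (arr[:-2] == codes[0]) & (arr[1:-1] == codes[1]) & (arr[2:] == codes[2])
                hits.append(np.flatnonzero(mask))
            candidates = np.unique(np.concatenate(hits)) + 1 + lo + 1
        else:
            tile = (m.pos - 1) // window
            candidates = finder.matches(chrom, tile, channel_ctx)

        if len(candidates) == 0:
            report.n_kept_original += 1
            out.append(Mutation(m.sample_id, chrom, m.pos, m.ref, m.alt))
            continue
        new_pos = int(candidates[rng.integers(len(candidates))])
        new_ref = genome.base(chrom, new_pos)
        if new_ref == channel_ctx[1]:
            new_alt = alt_pyr
        else:
            new_alt = COMPLEMENT[alt_pyr]
        out.append(Mutation(m.sample_id, chrom, new_pos, new_ref, new_alt))
        report.n_repositioned += 1
    if report.n_kept_original:
        log.info(
            "randomization kept %d/%d mutation(s) at their original position",
            report.n_kept_original, report.n_mutations,
        )
    return (
        MutationSet(out, set(mutations.samples), provenance=f"randomized({mutations.provenance})"),
        report,
    )
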