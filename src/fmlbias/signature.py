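"""96-channel trinucleotide substitution signatures.

A channel is a substitution class ``5'[ref>alt]3'`` with the mutated base
collapsed to the pyrimidine strand: 64 trinucleotide contexts x 3 alternate
alleles give 192 raw (context, alt) pairs, and identifying each pair with
its reverse complement leaves exactly 96 classes.  Signature probabilities
are the normalized channel counts over a mutation set and drive the
position-and-allele weighting of the Monte-Carlo background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np

from .core import BASES, Mutation, MutationSet, reverse_complement
from .genome import ReferenceGenome

log = logging.getLogger(__name__)

PYRIMIDINES = "CT"


def _build_channels() -> list[str]:
    chans = []
    for ref in PYRIMIDINES:
        for alt in BASES:
            if alt == ref:
                continue
            for five in BASES:
                for three in BASES:
                    chans.append(f"{five}[{ref}>{alt}]{three}")
    return chans


#: Canonical channel order: ref C then T, alt alphabetical, then 5'/3' context.
CHANNELS: tuple[str, ...] = tuple(sorted(_build_channels()))
CHANNEL_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}
N_CHANNELS = len(CHANNELS)
assert N_CHANNELS == 96


class ContextError(ValueError):
    """Context unavailable (chromosome edge) or unscorable (ambiguous base)."""


def trinucleotide_context(genome: ReferenceGenome, chrom: str, pos: int) -> str:
    """Uppercase + strand bases at 1-based positions pos-1, pos, pos+1."""
    chrom = genome.resolve_chrom(chrom)
    if pos < 2 or pos > genome.length(chrom) - 1:
        raise ContextError(f"{chrom}:{pos} has no trinucleotide context")
    return genome.fetch(chrom, pos - 2, pos + 1).upper()


def canonical_channel(context: str, alt: str) -> str:
    """Collapse a (+ strand trinucleotide, alt) pair to its pyrimidine channel."""
    context = context.upper()
    alt = alt.upper()
    if len(context) != 3:
        raise ValueError(f"context must be 3 bases, got {context!r}")
    if any(b not in BASES for b in context) or alt not in BASES:
        raise ContextError(f"unscorable context {context!r} > {alt!r}")
    if context[1] == alt:
        raise ValueError(f"alt equals reference center in {context!r} > {alt!r}")
    if context[1] not in PYRIMIDINES:
        context = reverse_complement(context)
        alt = reverse_complement(alt)
    return f"{context[0]}[{context[1]}>{alt}]{context[2]}"


def channel_of_mutation(genome: ReferenceGenome, m: Mutation) -> str:
    return canonical_channel(trinucleotide_context(genome, m.chrom, m.pos), m.alt)


@dataclass
class SignatureMatrix:
    """Probabilities over the 96 channels, in ``CHANNELS`` order."""

    probabilities: np.ndarray
    mode: str = "cohort"  # cohort | per_sample | precomputed | uniform
    counts: Optional[np.ndarray] = None

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} channel probabilities, got {p.shape}")
        if (p < 0).any():
            raise ValueError("negative channel probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"channel probabilities sum to {p.sum()}, not 1")
        self.probabilities = p

    def prob(self, channel: str) -> float:
        return float(self.probabilities[CHANNEL_INDEX[channel]])

    __getitem__ = prob

    @classmethod
    def uniform(cls) -> "SignatureMatrix":
        return cls(np.full(N_CHANNELS, 1.0 / N_CHANNELS), mode="uniform")

    @classmethod
    def from_counts(cls, counts: np.ndarray, mode: str = "cohort") -> "SignatureMatrix":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(
                "no countable mutations; use uniform or a precomputed signature"
            )
        return cls(counts / total, mode=mode, counts=counts)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("CHANNEL\tPROBABILITY\n")
            for chan, p in zip(CHANNELS, self.probabilities):
                fh.write(f"{chan}\t{p:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "SignatureMatrix":
        probs = np.zeros(N_CHANNELS)
        seen = set()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["CHANNEL", "PROBABILITY"]:
                raise ValueError(f"{path}: unexpected signature header {header}")
            for line in fh:
                chan, p = line.rstrip("\n").split("\t")[:2]
                if chan not in CHANNEL_INDEX:
                    raise ValueError(f"{path}: unknown channel {chan!r}")
                probs[CHANNEL_INDEX[chan]] = float(p)
                seen.add(chan)
        if len(seen) != N_CHANNELS:
            raise ValueError(f"{path}: {len(seen)}/{N_CHANNELS} channels present")
        return cls(probs / probs.sum() if probs.sum() else probs, mode="precomputed")


def count_channels(
    mutations: MutationSet, genome: ReferenceGenome
) -> tuple[np.ndarray, int]:
    """Channel counts over a mutation set; returns (counts, n_skipped).

    Mutations at chromosome edges (no trinucleotide context) or with
    ambiguous reference context are skipped and counted.
    """
    counts = np.zeros(N_CHANNELS)
    skipped = 0
    for m in mutations:
        try:
            counts[CHANNEL_INDEX[channel_of_mutation(genome, m)]] += 1
        except ContextError:
            skipped += 1
    if skipped:
        log.info("signature counting skipped %d mutation(s) without context", skipped)
    return counts, skipped


def compute_signature(
    mutations: MutationSet,
    genome: ReferenceGenome,
    mode: str = "cohort",
) -> Union[SignatureMatrix, Dict[str, SignatureMatrix]]:
    """Estimate the signature from observed mutations.

    ``cohort`` pools all samples; ``per_sample`` returns one matrix per
    sample; ``uniform`` ignores the data.  Channels never observed keep
    probability zero (no pseudocount).
    """
    if mode == "uniform":
        return SignatureMatrix.uniform()
    if mode == "cohort":
        counts, _ = count_channels(mutations, genome)
        return SignatureMatrix.from_counts(counts, mode="cohort")
    if mode == "per_sample":
        out: Dict[str, SignatureMatrix] = {}
        by_sample: Dict[str, list[Mutation]] = {}
        for m in mutations:
            by_sample.setdefault(m.sample_id, []).append(m)
        for sample, muts in by_sample.items():
            counts, _ = count_channels(
                MutationSet.from_mutations(muts, provenance=sample), genome
            )
            if counts.sum() <= 0:
                raise ValueError(
                    f"sample {sample!r} has no countable mutations; "
                    "use cohort, uniform, or a precomputed signature"
                )
            out[sample] = SignatureMatrix.from_counts(counts, mode="per_sample")
        return out
    raise ValueError(f"unknown signature mode {mode!r}")
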