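"""Synthetic toy data with the statistical structure the FM-bias test assumes.

Generates, from one seed: a random reference chromosome, a Gencode-style
GTF of protein-coding and lincRNA genes laid out on a fixed grid, a
complete per-substitution score table over the resulting element catalog
(exponential-tailed base scores plus alt-specific jitter, with designated
hotspot entries above each element's maximum), and tumor cohorts.

Null cohorts draw every mutation from the pooled element substitution
space with probabilities proportional to a generating 96-channel
signature — the exact sampling model of the test's background, so the
test's p-values on such cohorts must be uniform.  Driver injection
redirects a stated fraction of extra mutations in chosen elements to
hotspot entries, emulating positive selection for high-impact mutations.

The default scale (1 chromosome x 2 Mb, ~200 elements, 50 samples, ~40
mutations/sample) runs the full pipeline in seconds.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Mutation, MutationSet
from .genome import ReferenceGenome
from .regions import ElementCatalog, RegionConfig, build_catalog
from .scores import ElementScorer, InMemoryScoreStore
from .signature import CHANNELS, N_CHANNELS, SignatureMatrix

BASES = "ACGT"

# deterministic gene layout, coordinates relative to the transcript anchor
_GENE_SPAN = 2000
_PROMOTER_UP = 2500


def default_signature() -> np.ndarray:
    """A fixed, skewed generating signature: C>T channels 5x enriched.

    Emulates the deamination-dominated spectra common in real tumors while
    keeping every channel possible.
    """
    w = np.array([5.0 if "[C>T]" in c else 1.0 for c in CHANNELS])
    return w / w.sum()


@dataclass
class SyntheticSpec:
    """Study conditions for the toy world."""

    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    gc_content: float = 0.5
    n_protein_coding: int = 38
    n_lincrna: int = 10
    score_scale: float = 3.0          # exponential base-score scale
    score_jitter_sd: float = 0.3      # alt-specific Gaussian jitter
    hotspot_fraction: float = 0.01    # fraction of entries per element set as hotspots
    n_samples: int = 50
    mutations_per_sample: float = 40.0   # Poisson mean
    signature: np.ndarray = field(default_factory=default_signature)
    driver_elements: tuple[str, ...] = ()
    driver_fraction: float = 0.8      # probability a driver mutation hits a hotspot
    driver_samples: int = 10          # mutated samples per driver element
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.driver_fraction <= 1.0):
            raise ValueError("driver_fraction must lie in [0, 1]")
        sig = np.asarray(self.signature, dtype=float)
        if sig.shape != (N_CHANNELS,) or (sig < 0).any() or abs(sig.sum() - 1) > 1e-9:
            raise ValueError("signature must be 96 valid probabilities")
        self.signature = sig


def _rng(spec_seed: int, stream: int, seed: Optional[int] = None) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        [seed if seed is not None else spec_seed, stream]
    ))


def generate_genome(spec: SyntheticSpec, seed: Optional[int] = None) -> ReferenceGenome:
    """Random reference sequence at the requested GC content; deterministic."""
    if spec.chrom_length <= 3:
        raise ValueError("chromosome length must exceed 3")
    rng = _rng(spec.seed, 0, seed)
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list(BASES), size=spec.chrom_length, p=probs)
    return ReferenceGenome({spec.chrom: "".join(seq)})


def generate_annotation(spec: SyntheticSpec) -> list[str]:
    """Gencode-style GTF lines for a fixed grid of toy genes.

    Protein-coding genes carry three exons (5' UTR / CDS x3 / 3' UTR) with
    two 500-bp introns; lincRNA genes carry two exons.  Strands alternate.
    Layout is deterministic (independent of the genome sequence).
    """
    n_genes = spec.n_protein_coding + spec.n_lincrna
    usable = spec.chrom_length - 2 * (_PROMOTER_UP + _GENE_SPAN + 1000)
    spacing = usable // max(n_genes, 1)
    if spacing < _GENE_SPAN + 2 * _PROMOTER_UP:
        raise ValueError("chromosome too short for the requested gene count")
    lines: list[str] = []

    def row(feature: str, start0: int, end0: int, strand: str, attrs: str) -> None:
        lines.append(
            f"{spec.chrom}\tsynthetic\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}"
        )

    for i in range(n_genes):
        anchor = _PROMOTER_UP + 1000 + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        if i < spec.n_protein_coding:
            gid, name, btype = f"SYNG{i:04d}", f"GENE{i}", "protein_coding"
            tid = gid + ".1"
            attrs = (
                f'gene_id "{gid}"; transcript_id "{tid}"; gene_type "{btype}"; '
                f'transcript_type "{btype}"; gene_name "{name}";'
            )
            # relative layout on the + strand; mirror for -
            utr5, cds1 = (0, 150), (150, 300)
            cds2 = (800, 1100)
            cds3, utr3 = (1600, 1750), (1750, 2000)
            exons = [(0, 300), (800, 1100), (1600, 2000)]
            blocks = {"UTR": [utr5, utr3], "CDS": [cds1, cds2, cds3], "exon": exons}
            if strand == "-":
                blocks = {
                    k: sorted((_GENE_SPAN - b, _GENE_SPAN - a) for a, b in v)
                    for k, v in blocks.items()
                }
            row("gene", anchor, anchor + _GENE_SPAN, strand, attrs)
            row("transcript", anchor, anchor + _GENE_SPAN, strand, attrs)
            for feat in ("exon", "CDS", "UTR"):
                for a, b in blocks[feat]:
                    row(feat, anchor + a, anchor + b, strand, attrs)
        else:
            j = i - spec.n_protein_coding
            gid, name, btype = f"SYNL{j:04d}", f"LINC{j}", "lincRNA"
            tid = gid + ".1"
            attrs = (
                f'gene_id "{gid}"; transcript_id "{tid}"; gene_type "{btype}"; '
                f'transcript_type "{btype}"; gene_name "{name}";'
            )
            row("gene", anchor, anchor + 800, strand, attrs)
            row("transcript", anchor, anchor + 800, strand, attrs)
            for a, b in ((0, 300), (500, 800)):
                row("exon", anchor + a, anchor + b, strand, attrs)
    return lines


def build_toy_catalog(
    spec: SyntheticSpec, genome: ReferenceGenome,
    config: Optional[RegionConfig] = None,
) -> ElementCatalog:
    return build_catalog(generate_annotation(spec), genome, config)


def generate_scores(
    spec: SyntheticSpec,
    genome: ReferenceGenome,
    catalog: ElementCatalog,
    seed: Optional[int] = None,
) -> tuple[InMemoryScoreStore, dict[str, list[tuple[str, int, str]]]]:
    """Score every possible substitution in every element.

    Per position: base score ~ Exponential(scale); per alt: base + Gaussian
    jitter.  A ``hotspot_fraction`` of entries per element is then raised
    above the element's maximum, so hotspots exceed the 99th percentile of
    the remaining scores by construction.  Returns the store and the
    hotspot manifest (element id -> [(chrom, pos, alt), ...]).
    """
    rng = _rng(spec.seed, 1, seed)
    store = InMemoryScoreStore(provider="synthetic")
    hotspots: dict[str, list[tuple[str, int, str]]] = {}
    for element in sorted(catalog, key=lambda e: e.element_id):
        entries: list[tuple[str, int, str]] = []
        scores: list[float] = []
        for pos1 in element.positions():
            ref = genome.base(element.chrom, pos1)
            if ref not in BASES:
                continue
            base = rng.exponential(spec.score_scale)
            for alt in BASES:
                if alt == ref:
                    continue
                s = base + rng.normal(0.0, spec.score_jitter_sd)
                if store.get(element.chrom, pos1, alt) is None:
                    store.add(element.chrom, pos1, ref, alt, s)
                entries.append((element.chrom, pos1, alt))
                scores.append(s)
        if not entries:
            continue
        n_hot = max(3, int(round(spec.hotspot_fraction * len(entries))))
        n_hot = min(n_hot, len(entries))
        top = max(scores)
        hot_idx = rng.choice(len(entries), size=n_hot, replace=False)
        hotspots[element.element_id] = []
        for idx in hot_idx:
            chrom, pos1, alt = entries[idx]
            store.add(chrom, pos1, store.ref_at(chrom, pos1), alt,
                      top + 1.0 + rng.exponential(spec.score_scale))
            hotspots[element.element_id].append((chrom, pos1, alt))
    return store, hotspots


def generate_cohort(
    spec: SyntheticSpec,
    genome: ReferenceGenome,
    catalog: ElementCatalog,
    store: InMemoryScoreStore,
    hotspots: Optional[dict[str, list[tuple[str, int, str]]]] = None,
    seed: Optional[int] = None,
    scorer: Optional[ElementScorer] = None,
) -> MutationSet:
    """Draw a tumor cohort from the generating signature.

    Null mutations: per sample, a Poisson number of draws from the pooled
    element substitution space, each entry weighted by the generating
    signature probability of its channel — the same sampling machinery the
    test's background uses (via :class:`ElementScorer`), which makes null
    calibration a true self-test.  Driver elements additionally receive one
    mutation from each of ``driver_samples`` distinct samples, redirected
    to a hotspot entry with probability ``driver_fraction``.
    """
    rng = _rng(spec.seed, 2, seed)
    sig = SignatureMatrix(spec.signature.copy(), mode="precomputed")
    scorer = scorer or ElementScorer(store, genome)

    pool_pos, pool_alt, pool_w = [], [], []
    vectors = {}
    for element in sorted(catalog, key=lambda e: e.element_id):
        vec, w = scorer.raw_weights(element, sig)
        vectors[element.element_id] = vec
        pool_pos.append(vec.pos)
        pool_alt.append(vec.alt)
        pool_w.append(w)
    pos = np.concatenate(pool_pos)
    alt = np.concatenate(pool_alt)
    w = np.concatenate(pool_w)
    p = w / w.sum()
    chrom = spec.chrom

    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    muts: list[Mutation] = []
    counts = rng.poisson(spec.mutations_per_sample, size=spec.n_samples)
    for sample, c in zip(samples, counts):
        if c == 0:
            continue
        idx = rng.choice(len(pos), size=c, p=p)
        for i in idx:
            muts.append(
                Mutation(sample, chrom, int(pos[i]),
                         genome.base(chrom, int(pos[i])), str(alt[i]))
            )

    if spec.driver_elements:
        if hotspots is None:
            raise ValueError("driver injection requires the hotspot manifest")
        for eid in spec.driver_elements:
            vec = vectors[eid]
            hot = hotspots[eid]
            n_drv = min(spec.driver_samples, spec.n_samples)
            chosen = rng.choice(spec.n_samples, size=n_drv, replace=False)
            for si in chosen:
                if rng.random() < spec.driver_fraction:
                    c_chrom, c_pos, c_alt = hot[rng.integers(len(hot))]
                else:
                    i = rng.choice(len(vec), p=vec.prob)
                    c_chrom, c_pos, c_alt = chrom, int(vec.pos[i]), str(vec.alt[i])
                muts.append(
                    Mutation(samples[si], c_chrom, c_pos,
                             genome.base(c_chrom, c_pos), c_alt)
                )

    return MutationSet(muts, set(samples), provenance=f"synthetic(seed={seed if seed is not None else spec.seed})")


def write_fixture_dir(spec: SyntheticSpec, outdir: str) -> dict[str, str]:
    """Materialize the full toy world as files; returns the path manifest."""
    os.makedirs(outdir, exist_ok=True)
    genome = generate_genome(spec)
    catalog = build_toy_catalog(spec, genome)
    store, hotspots = generate_scores(spec, genome, catalog)
    cohort = generate_cohort(spec, genome, catalog, store, hotspots)

    from .core import write_mutations_tsv

    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gtf"),
        "elements": os.path.join(outdir, "elements.tsv"),
        "scores": os.path.join(outdir, "scores.tsv"),
        "mutations": os.path.join(outdir, "mutations.tsv"),
        "signature": os.path.join(outdir, "signature.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    genome.to_fasta(paths["genome"])
    with open(paths["annotation"], "w") as fh:
        fh.write("\n".join(generate_annotation(spec)) + "\n")
    catalog.to_tsv(paths["elements"])
    store.to_tsv(paths["scores"])
    write_mutations_tsv(cohort, paths["mutations"])
    SignatureMatrix(spec.signature.copy(), mode="precomputed").to_tsv(paths["signature"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "driver_elements": list(spec.driver_elements),
                "hotspots": {k: [[c, p, a] for c, p, a in v] for k, v in hotspots.items()
                             if k in spec.driver_elements},
                "seed": spec.seed,
            },
            fh, indent=2,
        )
    return paths
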