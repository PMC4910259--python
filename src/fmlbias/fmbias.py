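"""The FM-bias test: observed mean impact, Monte-Carlo background, empirical
p-value, and cohort-level FDR.

For each mutated element the test (i) averages the impact scores of the
observed mutations (k of them, counted per occurrence), (ii) draws N
background sets of k substitutions from the element's own substitution
space, each candidate weighted by the trinucleotide-signature probability
of its channel, (iii) reports the fraction of background means at least as
large as the observed mean as an empirical p-value, and (iv) adjusts
p-values across elements with Benjamini-Hochberg, restricted to elements
mutated in a minimum number of samples.

Zero exceedances trigger adaptive escalation: N doubles (fresh draws from
the same per-element stream) up to a ceiling; a still-empty count is
reported as the one-sided bound 1/N_max.  Per-element random streams are
derived from the master seed and a stable hash of the element id, so
results do not depend on element iteration order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import FMBiasResult, GenomicElement, Mutation, MutationSet
from .genome import ReferenceGenome
from .regions import ElementCatalog
from .scores import (
    ElementScorer,
    ElementScoreVector,
    ScoreStore,
    SignatureMismatchError,
)
from .signature import SignatureMatrix

log = logging.getLogger(__name__)

SignatureLike = Union[SignatureMatrix, Dict[str, SignatureMatrix]]


@dataclass
class TestConfig:
    """Knobs of the FM-bias test.

    ``n_iterations`` trades runtime for p-value resolution (floor 1/N);
    ``escalation_max`` caps the adaptive doubling used when no background
    mean reaches the observed mean.  ``min_samples_for_fdr`` is the
    mutated-sample threshold for inclusion in the BH adjustment (2 for
    single tumor-type cohorts; 5 is the pan-cancer preset).
    """

    n_iterations: int = 10_000
    seed: int = 0
    sampling_mode: str = "signature"  # signature | uniform | per_sample_signature
    escalation_max: int = 1_000_000
    min_samples_for_fdr: int = 2
    statistic: str = "mean"
    strict_ties: bool = False      # count only background means strictly > observed
    pseudocount: bool = False      # p = (count+1)/(N+1) instead of count/N
    tail: str = "right"            # "left" probes negative selection

    def __post_init__(self):
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be at least 100")
        if self.escalation_max < self.n_iterations:
            raise ValueError("escalation_max must be >= n_iterations")
        if self.statistic != "mean":
            raise ValueError(f"unsupported statistic {self.statistic!r}")
        if self.tail not in ("right", "left"):
            raise ValueError(f"tail must be 'right' or 'left', got {self.tail!r}")


@dataclass
class BackgroundSample:
    element_id: str
    means: np.ndarray
    k: int

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)


def element_rng(seed: int, element_id: str) -> np.random.Generator:
    """Per-element stream: stable across iteration order and parallelism."""
    digest = hashlib.blake2b(element_id.encode(), digest_size=4).digest()
    sub = int.from_bytes(digest, "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def observed_mean(
    element: GenomicElement,
    mutations: Union[MutationSet, Sequence[Mutation]],
    store: ScoreStore,
) -> tuple[Optional[float], int, int, int]:
    """Mean impact score of the observed mutations in an element.

    Recurrent mutations count once per occurrence.  Mutations at unscored
    positions are excluded (and tallied).  Returns
    ``(mean, k, n_samples, n_unscored)``; mean is None when nothing scores.
    """
    scores, samples = [], set()
    n_unscored = 0
    for m in mutations:
        if m.chrom != element.chrom or not element.covers(m.pos):
            continue
        s = store.get(m.chrom, m.pos, m.alt)
        if s is None:
            n_unscored += 1
            continue
        scores.append(s)
        samples.add(m.sample_id)
    if not scores:
        return None, 0, len(samples), n_unscored
    arr = np.asarray(scores, dtype=float)
    return float(arr.mean()), len(arr), len(samples), n_unscored


def sample_background(
    vector: ElementScoreVector,
    k: int,
    n_iterations: int,
    rng: np.random.Generator,
    slot_probs: Optional[Sequence[np.ndarray]] = None,
) -> BackgroundSample:
    """Draw ``n_iterations`` background sets of ``k`` substitutions.

    Draws are with replacement, each candidate with its sampling
    probability.  ``slot_probs`` (per-sample-signature mode) supplies one
    probability vector per slot; slot j is then drawn under its own
    weights.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(vector) == 0:
        raise SignatureMismatchError(f"{vector.element_id}: empty score vector")
    if slot_probs is None:
        idx = rng.choice(len(vector), size=n_iterations * k, p=vector.prob)
        means = vector.score[idx].reshape(n_iterations, k).mean(axis=1)
    else:
        if len(slot_probs) != k:
            raise ValueError(f"need {k} slot probability vectors, got {len(slot_probs)}")
        total = np.zeros(n_iterations)
        for p in slot_probs:
            idx = rng.choice(len(vector), size=n_iterations, p=p)
            total += vector.score[idx]
        means = total / k
    return BackgroundSample(vector.element_id, means, k)


def empirical_p(
    observed: float, background: BackgroundSample, config: TestConfig
) -> float:
    """Fraction of background means at least as extreme as the observed mean.

    Ties count toward the exceedance by default (conservative); with
    ``strict_ties`` only strict exceedances count.  ``pseudocount`` switches
    to (count+1)/(N+1).
    """
    means = background.means
    if len(means) == 0:
        raise ValueError("empty background")
    if config.tail == "right":
        count = int((means > observed).sum() if config.strict_ties
                    else (means >= observed).sum())
    else:
        count = int((means < observed).sum() if config.strict_ties
                    else (means <= observed).sum())
    n = len(means)
    return (count + 1) / (n + 1) if config.pseudocount else count / n


def _test_element(
    vector: ElementScoreVector,
    obs_mean: float,
    k: int,
    config: TestConfig,
    rng: np.random.Generator,
    slot_probs: Optional[Sequence[np.ndarray]] = None,
) -> tuple[float, int]:
    """Empirical p with adaptive escalation; returns (p, iterations used)."""
    n = config.n_iterations
    while True:
        bg = sample_background(vector, k, n, rng, slot_probs=slot_probs)
        p = empirical_p(obs_mean, bg, config)
        if p > 0 or n >= config.escalation_max:
            break
        n = min(2 * n, config.escalation_max)
    if p == 0.0:
        # no exceedance even at the ceiling: report the one-sided bound
        p = 1.0 / config.escalation_max
    return p, n


def adjust_fdr(
    results: Sequence[FMBiasResult], min_samples: int = 2
) -> list[FMBiasResult]:
    """Benjamini-Hochberg over elements mutated in >= ``min_samples`` samples.

    Elements below the threshold keep their p-value but receive no q-value.
    """
    eligible = [i for i, r in enumerate(results) if r.n_samples >= min_samples]
    out = [r.with_q(None) for r in results]
    if not eligible:
        log.warning("no element meets the FDR sample threshold (%d)", min_samples)
        return out
    ps = np.array([results[i].p_value for i in eligible])
    qs = multipletests(ps, method="fdr_bh")[1]
    for i, q in zip(eligible, qs):
        out[i] = results[i].with_q(float(q))
    return out


def map_mutations_to_elements(
    catalog: ElementCatalog, mutations: MutationSet
) -> Dict[str, list[Mutation]]:
    """Element id -> observed mutations; a mutation in two elements counts in both."""
    hits: Dict[str, list[Mutation]] = {}
    for m in mutations:
        for eid in catalog.lookup(m.chrom, m.pos):
            hits.setdefault(eid, []).append(m)
    return hits


def run_fml(
    catalog: ElementCatalog,
    mutations: MutationSet,
    store: ScoreStore,
    signature: SignatureLike,
    config: Optional[TestConfig] = None,
    genome: Optional[ReferenceGenome] = None,
    scorer: Optional[ElementScorer] = None,
) -> list[FMBiasResult]:
    """Run the FM-bias test over every mutated element of the catalog.

    ``signature`` is a single matrix (cohort/uniform/precomputed) or, in
    per-sample mode, a mapping sample id -> matrix.  ``genome`` is needed
    to enumerate trinucleotide channels (omit only when passing a prebuilt
    ``scorer``).  Results are sorted by (p, element id); failures on single
    elements are logged and skipped.
    """
    config = config or TestConfig()
    if scorer is None:
        if genome is None:
            raise ValueError("run_fml needs a genome or a prebuilt ElementScorer")
        scorer = ElementScorer(store, genome)
    per_sample = isinstance(signature, dict)
    if per_sample != (config.sampling_mode == "per_sample_signature"):
        if per_sample:
            raise ValueError("per-sample signatures require sampling_mode='per_sample_signature'")
        raise ValueError("sampling_mode='per_sample_signature' requires a sample->signature map")
    base_sig = (
        SignatureMatrix.uniform()
        if config.sampling_mode == "uniform"
        else signature
    )

    hits = map_mutations_to_elements(catalog, mutations)
    results: list[FMBiasResult] = []
    for eid in sorted(hits):
        element = catalog[eid]
        obs, k, n_samp, n_unscored = observed_mean(element, hits[eid], store)
        if obs is None:
            log.info("%s: no scored observed mutations; not tested", eid)
            continue
        try:
            if per_sample:
                # pool signatures for enumeration weighting; slots drawn per sample
                pooled = SignatureMatrix.uniform()
                vector = scorer.vector(element, pooled)
                slot_probs = []
                for m in hits[eid]:
                    if store.get(m.chrom, m.pos, m.alt) is None:
                        continue
                    sig = signature[m.sample_id]
                    w = np.where(
                        vector.channel >= 0,
                        sig.probabilities[np.clip(vector.channel, 0, None)],
                        0.0,
                    )
                    if w.sum() <= 0:
                        raise SignatureMismatchError(
                            f"{eid}: sample {m.sample_id} signature assigns zero "
                            "probability to every substitution"
                        )
                    slot_probs.append(w / w.sum())
                rng = element_rng(config.seed, eid)
                p, n_used = _test_element(vector, obs, k, config, rng, slot_probs)
            else:
                vector = scorer.vector(element, base_sig)
                rng = element_rng(config.seed, eid)
                p, n_used = _test_element(vector, obs, k, config, rng)
        except SignatureMismatchError as exc:
            log.error("%s: %s", eid, exc)
            continue
        results.append(
            FMBiasResult(
                element_id=eid,
                n_mutations=k,
                n_samples=n_samp,
                observed_mean=obs,
                p_value=p,
                q_value=None,
                n_iterations=n_used,
                symbol=element.symbol,
                element_type=element.element_type,
            )
        )
    results = adjust_fdr(results, config.min_samples_for_fdr)
    results.sort(key=lambda r: (r.p_value, r.element_id))
    return results


# ---------------------------------------------------------------------------
# Results I/O

_RESULT_COLUMNS = [
    "ELEMENT_ID", "SYMBOL", "ELEMENT_TYPE", "N_MUTATIONS", "N_SAMPLES",
    "OBSERVED_MEAN", "P_VALUE", "Q_VALUE", "N_ITERATIONS",
]


def write_results(results: Sequence[FMBiasResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            q = "" if r.q_value is None else f"{r.q_value:.6g}"
            fh.write(
                f"{r.element_id}\t{r.symbol}\t{r.element_type}\t{r.n_mutations}\t"
                f"{r.n_samples}\t{r.observed_mean:.6g}\t{r.p_value:.6g}\t{q}\t"
                f"{r.n_iterations}\n"
            )


def read_results(path: str) -> list[FMBiasResult]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _RESULT_COLUMNS:
            raise ValueError(f"{path}: unexpected results header {header}")
        for line in fh:
            eid, symbol, etype, k, ns, mean, p, q, n = line.rstrip("\n").split("\t")
            out.append(
                FMBiasResult(
                    element_id=eid, symbol=symbol, element_type=etype,
                    n_mutations=int(k), n_samples=int(ns),
                    observed_mean=float(mean), p_value=float(p),
                    q_value=float(q) if q else None, n_iterations=int(n),
                )
            )
    return out
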