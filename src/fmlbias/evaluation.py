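"""Calibration and benchmarking utilities.

QQ-plot data for p-value calibration against the uniform null, fold
enrichment of a truth set (e.g. the Cancer Gene Census) among top-ranked
elements, and needle-plot data export (mutation recurrence and impact along
a concatenated element).  All outputs are tidy tables; rendering is left to
any plotting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicElement, MutationSet
from .scores import ScoreStore, get_score


def qq_data(p_values: Sequence[float]) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p-values are sorted ascending; the expected quantile of rank i
    (1-based) is i/(n+1).  Columns: ``expected``, ``observed``.
    """
    p = np.asarray(sorted(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    expected = np.arange(1, n + 1) / (n + 1)
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(p)}
    )


def fold_enrichment(
    ranked_ids: Sequence[str],
    truth_set: Iterable[str],
    top_k_grid: Sequence[int],
) -> pd.DataFrame:
    """Fold increase of the truth-set proportion among the top k elements.

    fold(k) = (|truth AND top k| / k) / (|truth AND ranked| / |ranked|);
    an empty overlap gives fold 0.  Columns: ``k``, ``fold``.
    """
    ranked = list(ranked_ids)
    if not ranked:
        raise ValueError("empty ranking")
    truth = set(truth_set)
    background = sum(1 for e in ranked if e in truth) / len(ranked)
    rows = []
    for k in top_k_grid:
        k = min(int(k), len(ranked))
        if k < 1:
            raise ValueError("k must be >= 1")
        top = sum(1 for e in ranked[:k] if e in truth) / k
        rows.append((k, top / background if background > 0 else 0.0))
    return pd.DataFrame(rows, columns=["k", "fold"])


def load_truth_set(path: str) -> set[str]:
    """One element/gene id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return {
            line.strip() for line in fh
            if line.strip() and not line.startswith("#")
        }


@dataclass
class NeedleData:
    """Needle-plot export for one element.

    ``mutations``: one row per distinct (position, alt) with recurrence
    (samples sharing the mutation), the impact score, and the score
    normalized to the element's full possible score range.
    ``max_score_track``: per concatenated position, the highest possible
    score among the three substitutions (NaN where unscored).
    ``segment_offsets``: cumulative start offset of each segment in the
    concatenation; ``strand`` marks element orientation.
    """

    element_id: str
    mutations: pd.DataFrame
    max_score_track: np.ndarray
    segment_offsets: list[int]
    strand: str
    score_min: float
    score_max: float

    def write_tsv(self, mutations_path: str, track_path: Optional[str] = None) -> None:
        self.mutations.to_csv(mutations_path, sep="\t", index=False)
        if track_path:
            pd.DataFrame(
                {"OFFSET": np.arange(len(self.max_score_track)),
                 "MAX_SCORE": self.max_score_track}
            ).to_csv(track_path, sep="\t", index=False)


def needle_data(
    element: GenomicElement, mutations: MutationSet, store: ScoreStore
) -> NeedleData:
    """Assemble needle-plot data for one element.

    Positions are mapped to cumulative offsets across the concatenated
    segments; recurrence is the number of samples sharing a (position, alt)
    mutation; colors normalize scores by the range over all possible
    substitutions in the element.
    """
    offsets: dict[int, int] = {}
    seg_offsets: list[int] = []
    cum = 0
    for seg in element.segments:
        seg_offsets.append(cum)
        for pos0 in range(seg.start, seg.end):
            offsets[pos0 + 1] = cum
            cum += 1

    # full possible score range and per-position maxima
    track = np.full(element.length, np.nan)
    all_scores: list[float] = []
    for pos1, off in offsets.items():
        best = None
        for alt in "ACGT":
            try:
                s = get_score(store, element.chrom, pos1, alt)
            except Exception:
                continue
            if s is not None:
                all_scores.append(s)
                best = s if best is None else max(best, s)
        if best is not None:
            track[off] = best
    smin = min(all_scores) if all_scores else float("nan")
    smax = max(all_scores) if all_scores else float("nan")
    span = smax - smin if smax > smin else 1.0

    counts: dict[tuple[int, str], set[str]] = {}
    for m in mutations:
        if m.chrom == element.chrom and element.covers(m.pos):
            counts.setdefault((m.pos, m.alt), set()).add(m.sample_id)
    rows = []
    for (pos1, alt), samples in sorted(counts.items()):
        s = store.get(element.chrom, pos1, alt)
        rows.append(
            {
                "OFFSET": offsets[pos1],
                "POSITION": pos1,
                "ALT": alt,
                "N_SAMPLES": len(samples),
                "SCORE": np.nan if s is None else s,
                "SCORE_NORM": np.nan if s is None else (s - smin) / span,
            }
        )
    muts_df = pd.DataFrame(
        rows,
        columns=["OFFSET", "POSITION", "ALT", "N_SAMPLES", "SCORE", "SCORE_NORM"],
    )
    return NeedleData(
        element_id=element.element_id,
        mutations=muts_df,
        max_score_track=track,
        segment_offsets=seg_offsets,
        strand=element.strand,
        score_min=smin,
        score_max=smax,
    )
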