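"""Turning per-residue perturbation scores into contiguous region calls.

Difference maps (fluctuation matrices, strain profiles) are read off as
contiguous stretches of residues whose perturbation exceeds a data-driven
threshold.  The same machinery serves both the pairwise-fluctuation caller
and the strain-hotspot caller: residues are scored, scores below the
significance threshold are dropped, and runs of at least `min_len`
consecutive residues with the same perturbation sign become calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ResidueRange

__all__ = ["RegionCall", "significance_threshold", "calls_from_scores"]


@dataclass(frozen=True)
class RegionCall:
    """A contiguous residue segment with coherent direction of change.

    direction 'quenched' means reduced fluctuation/strain in the perturbed
    state (negative difference), 'enhanced' the opposite.  score is the mean
    absolute significant difference over the segment.
    """

    range: ResidueRange
    direction: str  # 'quenched' | 'enhanced'
    score: float

    def overlaps(self, other: ResidueRange) -> bool:
        return self.range.first <= other.last and other.first <= self.range.last


def significance_threshold(values: np.ndarray, k: float) -> float:
    """mean + k*SD of |values| over the finite entries (population SD)."""
    v = np.abs(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.inf
    return float(v.mean() + k * v.std())


def calls_from_scores(
    residue_ids: np.ndarray,
    scores: np.ndarray,
    min_len: int,
) -> list[RegionCall]:
    """Group signed per-residue scores into same-sign contiguous calls.

    `scores` is NaN for residues with no significant perturbation; residue
    ids must be sorted ascending.  Contiguity requires consecutive ids, so
    numbering gaps break runs.  Calls are returned sorted and non-overlapping
    by construction.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ids = np.asarray(residue_ids, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if ids.size != scores.size:
        raise ValueError("residue_ids/scores length mismatch")
    if np.any(np.diff(ids) <= 0):
        raise ValueError("residue_ids must be strictly increasing")

    calls: list[RegionCall] = []
    run: list[int] = []  # indices into ids

    def flush() -> None:
        if len(run) >= min_len:
            seg = scores[run]
            direction = "quenched" if seg[0] < 0 else "enhanced"
            calls.append(
                RegionCall(
                    range=ResidueRange(int(ids[run[0]]), int(ids[run[-1]])),
                    direction=direction,
                    score=float(np.mean(np.abs(seg))),
                )
            )
        run.clear()

    for i in range(ids.size):
        s = scores[i]
        if not np.isfinite(s) or s == 0.0:
            flush()
            continue
        if run:
            prev = run[-1]
            same_sign = (scores[prev] < 0) == (s < 0)
            consecutive = ids[i] == ids[prev] + 1
            if not (same_sign and consecutive):
                flush()
        run.append(i)
    flush()
    return calls
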