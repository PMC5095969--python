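"""CpG-island detection by sliding-window GC / observed-expected criteria.

An island is a run of sequence at least ``min_len`` bases long with GC
fraction above ``gc_min`` and an observed/expected CpG ratio above
``oe_min``, where

    obs/exp = (#CpG dinucleotides * L) / (#C * #G)

on the evaluated interval (0 when #C * #G = 0).  Detection slides a window
of ``min_len`` bases along the sequence, merges overlapping or adjacent
passing windows, and re-scores each merged interval; intervals that fail
re-scoring are trimmed greedily from their ends until they pass or fall
below the minimum length.  N bases never count as C, G, or part of a CpG,
and the effective length excludes them.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CpGIsland", "gc_and_oe", "scan_islands"]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class CpGIsland:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    gc_fraction: float
    obs_exp_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq


def gc_and_oe(seq: str) -> tuple[float, float]:
    """GC fraction and observed/expected CpG ratio of one window."""
    seq = _validate(seq)
    if not seq:
        raise ValueError("empty window")
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_n = seq.count("N")
    L = len(seq) - n_n
    if L == 0:
        return (0.0, 0.0)
    n_cpg = seq.count("CG")
    gc = (n_c + n_g) / L
    oe = (n_cpg * L) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return (gc, oe)


class _SeqStats:
    """Prefix sums for O(1) window GC / CpG statistics."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_n = arr == ord("N")
        cpg = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            cpg[:-1] = is_c[:-1] & is_g[1:]
        z = np.zeros(1, dtype=np.int64)
        self.c = np.concatenate([z, np.cumsum(is_c)])
        self.g = np.concatenate([z, np.cumsum(is_g)])
        self.n = np.concatenate([z, np.cumsum(is_n)])
        # CpG starts strictly inside [start, end): start index in [start, end-1)
        self.cpg = np.concatenate([z, np.cumsum(cpg)])

    def score(self, start: int, end: int) -> tuple[float, float]:
        n_c = int(self.c[end] - self.c[start])
        n_g = int(self.g[end] - self.g[start])
        n_n = int(self.n[end] - self.n[start])
        L = (end - start) - n_n
        if L == 0:
            return (0.0, 0.0)
        n_cpg = int(self.cpg[end - 1] - self.cpg[start]) if end - 1 > start else 0
        gc = (n_c + n_g) / L
        oe = (n_cpg * L) / (n_c * n_g) if n_c * n_g > 0 else 0.0
        return (gc, oe)


def _passes(gc: float, oe: float, gc_min: float, oe_min: float) -> bool:
    return gc > gc_min and oe > oe_min


def scan_islands(
    seq: str,
    chrom: str = "seq",
    min_len: int = 300,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    window: int | None = None,
    step: int = 1,
) -> list[CpGIsland]:
    """Scan a sequence for CpG islands (sliding window + merge + re-score)."""
    seq = _validate(seq)
    if window is None:
        window = min_len
    if window < min_len:
        raise ValueError("window must be >= min_len")
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(seq) < window:
        warnings.warn(
            f"sequence shorter than window ({len(seq)} < {window}); no islands",
            stacklevel=2,
        )
        return []
    stats = _SeqStats(seq)
    starts = np.arange(0, len(seq) - window + 1, step)
    # vectorized window scores
    ends = starts + window
    n_c = stats.c[ends] - stats.c[starts]
    n_g = stats.g[ends] - stats.g[starts]
    n_n = stats.n[ends] - stats.n[starts]
    L = window - n_n
    n_cpg = stats.cpg[ends - 1] - stats.cpg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(L > 0, (n_c + n_g) / np.maximum(L, 1), 0.0)
        prod = n_c * n_g
        oe = np.where(prod > 0, n_cpg * L / np.maximum(prod, 1), 0.0)
    passing = (gc > gc_min) & (oe > oe_min) & (L > 0)
    # merge overlapping/adjacent passing windows
    merged: list[list[int]] = []
    for s in starts[passing]:
        e = int(s) + window
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([int(s), e])
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    base_score = np.where(
        (arr == ord("C")) | (arr == ord("G")), 1.0 - gc_min,
        np.where(arr == ord("N"), 0.0, -gc_min),
    )
    islands: list[CpGIsland] = []
    for start, end in merged:
        start, end = _max_scoring_subsegment(base_score, start, end)
        interval = _rescore_or_trim(stats, start, end, min_len, gc_min, oe_min)
        if interval is not None:
            s, e, g, o = interval
            islands.append(CpGIsland(chrom, s, e, g, o))
    return islands


def _max_scoring_subsegment(score: np.ndarray, start: int, end: int) -> tuple[int, int]:
    """Refine a candidate's boundaries to its maximal GC-scoring subsegment.

    The span-union of passing windows overhangs the true GC-rich run by up
    to a window length on each side; within the candidate, the subsegment
    maximizing the sum of per-base scores (is_GC - gc_min) localizes the
    boundary to within a few bases (Kadane's algorithm).
    """
    best_sum = -np.inf
    best = (start, end)
    run_sum = 0.0
    run_start = start
    for i in range(start, end):
        if run_sum <= 0:
            run_sum = 0.0
            run_start = i
        run_sum += score[i]
        if run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, i + 1)
    return best


def _rescore_or_trim(stats, start, end, min_len, gc_min, oe_min):
    """Re-score a merged interval; trim greedily from the ends until it passes."""
    while end - start >= min_len:
        gc, oe = stats.score(start, end)
        if _passes(gc, oe, gc_min, oe_min):
            return (start, end, gc, oe)
        # drop the end base whose removal leaves the better-scoring interval
        gl, ol = stats.score(start + 1, end)
        gr, or_ = stats.score(start, end - 1)
        if (min(gl - gc_min, ol - oe_min)) >= (min(gr - gc_min, or_ - oe_min)):
            start += 1
        else:
            end -= 1
    return None
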