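"""Piecewise-constant segmentation of log R ratio tracks.

A breakpoint is placed between every adjacent probe pair and breakpoints are
then removed by backward elimination: at each step the breakpoint with the
smallest t-like score

    t = |mean_left - mean_right| / (sigma * sqrt(1/n_left + 1/n_right))

is deleted (means and counts taken over the two segments currently flanking
it, recomputed after every deletion) until every surviving breakpoint scores
above the threshold T.  A second pass merges away segments shorter than the
minimum probe count by deleting their lower-scoring flanking breakpoint.
The defaults (T = 10, at least 50 consecutive probes per segment) are the
standard operating point for Illumina tumor arrays.

The noise scale sigma is estimated robustly from successive differences
(MAD / (0.6745 * sqrt(2))) and shared across a sample as the median of the
per-chromosome estimates, which stabilizes scores on short chromosomes.

Ties in the minimum score are broken by leftmost genomic position, so the
output is deterministic.  Missing LRR values are dropped before
segmentation with index bookkeeping, and segments always partition the
probe sequence of each chromosome.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .array_io import ProbeMap, SampleIntensities, ValidationError

__all__ = [
    "SegmentationParams",
    "RawSegment",
    "estimate_noise",
    "segment_chromosome",
    "segment_sample",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Backward-elimination parameters.

    T            breakpoint-score threshold; a breakpoint survives only if
                 its t-score strictly exceeds T
    min_probes   minimum probes per final segment (unless the chromosome
                 itself is shorter)
    sigma_floor  lower bound on the noise estimate, guards zero-variance
                 input
    """

    T: float = 10.0
    min_probes: int = 50
    sigma_floor: float = 1e-6

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("T must be nonnegative")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not self.sigma_floor > 0:
            raise ValueError("sigma_floor must be positive")


@dataclass
class RawSegment:
    """A maximal run of probes with a common mean LRR.

    Indices are inclusive positions into the chromosome's probe vector;
    coordinates are 1-based inclusive base pairs.
    """

    sample_id: str
    chromosome: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    n_probes: int
    mean_lrr: float


def estimate_noise(lrr, sigma_floor: float = 1e-6) -> float:
    """Robust noise SD from successive differences.

    sigma = MAD(diff) / (0.6745 * sqrt(2)); the sqrt(2) removes the variance
    doubling of differencing and the MAD constant makes the estimate
    consistent for Gaussian noise while ignoring step changes and outliers.
    """
    x = np.asarray(lrr, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValidationError("need at least 2 non-missing values to estimate noise")
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return max(float(mad) / (0.6745 * math.sqrt(2.0)), sigma_floor)


def _breakpoint_score(csum, left_start, bp, right_end, sigma) -> float:
    # segments are [left_start, bp] and [bp+1, right_end] (inclusive indices)
    n_l = bp - left_start + 1
    n_r = right_end - bp
    mean_l = (csum[bp + 1] - csum[left_start]) / n_l
    mean_r = (csum[right_end + 1] - csum[bp + 1]) / n_r
    return abs(mean_l - mean_r) / (sigma * math.sqrt(1.0 / n_l + 1.0 / n_r))


def _backward_eliminate(values: np.ndarray, params: SegmentationParams, sigma: float):
    """Return sorted inclusive (start, end) index pairs partitioning values."""
    n = len(values)
    if n < 2:
        return [(0, n - 1)] if n else []

    csum = np.concatenate([[0.0], np.cumsum(values)])
    # doubly linked list over breakpoint ids; breakpoint b sits after probe b
    left = {b: b - 1 for b in range(n - 1)}   # previous live breakpoint (-1 = chrom start)
    right = {b: b + 1 for b in range(n - 1)}  # next live breakpoint (n-1 = chrom end)
    left[0] = -1
    right[n - 2] = n - 1

    def seg_bounds(b):
        l = left[b]
        r = right[b]
        return (l + 1 if l >= 0 else 0), (r if r <= n - 1 else n - 1)

    def score(b):
        l = left[b]
        r = right[b]
        left_start = l + 1
        right_end = r
        return _breakpoint_score(csum, left_start, b, right_end, sigma)

    heap: list[tuple[float, int, int]] = []
    version = {b: 0 for b in left}
    for b in left:
        heapq.heappush(heap, (score(b), b, 0))

    alive = set(left)

    def delete(b):
        alive.discard(b)
        l, r = left[b], right[b]
        if l >= 0:
            right[l] = r
            version[l] += 1
            heapq.heappush(heap, (score(l), l, version[l]))
        if r <= n - 2:
            left[r] = l
            version[r] += 1
            heapq.heappush(heap, (score(r), r, version[r]))
        del left[b], right[b]

    # phase 1: remove weakest breakpoints until all exceed T
    while heap:
        s, b, ver = heapq.heappop(heap)
        if b not in alive or version[b] != ver:
            continue
        if s > params.T:
            heapq.heappush(heap, (s, b, ver))
            break
        delete(b)

    # phase 2: merge away short segments, weakest flanking breakpoint first
    def segments():
        bps = sorted(alive)
        bounds = []
        start = 0
        for b in bps:
            bounds.append((start, b))
            start = b + 1
        bounds.append((start, n - 1))
        return bounds

    while True:
        bounds = segments()
        if len(bounds) == 1:
            break
        short = [(s, e) for s, e in bounds if e - s + 1 < params.min_probes]
        if not short:
            break
        # delete the globally weakest breakpoint flanking any short segment;
        # leftmost position breaks ties -> deterministic
        candidates = set()
        for s, e in short:
            if s - 1 >= 0 and (s - 1) in alive:
                candidates.add(s - 1)
            if e in alive:
                candidates.add(e)
        best = min(candidates, key=lambda b: (score(b), b))
        delete(best)

    return segments()


def segment_chromosome(
    lrr,
    positions,
    params: SegmentationParams | None = None,
    sigma: float | None = None,
    chromosome: str = ".",
    sample_id: str = ".",
) -> list[RawSegment]:
    """Segment one chromosome's LRR track into mean-constant runs.

    Missing values are excluded from means and scores but remain inside the
    segment whose non-missing neighbours flank them, so the output still
    partitions every probe.  A chromosome with fewer than two usable probes
    yields a single trivial segment.
    """
    params = params or SegmentationParams()
    lrr = np.asarray(lrr, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if lrr.shape != positions.shape:
        raise ValidationError("lrr and positions must have equal length")
    n = len(lrr)
    if n == 0:
        return []

    finite = ~np.isnan(lrr)
    obs_idx = np.flatnonzero(finite)

    def make(start, end):
        vals = lrr[start : end + 1]
        vals = vals[~np.isnan(vals)]
        mean = float(np.mean(vals)) if len(vals) else float("nan")
        return RawSegment(
            sample_id=sample_id,
            chromosome=chromosome,
            start_index=int(start),
            end_index=int(end),
            start_bp=int(positions[start]),
            end_bp=int(positions[end]),
            n_probes=int(end - start + 1),
            mean_lrr=mean,
        )

    if len(obs_idx) < 2:
        return [make(0, n - 1)]

    if sigma is None:
        sigma = estimate_noise(lrr[obs_idx], params.sigma_floor)
    sigma = max(sigma, params.sigma_floor)

    bounds = _backward_eliminate(lrr[obs_idx], params, sigma)

    # map observed-index bounds back to full probe indices; stretch the first
    # and last segment to the chromosome ends so missing flanks are covered
    segs = []
    for k, (s, e) in enumerate(bounds):
        start = obs_idx[s] if k > 0 else 0
        end = obs_idx[e] if k < len(bounds) - 1 else n - 1
        if k > 0:
            # absorb missing probes between segments into the right segment
            prev_end = obs_idx[bounds[k - 1][1]]
            start = prev_end + 1
        segs.append(make(start, end))
    return segs


def segment_sample(
    sample: SampleIntensities,
    probe_map: ProbeMap,
    params: SegmentationParams | None = None,
) -> list[RawSegment]:
    """Segment every chromosome of one sample; output in genome order.

    A single noise scale per sample (median of per-chromosome estimates) is
    used so scores are comparable across chromosomes.
    """
    params = params or SegmentationParams()
    if len(sample) != len(probe_map):
        raise ValidationError(
            f"sample {sample.sample_id}: {len(sample)} values for "
            f"{len(probe_map)} probes"
        )
    slices = probe_map.chrom_slices()
    sigmas = []
    for sl in slices.values():
        vals = sample.lrr[sl]
        if np.sum(~np.isnan(vals)) >= 2:
            sigmas.append(estimate_noise(vals, params.sigma_floor))
    sigma = float(np.median(sigmas)) if sigmas else params.sigma_floor

    out: list[RawSegment] = []
    for chrom, sl in slices.items():
        segs = segment_chromosome(
            sample.lrr[sl],
            probe_map.positions[sl],
            params,
            sigma=sigma,
            chromosome=chrom,
            sample_id=sample.sample_id,
        )
        offset = sl.start
        for s in segs:
            s.start_index += offset
            s.end_index += offset
        out.extend(segs)
    return out
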