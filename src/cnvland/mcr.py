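"""Recurrent minimal common regions (MCRs) from cohort segment calls.

The approach follows the GISTIC recipe.  Each marker (probe) gets, per
sample, a signed amplitude: the mean LRR of the covering segment when that
segment is a gain at or above +0.1 (or a loss at or below -0.1), zero
otherwise.  The marker G-score in each direction is the sum of carrier
amplitudes (frequency x average amplitude x n).  Significance comes from a
permutation null that independently permutes each sample's amplitudes
across the genome, preserving per-sample amplitude distributions; empirical
p-values are pooled over markers and permutations and converted to
q-values by Benjamini-Hochberg within each direction.

Peaks are extracted by peel-off: take the genome-wide maximal-G significant
marker, define the region as the intersection of the carrier segments
covering it (a literal minimal common region), remove those samples'
contributions on that chromosome, and repeat until nothing is significant.

Carrier status for a finished region requires segments of the matching
state to cover at least half of the region's span; region frequency is the
carrier percentage of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .array_io import CytobandMap, ProbeMap, ValidationError
from .state_calling import SegmentCall

__all__ = [
    "McrParams",
    "MCRRegion",
    "marker_matrix",
    "g_scores",
    "permutation_q",
    "peel_off",
    "carriers",
    "carrier_matrix",
    "call_mcrs",
]


@dataclass(frozen=True)
class McrParams:
    """GISTIC-style parameters.

    amp_lrr_threshold / del_lrr_threshold   segment-mean cutoffs defining an
        amplification/deletion contribution (+0.1 / -0.1)
    q_cutoff          markers with q below this are significant (0.01)
    n_permutations    permutations for the empirical null
    confidence        reserved boundary-confidence level (recorded, unused:
                      boundaries here are the exact carrier intersection)
    carrier_overlap_fraction   minimum covered fraction of a region's span
                               for a sample to count as a carrier
    seed              permutation RNG seed
    """

    amp_lrr_threshold: float = 0.1
    del_lrr_threshold: float = -0.1
    q_cutoff: float = 0.01
    n_permutations: int = 1000
    confidence: float = 0.99
    carrier_overlap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.amp_lrr_threshold <= 0 or self.del_lrr_threshold >= 0:
            raise ValueError("amplification threshold must be > 0 and deletion < 0")
        if not (0 < self.q_cutoff < 1):
            raise ValueError("q_cutoff must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class MCRRegion:
    """A recurrent gain or loss region (1-based inclusive boundaries)."""

    cytoband: str
    type: str
    chromosome: str
    start_bp: int
    end_bp: int
    size_kb: float
    g_score: float
    q_value: float
    frequency_percent: float
    carrier_ids: list[str] = field(default_factory=list)


def _sorted_sample_ids(cohort_calls: dict[str, Sequence[SegmentCall]]) -> list[str]:
    return sorted(cohort_calls)


def marker_matrix(
    cohort_calls: dict[str, Sequence[SegmentCall]],
    probe_map: ProbeMap,
    params: McrParams | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Signed per-marker amplitudes, one row per sample (sorted by id).

    Amplitude at a marker is the covering segment's mean LRR when the
    segment is a gain with mean >= amp threshold or a loss with mean <= del
    threshold, zero otherwise.  Every marker must be covered by exactly one
    segment per sample (partition violation is an error).
    """
    params = params or McrParams()
    ids = _sorted_sample_ids(cohort_calls)
    n_markers = len(probe_map)
    A = np.zeros((len(ids), n_markers))
    for row, sid in enumerate(ids):
        covered = np.zeros(n_markers, dtype=bool)
        for seg in cohort_calls[sid]:
            sl = slice(seg.start_index, seg.end_index + 1)
            if covered[sl].any():
                raise ValidationError(f"sample {sid}: overlapping segments at markers")
            covered[sl] = True
            if seg.state == "gain" and seg.mean_lrr >= params.amp_lrr_threshold:
                A[row, sl] = seg.mean_lrr
            elif seg.state == "loss" and seg.mean_lrr <= params.del_lrr_threshold:
                A[row, sl] = seg.mean_lrr
        if not covered.all():
            raise ValidationError(
                f"sample {sid}: {int((~covered).sum())} markers not covered by any segment"
            )
    return A, ids


def g_scores(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker G-scores: sum of positive amplitudes (gain) and of
    absolute negative amplitudes (loss), over samples."""
    pos = np.where(matrix > 0, matrix, 0.0)
    neg = np.where(matrix < 0, -matrix, 0.0)
    return pos.sum(axis=0), neg.sum(axis=0)


@dataclass
class PermutationNull:
    """Sorted pooled null G-scores per direction (markers x permutations)."""

    sorted_gain: np.ndarray
    sorted_loss: np.ndarray

    def p_values(self, g_obs: np.ndarray, direction: str) -> np.ndarray:
        null = self.sorted_gain if direction == "gain" else self.sorted_loss
        # fraction of pooled null >= observed; null is sorted ascending
        n_ge = len(null) - np.searchsorted(null, g_obs, side="left")
        return n_ge / len(null)


def build_null(matrix: np.ndarray, params: McrParams) -> PermutationNull:
    """Permutation null: each sample's amplitudes shuffled across the genome
    independently, G recomputed, pooled over markers and permutations."""
    rng = np.random.default_rng(params.seed)
    n_perm = params.n_permutations
    n_markers = matrix.shape[1]
    null_gain = np.empty((n_perm, n_markers), dtype=np.float32)
    null_loss = np.empty((n_perm, n_markers), dtype=np.float32)
    for i in range(n_perm):
        perm = rng.permuted(matrix, axis=1)
        g, l = g_scores(perm)
        null_gain[i] = g
        null_loss[i] = l
    return PermutationNull(np.sort(null_gain.ravel()), np.sort(null_loss.ravel()))


def _bh(p: np.ndarray) -> np.ndarray:
    return false_discovery_control(p, method="bh")


def permutation_q(
    matrix: np.ndarray,
    params: McrParams | None = None,
    null: PermutationNull | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg q-values per marker for gains and losses."""
    params = params or McrParams()
    if null is None:
        null = build_null(matrix, params)
    g_gain, g_loss = g_scores(matrix)
    q_gain = _bh(null.p_values(g_gain, "gain"))
    q_loss = _bh(null.p_values(g_loss, "loss"))
    return q_gain, q_loss


def _covering_segment(calls: Sequence[SegmentCall], marker_index: int) -> SegmentCall | None:
    for seg in calls:
        if seg.start_index <= marker_index <= seg.end_index:
            return seg
    return None


def peel_off(
    matrix: np.ndarray,
    sample_ids: list[str],
    cohort_calls: dict[str, Sequence[SegmentCall]],
    probe_map: ProbeMap,
    params: McrParams | None = None,
    null: PermutationNull | None = None,
    cytobands: CytobandMap | None = None,
) -> list[MCRRegion]:
    """Iterative peak extraction per direction.

    Each iteration takes the maximal-G marker with q below the cutoff, sets
    the region to the intersection of the carrier segments covering it, and
    zeroes those samples' amplitudes across the peak's chromosome before
    re-scoring.  Terminates because every iteration removes at least one
    sample contribution.
    """
    params = params or McrParams()
    if null is None:
        null = build_null(matrix, params)
    slices = probe_map.chrom_slices()
    marker_chrom = probe_map.chromosomes

    regions: list[MCRRegion] = []
    for direction, sign in (("gain", 1.0), ("loss", -1.0)):
        A = matrix.copy()
        for _ in range(10000):  # hard bound; terminates long before
            g_gain, g_loss = g_scores(A)
            g = g_gain if direction == "gain" else g_loss
            q = _bh(null.p_values(g, direction))
            sig = q < params.q_cutoff
            if not sig.any():
                break
            # genome-wide maximal-G significant marker; leftmost tie-break
            masked = np.where(sig, g, -np.inf)
            peak = int(np.argmax(masked))
            chrom = marker_chrom[peak]
            carrier_rows = np.flatnonzero(sign * A[:, peak] > 0)
            if len(carrier_rows) == 0:
                raise RuntimeError("significant peak with no carriers (internal error)")
            # minimal common region: intersection of carrier segments at peak
            start_bp = -np.inf
            end_bp = np.inf
            for r in carrier_rows:
                seg = _covering_segment(cohort_calls[sample_ids[r]], peak)
                if seg is None or seg.state != direction:
                    raise RuntimeError("carrier without covering segment (internal error)")
                start_bp = max(start_bp, seg.start_bp)
                end_bp = min(end_bp, seg.end_bp)
            start_bp, end_bp = int(start_bp), int(end_bp)
            if end_bp < start_bp:
                raise RuntimeError("empty carrier intersection (internal error)")
            pos = probe_map.positions[peak]
            label = (
                cytobands.label(chrom, int(pos)) if cytobands is not None
                else f"chr{chrom}:{start_bp}-{end_bp}"
            )
            regions.append(
                MCRRegion(
                    cytoband=label,
                    type=direction,
                    chromosome=chrom,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    size_kb=(end_bp - start_bp + 1) / 1000.0,
                    g_score=float(g[peak]),
                    q_value=float(q[peak]),
                    frequency_percent=0.0,  # filled from carrier assignment below
                )
            )
            A[carrier_rows, slices[chrom]] = 0.0

    # carrier assignment and frequencies against the full (un-peeled) cohort
    for region in regions:
        status = carriers(region, cohort_calls, params)
        ids = sorted(s for s, st in status.items() if st == region.type)
        region.carrier_ids = ids
        region.frequency_percent = 100.0 * len(ids) / len(cohort_calls)
    regions.sort(key=lambda r: (r.type, -r.g_score))
    return regions


def carriers(
    region: MCRRegion,
    cohort_calls: dict[str, Sequence[SegmentCall]],
    params: McrParams | None = None,
) -> dict[str, str]:
    """Per-sample carrier status {'gain', 'loss', 'none'} for one region.

    A sample carries a state when its segments of that state cover at least
    ``carrier_overlap_fraction`` of the region's bp span; the region's own
    type wins when both states qualify.
    """
    params = params or McrParams()
    span = region.end_bp - region.start_bp + 1
    out: dict[str, str] = {}
    for sid, calls in cohort_calls.items():
        covered = {"gain": 0, "loss": 0}
        for seg in calls:
            if seg.chromosome != region.chromosome or seg.state not in covered:
                continue
            lo = max(seg.start_bp, region.start_bp)
            hi = min(seg.end_bp, region.end_bp)
            if hi >= lo:
                covered[seg.state] += hi - lo + 1
        order = (region.type, "loss" if region.type == "gain" else "gain")
        status = "none"
        for state in order:
            if covered[state] / span >= params.carrier_overlap_fraction:
                status = state
                break
        out[sid] = status
    return out


def carrier_matrix(
    regions: Sequence[MCRRegion],
    cohort_calls: dict[str, Sequence[SegmentCall]],
    params: McrParams | None = None,
) -> pd.DataFrame:
    """Samples x regions status table with values in {'gain','loss','none'}.

    Columns are labelled '<cytoband>:<type>' to keep gain and loss regions
    at one cytoband distinct.
    """
    ids = _sorted_sample_ids(cohort_calls)
    data = {}
    for region in regions:
        status = carriers(region, cohort_calls, params)
        data[f"{region.cytoband}:{region.type}"] = [status[s] for s in ids]
    return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))


def call_mcrs(
    cohort_calls: dict[str, Sequence[SegmentCall]],
    probe_map: ProbeMap,
    params: McrParams | None = None,
    cytobands: CytobandMap | None = None,
) -> list[MCRRegion]:
    """Full MCR pipeline: amplitudes -> null -> peel-off -> carrier stats."""
    params = params or McrParams()
    A, ids = marker_matrix(cohort_calls, probe_map, params)
    null = build_null(A, params)
    return peel_off(A, ids, cohort_calls, probe_map, params, null, cytobands)
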