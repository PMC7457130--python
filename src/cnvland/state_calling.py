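"""Four-state classification of LRR segments: normal / gain / loss / CNNLOH.

States are assigned from a segment's mean LRR and from a sliding-window
loss-of-heterozygosity (LOH) detector on the BAF track:

* gain   iff mean LRR >= 0.075
* loss   iff mean LRR <= -0.075
* otherwise |LRR| < 0.075 and the call is CNNLOH when the segment has lost
  heterozygosity (copy-neutral LOH), normal when heterozygosity is retained.

LOH detection slides a window of 100 consecutive informative SNPs (step 1,
per chromosome); a window represents LOH when strictly more than 80% of its
SNPs appear homozygous (BAF <= 0.1 or BAF >= 0.9).  A probe is LOH-flagged
when it lies in at least one LOH window, and a segment is considered to
have lost heterozygosity when at least half of its informative SNPs are
flagged.  "Informative" means the probe has a non-missing BAF; with
tumor-only arrays there are no matched normals to restrict to germline
heterozygous sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .array_io import ProbeMap, SampleIntensities, ValidationError
from .segmentation import RawSegment

__all__ = [
    "LohParams",
    "SegmentCall",
    "STATES",
    "loh_windows",
    "classify_segment",
    "call_sample",
]

STATES = ("normal", "gain", "loss", "cnnloh")

GAIN_LRR = 0.075
LOSS_LRR = -0.075


@dataclass(frozen=True)
class LohParams:
    """LOH sliding-window and segment-classification parameters.

    window_snps           informative SNPs per sliding window
    hom_window_fraction   a window is LOH iff its homozygous fraction is
                          STRICTLY greater than this
    hom_baf_low/high      BAF at or outside [low, high] counts as
                          homozygous-appearing
    segment_loh_fraction  segment calls CNNLOH iff at least this fraction of
                          its informative SNPs is LOH-flagged
    gain_lrr / loss_lrr   inclusive mean-LRR thresholds for gain and loss
    """

    window_snps: int = 100
    hom_window_fraction: float = 0.8
    hom_baf_low: float = 0.1
    hom_baf_high: float = 0.9
    segment_loh_fraction: float = 0.5
    gain_lrr: float = GAIN_LRR
    loss_lrr: float = LOSS_LRR

    def __post_init__(self):
        if not (0 < self.hom_window_fraction < 1):
            raise ValueError("hom_window_fraction must be in (0, 1)")
        if not (0 < self.segment_loh_fraction < 1):
            raise ValueError("segment_loh_fraction must be in (0, 1)")
        if not self.hom_baf_low < self.hom_baf_high:
            raise ValueError("hom_baf_low must be below hom_baf_high")
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")


@dataclass
class SegmentCall(RawSegment):
    """A RawSegment plus its alteration state and LOH evidence."""

    state: str = "normal"
    loh_fraction: float = 0.0

    @property
    def is_cnv(self) -> bool:
        return self.state in ("gain", "loss")


def loh_windows(baf, params: LohParams | None = None) -> np.ndarray:
    """Boolean LOH flag per probe from the sliding-window homozygosity test.

    Windows span ``window_snps`` consecutive informative SNPs; a probe is
    flagged iff it lies inside at least one window whose homozygous fraction
    strictly exceeds ``hom_window_fraction``.  Sequences with fewer
    informative SNPs than one window yield an all-false mask; the mask is
    symmetric under BAF mirroring (b -> 1-b).
    """
    params = params or LohParams()
    baf = np.asarray(baf, dtype=float)
    n = len(baf)
    mask = np.zeros(n, dtype=bool)
    info_idx = np.flatnonzero(~np.isnan(baf))
    w = params.window_snps
    if len(info_idx) < w:
        return mask
    b = baf[info_idx]
    hom = (b <= params.hom_baf_low) | (b >= params.hom_baf_high)
    # rolling count of homozygous SNPs over windows of w informative probes
    csum = np.concatenate([[0], np.cumsum(hom)])
    counts = csum[w:] - csum[:-w]  # counts[j] = hom SNPs in info window [j, j+w)
    is_loh = counts > params.hom_window_fraction * w
    # a probe (informative index k) is flagged iff any window j <= k <= j+w-1 is LOH
    run_csum = np.concatenate([[0], np.cumsum(is_loh)])
    k = np.arange(len(info_idx))
    j_lo = np.maximum(0, k - w + 1)
    j_hi = np.minimum(len(is_loh) - 1, k)
    flag = (run_csum[j_hi + 1] - run_csum[j_lo]) > 0
    mask[info_idx] = flag
    return mask


def classify_segment(mean_lrr: float, loh_fraction: float, params: LohParams | None = None) -> str:
    """Map (mean LRR, LOH fraction) to one of the four alteration states.

    Gain/loss thresholds are inclusive; in the copy-neutral band the call is
    CNNLOH when loh_fraction >= segment_loh_fraction, otherwise normal.  The
    four states partition the plane: exactly one state for every input.
    """
    params = params or LohParams()
    if not np.isfinite(mean_lrr):
        raise ValidationError(f"segment mean LRR is not finite: {mean_lrr}")
    if mean_lrr >= params.gain_lrr:
        return "gain"
    if mean_lrr <= params.loss_lrr:
        return "loss"
    if loh_fraction >= params.segment_loh_fraction:
        return "cnnloh"
    return "normal"


def call_sample(
    segments: Sequence[RawSegment],
    sample: SampleIntensities,
    params: LohParams | None = None,
    probe_map: ProbeMap | None = None,
) -> list[SegmentCall]:
    """Attach an LOH fraction and state to every segment of one sample.

    The LOH mask is computed per chromosome over the sample's BAF track
    (windows never straddle chromosomes); each segment's loh_fraction is the
    flagged share of its informative SNPs.  Gains and losses among the
    returned calls constitute the sample's CNV set.
    """
    params = params or LohParams()
    baf = sample.baf
    if probe_map is not None:
        mask = np.zeros(len(baf), dtype=bool)
        for _, sl in probe_map.chrom_slices().items():
            mask[sl] = loh_windows(baf[sl], params)
    else:
        # fall back to per-segment chromosome grouping by index ranges
        mask = np.zeros(len(baf), dtype=bool)
        by_chrom: dict[str, list[RawSegment]] = {}
        for seg in segments:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in by_chrom.items():
            lo = min(s.start_index for s in segs)
            hi = max(s.end_index for s in segs)
            mask[lo : hi + 1] = loh_windows(baf[lo : hi + 1], params)

    calls = []
    for seg in segments:
        b = baf[seg.start_index : seg.end_index + 1]
        m = mask[seg.start_index : seg.end_index + 1]
        informative = ~np.isnan(b)
        n_info = int(np.sum(informative))
        loh_fraction = float(np.sum(m[informative]) / n_info) if n_info else 0.0
        state = classify_segment(seg.mean_lrr, loh_fraction, params)
        calls.append(
            SegmentCall(
                sample_id=seg.sample_id,
                chromosome=seg.chromosome,
                start_index=seg.start_index,
                end_index=seg.end_index,
                start_bp=seg.start_bp,
                end_bp=seg.end_bp,
                n_probes=seg.n_probes,
                mean_lrr=seg.mean_lrr,
                state=state,
                loh_fraction=loh_fraction,
            )
        )
    return calls
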