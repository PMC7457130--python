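"""Per-sample genome-instability metrics.

A sample's CNV set is its gain and loss segment calls (CNNLOH is tracked
separately and never counted as a CNV).  Burden metrics are CNV counts,
counts per size bin, and altered-SNP fractions: the number of SNPs under a
given alteration divided by the total SNPs in the chromosome or genome.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .array_io import ProbeMap, ValidationError
from .state_calling import SegmentCall

__all__ = ["SIZE_BINS", "size_bin", "altered_fraction", "burden_table"]

# half-open size bins in bp: [1, 500 kb), [500 kb, 1 Mb), [1 Mb, 5 Mb), [5 Mb, inf)
SIZE_BINS = ("<500 kb", "500-1,000 kb", "1-5 Mb", ">5 Mb")
_BIN_EDGES = (500_000, 1_000_000, 5_000_000)


def size_bin(segment) -> str:
    """Size-bin label for a segment; span = end_bp - start_bp + 1."""
    span = segment.end_bp - segment.start_bp + 1
    if span <= 0:
        raise ValidationError(
            f"segment chr{segment.chromosome}:{segment.start_bp}-{segment.end_bp} "
            "has nonpositive span"
        )
    if span < _BIN_EDGES[0]:
        return SIZE_BINS[0]
    if span < _BIN_EDGES[1]:
        return SIZE_BINS[1]
    if span < _BIN_EDGES[2]:
        return SIZE_BINS[2]
    return SIZE_BINS[3]


def altered_fraction(
    calls: Sequence[SegmentCall],
    probe_map: ProbeMap,
    scope: str = "genome",
    state: str = "loss",
) -> float:
    """Fraction of SNPs under segments of ``state`` within ``scope``.

    scope is 'genome' or a chromosome name; the denominator is the total
    number of probes in that scope.
    """
    if scope == "genome":
        denom = len(probe_map)
        in_scope = lambda c: True  # noqa: E731
    else:
        denom = probe_map.n_probes_chrom(scope)
        in_scope = lambda c: c.chromosome == scope  # noqa: E731
    if denom == 0:
        raise ValidationError(f"scope {scope!r} contains no probes")
    count = sum(c.n_probes for c in calls if c.state == state and in_scope(c))
    return count / denom


def burden_table(
    cohort_calls: dict[str, Sequence[SegmentCall]],
    probe_map: ProbeMap | None = None,
) -> pd.DataFrame:
    """One burden row per sample: CNV counts, size-bin counts, altered fractions.

    ``cohort_calls`` maps sample id -> that sample's segment calls.  Rows are
    ordered by sample id; altered fractions require a probe map and are
    omitted without one.
    """
    ids = list(cohort_calls)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in cohort")
    rows = []
    for sid in sorted(ids):
        calls = cohort_calls[sid]
        cnvs = [c for c in calls if c.state in ("gain", "loss")]
        row = {
            "sample_id": sid,
            "n_cnvs": len(cnvs),
            "n_gains": sum(1 for c in cnvs if c.state == "gain"),
            "n_losses": sum(1 for c in cnvs if c.state == "loss"),
        }
        bins = {b: 0 for b in SIZE_BINS}
        for c in cnvs:
            bins[size_bin(c)] += 1
        row.update({f"n_{b}": n for b, n in bins.items()})
        if probe_map is not None:
            for state in ("gain", "loss", "cnnloh"):
                row[f"frac_{state}"] = altered_fraction(calls, probe_map, "genome", state)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        cols = ["sample_id", "n_cnvs", "n_gains", "n_losses"]
        cols += [f"n_{b}" for b in SIZE_BINS]
        if probe_map is not None:
            cols += [f"frac_{s}" for s in ("gain", "loss", "cnnloh")]
        df = pd.DataFrame(columns=cols)
    return df.set_index("sample_id")


def chromosome_fractions(
    calls: Sequence[SegmentCall], probe_map: ProbeMap
) -> pd.DataFrame:
    """Per-chromosome altered fractions (gain/loss/cnnloh) for one sample."""
    rows = []
    for chrom in probe_map.chrom_order:
        rows.append(
            {
                "chromosome": chrom,
                **{
                    f"frac_{s}": altered_fraction(calls, probe_map, chrom, s)
                    for s in ("gain", "loss", "cnnloh")
                },
            }
        )
    return pd.DataFrame(rows).set_index("chromosome")
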