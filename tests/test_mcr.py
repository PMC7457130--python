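"""GISTIC-style recurrent-region caller: G-scores, permutation q, peel-off."""

import numpy as np
import pytest

from cnvland.array_io import ProbeMap, ValidationError
from cnvland.mcr import (
    MCRRegion,
    McrParams,
    build_null,
    call_mcrs,
    carrier_matrix,
    carriers,
    g_scores,
    marker_matrix,
    peel_off,
    permutation_q,
)
from cnvland.state_calling import SegmentCall


def _probe_map(n_per_chrom=100, chroms=("1",)):
    ids, cs, ps = [], [], []
    for c in chroms:
        for i in range(n_per_chrom):
            ids.append(f"{c}_{i}")
            cs.append(c)
            ps.append((i + 1) * 100_000)
    return ProbeMap(np.array(ids, object), np.array(cs, object), np.array(ps))


def _seg(sample_id, chrom, lo, hi, state, mean_lrr, pm):
    sl = pm.chrom_slices()[chrom]
    return SegmentCall(
        sample_id=sample_id, chromosome=chrom,
        start_index=sl.start + lo, end_index=sl.start + hi,
        start_bp=int(pm.positions[sl.start + lo]),
        end_bp=int(pm.positions[sl.start + hi]),
        n_probes=hi - lo + 1, mean_lrr=mean_lrr, state=state, loh_fraction=0.0,
    )


def _cohort_with_planted_loss(pm, n_samples=100, n_carriers=40, lo=40, hi=59,
                              amplitude=-0.4, chrom="1"):
    """Carriers share one loss segment; everyone else is flat normal."""
    cohort = {}
    n = pm.n_probes_chrom(chrom)
    for i in range(n_samples):
        sid = f"S{i:03d}"
        if i < n_carriers:
            cohort[sid] = [
                _seg(sid, chrom, 0, lo - 1, "normal", 0.0, pm),
                _seg(sid, chrom, lo, hi, "loss", amplitude, pm),
                _seg(sid, chrom, hi + 1, n - 1, "normal", 0.0, pm),
            ]
        else:
            cohort[sid] = [_seg(sid, chrom, 0, n - 1, "normal", 0.0, pm)]
        for other in pm.chrom_order:
            if other != chrom:
                m = pm.n_probes_chrom(other)
                cohort[sid].append(_seg(sid, other, 0, m - 1, "normal", 0.0, pm))
    return cohort


class TestMarkerMatrix:
    def test_amplitude_below_threshold_zeroed(self):
        pm = _probe_map(10)
        cohort = {"S": [_seg("S", "1", 0, 4, "gain", 0.05, pm),
                        _seg("S", "1", 5, 9, "normal", 0.0, pm)]}
        A, ids = marker_matrix(cohort, pm)
        assert ids == ["S"]
        assert np.all(A == 0.0)

    def test_loss_amplitude_carried_through(self):
        pm = _probe_map(10)
        cohort = {"S": [_seg("S", "1", 0, 4, "loss", -0.4, pm),
                        _seg("S", "1", 5, 9, "normal", 0.0, pm)]}
        A, _ = marker_matrix(cohort, pm)
        assert np.all(A[0, :5] == -0.4) and np.all(A[0, 5:] == 0.0)

    def test_partition_violation_rejected(self):
        pm = _probe_map(10)
        cohort = {"S": [_seg("S", "1", 0, 4, "normal", 0.0, pm)]}
        with pytest.raises(ValidationError, match="not covered"):
            marker_matrix(cohort, pm)


class TestGScores:
    def test_additive_over_samples(self):
        A = np.array([[0.2, 0.0], [0.3, -0.1]])
        g, l = g_scores(A)
        assert g[0] == pytest.approx(0.5) and g[1] == 0.0
        assert l[1] == pytest.approx(0.1) and l[0] == 0.0

    def test_uniform_marker_identity(self):
        # G = carrier_count x amplitude = frequency x mean amplitude x n
        n, freq, amp = 50, 0.3, 0.25
        A = np.zeros((n, 1))
        A[: int(n * freq), 0] = amp
        g, _ = g_scores(A)
        assert g[0] == pytest.approx(freq * amp * n)


class TestPermutationQ:
    def test_all_zero_matrix_all_q_one(self):
        A = np.zeros((10, 50))
        qg, ql = permutation_q(A, McrParams(n_permutations=100, seed=1))
        assert np.all(qg == 1.0) and np.all(ql == 1.0)

    def test_planted_loss_significant_background_not(self):
        """Loss in 40% of 100 samples over 200 of 2,000 markers: q < 0.01
        inside, q > 0.1 for >= 95% of background markers."""
        rng = np.random.default_rng(42)
        n_s, n_m = 100, 2000
        A = np.zeros((n_s, n_m))
        A[:40, 900:1100] = -0.4
        # mild scattered background alterations
        for i in range(n_s):
            start = rng.integers(0, n_m - 20)
            A[i, start : start + 20] = -0.15
        params = McrParams(n_permutations=200, seed=7)
        _, ql = permutation_q(A, params)
        assert np.all(ql[900:1100] < 0.01)
        background = np.r_[ql[:900], ql[1100:]]
        assert np.mean(background > 0.1) >= 0.95

    def test_doubling_carriers_never_raises_q_at_planted_markers(self):
        n_m = 500
        base = np.zeros((60, n_m))
        base[:12, 200:240] = -0.4
        double = base.copy()
        double[12:24, 200:240] = -0.4
        params = McrParams(n_permutations=200, seed=3)
        _, q1 = permutation_q(base, params)
        _, q2 = permutation_q(double, params)
        assert np.all(q2[200:240] <= q1[200:240])


class TestPeelOff:
    def test_single_planted_region_single_mcr(self):
        pm = _probe_map(100)
        cohort = _cohort_with_planted_loss(pm, lo=40, hi=59)
        params = McrParams(n_permutations=200, seed=5)
        regions = call_mcrs(cohort, pm, params)
        losses = [r for r in regions if r.type == "loss"]
        assert len(losses) == 1
        r = losses[0]
        assert r.start_bp == int(pm.positions[40])
        assert r.end_bp == int(pm.positions[59])
        assert r.q_value < 0.01
        assert r.frequency_percent == pytest.approx(40.0)

    def test_two_disjoint_regions_one_chromosome(self):
        pm = _probe_map(1000)
        cohort = {}
        for i in range(60):
            sid = f"S{i:03d}"
            segs = []
            cursor = 0
            if i < 25:  # region A carriers
                segs += [_seg(sid, "1", 0, 99, "normal", 0.0, pm),
                         _seg(sid, "1", 100, 139, "loss", -0.4, pm)]
                cursor = 140
            if 15 <= i < 45:  # region B carriers (overlapping membership)
                segs += [_seg(sid, "1", cursor, 599, "normal", 0.0, pm),
                         _seg(sid, "1", 600, 659, "loss", -0.4, pm)]
                cursor = 660
            segs += [_seg(sid, "1", cursor, 999, "normal", 0.0, pm)]
            cohort[sid] = segs
        params = McrParams(n_permutations=200, seed=6)
        regions = [r for r in call_mcrs(cohort, pm, params) if r.type == "loss"]
        assert len(regions) == 2
        starts = sorted(r.start_bp for r in regions)
        assert starts == [int(pm.positions[100]), int(pm.positions[600])]

    def test_no_significant_markers_empty_list(self):
        pm = _probe_map(60)
        cohort = {f"S{i}": [_seg(f"S{i}", "1", 0, 59, "normal", 0.0, pm)]
                  for i in range(20)}
        params = McrParams(n_permutations=100, seed=2)
        assert call_mcrs(cohort, pm, params) == []


class TestCarriers:
    def _region(self, pm, lo=40, hi=59):
        return MCRRegion(
            cytoband="x", type="loss", chromosome="1",
            start_bp=int(pm.positions[lo]), end_bp=int(pm.positions[hi]),
            size_kb=0.0, g_score=0.0, q_value=0.0, frequency_percent=0.0,
        )

    def test_full_overlap_is_carrier(self):
        pm = _probe_map(100)
        cohort = _cohort_with_planted_loss(pm, n_samples=3, n_carriers=1)
        status = carriers(self._region(pm), cohort)
        assert status["S000"] == "loss"
        assert status["S001"] == "none"

    def test_forty_percent_overlap_is_not_carrier(self):
        pm = _probe_map(100)
        region = self._region(pm, lo=40, hi=59)  # spans positions 41e5..60e5
        span = region.end_bp - region.start_bp + 1
        # loss covering only 40% of the region's span
        hi = 40 + int(0.4 * 20) - 1
        cohort = {"S": [
            _seg("S", "1", 0, 39, "normal", 0.0, pm),
            _seg("S", "1", 40, hi, "loss", -0.4, pm),
            _seg("S", "1", hi + 1, 99, "normal", 0.0, pm),
        ]}
        covered = cohort["S"][1].end_bp - region.start_bp + 1
        assert covered / span < 0.5
        assert carriers(region, cohort)["S"] == "none"

    def test_published_style_frequency(self):
        # 135 carriers of 383 -> 35.25%
        assert round(100 * 135 / 383, 2) == 35.25

    def test_carrier_matrix_shape_and_values(self):
        pm = _probe_map(100)
        cohort = _cohort_with_planted_loss(pm, n_samples=5, n_carriers=2)
        region = self._region(pm)
        cm = carrier_matrix([region], cohort)
        assert cm.shape == (5, 1)
        assert (cm.iloc[:, 0] == "loss").sum() == 2
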