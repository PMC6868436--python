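"""Phasogram mechanics, smoothing, peak detection and the NRL regression,
validated against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nrlkit as nk
from nrlkit.phasogram import RegionSpec, detect_peaks, fit_nrl, smooth

from conftest import GENOME_SIZE, make_anchor


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_phasogram(dyads, anchors, region, d_max):
    """O(n^2)-per-window reference implementation with explicit loops."""
    counts = np.zeros(d_max + 1, dtype=int)
    for anchor in anchors:
        strand = anchor.strand if anchor.strand in "+-" else "+"
        a, b = region.window
        if region.strand_aware and strand == "-":
            lo, hi = anchor.centre - b, anchor.centre - a
        else:
            lo, hi = anchor.centre + a, anchor.centre + b
        window = [
            p for p in dyads.positions.get(anchor.chrom, []) if lo <= p <= hi
        ]
        for i in range(len(window)):
            for j in range(i + 1, len(window)):
                d = abs(window[i] - window[j])
                if 1 <= d <= d_max:
                    counts[d] += 1
    return counts


def oracle_prominence(values, idx):
    v = values[idx]
    bases = []
    for step in (-1, 1):
        j = idx + step
        lowest = v
        while 0 <= j < len(values) and values[j] <= v:
            lowest = min(lowest, values[j])
            j += step
        bases.append(lowest)
    return v - max(bases)


def oracle_detect_peaks(values, min_first, min_sep, max_peaks,
                        min_prominence_frac=0.03):
    """Enumerate all (plateau-leftmost) maxima, apply the prominence floor
    and the same greedy left-to-right rule."""
    maxima = []
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] == values[i]:
            j += 1
        if i > 0 and j + 1 < len(values):
            if values[i] > values[i - 1] and values[i] > values[j + 1]:
                maxima.append(i)
        i = j + 1
    if not maxima:
        return []
    proms = [oracle_prominence(values, m) for m in maxima]
    floor = min_prominence_frac * max(proms)
    kept = []
    for m, p in zip(maxima, proms):
        pos = m + 1
        if p < floor or pos < min_first:
            continue
        if kept and pos - kept[-1][0] < min_sep:
            if p > kept[-1][1]:  # the more prominent close maximum wins
                kept[-1] = (pos, p)
            continue
        if len(kept) == max_peaks:
            break
        kept.append((pos, p))
    return [(k, pos) for k, (pos, _) in enumerate(kept, 1)]


# ---------------------------------------------------------------------------
# compute_phasogram
# ---------------------------------------------------------------------------


class TestComputePhasogram:
    def test_all_pairs_by_hand(self):
        dm = nk.DyadMap({"chrS": [10150, 10336, 10522]})
        ph = nk.compute_phasogram(dm, [make_anchor(10000, "+")],
                                  RegionSpec((100, 2000)))
        assert ph.counts[186] == 2 and ph.counts[372] == 1
        assert ph.counts.sum() == 3

    def test_minus_anchor_mirror_bookkeeping(self):
        dm = nk.DyadMap({"chrS": [10150, 10336, 10522]})
        minus = make_anchor(10000, "-")
        down = nk.compute_phasogram(dm, [minus], RegionSpec((100, 2000)))
        assert down.counts.sum() == 0
        up = nk.compute_phasogram(dm, [minus], RegionSpec((-2000, -100)))
        assert up.counts[186] == 2 and up.counts[372] == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(55)
        anchors = [
            make_anchor(int(c), rng.choice(["+", "-"]))
            for c in rng.integers(3000, 600_000, size=200)
        ]
        dm = nk.DyadMap({"chrS": rng.integers(0, 600_000, size=6000)})
        region = RegionSpec((100, 2000))
        ph = nk.compute_phasogram(dm, anchors, region)
        assert np.array_equal(
            ph.counts, oracle_phasogram(dm, anchors, region, ph.d_max)
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(56)
        anchors = [make_anchor(int(c)) for c in
                   rng.integers(3000, 50_000, size=20)]
        dm = nk.DyadMap({"chrS": rng.integers(0, 50_000, size=500)})
        region = RegionSpec((100, 2000))
        base = nk.compute_phasogram(dm, anchors, region)
        shift = 7919
        moved = nk.compute_phasogram(
            dm.shifted(shift),
            [make_anchor(a.centre + shift, a.strand) for a in anchors],
            region,
        )
        assert np.array_equal(base.counts, moved.counts)

    def test_empty_anchor_list_gives_empty_phasogram(self):
        dm = nk.DyadMap({"chrS": [1, 2, 3]})
        ph = nk.compute_phasogram(dm, [], RegionSpec((100, 2000)))
        assert ph.counts.sum() == 0 and ph.n_regions == 0


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


class TestSmooth:
    def test_constant_signal_unchanged(self):
        assert np.allclose(smooth(np.full(50, 5), 20), 5.0)

    def test_linear_ramp_unchanged_at_interior(self):
        ramp = np.arange(100, dtype=float)
        sm = smooth(ramp, 20)
        assert np.allclose(sm[10:-10], ramp[10:-10])

    def test_impulse_becomes_unit_plateau(self):
        x = np.zeros(100, dtype=np.int64)
        x[50] = 21
        sm = smooth(x, 20)
        assert np.allclose(sm[40:61], 1.0)
        assert sm[39] == 0 and sm[61] == 0

    @given(st.lists(st.integers(0, 1000), min_size=30, max_size=80))
    def test_mean_of_truncated_window_everywhere(self, data):
        x = np.array(data, dtype=np.int64)
        sm = smooth(x, 20)
        for i in range(len(x)):
            lo, hi = max(0, i - 10), min(len(x), i + 11)
            assert sm[i] == pytest.approx(x[lo:hi].mean())


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------


class TestDetectPeaks:
    def test_forced_maxima(self):
        x = np.zeros(700)
        for pos in (186, 372, 558):
            x[pos - 1] = 10.0
        assert detect_peaks(x) == [(1, 186), (2, 372), (3, 558)]

    def test_plateau_reports_leftmost_index(self):
        x = np.zeros(400)
        x[199] = x[200] = 5.0
        assert detect_peaks(x, min_first=100, min_sep=50) == [(1, 200)]

    def test_matches_exhaustive_oracle_on_noisy_phasogram(self, sim186):
        anchors, dyads, _ = sim186
        ph = nk.compute_phasogram(dyads, anchors, RegionSpec.downstream())
        sm = ph.smoothed(20)
        assert detect_peaks(sm) == oracle_detect_peaks(sm, 100, 120, 10)
        assert detect_peaks(sm, min_sep=40) == oracle_detect_peaks(
            sm, 100, 40, 10
        )

    def test_min_first_excludes_early_maxima(self):
        x = np.zeros(600)
        x[49] = x[299] = x[449] = x[599 - 50] = 3.0
        peaks = detect_peaks(x, min_first=100, min_sep=120)
        assert all(pos >= 100 for _, pos in peaks)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


class TestFitNrl:
    def test_perfect_line(self):
        est = fit_nrl([(1, 185), (2, 370), (3, 555)])
        assert est.nrl_bp == pytest.approx(185.0)
        assert est.intercept == pytest.approx(0.0)
        assert est.p_value == 0.0 and est.passed

    def test_hand_computed_regression_and_f_test(self):
        est = fit_nrl([(1, 190), (2, 375), (3, 545)])
        assert est.nrl_bp == pytest.approx(177.5)
        assert est.intercept == pytest.approx(15.0)
        # F = slope^2 * Sxx / (SSE / (n-2)) with these peaks is 1680.33
        f = (est.nrl_bp / est.slope_sd) ** 2
        assert f == pytest.approx(1680.33, rel=1e-3)
        assert est.p_value == pytest.approx(0.0155, abs=2e-4)
        assert est.passed

    def test_poor_fit_fails_significance(self):
        est = fit_nrl([(1, 100), (2, 90), (3, 350)])
        assert est.nrl_bp == pytest.approx(125.0)
        assert est.p_value > 0.05 and not est.passed

    def test_fewer_than_three_peaks_rejected(self):
        with pytest.raises(ValueError):
            fit_nrl([(1, 186), (2, 372)])


# ---------------------------------------------------------------------------
# composed estimation
# ---------------------------------------------------------------------------


class TestNrlForAnchors:
    def test_zero_jitter_returns_exact_spacing(self):
        # sparse anchors: windows must not reach the neighbouring arrays
        anchors = nk.generate_anchor_sites(50, 800_000, min_spacing=12_000,
                                           seed=61)
        model = nk.ArrayModel(jitter_sd_down=0, jitter_sd_up=0,
                              depth=1, depth_law="fixed", background_rate=0)
        dyads = nk.generate_nucleosome_map(anchors, model, seed=62)
        est = nk.nrl_for_anchors(dyads, anchors, side="downstream")
        assert est.nrl_bp == pytest.approx(186.0, abs=1e-9)
        assert est.p_value == 0.0
        # intercept consistent with the first peak position
        assert est.intercept + est.nrl_bp == pytest.approx(est.peaks[0][1])

    def test_asymmetric_spacings_recovered_per_side(self, sim_asym):
        anchors, dyads, model = sim_asym
        down = nk.nrl_for_anchors(dyads, anchors, side="downstream")
        up = nk.nrl_for_anchors(dyads, anchors, side="upstream")
        assert abs(down.nrl_bp - model.nrl_down) <= 2
        assert abs(up.nrl_bp - model.nrl_up) <= 2

    def test_symmetric_side_matches_downstream_on_balanced_data(self, sim186):
        anchors, dyads, model = sim186
        down = nk.nrl_for_anchors(dyads, anchors, side="downstream")
        sym = nk.nrl_for_anchors(dyads, anchors, side="symmetric")
        assert abs(sym.nrl_bp - down.nrl_bp) <= 1

    def test_start_mode_gives_same_slope_as_dyad_mode(self):
        """Start-to-start distances on fixed-length fragments are dyad
        distances shifted by a constant, so the slope is unchanged."""
        anchors = nk.generate_anchor_sites(300, 1_600_000, seed=63)
        model = nk.ArrayModel()
        dyads = nk.generate_nucleosome_map(anchors, model, 1_600_000, seed=64)
        starts = nk.DyadMap(
            {c: p - 73 for c, p in dyads.positions.items()}, mode="start"
        )
        e1 = nk.nrl_for_anchors(dyads, anchors, side="downstream")
        e2 = nk.nrl_for_anchors(starts, anchors, side="downstream")
        assert abs(e1.nrl_bp - e2.nrl_bp) <= 1


@pytest.fixture(scope="module")
def sharp_anchors():
    return nk.generate_anchor_sites(500, GENOME_SIZE, seed=71)


class TestInterferenceDiagnostic:
    def test_two_sided_arrays_produce_artefact(self, sharp_anchors):
        model = nk.ArrayModel(jitter_sd_down=5, jitter_sd_up=5)
        dyads = nk.generate_nucleosome_map(sharp_anchors, model,
                                           GENOME_SIZE, seed=72)
        rep = nk.interference_diagnostic(dyads, sharp_anchors)
        assert rep.artefact_prone and rep.extra_peaks
        assert rep.spanning is not None and rep.flanking is not None
        assert rep.spanning.nrl_bp < model.nrl_down
        assert abs(rep.flanking.nrl_bp - model.nrl_down) <= 2

    def test_one_sided_arrays_are_silent(self, sharp_anchors):
        model = nk.ArrayModel(jitter_sd_down=5, n_up=0)
        dyads = nk.generate_nucleosome_map(sharp_anchors, model,
                                           GENOME_SIZE, seed=73)
        rep = nk.interference_diagnostic(dyads, sharp_anchors,
                                         spanning=(-1000, 1000))
        assert not rep.artefact_prone and rep.extra_peaks == []
        assert abs(rep.spanning.nrl_bp - rep.flanking.nrl_bp) <= 2


def test_phasogram_count_conservation(sim186):
    """Total phasogram mass equals the number of within-window pairs at
    distance <= d_max (checked against the oracle's total)."""
    anchors, dyads, _ = sim186
    region = RegionSpec.downstream()
    ph = nk.compute_phasogram(dyads, anchors[:50], region)
    oracle = oracle_phasogram(dyads, anchors[:50], region, ph.d_max)
    assert ph.counts.sum() == oracle.sum()
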