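"""PWM construction, genome scanning, TRAP affinity, stratification and site
filtering, each checked against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nrlkit as nk
from nrlkit.motif import TrapParams, reverse_complement

from conftest import make_anchor

BASES = "ACGT"


def toy_pfm():
    # 3-column toy matrix with a clear consensus ACG
    return nk.PFMatrix(
        np.array(
            [[8.0, 1.0, 1.0], [1.0, 7.0, 0.0], [0.0, 1.0, 9.0], [1.0, 1.0, 0.0]]
        )
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_pwm_score(seq, pwm_matrix):
    return sum(pwm_matrix[BASES.index(b), j] for j, b in enumerate(seq))


def oracle_scan(sequence, pfm, threshold, pseudocount=0.8):
    """Double-loop scan of every window on both strands."""
    pwm = nk.pfm_to_pwm(pfm, pseudocount=pseudocount)
    L = pfm.length
    span = pwm.max_score - pwm.min_score
    hits = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        for strand, w in (("+", window), ("-", reverse_complement(window))):
            rel = (oracle_pwm_score(w, pwm.matrix) - pwm.min_score) / span
            if rel >= threshold - 1e-12:
                hits.append((i, strand, round(rel, 10)))
    return sorted(hits)


def oracle_trap(context, pfm, params):
    """Window-by-window TRAP affinity with explicit loops."""
    bg = 0.25
    counts = pfm.counts
    p = (counts + params.pseudocount * bg) / (counts.sum(axis=0) + params.pseudocount)
    L = pfm.length
    r0 = math.exp(params.ln_r0_for(L))
    total = 0.0
    for seq in (context, reverse_complement(context)):
        for i in range(len(seq) - L + 1):
            e = 0.0
            for j, b in enumerate(seq[i : i + L]):
                col = p[:, j]
                e += math.log(col.max() / col[BASES.index(b)])
            e /= params.lam
            x = r0 * math.exp(-e)
            total += x / (1 + x)
    return total


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------


class TestPfmToPwm:
    def test_uniform_column_scores_zero(self):
        pfm = nk.PFMatrix(np.ones((4, 1)))
        pwm = nk.pfm_to_pwm(pfm, pseudocount=1.0)
        assert np.allclose(pwm.matrix, 0.0)
        assert pwm.max_score == pytest.approx(0.0)

    def test_hand_computed_entry(self):
        pfm = nk.PFMatrix(np.array([[3.0], [1.0], [0.0], [0.0]]))
        pwm = nk.pfm_to_pwm(pfm, pseudocount=1.0)
        assert pwm.matrix[0, 0] == pytest.approx(math.log2(2.6))

    def test_min_max_are_columnwise_extreme_sums(self):
        pfm = toy_pfm()
        pwm = nk.pfm_to_pwm(pfm)
        assert pwm.max_score == pytest.approx(pwm.matrix.max(axis=0).sum())
        assert pwm.min_score == pytest.approx(pwm.matrix.min(axis=0).sum())


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


class TestScanGenome:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list(BASES), 5000))
        pfm = toy_pfm()
        hits = nk.scan_genome({"c": seq}, pfm, rel_threshold=0.8)
        got = sorted(
            (h.interval.start, h.strand, round(h.score, 10)) for h in hits
        )
        assert got == oracle_scan(seq, pfm, 0.8)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list(BASES), 3000))
        pfm = toy_pfm()
        fwd = nk.scan_genome({"c": seq}, pfm, rel_threshold=0.85)
        rev = nk.scan_genome({"c": reverse_complement(seq)}, pfm,
                             rel_threshold=0.85)
        assert len(fwd) == len(rev)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (len(seq) - h.interval.end, flip[h.strand], round(h.score, 9))
            for h in rev
        )
        assert mirrored == sorted(
            (h.interval.start, h.strand, round(h.score, 9)) for h in fwd
        )

    def test_higher_threshold_returns_subset(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list(BASES), 4000))
        pfm = toy_pfm()
        loose = {
            (h.interval.start, h.strand)
            for h in nk.scan_genome({"c": seq}, pfm, rel_threshold=0.7)
        }
        tight = {
            (h.interval.start, h.strand)
            for h in nk.scan_genome({"c": seq}, pfm, rel_threshold=0.9)
        }
        assert tight <= loose

    def test_sequence_shorter_than_motif_is_empty(self, pfm):
        assert nk.scan_genome({"c": "ACGT"}, pfm) == []

    def test_centre_convention(self):
        pfm = toy_pfm()
        seq = "TTTTTACGTTTTT"
        hits = nk.scan_genome({"c": seq}, pfm, rel_threshold=0.99)
        h = next(h for h in hits if h.strand == "+")
        assert h.centre == h.interval.start + pfm.length // 2


# ---------------------------------------------------------------------------
# TRAP
# ---------------------------------------------------------------------------


class TestTrapAffinity:
    def test_consensus_window_closed_form(self, pfm):
        """A perfect-match window occupies with probability R0/(1+R0)."""
        term = nk.trap_affinity(pfm.consensus(), pfm, TrapParams(),
                                strands="forward")
        ln_r0 = 0.584 * pfm.length - 5.66
        assert ln_r0 == pytest.approx(5.436)
        expected = math.exp(ln_r0) / (1 + math.exp(ln_r0))
        assert term == pytest.approx(expected, rel=1e-12)
        assert term == pytest.approx(0.99566, abs=5e-6)

    def test_exact_length_context_sums_both_strand_terms(self, pfm):
        ctx = pfm.consensus()
        both = nk.trap_affinity(ctx, pfm)
        fwd = nk.trap_affinity(ctx, pfm, strands="forward")
        rev = nk.trap_affinity(ctx, pfm, strands="reverse")
        assert both == pytest.approx(fwd + rev, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        ctx = "".join(rng.choice(list(BASES), 79))
        pfm = toy_pfm()
        params = TrapParams()
        assert nk.trap_affinity(ctx, pfm, params) == pytest.approx(
            oracle_trap(ctx, pfm, params), rel=1e-9
        )

    def test_reverse_complement_invariance(self, pfm):
        rng = np.random.default_rng(22)
        ctx = "".join(rng.choice(list(BASES), 79))
        a = nk.trap_affinity(ctx, pfm)
        b = nk.trap_affinity(reverse_complement(ctx), pfm)
        assert a == pytest.approx(b, rel=1e-12)

    def test_mismatch_never_increases_consensus_term(self, pfm):
        cons = pfm.consensus()
        base_term = nk.trap_affinity(cons, pfm, strands="forward")
        for j in range(pfm.length):
            for b in BASES:
                if b == cons[j]:
                    continue
                mut = cons[:j] + b + cons[j + 1 :]
                term = nk.trap_affinity(mut, pfm, strands="forward")
                assert term <= base_term + 1e-12

    def test_short_context_yields_zero(self, pfm):
        assert nk.trap_affinity("ACGT", pfm) == 0.0

    def test_affinity_bounded_by_window_count(self, pfm):
        rng = np.random.default_rng(23)
        ctx = "".join(rng.choice(list(BASES), 100))
        n_win = len(ctx) - pfm.length + 1
        a = nk.trap_affinity(ctx, pfm)
        assert 0 < a < 2 * n_win


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


class TestStratifyQuintiles:
    def _sites(self, scores):
        return [
            make_anchor(1000 + 100 * i, "+", score=s)
            for i, s in enumerate(scores)
        ]

    def test_forced_partition_of_ten(self):
        sites = nk.stratify_quintiles(self._sites(range(1, 11)))
        by_q = {
            q: sorted(s.score for s in sites if s.quintile == q)
            for q in range(1, 6)
        }
        assert by_q == {1: [1, 2], 2: [3, 4], 3: [5, 6], 4: [7, 8], 5: [9, 10]}

    def test_remainder_goes_to_weakest_quintile(self):
        sites = nk.stratify_quintiles(self._sites(range(11)))
        sizes = [sum(1 for s in sites if s.quintile == q) for q in range(1, 6)]
        assert sizes == [3, 2, 2, 2, 2]

    def test_ties_are_deterministic_and_balanced(self):
        sites = nk.stratify_quintiles(self._sites([5.0] * 12))
        sizes = [sum(1 for s in sites if s.quintile == q) for q in range(1, 6)]
        assert max(sizes) - min(sizes) <= 1
        again = nk.stratify_quintiles(self._sites([5.0] * 12))
        assert [s.centre for s in sites] == [s.centre for s in again]

    def test_mean_key_non_decreasing(self):
        rng = np.random.default_rng(31)
        sites = nk.stratify_quintiles(self._sites(rng.random(53)))
        means = [
            np.mean([s.score for s in sites if s.quintile == q])
            for q in range(1, 6)
        ]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_fewer_than_five_sites_is_an_error(self):
        with pytest.raises(ValueError):
            nk.stratify_quintiles(self._sites([1, 2, 3]))

    @given(st.lists(st.integers(0, 100), min_size=5, max_size=60))
    def test_sizes_differ_by_at_most_one(self, scores):
        sites = nk.stratify_quintiles(self._sites(scores))
        sizes = [sum(1 for s in sites if s.quintile == q) for q in range(1, 6)]
        assert sum(sizes) == len(scores)
        assert max(sizes) - min(sizes) <= 1


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


class TestFilterSites:
    def test_motif_near_tss_removed(self):
        motif = make_anchor(5000, "+")
        tss = [nk.GenomicInterval("chrS", 5800, 5801)]
        assert nk.filter_sites([motif], (), tss) == []

    def test_supported_motif_far_from_tss_kept(self):
        motif = make_anchor(5000, "+")
        peaks = [[nk.GenomicInterval("chrS", 4990, 5020)]]
        tss = [nk.GenomicInterval("chrS", 6200, 6201)]
        assert nk.filter_sites([motif], peaks, tss) == [motif]

    def test_no_evidence_overlap_removed(self):
        motif = make_anchor(5000, "+")
        peaks = [[nk.GenomicInterval("chrS", 8000, 8100)]]
        assert nk.filter_sites([motif], peaks, []) == []

    def test_matches_brute_force_on_toy_set(self):
        rng = np.random.default_rng(41)
        motifs = [make_anchor(int(c), "+") for c in
                  rng.integers(2000, 50_000, size=6)]
        evidence = [
            [nk.GenomicInterval("chrS", int(s), int(s) + 150)
             for s in rng.integers(0, 50_000, size=8)]
            for _ in range(2)
        ]
        tss = [nk.GenomicInterval("chrS", 25_000, 25_001)]
        kept = nk.filter_sites(motifs, evidence, tss, min_tss_dist=1000)

        def brute(m):
            ok_ev = any(
                m.interval.start < iv.end and iv.start < m.interval.end
                for track in evidence
                for iv in track
            )
            ok_tss = all(abs(m.centre - t.midpoint) >= 1000 for t in tss)
            return ok_ev and ok_tss

        assert kept == [m for m in motifs if brute(m)]
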