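"""Motif scanning, TRAP binding affinity, site filtering and quintile
stratification.

The scanner reports every window, on either strand, whose log-odds score
reaches a stated fraction of the achievable score range (``(S - S_min) /
(S_max - S_min)``, the "relative score" convention of the common PWM scanning
tools).  TRAP converts a position frequency matrix into a mismatch-energy
model and sums Fermi-Dirac occupation terms over every window of an extended
sequence context, yielding a total affinity proportional to the binding
probability of the factor for the site.  Sites are then stratified into five
equal-size binding-strength quintiles (Q1 weakest .. Q5 strongest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GenomicInterval, PFMatrix, fetch_sequence, sequence_length

logger = logging.getLogger("nrlkit")

_NEG = -1e9  # sentinel log-odds for non-ACGT bases: never above threshold

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0,C=1,G=2,T=3; anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AnchorSite:
    """An oriented, scored genomic point: a motif hit or a peak summit."""

    interval: GenomicInterval
    centre: int
    strand: str
    score: float
    trap_score: float | None = None
    quintile: int | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.centre < self.interval.end):
            raise ValueError("anchor centre must lie inside its interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class TrapParams:
    """TRAP model parameters.

    ``lam`` is the dimensionless energy scale of the mismatch model;
    ``ln_r0``, when left unset, follows the width-dependent default
    ``0.584 * L - 5.66``; ``extension`` is the number of bases added on each
    side of the motif before summing window terms; ``pseudocount`` regularises
    the PFM (distributed by the background composition).
    """

    lam: float = 0.7
    ln_r0: float | None = None
    extension: int = 30
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    def ln_r0_for(self, motif_length: int) -> float:
        if self.ln_r0 is not None:
            return self.ln_r0
        return 0.584 * motif_length - 5.66


@dataclass
class PWM:
    """Log-odds matrix with its achievable score range."""

    matrix: np.ndarray  # 4 x L, log2 odds
    min_score: float
    max_score: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# PWM construction and genome scanning
# ---------------------------------------------------------------------------


def pfm_to_pwm(
    pfm: PFMatrix,
    pseudocount: float = 0.8,
    background: Sequence[float] = UNIFORM_BG,
) -> PWM:
    """Log2-odds matrix: ``entry(b, j) = log2(((n_bj + pc*bg_b) /
    (colsum_j + pc)) / bg_b)`` with the pseudocount distributed by the
    background, plus the column-wise min/max achievable scores."""
    bg = np.asarray(background, dtype=float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background probabilities must sum to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("zero column sum in PFM")
    p = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    matrix = np.log2(p / bg[:, None])
    return PWM(
        matrix=matrix,
        min_score=float(matrix.min(axis=0).sum()),
        max_score=float(matrix.max(axis=0).sum()),
    )


def _window_scores(enc: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score every window of an encoded sequence against a 4 x L matrix;
    windows containing non-ACGT bases score far below any threshold."""
    L = matrix.shape[1]
    n_win = len(enc) - L + 1
    if n_win <= 0:
        return np.empty(0)
    ext = np.vstack([matrix, np.full((1, L), _NEG)])
    scores = np.zeros(n_win)
    for j in range(L):
        scores += ext[enc[j : j + n_win], j]
    return scores


def scan_genome(
    genome,
    pfm: PFMatrix,
    rel_threshold: float = 0.8,
    pseudocount: float = 0.8,
    background: Sequence[float] = UNIFORM_BG,
) -> list[AnchorSite]:
    """Report every window on either strand whose relative log-odds score
    reaches ``rel_threshold``.

    ``genome`` is a mapping of chromosome name to sequence (plain dict of
    strings or ``pyfaidx.Fasta``).  The hit interval spans the motif
    footprint; ``centre = start + floor(L / 2)``; ``score`` is the relative
    score.  Hits on opposite strands at the same locus are both reported.
    Results are sorted by coordinate.
    """
    if not (0 < rel_threshold <= 1):
        raise ValueError("rel_threshold must be in (0, 1]")
    pwm = pfm_to_pwm(pfm, pseudocount=pseudocount, background=background)
    L = pwm.length
    span = pwm.max_score - pwm.min_score
    rc_matrix = pwm.matrix[::-1, ::-1]
    hits: list[AnchorSite] = []
    chroms = genome.keys() if hasattr(genome, "keys") else [r.name for r in genome]
    for chrom in chroms:
        seq = fetch_sequence(genome, chrom, 0, sequence_length(genome, chrom))
        enc = encode_sequence(seq)
        per_chrom: list[tuple[int, str, float]] = []
        for strand, matrix in (("+", pwm.matrix), ("-", rc_matrix)):
            scores = _window_scores(enc, matrix)
            rel = (scores - pwm.min_score) / span
            for i in np.flatnonzero(rel >= rel_threshold - 1e-12):
                per_chrom.append((int(i), strand, float(rel[i])))
        per_chrom.sort(key=lambda t: (t[0], t[1]))
        for start, strand, rel_score in per_chrom:
            iv = GenomicInterval(chrom, start, start + L, strand, rel_score)
            hits.append(AnchorSite(iv, centre=start + L // 2, strand=strand,
                                   score=rel_score))
    return hits


# ---------------------------------------------------------------------------
# TRAP affinity
# ---------------------------------------------------------------------------


def _trap_energy_matrix(pfm: PFMatrix, params: TrapParams,
                        background: Sequence[float] = UNIFORM_BG) -> np.ndarray:
    """Per-base, per-column mismatch energies ``(1/lam) * ln(p_max_j / p_bj)``
    from the pseudocounted PFM."""
    bg = np.asarray(background, dtype=float)
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    p = (counts + params.pseudocount * bg[:, None]) / (colsum + params.pseudocount)
    lnp = np.log(p)
    return (lnp.max(axis=0)[None, :] - lnp) / params.lam


def trap_affinity(
    context: str,
    pfm: PFMatrix,
    params: TrapParams | None = None,
    strands: str = "both",
    background: Sequence[float] = UNIFORM_BG,
) -> float:
    """Total TRAP affinity of a sequence context.

    Sums, over every window i of the context (both strands unless ``strands``
    is "forward"/"reverse"), the occupation term ``R0 exp(-E_i) /
    (1 + R0 exp(-E_i))`` with mismatch energy ``E_i`` from the pseudocounted
    PFM; each term lies in (0, 1).  A context shorter than the motif yields
    affinity 0 with a warning.
    """
    params = params or TrapParams()
    L = pfm.length
    if len(context) < L:
        logger.warning("TRAP context shorter than motif (%d < %d)", len(context), L)
        return 0.0
    w = _trap_energy_matrix(pfm, params, background)
    r0 = np.exp(params.ln_r0_for(L))
    enc = encode_sequence(context)
    n_win = len(enc) - L + 1
    big = 1e30  # windows with non-ACGT bases contribute ~0
    total = 0.0
    mats = []
    if strands in ("both", "forward"):
        mats.append(w)
    if strands in ("both", "reverse"):
        mats.append(w[::-1, ::-1])
    if not mats:
        raise ValueError(f"invalid strands {strands!r}")
    for mat in mats:
        ext = np.vstack([mat, np.full((1, L), big)])
        energies = np.zeros(n_win)
        for j in range(L):
            energies += ext[enc[j : j + n_win], j]
        x = r0 * np.exp(-np.clip(energies, 0, 700))
        total += float(np.sum(x / (1.0 + x)))
    return total


def trap_scores_for_sites(
    sites: Sequence[AnchorSite],
    genome,
    pfm: PFMatrix,
    params: TrapParams | None = None,
) -> list[AnchorSite]:
    """Assign each site the TRAP affinity of its motif interval extended by
    ``params.extension`` on each side (clipped to the chromosome)."""
    params = params or TrapParams()
    for site in sites:
        lo = max(0, site.interval.start - params.extension)
        hi = min(sequence_length(genome, site.chrom),
                 site.interval.end + params.extension)
        context = fetch_sequence(genome, site.chrom, lo, hi)
        site.trap_score = trap_affinity(context, pfm, params)
    return list(sites)


# ---------------------------------------------------------------------------
# stratification and filtering
# ---------------------------------------------------------------------------


def stratify_quintiles(
    sites: Sequence[AnchorSite], key: str = "score", n_groups: int = 5
) -> list[AnchorSite]:
    """Label sites with binding-strength quintiles Q1 (weakest) .. Q5.

    Sites are sorted ascending by ``key`` (ties broken by chromosome, then
    position) and split into ``n_groups`` contiguous rank blocks whose sizes
    differ by at most one; when the count does not divide evenly the larger
    blocks sit at the low-scoring end (Q1 first).  Returns the sorted list
    with ``quintile`` set.
    """
    if len(sites) < n_groups:
        raise ValueError(f"need at least {n_groups} sites to stratify")
    if key not in ("score", "trap_score"):
        raise ValueError(f"invalid key {key!r}")
    for s in sites:
        if getattr(s, key) is None:
            raise ValueError(f"site missing {key}")
    ordered = sorted(
        sites, key=lambda s: (getattr(s, key), s.chrom, s.interval.start)
    )
    n = len(ordered)
    base, rem = divmod(n, n_groups)
    sizes = [base + 1] * rem + [base] * (n_groups - rem)
    i = 0
    for q, size in enumerate(sizes, start=1):
        for s in ordered[i : i + size]:
            s.quintile = q
        i += size
    return ordered


def _tree_per_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def filter_sites(
    motifs: Sequence[AnchorSite],
    evidence_peaks: Sequence[Sequence[GenomicInterval]] = (),
    tss: Sequence[GenomicInterval] = (),
    min_tss_dist: int = 1000,
) -> list[AnchorSite]:
    """Keep motifs supported by binding evidence and away from promoters.

    A motif survives iff (a) it overlaps, by at least 1 bp, at least one
    interval in at least one evidence set (skipped when ``evidence_peaks`` is
    empty) and (b) its centre lies at least ``min_tss_dist`` bp from the
    nearest TSS (TSS position = interval midpoint; no TSS on the chromosome
    counts as infinitely far).
    """
    evidence_trees = [_tree_per_chrom(peaks) for peaks in evidence_peaks]
    tss_pos: dict[str, np.ndarray] = {}
    for iv in tss:
        tss_pos.setdefault(iv.chrom, None)
    for chrom in tss_pos:
        tss_pos[chrom] = np.sort(
            np.array([iv.midpoint for iv in tss if iv.chrom == chrom])
        )
    kept = []
    for site in motifs:
        if evidence_trees:
            supported = any(
                trees.get(site.chrom) is not None
                and trees[site.chrom].overlap(site.interval.start, site.interval.end)
                for trees in evidence_trees
            )
            if not supported:
                continue
        pos = tss_pos.get(site.chrom)
        if pos is not None and len(pos):
            i = np.searchsorted(pos, site.centre)
            dists = [
                abs(site.centre - pos[j]) for j in (i - 1, i) if 0 <= j < len(pos)
            ]
            if min(dists) < min_tss_dist:
                continue
        kept.append(site)
    return kept


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_hits(
    sites: Sequence[AnchorSite], path: str, sidecar_path: str | None = None
) -> None:
    """Write hits as BED6 (score = relative score x 1000, rounded); the
    optional sidecar TSV carries raw scores, TRAP affinities and quintiles."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(
                f"{s.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                f"site{i}\t{round(s.score * 1000)}\t{s.strand}\n"
            )
    if sidecar_path:
        import pandas as pd

        pd.DataFrame(
            {
                "chrom": [s.chrom for s in sites],
                "start": [s.interval.start for s in sites],
                "end": [s.interval.end for s in sites],
                "strand": [s.strand for s in sites],
                "score": [s.score for s in sites],
                "trap_score": [s.trap_score for s in sites],
                "quintile": [s.quintile for s in sites],
            }
        ).to_csv(sidecar_path, sep="\t", index=False)


def read_anchors_bed(path: str) -> list[AnchorSite]:
    """Read anchors from BED6; the centre is the interval midpoint."""
    from .io import read_bed

    return [
        AnchorSite(iv, centre=iv.midpoint, strand=iv.strand, score=iv.score)
        for iv in read_bed(path)
    ]
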