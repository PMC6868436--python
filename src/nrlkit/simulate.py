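"""Synthetic nucleosome maps, anchor sites, genomes and read tracks.

The generator emulates the statistical structure of phased nucleosome arrays
flanking an oriented anchor (a CTCF-like motif): a nucleosome-depleted region
(NDR) centred a configurable distance 5' of the motif centre, a 3' array
whose first dyad sits at a configurable offset downstream, per-side spacing
(repeat length) and Gaussian positional jitter, Poisson sampling depth per
nucleosome, and uniform background dyads.  Minus-strand anchors mirror the
whole construction through the anchor position, so every strand-aware
downstream statistic is exercised for real.

Defaults follow the geometry measured around CTCF in mouse embryonic stem
cells: NDR centre at -41 bp, first downstream dyad at +105 bp, about 20
nucleosomes organised per side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io import DyadMap, GenomicInterval, PFMatrix
from .motif import AnchorSite, reverse_complement

logger = logging.getLogger("nrlkit")


class SizingError(ValueError):
    """Requested objects do not fit in the given genome."""


@dataclass
class ArrayModel:
    """Geometry and sampling model of the nucleosome arrays around an anchor.

    Spacings and offsets are in bp, relative to the (strand-oriented) anchor
    centre; negative offsets are 5' of the motif.  ``depth`` is the mean
    number of sampled dyads per true nucleosome; with ``depth_law="poisson"``
    (the realistic default) each nucleosome emits ``Poisson(depth)`` dyads,
    while ``"fixed"`` emits exactly ``round(depth)`` for deterministic
    constructions.  Jitter is applied per sampled dyad, mimicking MNase
    sampling of a positioned nucleosome, so higher depth sharpens phasogram
    peaks realistically.
    """

    nrl_down: float = 186.0
    nrl_up: float = 186.0
    jitter_sd_down: float = 15.0
    jitter_sd_up: float = 15.0
    ndr_offset: int = -41
    ndr_halfwidth: int | None = None
    n_per_side: int = 20
    n_down: int | None = None
    n_up: int | None = None
    first_dyad_down: int = 105
    background_rate: float = 2e-4
    depth: float = 5.0
    depth_law: str = "poisson"
    jitter_slope: float = 0.0  # optional extra jitter sd per array position
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_down is None:
            self.n_down = self.n_per_side
        if self.n_up is None:
            self.n_up = self.n_per_side
        if self.ndr_halfwidth is None:
            # place the NDR edges symmetrically about ndr_offset: the 5' array
            # edge mirrors the first downstream dyad through the NDR centre
            self.ndr_halfwidth = self.first_dyad_down - self.ndr_offset
        if self.ndr_halfwidth <= 0:
            raise ValueError("ndr_halfwidth must be > 0")
        if self.nrl_down <= 0 or self.nrl_up <= 0:
            raise ValueError("nrl_down and nrl_up must be > 0")
        if self.n_down < 0 or self.n_up < 0:
            raise ValueError("nucleosome counts must be >= 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.depth_law not in ("poisson", "fixed"):
            raise ValueError(f"invalid depth_law {self.depth_law!r}")

    def true_dyad_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Strand-oriented offsets of the true nucleosome dyads
        (downstream array, upstream array)."""
        down = self.first_dyad_down + self.nrl_down * np.arange(self.n_down)
        up = (
            self.ndr_offset
            - self.ndr_halfwidth
            - self.nrl_up * np.arange(self.n_up)
        )
        return down, up


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def default_score_law(rng: np.random.Generator, n: int) -> np.ndarray:
    """Lognormal peak heights, the usual shape of ChIP-seq peak scores."""
    return rng.lognormal(mean=3.0, sigma=1.0, size=n)


def generate_anchor_sites(
    n: int,
    genome_size: int,
    strand_fraction_plus: float = 0.5,
    score_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed=None,
    chrom: str = "chrS",
    min_spacing: int = 4000,
    edge: int = 2000,
    motif_length: int = 19,
    gap_shape: float = 4.0,
    gap_scale: float = 150.0,
) -> list[AnchorSite]:
    """Place ``n`` oriented, scored anchors at least ``min_spacing`` apart and
    ``edge`` bp from the chromosome ends; reproducible under a fixed seed.

    Inter-anchor gaps beyond the minimum spacing are Gamma distributed
    (smooth, with sd larger than one nucleosome repeat), so cross-anchor dyad
    distances carry no residual periodicity from the placement itself.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if 2 * edge + n * min_spacing >= genome_size:
        raise SizingError(
            f"genome of {genome_size} bp cannot hold {n} anchors "
            f"{min_spacing} bp apart with {edge} bp margins"
        )
    gaps = min_spacing + rng.gamma(gap_shape, gap_scale, size=n)
    centres = (edge + np.cumsum(gaps)).astype(np.int64)
    if centres[-1] > genome_size - edge:
        raise SizingError(
            f"genome of {genome_size} bp too small for {n} anchors with mean "
            f"spacing {min_spacing + gap_shape * gap_scale:.0f} bp"
        )
    strands = np.where(rng.random(n) < strand_fraction_plus, "+", "-")
    scores = (score_law or default_score_law)(rng, n)
    sites = []
    for c, s, sc in zip(centres, strands, scores):
        start = int(c) - motif_length // 2
        iv = GenomicInterval(chrom, start, start + motif_length, str(s), float(sc))
        sites.append(AnchorSite(iv, centre=int(c), strand=str(s), score=float(sc)))
    return sites


# ---------------------------------------------------------------------------
# nucleosome maps
# ---------------------------------------------------------------------------


def generate_nucleosome_map(
    anchors: Sequence[AnchorSite],
    model: ArrayModel,
    genome_size: int | None = None,
    seed=None,
) -> DyadMap:
    """Sample a dyad map with phased arrays around every anchor.

    For a plus-strand anchor at position ``a`` the k-th true downstream dyad
    (k = 1..n_down) is centred at ``a + first_dyad_down + (k-1) * nrl_down``;
    the upstream array is anchored at the 5' NDR edge, with the k-th true
    upstream dyad at ``a + ndr_offset - ndr_halfwidth - (k-1) * nrl_up``.
    Each true nucleosome emits ``Poisson(depth)`` dyads displaced by
    ``Gaussian(0, jitter_sd)``; minus-strand anchors mirror the construction
    through the anchor position; uniform background dyads are added at
    ``background_rate`` per bp when ``genome_size`` is given.
    """
    rng = _as_rng(seed if seed is not None else model.seed)
    positions: dict[str, list[int]] = {}
    down_mu, up_mu = model.true_dyad_offsets()
    sides = (
        (down_mu, model.jitter_sd_down),
        (up_mu, model.jitter_sd_up),
    )
    for anchor in anchors:
        sgn = -1 if anchor.strand == "-" else 1
        chrom_pos = positions.setdefault(anchor.chrom, [])
        for mu_rel, sd in sides:
            for k, mu in enumerate(mu_rel):
                if model.depth_law == "poisson":
                    m = int(rng.poisson(model.depth))
                else:
                    m = int(round(model.depth))
                if m == 0:
                    continue
                sd_k = sd + model.jitter_slope * k
                centre = anchor.centre + sgn * mu
                if sd_k > 0:
                    draws = centre + rng.normal(0.0, sd_k, size=m)
                else:
                    draws = np.full(m, centre, dtype=float)
                chrom_pos.extend(int(round(x)) for x in draws)
    if genome_size is not None and model.background_rate > 0:
        n_bg = int(rng.poisson(model.background_rate * genome_size))
        bg = rng.integers(0, genome_size, size=n_bg)
        chroms = {a.chrom for a in anchors} or {"chrS"}
        per = np.array_split(np.sort(bg), len(chroms))
        for chrom, chunk in zip(sorted(chroms), per):
            positions.setdefault(chrom, []).extend(int(x) for x in chunk)
    return DyadMap(positions, mode="dyad")


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


def generate_planted_genome(
    length: int,
    pfm: PFMatrix,
    plant_positions: Sequence[tuple[int, str]] = (),
    gc: float = 0.42,
    seed=None,
) -> str:
    """An i.i.d. background sequence with P(G) + P(C) = ``gc`` and the motif
    consensus planted (reverse-complemented on '-') at the given positions;
    planted motifs must lie in bounds and not overlap."""
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0, 1]")
    rng = _as_rng(seed)
    L = pfm.length
    plants = sorted(plant_positions)
    for (p1, _), (p2, _) in zip(plants, plants[1:]):
        if p2 < p1 + L:
            raise SizingError(f"planted motifs at {p1} and {p2} overlap")
    for p, _ in plants:
        if p < 0 or p + L > length:
            raise SizingError(f"planted motif at {p} out of bounds")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    seq = bytearray(seq.tobytes())
    consensus = pfm.consensus()
    for p, strand in plants:
        word = consensus if strand != "-" else reverse_complement(consensus)
        seq[p : p + L] = word.encode("ascii")
    return seq.decode("ascii")


# ---------------------------------------------------------------------------
# RNA-like flank reads
# ---------------------------------------------------------------------------


def generate_flank_reads(
    anchors: Sequence[AnchorSite],
    rate_up: float,
    rate_down: float,
    read_len: int = 50,
    seed=None,
    flank: int = 1000,
) -> list[GenomicInterval]:
    """Poisson read counts per flank, placed uniformly (and fully) inside the
    strand-oriented [-flank, 0] and [0, flank] windows of each anchor."""
    if rate_up < 0 or rate_down < 0:
        raise ValueError("rates must be >= 0")
    rng = _as_rng(seed)
    reads = []
    for anchor in anchors:
        sgn = -1 if anchor.strand == "-" else 1
        for rate, rel_window in (
            (rate_up, (-flank, 0)),
            (rate_down, (0, flank)),
        ):
            m = int(rng.poisson(rate))
            if m == 0:
                continue
            if sgn == 1:
                lo, hi = anchor.centre + rel_window[0], anchor.centre + rel_window[1]
            else:
                lo, hi = anchor.centre - rel_window[1], anchor.centre - rel_window[0]
            starts = rng.integers(lo, hi - read_len, size=m)
            for s in starts:
                reads.append(
                    GenomicInterval(
                        anchor.chrom, int(s), int(s) + read_len, anchor.strand
                    )
                )
    reads.sort(key=lambda iv: (iv.chrom, iv.start))
    return reads


# ---------------------------------------------------------------------------
# reflection helpers (mirror-invariance checks)
# ---------------------------------------------------------------------------


def reflect_intervals(
    intervals: Sequence[GenomicInterval], genome_size: int
) -> list[GenomicInterval]:
    """Reverse-complement coordinate transform: [s, e) -> [G - e, G - s) with
    the strand flipped."""
    flip = {"+": "-", "-": "+", ".": "."}
    return [
        GenomicInterval(
            iv.chrom,
            genome_size - iv.end,
            genome_size - iv.start,
            flip[iv.strand],
            iv.score,
            iv.name,
        )
        for iv in intervals
    ]


def reflect_anchors(
    anchors: Sequence[AnchorSite], genome_size: int
) -> list[AnchorSite]:
    """Reflect anchors through the genome midpoint and flip their strands.

    With an odd motif length the reflected centre is exactly
    ``genome_size - 1 - centre``, so oriented offsets are preserved."""
    out = []
    for a in anchors:
        iv = reflect_intervals([a.interval], genome_size)[0]
        L = len(a.interval)
        out.append(
            AnchorSite(
                iv,
                centre=iv.start + L // 2,
                strand=iv.strand,
                score=a.score,
                trap_score=a.trap_score,
                quintile=a.quintile,
            )
        )
    out.reverse()
    return out
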