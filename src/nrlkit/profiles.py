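"""Strand-aware aggregate profiles around oriented anchors, nucleosome-
depleted region (NDR) localisation, and array-asymmetry summaries.

A profile value at offset x is the mean signal at strand-oriented offset x
over all anchors: plus-strand windows run left to right, minus-strand windows
are mirrored through the anchor centre, so negative offsets are always 5' of
the motif.  Per-offset means are edge-aware: anchors whose window runs off a
chromosome end contribute only where they have data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import DyadMap, GenomicInterval, fetch_sequence, sequence_length
from .motif import AnchorSite
from .phasogram import NRLEstimate, nrl_for_anchors, smooth

logger = logging.getLogger("nrlkit")


@dataclass
class AggregateProfile:
    """Mean signal per strand-oriented offset around a set of anchors."""

    offsets: np.ndarray
    values: np.ndarray
    n_regions: int
    bin: int = 1
    signal_kind: str = ""
    n_per_offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values must have the same length")

    def value_at(self, offset: int) -> float:
        idx = np.searchsorted(self.offsets, offset)
        if idx >= len(self.offsets) or self.offsets[idx] != offset:
            raise KeyError(f"offset {offset} not in profile")
        return float(self.values[idx])


@dataclass
class AsymmetryReport:
    """Scalar summary of the nucleosome-array asymmetry around anchors.

    ``ndr_offset`` is the location of the occupancy minimum (negative = 5' of
    the motif); ``nrl_up``/``nrl_down`` are the per-side repeat lengths (None
    when a side has too few peaks or fails the significance filter, with a
    note in ``flags``); ``amp_105``/``amp_165`` sample the smoothed occupancy
    at the two characteristic downstream offsets.
    """

    ndr_offset: int
    nrl_up: float | None
    nrl_down: float | None
    nrl_delta: float | None
    amp_105: float
    amp_165: float
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# profile computation
# ---------------------------------------------------------------------------


def _bin_offsets(half_width: int, bin: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges (relative, half-open per bin) and representative offsets."""
    edges = np.arange(-half_width, half_width + 2, bin)
    if edges[-1] <= half_width:
        edges = np.append(edges, edges[-1] + bin)
    offsets = edges[:-1] + bin // 2
    return edges, offsets


def _oriented_offsets(anchor: AnchorSite, positions: np.ndarray) -> np.ndarray:
    if anchor.strand == "-":
        return anchor.centre - positions
    return positions - anchor.centre


def _valid_mask(
    anchor: AnchorSite, offsets: np.ndarray, bin: int, chrom_size: int | None
) -> np.ndarray:
    """Which profile bins fall entirely on the chromosome for this anchor."""
    if chrom_size is None:
        return np.ones(len(offsets), dtype=bool)
    lo_rel = offsets - (bin - 1) // 2
    hi_rel = offsets + bin // 2
    if anchor.strand == "-":
        lo_abs = anchor.centre - hi_rel
        hi_abs = anchor.centre - lo_rel
    else:
        lo_abs = anchor.centre + lo_rel
        hi_abs = anchor.centre + hi_rel
    return (lo_abs >= 0) & (hi_abs < chrom_size)


def aggregate_signal(
    track,
    anchors: Sequence[AnchorSite],
    half_width: int = 1000,
    bin: int = 1,
    occupancy_mode: str = "fragment_coverage",
    chrom_sizes: dict[str, int] | None = None,
) -> AggregateProfile:
    """Aggregate a signal track over strand-oriented anchor windows.

    ``track`` is a :class:`DyadMap` for ``occupancy_mode="dyad_count"`` (dyads
    per bin) or a list of intervals for ``"fragment_coverage"`` (overlapping
    fragments per bp) and ``"interval_density"`` (interval midpoints per bin,
    e.g. remodeller peaks, or motifs near TAD boundaries at bin 5000).
    Unstranded anchors are treated as plus strand (logged).
    """
    if occupancy_mode not in ("dyad_count", "fragment_coverage",
                              "interval_density"):
        raise ValueError(f"invalid occupancy_mode {occupancy_mode!r}")
    n_unstranded = sum(1 for a in anchors if a.strand not in ("+", "-"))
    if n_unstranded:
        logger.info("%d unstranded anchors treated as plus strand", n_unstranded)
    edges, offsets = _bin_offsets(half_width, bin)
    acc = np.zeros(len(offsets))
    n_per = np.zeros(len(offsets), dtype=np.int64)

    if occupancy_mode == "dyad_count":
        dyads: DyadMap = track
        get_positions = lambda a: dyads.in_window(
            a.chrom, a.centre - half_width - bin, a.centre + half_width + bin
        )
    elif occupancy_mode == "interval_density":
        mids: dict[str, np.ndarray] = {}
        for iv in track:
            mids.setdefault(iv.chrom, []).append(iv.midpoint)
        mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
        def get_positions(a, _mids=mids):
            arr = _mids.get(a.chrom)
            if arr is None:
                return np.empty(0, dtype=np.int64)
            i = np.searchsorted(arr, a.centre - half_width - bin)
            j = np.searchsorted(arr, a.centre + half_width + bin, side="right")
            return arr[i:j]
    else:  # fragment_coverage
        cov = _coverage_arrays(track, chrom_sizes)

    for anchor in anchors:
        chrom_size = (chrom_sizes or {}).get(anchor.chrom)
        mask = _valid_mask(anchor, offsets, bin, chrom_size)
        n_per += mask
        if occupancy_mode == "fragment_coverage":
            arr = cov.get(anchor.chrom)
            if arr is None:
                continue
            window = _window_values(arr, anchor, half_width)
            binned = np.add.reduceat(window, edges[:-1] + half_width)
            acc += np.where(mask, binned / bin, 0.0)
        else:
            rel = _oriented_offsets(anchor, get_positions(anchor))
            idx = np.searchsorted(edges, rel, side="right") - 1
            ok = (idx >= 0) & (idx < len(offsets))
            contrib = np.bincount(idx[ok], minlength=len(offsets))
            acc += np.where(mask, contrib, 0.0)

    values = np.divide(acc, n_per, out=np.zeros_like(acc), where=n_per > 0)
    return AggregateProfile(
        offsets=offsets,
        values=values,
        n_regions=len(anchors),
        bin=bin,
        signal_kind=occupancy_mode,
        n_per_offset=n_per,
    )


def _coverage_arrays(
    fragments: Sequence[GenomicInterval], chrom_sizes: dict[str, int] | None
) -> dict[str, np.ndarray]:
    """Per-bp fragment coverage via a difference array."""
    extents: dict[str, int] = dict(chrom_sizes or {})
    for iv in fragments:
        extents[iv.chrom] = max(extents.get(iv.chrom, 0), iv.end)
    cov = {c: np.zeros(n + 1) for c, n in extents.items()}
    for iv in fragments:
        cov[iv.chrom][iv.start] += 1
        cov[iv.chrom][iv.end] -= 1
    return {c: np.cumsum(v[:-1]) for c, v in cov.items()}


def _window_values(arr: np.ndarray, anchor: AnchorSite, half_width: int) -> np.ndarray:
    """Signal over the oriented window [-W, W]; off-array positions are 0."""
    lo = anchor.centre - half_width
    hi = anchor.centre + half_width + 1
    window = np.zeros(hi - lo)
    a, b = max(0, lo), min(len(arr), hi)
    if b > a:
        window[a - lo : b - lo] = arr[a:b]
    if anchor.strand == "-":
        window = window[::-1]
    return window


def gc_profile(
    genome, anchors: Sequence[AnchorSite], half_width: int = 1000
) -> AggregateProfile:
    """Per-offset G/C fraction around anchors; minus-strand anchors read the
    reverse complement (GC content itself is strand-symmetric, so only the
    mirroring matters).  Anchors with missing sequence are excluded per
    offset."""
    width = 2 * half_width + 1
    offsets = np.arange(-half_width, half_width + 1)
    acc = np.zeros(width)
    n_per = np.zeros(width, dtype=np.int64)
    for anchor in anchors:
        size = sequence_length(genome, anchor.chrom)
        lo = anchor.centre - half_width
        hi = anchor.centre + half_width + 1
        seq = fetch_sequence(genome, anchor.chrom, max(0, lo), min(size, hi))
        gc = np.isin(
            np.frombuffer(seq.encode("ascii"), dtype=np.uint8),
            np.frombuffer(b"GCgc", dtype=np.uint8),
        ).astype(float)
        window = np.full(width, np.nan)
        window[max(0, lo) - lo : max(0, lo) - lo + len(gc)] = gc
        if anchor.strand == "-":
            window = window[::-1]
        ok = ~np.isnan(window)
        acc[ok] += window[ok]
        n_per += ok
    values = np.divide(acc, n_per, out=np.zeros(width), where=n_per > 0)
    return AggregateProfile(
        offsets=offsets,
        values=values,
        n_regions=len(anchors),
        bin=1,
        signal_kind="gc_fraction",
        n_per_offset=n_per,
    )


# ---------------------------------------------------------------------------
# NDR localisation and asymmetry
# ---------------------------------------------------------------------------


def occupancy_profile(
    dyads: DyadMap,
    anchors: Sequence[AnchorSite],
    half_width: int = 1000,
    footprint: int = 147,
    chrom_sizes: dict[str, int] | None = None,
) -> AggregateProfile:
    """Nucleosome occupancy around anchors: each dyad is widened to its
    protected footprint (147 bp for a canonical nucleosome) and the per-bp
    coverage is averaged over strand-oriented windows.  This is the
    occupancy signal MNase fragment coverage would give, reconstructed from
    a dyad map."""
    half = footprint // 2
    fragments = [
        GenomicInterval(chrom, max(0, int(p) - half), int(p) - half + footprint)
        for chrom in dyads.chromosomes()
        for p in dyads.positions[chrom]
    ]
    prof = aggregate_signal(
        fragments, anchors, half_width=half_width, bin=1,
        occupancy_mode="fragment_coverage", chrom_sizes=chrom_sizes,
    )
    prof.signal_kind = "occupancy"
    return prof


def locate_ndr(
    profile: AggregateProfile,
    band: tuple[int, int] = (-300, 300),
    smooth_window: int = 101,
) -> int:
    """Offset of the occupancy minimum: argmin of the smoothed profile inside
    ``band`` (leftmost on ties; a flat profile returns the left band edge
    with a warning).

    The default smoothing window is about two thirds of a nucleosome
    footprint: wide enough that the flat-bottomed dip of a depleted region
    becomes a V with a unique minimum at the depletion centre, but narrower
    than the depletion itself, so the asymmetric occupancy further out does
    not drag the argmin sideways.
    """
    sm = smooth(profile.values, smooth_window)
    in_band = (profile.offsets >= band[0]) & (profile.offsets <= band[1])
    if not np.any(in_band):
        raise ValueError("band lies outside the profile range")
    band_vals = sm[in_band]
    band_offsets = profile.offsets[in_band]
    if np.all(band_vals == band_vals[0]):
        logger.warning("degenerate (flat) profile in NDR search band")
        return int(band_offsets[0])
    return int(band_offsets[int(np.argmin(band_vals))])


def asymmetry_report(
    dyads: DyadMap,
    anchors: Sequence[AnchorSite],
    half_width: int = 1000,
    smooth_window: int = 20,
    ndr_smooth_window: int = 101,
    band: tuple[int, int] = (-300, 300),
    footprint: int = 147,
    chrom_sizes: dict[str, int] | None = None,
    **nrl_kwargs,
) -> AsymmetryReport:
    """Bundle NDR location, per-side NRLs and the +105/+165 occupancy
    amplitudes into one asymmetry summary.

    Occupancy is the footprint-coverage profile of the dyad map; the NDR is
    its footprint-smoothed argmin, the amplitudes are read from the lightly
    (``smooth_window``) smoothed profile.  A side whose phasogram yields
    fewer than 3 peaks, or whose regression fails the p < 0.05 filter,
    reports None for that NRL with a flag.
    """
    profile = occupancy_profile(
        dyads, anchors, half_width=half_width, footprint=footprint,
        chrom_sizes=chrom_sizes,
    )
    ndr = locate_ndr(profile, band=band, smooth_window=ndr_smooth_window)
    sm = smooth(profile.values, smooth_window)
    sm_profile = AggregateProfile(
        offsets=profile.offsets, values=sm, n_regions=profile.n_regions,
        bin=1, signal_kind="dyad_count_smoothed",
    )
    flags: list[str] = []
    estimates: dict[str, float | None] = {}
    for side in ("upstream", "downstream"):
        est = nrl_for_anchors(dyads, anchors, side=side, **nrl_kwargs)
        if est is None:
            flags.append(f"{side}_nrl_unavailable")
            estimates[side] = None
        elif not est.passed:
            flags.append(f"{side}_nrl_not_significant")
            estimates[side] = None
        else:
            estimates[side] = est.nrl_bp
    nrl_up, nrl_down = estimates["upstream"], estimates["downstream"]
    delta = (nrl_up - nrl_down) if (nrl_up is not None and nrl_down is not None) else None
    return AsymmetryReport(
        ndr_offset=ndr,
        nrl_up=nrl_up,
        nrl_down=nrl_down,
        nrl_delta=delta,
        amp_105=sm_profile.value_at(105) if half_width >= 105 else float("nan"),
        amp_165=sm_profile.value_at(165) if half_width >= 165 else float("nan"),
        flags=flags,
    )
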