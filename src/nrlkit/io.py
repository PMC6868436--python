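"""Reading and writing of the genomic formats used throughout the package.

All coordinates are 0-based, half-open (BED-native): an interval ``[start, end)``
of length ``end - start``.  Positions written back to disk stay in the same
convention, so files round-trip exactly.

Supported formats: BED (3-6 columns) for fragments, dyads, peaks, TADs, CpG
islands, repeats, TSSs and RNA reads; FASTA for genome sequence (plain dict or
``pyfaidx.Fasta``); JASPAR text for position frequency matrices; two-column
text with a ``#``-header for phasograms and aggregate profiles; bedGraph for
occupancy tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import motifs as _bio_motifs

logger = logging.getLogger("nrlkit")

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the offending line."""


class MatrixFormatError(ValueError):
    """A position frequency matrix file is malformed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomicInterval:
    """A scored, oriented genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class DyadMap:
    """Per-chromosome sorted nucleosome dyad (or cut-start) positions.

    ``mode="dyad"`` means positions are fragment centres (paired-end MNase-seq);
    ``mode="start"`` means fragment 5' cut positions (chemical mapping, where
    cleavage happens at the dyad).
    """

    def __init__(self, positions: Mapping[str, Iterable[int]], mode: str = "dyad"):
        if mode not in ("dyad", "start"):
            raise ValueError(f"invalid mode {mode!r}")
        self.mode = mode
        self.positions: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(list(pos) if not isinstance(pos, np.ndarray) else pos)
            arr = np.sort(arr.astype(np.int64))
            self.positions[chrom] = arr

    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def __len__(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))

    def in_window(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """Positions p with lo <= p <= hi; empty for absent chromosomes."""
        arr = self.positions.get(chrom)
        if arr is None:
            return np.empty(0, dtype=np.int64)
        i = np.searchsorted(arr, lo, side="left")
        j = np.searchsorted(arr, hi, side="right")
        return arr[i:j]

    def shifted(self, delta: int) -> "DyadMap":
        return DyadMap(
            {c: p + int(delta) for c, p in self.positions.items()}, mode=self.mode
        )

    def reflected(self, genome_size: int) -> "DyadMap":
        """Reflect every position p -> genome_size - 1 - p (reverse-complement
        coordinates for point features)."""
        return DyadMap(
            {c: genome_size - 1 - p for c, p in self.positions.items()},
            mode=self.mode,
        )


@dataclass
class PFMatrix:
    """A 4 x L position frequency matrix; rows are A, C, G, T base counts."""

    counts: np.ndarray
    matrix_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise MatrixFormatError("PFM must be a 4 x L matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 1:
            raise MatrixFormatError("PFM must have at least one column")
        if np.any(self.counts < 0):
            raise MatrixFormatError("PFM counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise MatrixFormatError("every PFM column needs a positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))

    def reverse_complement(self) -> "PFMatrix":
        return PFMatrix(
            self.counts[::-1, ::-1].copy(), matrix_id=self.matrix_id, name=self.name
        )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _parse_bed_line(fields: list[str], path: str, lineno: int) -> tuple:
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
    except (IndexError, ValueError) as exc:
        raise BedParseError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    name = fields[3] if len(fields) > 3 else ""
    score = 0.0
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: bad score field: {exc}") from exc
    strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
    return chrom, start, end, name, score, strand


def _bed_records(path: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals; malformed or inverted
    records raise :class:`BedParseError` naming the line."""
    out = []
    for lineno, fields in _bed_records(path):
        chrom, start, end, name, score, strand = _parse_bed_line(fields, path, lineno)
        if end <= start:
            raise BedParseError(f"{path}:{lineno}: end <= start")
        out.append(GenomicInterval(chrom, start, end, strand, score, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score:.17g}\t{iv.strand}\n"
            )


def read_fragments_to_dyads(
    path: str,
    mode: str = "dyad",
    min_frag_len: int | None = None,
    max_frag_len: int | None = None,
) -> DyadMap:
    """Collapse a BED file of mapped fragments to one position per record.

    ``mode="dyad"`` takes the fragment centre, floor((start + end) / 2);
    ``mode="start"`` takes the 5' cut position (the BED start).  Records with
    ``end <= start`` are rejected and counted in the log; the optional
    fragment-length filter (off by default) drops fragments outside
    ``[min_frag_len, max_frag_len]``.
    """
    if mode not in ("dyad", "start"):
        raise ValueError(f"invalid mode {mode!r}")
    by_chrom: dict[str, list[int]] = {}
    n_rejected = 0
    n_filtered = 0
    for lineno, fields in _bed_records(path):
        chrom, start, end, _, _, _ = _parse_bed_line(fields, path, lineno)
        if end <= start:
            n_rejected += 1
            continue
        frag_len = end - start
        if (min_frag_len is not None and frag_len < min_frag_len) or (
            max_frag_len is not None and frag_len > max_frag_len
        ):
            n_filtered += 1
            continue
        pos = (start + end) // 2 if mode == "dyad" else start
        by_chrom.setdefault(chrom, []).append(pos)
    if n_rejected:
        logger.warning("%s: rejected %d records with end <= start", path, n_rejected)
    if n_filtered:
        logger.info("%s: dropped %d fragments by length filter", path, n_filtered)
    return DyadMap(by_chrom, mode=mode)


def dyads_from_intervals(
    intervals: Sequence[GenomicInterval], mode: str = "dyad"
) -> DyadMap:
    """In-memory counterpart of :func:`read_fragments_to_dyads`."""
    by_chrom: dict[str, list[int]] = {}
    for iv in intervals:
        pos = iv.midpoint if mode == "dyad" else iv.start
        by_chrom.setdefault(iv.chrom, []).append(pos)
    return DyadMap(by_chrom, mode=mode)


def write_dyads_bed(dyads: DyadMap, path: str) -> None:
    """Write each dyad as a 1-bp BED record."""
    with open(path, "w") as fh:
        for chrom in dyads.chromosomes():
            for p in dyads.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


def read_dyads_bed(path: str, mode: str = "dyad") -> DyadMap:
    """Read a BED of 1-bp dyad records (positions are the BED starts); ``mode``
    records how the positions were derived upstream."""
    raw = read_fragments_to_dyads(path, mode="start")
    return DyadMap(raw.positions, mode=mode)


# ---------------------------------------------------------------------------
# JASPAR matrices
# ---------------------------------------------------------------------------


def read_jaspar_pfm(path: str) -> PFMatrix:
    """Parse one JASPAR-format position frequency matrix.

    Rows are mapped to A, C, G, T by their labels regardless of the order in
    the file (label-free 4-row "pfm" layout is also accepted, in which case
    rows are taken in A, C, G, T order).  Missing base rows or ragged rows
    raise :class:`MatrixFormatError`.
    """
    motif = None
    for fmt in ("jaspar", "pfm"):
        try:
            with open(path) as fh:
                parsed = list(_bio_motifs.parse(fh, fmt))
            if parsed:
                motif = parsed[0]
                break
        except Exception:
            continue
    if motif is None:
        raise MatrixFormatError(f"{path}: could not parse a JASPAR matrix")
    try:
        rows = [np.asarray(motif.counts[b], dtype=float) for b in "ACGT"]
    except KeyError as exc:
        raise MatrixFormatError(f"{path}: missing base row {exc}") from exc
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MatrixFormatError(f"{path}: base rows have different lengths")
    matrix_id = getattr(motif, "matrix_id", None) or getattr(motif, "base_id", "") or ""
    name = getattr(motif, "name", "") or ""
    return PFMatrix(np.vstack(rows), matrix_id=str(matrix_id), name=str(name))


def write_jaspar_pfm(pfm: PFMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pfm.matrix_id or 'motif'} {pfm.name}\n".rstrip() + "\n")
        for base, row in zip("ACGT", pfm.counts):
            fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``genome[chrom][start:end]`` from a plain dict of strings or a
    ``pyfaidx.Fasta``; out-of-bounds parts are clipped."""
    seq = genome[chrom]
    start = max(0, start)
    return str(seq[start:end]).upper()


def sequence_length(genome, chrom: str) -> int:
    return len(genome[chrom])


# ---------------------------------------------------------------------------
# phasogram / profile text formats
# ---------------------------------------------------------------------------


def _write_table(path, header: dict, cols, rows) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        fh.write("# " + "\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _read_table(path) -> tuple[dict, list[list[str]]]:
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body and "\t" not in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
                continue
            rows.append(line.split("\t"))
    return header, rows


def write_phasogram(phasogram, path: str) -> None:
    """Two-column text (distance, count) with a ``#`` metadata header."""
    rows = (
        (str(d), str(int(c)))
        for d, c in zip(phasogram.distances, phasogram.values)
    )
    _write_table(
        path,
        {
            "n_regions": phasogram.n_regions,
            "mode": phasogram.mode,
            "window": f"{phasogram.region.window[0]},{phasogram.region.window[1]}",
            "strand_aware": int(phasogram.region.strand_aware),
        },
        ("distance", "count"),
        rows,
    )


def read_phasogram(path: str):
    from .phasogram import Phasogram, RegionSpec

    header, rows = _read_table(path)
    a, b = (int(x) for x in header.get("window", "100,2000").split(","))
    region = RegionSpec(
        window=(a, b), strand_aware=bool(int(header.get("strand_aware", 1)))
    )
    dist = np.array([int(r[0]) for r in rows])
    cnt = np.array([int(r[1]) for r in rows], dtype=np.int64)
    d_max = int(dist.max()) if len(dist) else 0
    counts = np.zeros(d_max + 1, dtype=np.int64)
    counts[dist] = cnt
    return Phasogram(
        counts=counts,
        mode=header.get("mode", "dyad"),
        n_regions=int(header.get("n_regions", 0)),
        region=region,
    )


def write_profile(profile, path: str) -> None:
    """Two-column text (offset, value) with a ``#`` metadata header; values
    are written with full precision so a round trip is exact."""
    rows = (
        (str(int(o)), f"{v:.17g}")
        for o, v in zip(profile.offsets, profile.values)
    )
    _write_table(
        path,
        {
            "n_regions": profile.n_regions,
            "bin": profile.bin,
            "signal_kind": profile.signal_kind,
        },
        ("offset", "value"),
        rows,
    )


def read_profile(path: str):
    from .profiles import AggregateProfile

    header, rows = _read_table(path)
    offsets = np.array([int(r[0]) for r in rows], dtype=np.int64)
    values = np.array([float(r[1]) for r in rows])
    return AggregateProfile(
        offsets=offsets,
        values=values,
        n_regions=int(header.get("n_regions", 0)),
        bin=int(header.get("bin", 1)),
        signal_kind=header.get("signal_kind", ""),
    )


def write_bedgraph(path: str, chrom: str, values: np.ndarray, start: int = 0) -> None:
    """Write a per-bp value array as a run-length-compressed bedGraph track."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        edges = np.concatenate(([0], change, [len(values)]))
        for i, j in zip(edges[:-1], edges[1:]):
            v = values[i]
            if v != 0:
                fh.write(f"{chrom}\t{start + i}\t{start + j}\t{v:.17g}\n")
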