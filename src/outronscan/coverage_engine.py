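"""Strand-specific per-base coverage, density queries and metagene matrices.

A :class:`CoverageTrack` holds dense per-base signal for one strand of a
library, keyed by contig.  Queries outside stored contigs (or past a contig
end) read as zero, matching the missing-data-as-zero convention of standard
metagene tooling.  bedGraph (4-column, 0-based half-open) is the canonical
text format; bigWig reading is optional behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genome_model import GenomicInterval


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Dense per-base signal per contig, for a single strand."""

    values: dict[str, np.ndarray] = field(default_factory=dict)
    strand: str = "."
    library_size: float | None = None
    scaled: bool = False

    def fetch(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); off-contig bases are zero."""
        if end <= start:
            raise CoverageError(f"zero-length query [{start}, {end})")
        arr = self.values.get(chrom)
        out = np.zeros(end - start, dtype=float)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, arr.shape[0])
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def mean(self, interval: GenomicInterval) -> float:
        return float(self.fetch(interval.chrom, interval.start, interval.end).mean())

    def sum(self, interval: GenomicInterval) -> float:
        return float(self.fetch(interval.chrom, interval.start, interval.end).sum())

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def read_bedgraph(
    path, strand: str = ".", library_size: float | None = None
) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense :class:`CoverageTrack`.

    Intervals must be non-overlapping per contig and values non-negative;
    bases not covered by any record are zero.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CoverageError(f"line {lineno}: bedGraph needs 4 fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if end <= start:
                raise CoverageError(f"line {lineno}: empty interval")
            if value < 0 or not np.isfinite(value):
                raise CoverageError(f"line {lineno}: negative or non-finite value")
            records.setdefault(chrom, []).append((start, end, value))

    values: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        prev_end = -1
        for start, end, _v in recs:
            if start < prev_end:
                raise CoverageError(f"overlapping bedGraph intervals on {chrom}")
            prev_end = end
        arr = np.zeros(recs[-1][1], dtype=float)
        for start, end, v in recs:
            arr[start:end] = v
        values[chrom] = arr
    return CoverageTrack(values=values, strand=strand, library_size=library_size)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write non-zero runs as bedGraph records (round-trips through the reader)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bigwig(path, strand: str = ".", library_size: float | None = None) -> CoverageTrack:
    """Optional bigWig reader behind the same contract as :func:`read_bedgraph`."""
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    try:
        values = {}
        for chrom, length in bw.chroms().items():
            arr = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, length), dtype=float), nan=0.0
            )
            if (arr < 0).any():
                raise CoverageError(f"negative values on {chrom}")
            values[chrom] = arr
    finally:
        bw.close()
    return CoverageTrack(values=values, strand=strand, library_size=library_size)


def cpm_scale(track: CoverageTrack) -> CoverageTrack:
    """Scale every value by 1e6 / library_size (counts-per-million)."""
    if track.scaled:
        raise CoverageError("track is already library-size scaled")
    if track.library_size is None or track.library_size <= 0:
        raise CoverageError("library_size must be positive for scaling")
    factor = 1e6 / track.library_size
    return replace(
        track,
        values={c: v * factor for c, v in track.values.items()},
        scaled=True,
    )


# ---------------------------------------------------------------------------
# Metagene matrices
# ---------------------------------------------------------------------------

@dataclass
class MetageneMatrix:
    matrix: np.ndarray  # regions x bins
    region_ids: list[str]
    bin_size: int
    layout: tuple[int, int, int]  # upstream flank bp, body bp (0 = ref-point), downstream flank bp

    @property
    def aggregate(self) -> np.ndarray:
        """Per-bin mean over regions."""
        return self.matrix.mean(axis=0)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        up, body, down = self.layout
        labels: list[str] = []
        n_up = up // self.bin_size
        n_body = body // self.bin_size
        n_down = down // self.bin_size
        for i in range(n_up):
            labels.append(f"up{-up + i * self.bin_size + self.bin_size // 2}")
        for i in range(n_body):
            labels.append(f"body{i}")
        for i in range(n_down):
            labels.append(f"down{i * self.bin_size + self.bin_size // 2}")
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("region\t" + "\t".join(labels) + "\n")
            for rid, row in zip(self.region_ids, self.matrix):
                fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _pick_track(
    tracks: CoverageTrack | Mapping[str, CoverageTrack],
    strand: str,
    antisense: bool = False,
) -> CoverageTrack:
    if isinstance(tracks, CoverageTrack):
        return tracks
    if strand not in ("+", "-"):
        strand = "+"
    if antisense:
        strand = "-" if strand == "+" else "+"
    return tracks[strand]


def _rescale_body(values: np.ndarray, n_bins: int, bin_size: int) -> np.ndarray:
    """Linearly rescale a 5'->3' per-base body vector to ``n_bins`` bin means.

    Bin edges are placed at fractional base positions; each bin's value is the
    length-weighted mean of the bases it covers.  A region shorter than one
    bin contributes its whole-region mean to every bin.
    """
    length = values.shape[0]
    if length < bin_size:
        return np.full(n_bins, values.mean())
    cum = np.concatenate([[0.0], np.cumsum(values)])

    def cum_at(x: float) -> float:
        i = int(np.floor(x))
        if i >= length:
            return cum[length]
        return cum[i] + (x - i) * values[i]

    edges = np.linspace(0.0, float(length), n_bins + 1)
    out = np.empty(n_bins)
    for k in range(n_bins):
        a, b = edges[k], edges[k + 1]
        out[k] = (cum_at(b) - cum_at(a)) / (b - a)
    return out


def metagene_scaled(
    tracks: CoverageTrack | Mapping[str, CoverageTrack],
    regions: Sequence[tuple[str, GenomicInterval]],
    flank: int = 1000,
    body: int = 1000,
    bin_size: int = 10,
    missing_as_zero: bool = True,
) -> MetageneMatrix:
    """Scale-regions metagene: flank | body rescaled to ``body`` bp | flank.

    ``regions`` is a sequence of (id, stranded interval); minus-strand rows
    are reversed so every row reads 5'->3'.  Flanks are binned at native
    resolution; the body is linearly rescaled to body/bin bins.
    """
    if flank % bin_size or body % bin_size:
        raise ValueError("flank and body must be multiples of bin_size")
    n_flank = flank // bin_size
    n_body = body // bin_size
    rows = []
    ids = []
    for rid, region in regions:
        track = _pick_track(tracks, region.strand)
        raw = track.fetch(region.chrom, region.start - flank, region.end + flank)
        if region.strand == "-":
            raw = raw[::-1]
        up = raw[:flank].reshape(n_flank, bin_size).mean(axis=1)
        body_vals = _rescale_body(raw[flank : flank + len(region)], n_body, bin_size)
        down = raw[flank + len(region) :].reshape(n_flank, bin_size).mean(axis=1)
        rows.append(np.concatenate([up, body_vals, down]))
        ids.append(rid)
    matrix = np.vstack(rows) if rows else np.zeros((0, 2 * n_flank + n_body))
    return MetageneMatrix(matrix, ids, bin_size, (flank, body, flank))


def metagene_reference_point(
    tracks: CoverageTrack | Mapping[str, CoverageTrack],
    points: Sequence[tuple[str, str, int, str]],
    window: int = 400,
    bin_size: int = 10,
    antisense: bool = False,
) -> MetageneMatrix:
    """Fixed +/-``window`` matrix around stranded reference points.

    ``points`` is a sequence of (id, chrom, position, strand).  Rows for
    minus-strand points are flipped so columns run 5'->3' relative to the
    point.  With ``antisense=True`` the opposite-strand track is sampled
    (coverage antisense to the point's orientation, e.g. PROMPT signal).
    """
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    n_half = window // bin_size
    rows = []
    ids = []
    for pid, chrom, pos, strand in points:
        track = _pick_track(tracks, strand, antisense=antisense)
        raw = track.fetch(chrom, pos - window, pos + window)
        if strand == "-":
            raw = raw[::-1]
        rows.append(raw.reshape(2 * n_half, bin_size).mean(axis=1))
        ids.append(pid)
    matrix = np.vstack(rows) if rows else np.zeros((0, 2 * n_half))
    return MetageneMatrix(matrix, ids, bin_size, (window, 0, window))


def mean_density(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Arithmetic mean of per-base signal over a half-open interval."""
    return track.mean(interval)
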