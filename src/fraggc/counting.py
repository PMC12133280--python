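"""Expected and observed fragment counting over (length, GC-bin) grids.

cfDNA GC bias is estimated per fragment length from two count matrices over
101 integer-percent GC bins:

* **expected counts** — for each fragment length ``l``, a GC context window
  is slid across every valid start position of the reference genome and the
  window's GC bin is tallied.  This is the "no bias" universe: what a
  perfectly uniform sequencer would have produced.
* **observed counts** — the same tally over the fragments actually present
  in a coordinate-sorted BAM, with the fragment's GC bin computed from the
  reference sequence under the fragment.

The GC context window excludes the first and last ``clip`` bases (default
10 bp) of the fragment, because base composition at fragment ends is
dominated by cleavage preference rather than amplification bias.

Two repair steps make the raw matrices usable at low depth:
:func:`interpolate_gaps` fills GC bins unattainable at a given integer
window size, and :func:`merge_neighbor_lengths` pools counts across
fragment lengths within +/- ``halfwidth`` bp, which share near-identical
bias curves.
"""

from __future__ import annotations

import hashlib
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import pysam

from .regions import RegionSet

__all__ = [
    "GCContext",
    "CountMatrix",
    "ReferenceGC",
    "gc_bin",
    "expected_counts",
    "observed_counts",
    "interpolate_gaps",
    "merge_neighbor_lengths",
    "fixed_window_expected",
    "fixed_window_observed",
    "fragment_interval",
    "eligible_pair",
]

N_GC_BINS = 101
DEFAULT_LENGTHS = (51, 400)
DEFAULT_CLIP = 10

_GC_BYTES = frozenset(b"GCgc")


@dataclass(frozen=True)
class GCContext:
    """Clipped window over which a fragment's GC content is measured."""

    fragment_length: int
    clip: int = DEFAULT_CLIP

    @property
    def window_size(self) -> int:
        return self.fragment_length - 2 * self.clip

    def __post_init__(self) -> None:
        if self.clip < 0:
            raise ValueError("clip must be >= 0")
        if self.window_size < 1:
            raise ValueError(
                f"fragment length {self.fragment_length} with clip "
                f"{self.clip} leaves an empty GC context window"
            )


@dataclass
class CountMatrix:
    """Fragment counts on a (fragment length) x (GC percent bin) grid.

    ``counts[i, g]`` is the count for fragment length ``lmin + i`` and GC
    bin ``g`` in 0..100.  With the default 51–400 bp range the matrix is
    350 x 101.
    """

    lmin: int
    lmax: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected_shape = (self.lmax - self.lmin + 1, N_GC_BINS)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != expected_shape:
            raise ValueError(
                f"counts shape {self.counts.shape} != {expected_shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def zeros(cls, lmin: int, lmax: int) -> "CountMatrix":
        return cls(lmin, lmax, np.zeros((lmax - lmin + 1, N_GC_BINS)))

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.lmin, self.lmax + 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row(self, length: int) -> np.ndarray:
        if not self.lmin <= length <= self.lmax:
            raise KeyError(f"length {length} outside [{self.lmin}, {self.lmax}]")
        return self.counts[length - self.lmin]

    def total(self) -> float:
        return float(self.counts.sum())

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(
            self.counts, index=self.lengths, columns=np.arange(N_GC_BINS)
        )
        df.index.name = "length"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str) -> "CountMatrix":
        df = pd.read_csv(path, index_col=0)
        lengths = df.index.to_numpy()
        return cls(int(lengths[0]), int(lengths[-1]), df.to_numpy())


class ReferenceGC:
    """Lazy per-contig GC prefix sums over an indexed FASTA.

    Ambiguous bases (N etc.) count as non-GC; valid-region BED files
    normally exclude N runs, so this only touches stray bases.
    """

    def __init__(self, fasta: str | pysam.FastaFile):
        self.fasta = (
            fasta if isinstance(fasta, pysam.FastaFile) else pysam.FastaFile(fasta)
        )
        self._prefix: dict[str, np.ndarray] = {}
        self._seq: dict[str, bytes] = {}

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(zip(self.fasta.references, self.fasta.lengths))

    def sequence(self, contig: str) -> bytes:
        if contig not in self._seq:
            self._seq[contig] = self.fasta.fetch(contig).upper().encode()
        return self._seq[contig]

    def prefix(self, contig: str) -> np.ndarray:
        """prefix[i] = number of G/C bases in contig[0:i]."""
        if contig not in self._prefix:
            arr = np.frombuffer(self.sequence(contig), dtype=np.uint8)
            is_gc = (arr == ord("G")) | (arr == ord("C"))
            pre = np.zeros(len(arr) + 1, dtype=np.int64)
            np.cumsum(is_gc, out=pre[1:])
            self._prefix[contig] = pre
        return self._prefix[contig]

    def gc_count(self, contig: str, start: int, end: int) -> int:
        pre = self.prefix(contig)
        return int(pre[end] - pre[start])


def _bin_from_counts(gc: np.ndarray | int, window: int):
    """Integer-percent GC bin with round-half-up, exact in integer math."""
    return (200 * gc + window) // (2 * window)


def gc_bin(window_sequence: str, context: GCContext | None = None) -> int:
    """GC bin (0..100) of a context window, round-half-up to integer percent.

    ``context`` only validates that the sequence has the expected window
    size; pass None to bin an arbitrary sequence.
    """
    seq = window_sequence.encode() if isinstance(window_sequence, str) else window_sequence
    w = len(seq)
    if context is not None and w != context.window_size:
        raise ValueError(
            f"window length {w} != context window size {context.window_size}"
        )
    if w < 1:
        raise ValueError("empty GC context window")
    gc = sum(b in _GC_BYTES for b in seq)
    return int(_bin_from_counts(gc, w))


def expected_counts(
    reference: str | pysam.FastaFile | ReferenceGC,
    regions: RegionSet,
    lengths: tuple[int, int] = DEFAULT_LENGTHS,
    clip: int = DEFAULT_CLIP,
) -> CountMatrix:
    """Slide length-specific GC context windows over all valid positions.

    A start position ``p`` is valid for length ``l`` iff the whole putative
    fragment ``[p, p+l)`` lies inside a single valid interval, mirroring the
    filter applied to observed fragments.  Every valid position is counted
    exactly — the sweep is exhaustive, not sampled.
    """
    lmin, lmax = lengths
    GCContext(lmin, clip)  # validates the smallest window
    ref = reference if isinstance(reference, ReferenceGC) else ReferenceGC(reference)
    mat = CountMatrix.zeros(lmin, lmax)
    for contig in regions.contigs:
        ivs = regions.intervals_for(contig)
        if len(ivs) == 0:
            continue
        pre = ref.prefix(contig)
        for li, l in enumerate(range(lmin, lmax + 1)):
            w = l - 2 * clip
            row = mat.counts[li]
            for s, e in ivs:
                if e - s < l:
                    continue
                starts = np.arange(s, e - l + 1)
                gc = pre[starts + (l - clip)] - pre[starts + clip]
                bins = _bin_from_counts(gc, w)
                row += np.bincount(bins, minlength=N_GC_BINS)
    return mat


def expected_counts_cached(
    reference_path: str,
    regions_path: str,
    regions: RegionSet,
    lengths: tuple[int, int] = DEFAULT_LENGTHS,
    clip: int = DEFAULT_CLIP,
    cache_dir: str | None = None,
) -> CountMatrix:
    """Expected counts, cached to CSV keyed by reference+regions+parameters.

    The sweep depends only on the genome, so it is computed once per
    (reference, valid-regions, length range, clip) combination.
    """
    if cache_dir is None:
        return expected_counts(reference_path, regions, lengths, clip)
    h = hashlib.sha256()
    for p in (reference_path, regions_path):
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    h.update(f"{lengths[0]}:{lengths[1]}:{clip}".encode())
    os.makedirs(cache_dir, exist_ok=True)
    cache = os.path.join(cache_dir, f"expected_{h.hexdigest()[:16]}.csv")
    if os.path.exists(cache):
        return CountMatrix.from_csv(cache)
    mat = expected_counts(reference_path, regions, lengths, clip)
    mat.to_csv(cache)
    return mat


def eligible_pair(read: pysam.AlignedSegment, min_mapq: int = 0) -> bool:
    """Pair-level read filters shared by counting, tagging and coverage.

    Excludes unmapped/mate-unmapped, secondary, supplementary, duplicate and
    QC-fail reads and requires a proper pair.  No mapping-quality cutoff by
    default.
    """
    if (
        read.is_unmapped
        or read.mate_is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
        or not read.is_proper_pair
    ):
        return False
    return read.mapping_quality >= min_mapq


def fragment_interval(read: pysam.AlignedSegment) -> tuple[int, int] | None:
    """Fragment [start, end) implied by POS/TLEN, from either mate.

    Returns None when the template length is zero (undefined fragment).
    """
    tlen = read.template_length
    if tlen > 0:
        start = read.reference_start
    elif tlen < 0:
        start = read.next_reference_start
        tlen = -tlen
    else:
        return None
    return start, start + tlen


def observed_counts(
    bam: str,
    reference: str | pysam.FastaFile | ReferenceGC,
    regions: RegionSet,
    lengths: tuple[int, int] = DEFAULT_LENGTHS,
    clip: int = DEFAULT_CLIP,
    min_mapq: int = 0,
    extra_filter: Callable[[pysam.AlignedSegment], bool] | None = None,
) -> CountMatrix:
    """Tally BAM fragments into a (length, GC bin) count matrix.

    Each fragment is counted exactly once, from the forward-strand read of a
    properly paired, non-duplicate, non-secondary, non-supplementary pair
    with positive template length; the fragment is ``[POS, POS+TLEN)``.
    Fragments outside the length range or not wholly inside a valid interval
    are skipped.  GC content comes from the reference sequence under the
    clipped window, never from read bases, so sequencing errors cannot
    perturb the bin.

    ``extra_filter`` is a pluggable per-read predicate (return False to drop
    the fragment); it defaults to no additional filtering.
    """
    lmin, lmax = lengths
    ref = reference if isinstance(reference, ReferenceGC) else ReferenceGC(reference)
    mat = CountMatrix.zeros(lmin, lmax)
    with pysam.AlignmentFile(bam, "rb") as af:
        if not af.has_index():
            raise ValueError(f"{bam} has no index (.bai); sort and index it")
        for contig in regions.contigs:
            if contig not in af.references:
                continue
            ivs = regions.intervals_for(contig)
            starts_arr, ends_arr = ivs[:, 0], ivs[:, 1]
            pre = ref.prefix(contig)
            counts = mat.counts
            for read in af.fetch(contig):
                if read.is_reverse or read.template_length <= 0:
                    continue
                if not eligible_pair(read, min_mapq):
                    continue
                if extra_filter is not None and not extra_filter(read):
                    continue
                l = read.template_length
                if l < lmin or l > lmax:
                    continue
                p = read.reference_start
                i = int(np.searchsorted(starts_arr, p, side="right")) - 1
                if i < 0 or p + l > ends_arr[i]:
                    continue
                w = l - 2 * clip
                gc = pre[p + l - clip] - pre[p + clip]
                counts[l - lmin, _bin_from_counts(gc, w)] += 1
    if mat.total() == 0:
        raise ValueError("no usable fragments")
    return mat


def attainable_bins(window: int) -> np.ndarray:
    """GC percent bins realizable by an integer window of the given size."""
    k = np.arange(window + 1)
    return np.unique(np.asarray(_bin_from_counts(k, window)))


def interpolate_gaps(row: np.ndarray, support: np.ndarray | None = None) -> np.ndarray:
    """Fill interior zero GC bins of one length row by linear interpolation.

    Integer context windows cannot realize every percent bin (an 80 bp
    fragment with a 60 bp window reaches at most 61 of the 101 bins), which
    leaves systematic zero gaps.  A zero bin strictly between two non-zero
    bins receives the linear interpolation of its nearest non-zero
    neighbors; non-zero bins are untouched and bins outside the outermost
    non-zero bins stay zero.  An all-zero row is returned unchanged.

    When ``support`` (the bins attainable at this window size) is given,
    only *unattainable* bins are filled: a zero at an attainable bin is
    genuine data (no fragments of that composition), and inventing counts
    there would systematically inflate sparsely populated rows.
    """
    row = np.asarray(row, dtype=np.float64).copy()
    nz = np.flatnonzero(row)
    if len(nz) < 2:
        return row
    inner = np.arange(nz[0] + 1, nz[-1])
    gaps = inner[row[inner] == 0]
    if support is not None and len(gaps):
        attain = np.zeros(len(row), dtype=bool)
        attain[np.asarray(support)] = True
        gaps = gaps[~attain[gaps]]
    if len(gaps):
        row[gaps] = np.interp(gaps, nz, row[nz])
    return row


def interpolate_matrix(matrix: CountMatrix, clip: int = DEFAULT_CLIP) -> CountMatrix:
    """:func:`interpolate_gaps` per length row, with the support implied by
    each length's clipped context window."""
    out = np.empty_like(matrix.counts)
    for i, l in enumerate(range(matrix.lmin, matrix.lmax + 1)):
        w = l - 2 * clip
        sup = attainable_bins(w) if w >= 1 else None
        out[i] = interpolate_gaps(matrix.counts[i], sup)
    return CountMatrix(matrix.lmin, matrix.lmax, out)


def merge_neighbor_lengths(matrix: CountMatrix, halfwidth: int = 2) -> CountMatrix:
    """Pool counts across fragment lengths within +/- ``halfwidth`` bp.

    Nearby fragment lengths show near-identical bias curves, so pooling
    sharpens per-length estimates — critically so for ultra-low-pass data.
    The window truncates at the ends of the length range.  Applied
    identically to observed and expected matrices so their ratio is
    unaffected when bias is length-independent.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    c = matrix.counts
    n = c.shape[0]
    cs = np.zeros((n + 1, c.shape[1]))
    np.cumsum(c, axis=0, out=cs[1:])
    lo = np.maximum(np.arange(n) - halfwidth, 0)
    hi = np.minimum(np.arange(n) + halfwidth + 1, n)
    return CountMatrix(matrix.lmin, matrix.lmax, cs[hi] - cs[lo])


def fixed_window_expected(
    reference: str | pysam.FastaFile | ReferenceGC,
    regions: RegionSet,
    window: int = 400,
) -> np.ndarray:
    """Expected GC-bin counts for a single fixed-size window (length-agnostic
    mode): the ``window``-bp context slid over all valid positions."""
    mat = expected_counts(reference, regions, lengths=(window, window), clip=0)
    return mat.counts[0]


def fixed_window_observed(
    bam: str,
    reference: str | pysam.FastaFile | ReferenceGC,
    regions: RegionSet,
    lengths: tuple[int, int] = DEFAULT_LENGTHS,
    window: int = 400,
    min_mapq: int = 0,
) -> np.ndarray:
    """Observed GC-bin counts with a fixed ``window``-bp context anchored at
    the fragment start, regardless of fragment length.

    Fragment eligibility is identical to :func:`observed_counts`; fragments
    whose window would run off the contig end are skipped.
    """
    lmin, lmax = lengths
    ref = reference if isinstance(reference, ReferenceGC) else ReferenceGC(reference)
    out = np.zeros(N_GC_BINS)
    contig_len = ref.contig_lengths
    with pysam.AlignmentFile(bam, "rb") as af:
        if not af.has_index():
            raise ValueError(f"{bam} has no index (.bai); sort and index it")
        for contig in regions.contigs:
            if contig not in af.references:
                continue
            ivs = regions.intervals_for(contig)
            starts_arr, ends_arr = ivs[:, 0], ivs[:, 1]
            pre = ref.prefix(contig)
            clen = contig_len[contig]
            for read in af.fetch(contig):
                if read.is_reverse or read.template_length <= 0:
                    continue
                if not eligible_pair(read, min_mapq):
                    continue
                l = read.template_length
                if l < lmin or l > lmax:
                    continue
                p = read.reference_start
                i = int(np.searchsorted(starts_arr, p, side="right")) - 1
                if i < 0 or p + l > ends_arr[i]:
                    continue
                if p + window > clen:
                    continue
                gc = pre[p + window] - pre[p]
                out[_bin_from_counts(gc, window)] += 1
    if out.sum() == 0:
        raise ValueError("no usable fragments")
    return out
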