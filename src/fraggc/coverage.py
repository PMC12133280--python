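"""Correction outputs: GC-tagged BAM and corrected binned coverage.

Given a fitted :class:`~fraggc.bias.CorrectionTable`, a sample can be
exported three ways:

* :meth:`CorrectionTable.to_csv` — the factor grid itself (see bias module);
* :func:`tag_bam` — a copy of the BAM where every read carries its
  fragment's correction factor as a float ``GC`` auxiliary tag (both mates
  of a pair get the same value; ineligible fragments get 0.0);
* :func:`corrected_coverage` — fixed-width genomic bins with raw fragment
  counts and correction-weighted counts, writable as CSV or fixedStep WIG
  for downstream copy-number callers.

Bin assignment is by fragment midpoint.  Correction factors are rounded to
single precision before accumulation so that summing ``GC`` tags from a
tagged BAM reproduces the corrected track bit-for-bit.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .bias import CorrectionTable
from .counting import ReferenceGC, _bin_from_counts, eligible_pair
from .regions import RegionSet

__all__ = ["CoverageTrack", "tag_bam", "corrected_coverage", "write_track"]

DEFAULT_BIN_SIZE = 100_000


@dataclass
class CoverageTrack:
    """Fixed-width bins tiling each contig with raw and corrected counts.

    ``bins`` columns: contig, start, end, raw, corrected.  Bins with no
    valid-region overlap are present but carry NaN (missing, not zero).
    """

    bin_size: int
    bins: pd.DataFrame = field(repr=False)

    def contig_bins(self, contig: str) -> pd.DataFrame:
        return self.bins[self.bins["contig"] == contig]


def _fragment_factor(
    read: pysam.AlignedSegment,
    table: CorrectionTable,
    regions: RegionSet | None,
    ref: ReferenceGC,
    clip: int,
    min_mapq: int,
) -> tuple[float, int, int] | None:
    """(float32 factor, fragment start, fragment end) for a read's fragment.

    Returns None when the read is not pair-eligible or the template length
    is zero; returns factor 0.0 for eligible fragments that fall outside
    the length range, the valid regions, or a zeroed GC bin.
    """
    if not eligible_pair(read, min_mapq):
        return None
    tlen = read.template_length
    if tlen > 0:
        start = read.reference_start
    elif tlen < 0:
        start = read.next_reference_start
        tlen = -tlen
    else:
        return None
    end = start + tlen
    contig = read.reference_name
    if tlen < table.lmin or tlen > table.lmax:
        return 0.0, start, end
    if regions is not None and not regions.contains_fragment(contig, start, end):
        return 0.0, start, end
    w = tlen - 2 * clip
    if w < 1:
        return 0.0, start, end
    gc = ref.gc_count(contig, start + clip, end - clip)
    g = int(_bin_from_counts(gc, w))
    return float(np.float32(table.factor(tlen, g))), start, end


def tag_bam(
    bam_in: str,
    bam_out: str,
    table: CorrectionTable,
    reference: str | ReferenceGC,
    regions: RegionSet | None = None,
    clip: int = 10,
    min_mapq: int = 0,
    chunk_by_contig: bool = False,
) -> str:
    """Write a copy of ``bam_in`` with a float ``GC`` tag on every read.

    Both mates of an eligible pair carry the fragment-level factor; reads
    whose fragment is out of the length range, outside ``regions`` (when
    given), or in a zeroed GC bin are tagged 0.0; reads that fail the pair
    filters are copied with tag 0.0 as well.  All reads, their order, and
    the header are otherwise preserved.  With ``chunk_by_contig`` the file
    is processed per reference sequence and concatenated, which yields an
    identical read set and tags as the single pass.
    """
    ref = reference if isinstance(reference, ReferenceGC) else ReferenceGC(reference)
    with pysam.AlignmentFile(bam_in, "rb") as af:
        if not af.has_index():
            raise ValueError(f"{bam_in} has no index (.bai); sort and index it")
        contigs = list(af.references)

    def _tag_range(out_path: str, contig: str | None) -> None:
        with pysam.AlignmentFile(bam_in, "rb") as src, pysam.AlignmentFile(
            out_path, "wb", template=src
        ) as dst:
            it = src.fetch(contig) if contig is not None else src.fetch(until_eof=True)
            for read in it:
                if read.is_unmapped:
                    read.set_tag("GC", 0.0, "f")
                else:
                    res = _fragment_factor(read, table, regions, ref, clip, min_mapq)
                    read.set_tag("GC", res[0] if res else 0.0, "f")
                dst.write(read)

    if not chunk_by_contig:
        _tag_range(bam_out, None)
    else:
        with tempfile.TemporaryDirectory(dir=os.path.dirname(bam_out) or ".") as td:
            parts = []
            for i, contig in enumerate(contigs):
                part = os.path.join(td, f"part{i}.bam")
                _tag_range(part, contig)
                parts.append(part)
            pysam.cat("-o", bam_out, *parts)
    pysam.index(bam_out)
    return bam_out


def corrected_coverage(
    bam: str,
    table: CorrectionTable,
    regions: RegionSet,
    reference: str | ReferenceGC,
    bin_size: int = DEFAULT_BIN_SIZE,
    clip: int = 10,
    min_mapq: int = 0,
) -> CoverageTrack:
    """Binned raw and correction-weighted fragment counts.

    Each eligible fragment (pair filters + length range + wholly inside a
    valid interval) adds 1 to its midpoint bin's raw count and its
    (single-precision) correction factor to the corrected count.  Bins with
    no valid-region overlap are marked missing (NaN).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    ref = reference if isinstance(reference, ReferenceGC) else ReferenceGC(reference)
    contig_lengths = ref.contig_lengths
    frames = []
    with pysam.AlignmentFile(bam, "rb") as af:
        if not af.has_index():
            raise ValueError(f"{bam} has no index (.bai); sort and index it")
        for contig in regions.contigs:
            if contig not in contig_lengths:
                continue
            clen = contig_lengths[contig]
            n_bins = (clen + bin_size - 1) // bin_size
            raw = np.zeros(n_bins)
            corr = np.zeros(n_bins)
            ivs = regions.intervals_for(contig)
            starts_arr, ends_arr = ivs[:, 0], ivs[:, 1]
            if contig in af.references:
                for read in af.fetch(contig):
                    if read.is_reverse or read.template_length <= 0:
                        continue
                    if not eligible_pair(read, min_mapq):
                        continue
                    l = read.template_length
                    if l < table.lmin or l > table.lmax:
                        continue
                    p = read.reference_start
                    i = int(np.searchsorted(starts_arr, p, side="right")) - 1
                    if i < 0 or p + l > ends_arr[i]:
                        continue
                    w = l - 2 * clip
                    if w < 1:
                        continue
                    gc = ref.gc_count(contig, p + clip, p + l - clip)
                    g = int(_bin_from_counts(gc, w))
                    k = (p + l // 2) // bin_size
                    raw[k] += 1
                    corr[k] += np.float32(table.factor(l, g))
            # bins with zero valid-region overlap are missing, not zero
            bin_starts = np.arange(n_bins) * bin_size
            bin_ends = np.minimum(bin_starts + bin_size, clen)
            overlap = np.zeros(n_bins, dtype=bool)
            for s, e in ivs:
                k0, k1 = s // bin_size, (e - 1) // bin_size
                overlap[k0 : k1 + 1] = True
            raw_col = raw.astype(float)
            corr_col = corr.astype(float)
            raw_col[~overlap] = np.nan
            corr_col[~overlap] = np.nan
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "start": bin_starts,
                        "end": bin_ends,
                        "raw": raw_col,
                        "corrected": corr_col,
                    }
                )
            )
    if not frames:
        raise ValueError("no contigs shared between regions and reference")
    return CoverageTrack(bin_size, pd.concat(frames, ignore_index=True))


def write_track(track: CoverageTrack, path: str, fmt: str = "csv") -> str:
    """Write a coverage track as CSV or fixedStep WIG.

    CSV columns: contig,start,end,raw,corrected (missing bins as empty
    cells).  WIG: 1-based fixedStep with step = span = bin size, carrying
    the corrected counts; missing bins break the block, and contigs with no
    data are omitted.
    """
    if fmt == "csv":
        track.bins.to_csv(path, index=False, float_format="%.6f")
    elif fmt == "wig":
        with open(path, "w") as fh:
            for contig, sub in track.bins.groupby("contig", sort=False):
                sub = sub.sort_values("start")
                prev_end = None
                for _, row in sub.iterrows():
                    if not np.isfinite(row["corrected"]):
                        prev_end = None
                        continue
                    if prev_end != row["start"]:
                        fh.write(
                            f"fixedStep chrom={contig} start={int(row['start']) + 1} "
                            f"step={track.bin_size} span={track.bin_size}\n"
                        )
                    fh.write(f"{row['corrected']:.4f}\n")
                    prev_end = row["start"] + track.bin_size
    else:
        raise ValueError(f"unknown track format {fmt!r}")
    return path
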