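"""Downstream application procedures: fetal-fraction mixing and NDR scores.

Fetal-fraction simulation: non-invasive prenatal testing estimates the
fetal fraction of maternal plasma cfDNA from per-autosome read counts.
Mixing X% of a male sample's fragments into a female sample yields a
synthetic "pregnancy" with an exactly known fetal fraction of
100·X/(X+100) percent.  The quality of count-based estimation depends on
how even coverage is across autosomes, summarized here by the SD of the 22
mean-normalized count-to-length ratios (ideally 0).

NDR score: the nucleosome-depleted region around a transcription start
site shows a coverage dip proportional to promoter activity.  The score is
the mean coverage in the strand-oriented −150..+50 bp window around the
TSS divided by the mean coverage in the ±1000..2000 bp flanks; GC
correction is applied by weighting each fragment with its correction
factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .bias import CorrectionTable
from .counting import ReferenceGC, _bin_from_counts, eligible_pair
from .regions import RegionSet

__all__ = [
    "MixSpec",
    "ground_truth_fetal_fraction",
    "mix_samples",
    "autosome_ratios",
    "autosome_ratio_sd",
    "TSSRecord",
    "ndr_score",
]


def ground_truth_fetal_fraction(x_percent: float) -> float:
    """Exact fetal fraction (percent) from mixing X% male into 100% female.

    ff = 100·X / (X + 100); e.g. X=5 → 4.7619…%, X=10 → 9.0909…%.
    Computed with rational arithmetic before conversion to float.
    """
    if not 0 < x_percent < 100:
        raise ValueError("mixing percent must be in (0, 100)")
    x = Fraction(x_percent).limit_denominator(10**9)
    return float(100 * x / (x + 100))


@dataclass(frozen=True)
class MixSpec:
    """Mixing recipe: X% of male fragments into the full female sample."""

    x_percent: float
    seed: int = 0

    @property
    def ground_truth_ff(self) -> float:
        return ground_truth_fetal_fraction(self.x_percent)


def _select_qnames(bam: str, fraction: float, seed: int) -> set[str]:
    """Deterministic pair-consistent fragment selection by query name."""
    with pysam.AlignmentFile(bam, "rb") as af:
        qnames = sorted({r.query_name for r in af.fetch(until_eof=True)})
    rng = np.random.default_rng(seed)
    u = rng.random(len(qnames))
    return {q for q, ui in zip(qnames, u) if ui < fraction}


def mix_samples(
    female_bam: str,
    male_bam: str,
    spec: MixSpec,
    out_bam: str,
) -> float:
    """Merge a seeded X% of male fragments with all female fragments.

    Selection is by query name, so mates are never orphaned.  Query names
    are prefixed ``F:``/``M:`` in the merged file so that reads from the
    two sources can never collide on a shared name.  Both BAMs must share
    the reference (identical SQ header lines).  The merged file is
    coordinate-sorted and indexed.  Returns the exact ground-truth fetal
    fraction in percent.
    """
    with pysam.AlignmentFile(female_bam, "rb") as f, pysam.AlignmentFile(
        male_bam, "rb"
    ) as m:
        fsq = [(c, l) for c, l in zip(f.references, f.lengths)]
        msq = [(c, l) for c, l in zip(m.references, m.lengths)]
        if fsq != msq:
            raise ValueError("female and male BAMs use different references")
    keep = _select_qnames(male_bam, spec.x_percent / 100.0, spec.seed)
    unsorted = out_bam + ".unsorted.bam"
    with pysam.AlignmentFile(female_bam, "rb") as f:
        with pysam.AlignmentFile(unsorted, "wb", template=f) as out:
            for read in f.fetch(until_eof=True):
                read.query_name = "F:" + read.query_name
                out.write(read)
            with pysam.AlignmentFile(male_bam, "rb") as m:
                for read in m.fetch(until_eof=True):
                    if read.query_name in keep:
                        read.query_name = "M:" + read.query_name
                        out.write(read)
    pysam.sort("-o", out_bam, unsorted)
    pysam.index(out_bam)
    import os

    os.remove(unsorted)
    return spec.ground_truth_ff


def _contig_fragment_weight(
    af: pysam.AlignmentFile,
    contig: str,
    table: CorrectionTable | None,
    ref: ReferenceGC | None,
    regions: RegionSet | None,
    lengths: tuple[int, int],
    clip: int,
    min_mapq: int,
) -> float:
    total = 0.0
    lmin, lmax = lengths
    ivs = regions.intervals_for(contig) if regions is not None else None
    for read in af.fetch(contig):
        if read.is_reverse or read.template_length <= 0:
            continue
        if not eligible_pair(read, min_mapq):
            continue
        l = read.template_length
        if l < lmin or l > lmax:
            continue
        p = read.reference_start
        if ivs is not None:
            i = int(np.searchsorted(ivs[:, 0], p, side="right")) - 1
            if i < 0 or p + l > ivs[i, 1]:
                continue
        if table is None:
            total += 1.0
        else:
            w = l - 2 * clip
            if w < 1:
                continue
            gc = ref.gc_count(contig, p + clip, p + l - clip)
            total += table.factor(l, int(_bin_from_counts(gc, w)))
    return total


def autosome_ratios(
    bam: str,
    autosome_lengths: Mapping[str, int],
    table: CorrectionTable | None = None,
    reference: str | ReferenceGC | None = None,
    regions: RegionSet | None = None,
    lengths: tuple[int, int] = (51, 400),
    clip: int = 10,
    min_mapq: int = 0,
) -> pd.Series:
    """Mean-normalized fragment-count-to-length ratio per autosome.

    With a :class:`CorrectionTable` (plus reference), fragments are
    factor-weighted before the ratio is taken.  Raises if any listed
    autosome is missing from the BAM header.
    """
    if table is not None and reference is None:
        raise ValueError("factor-weighted ratios require the reference FASTA")
    ref = (
        reference
        if isinstance(reference, ReferenceGC) or reference is None
        else ReferenceGC(reference)
    )
    with pysam.AlignmentFile(bam, "rb") as af:
        missing = [c for c in autosome_lengths if c not in af.references]
        if missing:
            raise ValueError(f"autosomes missing from BAM: {missing}")
        counts = {
            contig: _contig_fragment_weight(
                af, contig, table, ref, regions, lengths, clip, min_mapq
            )
            for contig in autosome_lengths
        }
    ratios = pd.Series(
        {c: counts[c] / autosome_lengths[c] for c in autosome_lengths},
        name="ratio",
        dtype=float,
    )
    return ratios / ratios.mean()


def autosome_ratio_sd(
    bam: str,
    autosome_lengths: Mapping[str, int],
    **kwargs,
) -> float:
    """Population SD of the mean-normalized per-autosome ratios (ideal: 0)."""
    ratios = autosome_ratios(bam, autosome_lengths, **kwargs)
    return float(ratios.to_numpy().std())


@dataclass(frozen=True)
class TSSRecord:
    """Transcription start site with strand-oriented score windows."""

    contig: str
    tss_position: int  # 0-based
    strand: str = "+"
    name: str = ""

    NDR_WINDOW = (-150, 50)
    FLANK_UPSTREAM = (-2000, -1000)
    FLANK_DOWNSTREAM = (1000, 2000)

    def _window(self, a: int, b: int) -> tuple[int, int]:
        """Genomic [start, end) for oriented offsets [a, b) around the TSS."""
        if self.strand == "-":
            a, b = -b + 1, -a + 1
        return self.tss_position + a, self.tss_position + b

    @property
    def ndr_window(self) -> tuple[int, int]:
        return self._window(*self.NDR_WINDOW)

    @property
    def flank_windows(self) -> list[tuple[int, int]]:
        return [
            self._window(*self.FLANK_UPSTREAM),
            self._window(*self.FLANK_DOWNSTREAM),
        ]


def load_tss_bed(path: str) -> list[TSSRecord]:
    """Read TSS positions from a BED6 file (name and strand columns used)."""
    out = []
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["contig", "start", "end", "name", "score", "strand"],
    )
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in ("+", "-") else "+"
        pos = row.start if strand == "+" else row.end - 1
        out.append(TSSRecord(row.contig, int(pos), strand, str(row.name)))
    return out


def _window_coverage(
    af: pysam.AlignmentFile,
    contig: str,
    start: int,
    end: int,
    table: CorrectionTable | None,
    ref: ReferenceGC | None,
    lengths: tuple[int, int],
    clip: int,
    min_mapq: int,
    max_fragment: int = 500,
) -> float:
    """Mean (optionally factor-weighted) fragment coverage over [start, end)."""
    total = 0.0
    lmin, lmax = lengths
    fetch_start = max(0, start - max_fragment)
    for read in af.fetch(contig, fetch_start, end):
        if read.is_reverse or read.template_length <= 0:
            continue
        if not eligible_pair(read, min_mapq):
            continue
        l = read.template_length
        if l < lmin or l > lmax:
            continue
        p = read.reference_start
        overlap = min(p + l, end) - max(p, start)
        if overlap <= 0:
            continue
        if table is None:
            weight = 1.0
        else:
            w = l - 2 * clip
            if w < 1:
                continue
            gc = ref.gc_count(contig, p + clip, p + l - clip)
            weight = table.factor(l, int(_bin_from_counts(gc, w)))
        total += overlap * weight
    return total / (end - start)


def ndr_score(
    bam: str,
    tss: TSSRecord,
    table: CorrectionTable | None = None,
    reference: str | ReferenceGC | None = None,
    lengths: tuple[int, int] = (51, 400),
    clip: int = 10,
    min_mapq: int = 0,
) -> float:
    """Mean NDR-window coverage divided by pooled flank coverage.

    Returns NaN (with a warning) when the flanks have zero coverage.  The
    score is invariant to global coverage scaling; a value below 1 marks
    nucleosome depletion at the TSS.
    """
    if table is not None and reference is None:
        raise ValueError("corrected NDR scores require the reference FASTA")
    ref = (
        reference
        if isinstance(reference, ReferenceGC) or reference is None
        else ReferenceGC(reference)
    )
    with pysam.AlignmentFile(bam, "rb") as af:
        s, e = tss.ndr_window
        ndr_mean = _window_coverage(
            af, tss.contig, s, e, table, ref, lengths, clip, min_mapq
        )
        flank_total = 0.0
        flank_bases = 0
        for fs, fe in tss.flank_windows:
            flank_total += _window_coverage(
                af, tss.contig, fs, fe, table, ref, lengths, clip, min_mapq
            ) * (fe - fs)
            flank_bases += fe - fs
    flank_mean = flank_total / flank_bases
    if flank_mean <= 0:
        warnings.warn(
            f"zero flank coverage at {tss.contig}:{tss.tss_position}; "
            "NDR score undefined",
            stacklevel=2,
        )
        return float("nan")
    return ndr_mean / flank_mean
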