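"""Synthetic cfDNA fixtures: reference genomes, regions and biased BAMs.

The simulator builds everything a correction run needs, with known ground
truth:

* :func:`make_reference` — a small multi-contig FASTA whose GC content
  sweeps blockwise across the contig (e.g. 30%→65%), so any GC bias
  expresses itself as coverage waves, plus a valid-regions BED that
  excludes short masked stretches.
* :func:`simulate_fragments` — paired-end fragments drawn by rejection
  sampling: a uniform candidate position and a mixture-of-normals length,
  accepted with probability a(l, g) given by a :class:`BiasSpec` (so the
  observed/expected ratio equals a(l, g) in expectation), optionally
  modulated by copy-number segments.  Emits a coordinate-sorted indexed
  BAM of proper pairs and a :class:`SimTruth` record of every accepted
  fragment.
* :func:`downsample` — seeded pair-consistent Bernoulli thinning, the
  standard way of emulating lower-coverage sequencing.

Read sequences are copied from the reference; sequencing error, base
quality and adapters are deliberately not modeled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import pysam

from .counting import ReferenceGC, _bin_from_counts
from .regions import RegionSet

__all__ = [
    "BiasSpec",
    "SimTruth",
    "CNVSegment",
    "make_reference",
    "simulate_fragments",
    "downsample",
    "DEFAULT_LENGTH_MIXTURE",
]

# mixture of normals (mean, sd, weight): mono-nucleosomal main peak,
# di-nucleosomal shoulder, short sub-nucleosomal tail
DEFAULT_LENGTH_MIXTURE = ((166.0, 10.0, 0.85), (320.0, 15.0, 0.10), (80.0, 8.0, 0.05))


@dataclass(frozen=True)
class CNVSegment:
    contig: str
    start: int
    end: int
    cn: float  # 2.0 = neutral; placement density scales with cn/2


@dataclass(frozen=True)
class BiasSpec:
    """Length-dependent GC acceptance curve a(l, g) in (0, 1].

    ``bands`` maps inclusive length ranges to a regime: ``flat`` (a = 1),
    ``bell`` (Gaussian in g around ``center`` with ``width``),
    ``increasing`` / ``decreasing`` (linear in g).  All regimes are floored
    at ``floor`` so acceptance never vanishes.
    """

    bands: tuple[tuple[int, int, str], ...] = ((1, 10_000, "flat"),)
    center: float = 50.0
    width: float = 10.0
    floor: float = 1e-3

    @classmethod
    def flat(cls) -> "BiasSpec":
        return cls()

    @classmethod
    def bell(cls, center: float = 50.0, width: float = 10.0) -> "BiasSpec":
        return cls(bands=((1, 10_000, "bell"),), center=center, width=width)

    @classmethod
    def increasing(cls) -> "BiasSpec":
        return cls(bands=((1, 10_000, "increasing"),))

    @classmethod
    def mixed(cls) -> "BiasSpec":
        """Regime shifts along fragment length: rising for the shortest
        fragments, bell through the mono-nucleosomal range, rising again,
        then bell for the longest."""
        return cls(
            bands=(
                (1, 80, "increasing"),
                (81, 220, "bell"),
                (221, 300, "increasing"),
                (301, 10_000, "bell"),
            )
        )

    def acceptance(self, lengths: np.ndarray, gc_bins: np.ndarray) -> np.ndarray:
        lengths = np.asarray(lengths)
        g = np.asarray(gc_bins, dtype=np.float64)
        a = np.ones_like(g, dtype=np.float64)
        for lo, hi, regime in self.bands:
            mask = (lengths >= lo) & (lengths <= hi)
            if not mask.any():
                continue
            if regime == "flat":
                val = np.ones(mask.sum())
            elif regime == "bell":
                val = np.exp(-((g[mask] - self.center) ** 2) / (2 * self.width**2))
            elif regime == "increasing":
                val = g[mask] / 100.0
            elif regime == "decreasing":
                val = 1.0 - g[mask] / 100.0
            else:
                raise ValueError(f"unknown bias regime {regime!r}")
            a[mask] = val
        return np.maximum(a, self.floor)


@dataclass
class SimTruth:
    """Ground truth for one simulated sample."""

    fragments: pd.DataFrame = field(repr=False)  # contig, start, length, gc_bin
    bias: BiasSpec = field(default_factory=BiasSpec.flat)
    cnv: tuple[CNVSegment, ...] = ()
    acceptance_rate: float = float("nan")

    @property
    def n(self) -> int:
        return len(self.fragments)


def _triangle(phase: np.ndarray) -> np.ndarray:
    """Triangle wave in [0, 1] with period 1."""
    frac = np.mod(phase, 1.0)
    return 1.0 - np.abs(2.0 * frac - 1.0)


def make_reference(
    seed: int,
    out_prefix: str,
    contigs: int = 3,
    contig_len: int = 300_000,
    gc_range: tuple[float, float] = (0.30, 0.70),
    block: int = 5_000,
    mask_every: int = 150_000,
    mask_len: int = 2_000,
    names: Sequence[str] | None = None,
) -> tuple[str, str]:
    """Write a synthetic FASTA (+ .fai) and valid-regions BED.

    Each contig's GC content sweeps as a triangle wave between the
    ``gc_range`` bounds in ``block``-bp blocks, with per-contig phase
    offsets so contigs differ.  Every ``mask_every`` bp a ``mask_len``-bp
    stretch is excluded from the BED (emulating blacklisted regions).
    Deterministic for a fixed seed.  Returns (fasta path, bed path).
    """
    rng = np.random.default_rng(seed)
    names = list(names) if names is not None else [f"chr{i + 1}" for i in range(contigs)]
    lo, hi = gc_range
    fasta_path = out_prefix + ".fa"
    bed_path = out_prefix + ".bed"
    bases_at = np.frombuffer(b"AT", dtype="S1")
    bases_gc = np.frombuffer(b"GC", dtype="S1")
    with open(fasta_path, "w") as fa, open(bed_path, "w") as bed:
        for ci, name in enumerate(names):
            n_blocks = (contig_len + block - 1) // block
            phase = np.arange(n_blocks) / max(n_blocks - 1, 1) * 2.0 + ci / len(names)
            targets = lo + (hi - lo) * _triangle(phase)
            seq_parts = []
            for j in range(n_blocks):
                blen = min(block, contig_len - j * block)
                is_gc = rng.random(blen) < targets[j]
                chars = np.where(
                    is_gc,
                    bases_gc[rng.integers(0, 2, blen)],
                    bases_at[rng.integers(0, 2, blen)],
                )
                seq_parts.append(chars.tobytes().decode())
            seq = "".join(seq_parts)
            fa.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fa.write(seq[i : i + 70] + "\n")
            # valid regions = contig minus periodic masks
            masks = [
                (s, min(s + mask_len, contig_len))
                for s in range(mask_every, contig_len, mask_every)
            ]
            prev = 0
            for ms, me in masks:
                if ms > prev:
                    bed.write(f"{name}\t{prev}\t{ms}\n")
                prev = me
            if prev < contig_len:
                bed.write(f"{name}\t{prev}\t{contig_len}\n")
    pysam.faidx(fasta_path)
    return fasta_path, bed_path


def _draw_lengths(
    rng: np.random.Generator,
    n: int,
    mixture: Sequence[tuple[float, float, float]],
    lrange: tuple[int, int],
) -> np.ndarray:
    means, sds, weights = (np.array(c) for c in zip(*mixture))
    weights = weights / weights.sum()
    comp = rng.choice(len(means), size=n, p=weights)
    raw = rng.normal(means[comp], sds[comp])
    return np.clip(np.rint(raw), lrange[0], lrange[1]).astype(np.int64)


def simulate_fragments(
    fasta: str,
    regions: RegionSet,
    n: int,
    out_bam: str,
    bias: BiasSpec | None = None,
    length_mixture: Sequence[tuple[float, float, float]] = DEFAULT_LENGTH_MIXTURE,
    cnv: Sequence[CNVSegment] = (),
    seed: int = 0,
    lengths: tuple[int, int] = (51, 400),
    clip: int = 10,
    read_len: int = 50,
) -> SimTruth:
    """Rejection-sample ``n`` fragments and write them as a paired BAM.

    Candidate fragments get a uniform start within a length-weighted valid
    interval and a mixture-drawn length (clipped to ``lengths``); a
    candidate is kept with probability a(l, g) · (cn/2) / max(cn/2), where
    g is the GC bin of the clipped context window on the reference.  Each
    accepted fragment becomes one proper pair (TLEN ±l, 50 bp reads copied
    from the reference).  Raises when fewer than 1% of candidates are
    accepted.
    """
    bias = bias or BiasSpec.flat()
    rng = np.random.default_rng(seed)
    ref = ReferenceGC(fasta)
    contig_names = list(ref.contig_lengths)
    name_to_idx = {c: i for i, c in enumerate(contig_names)}

    iv_contig, iv_start, iv_end = [], [], []
    for iv in regions:
        iv_contig.append(name_to_idx[iv.contig])
        iv_start.append(iv.start)
        iv_end.append(iv.end)
    iv_contig = np.array(iv_contig)
    iv_start = np.array(iv_start)
    iv_end = np.array(iv_end)
    iv_weight = (iv_end - iv_start).astype(np.float64)
    iv_weight /= iv_weight.sum()

    cnv = tuple(cnv)
    max_density = max([1.0] + [seg.cn / 2.0 for seg in cnv])

    acc_contig, acc_start, acc_len, acc_gc = [], [], [], []
    total_draws = 0
    total_accepted = 0
    while total_accepted < n:
        batch = max(int((n - total_accepted) * 2.5), 20_000)
        k = rng.choice(len(iv_start), size=batch, p=iv_weight)
        pos = iv_start[k] + (rng.random(batch) * (iv_end[k] - iv_start[k])).astype(np.int64)
        ls = _draw_lengths(rng, batch, length_mixture, lengths)
        ok = (pos + ls <= iv_end[k]) & (ls - 2 * clip >= 1)
        cidx = iv_contig[k]
        gc_bin = np.zeros(batch, dtype=np.int64)
        for ci in np.unique(cidx[ok]):
            m = ok & (cidx == ci)
            pre = ref.prefix(contig_names[ci])
            gc = pre[pos[m] + ls[m] - clip] - pre[pos[m] + clip]
            gc_bin[m] = _bin_from_counts(gc, ls[m] - 2 * clip)
        p_acc = np.where(ok, bias.acceptance(ls, gc_bin), 0.0)
        if cnv:
            density = np.ones(batch)
            mid = pos + ls // 2
            for seg in cnv:
                ci = name_to_idx[seg.contig]
                inside = (cidx == ci) & (mid >= seg.start) & (mid < seg.end)
                density[inside] = seg.cn / 2.0
            p_acc *= density / max_density
        keep = rng.random(batch) < p_acc
        total_draws += batch
        total_accepted += int(keep.sum())
        acc_contig.append(cidx[keep])
        acc_start.append(pos[keep])
        acc_len.append(ls[keep])
        acc_gc.append(gc_bin[keep])
        if total_draws >= 100_000 and total_accepted < 0.01 * total_draws:
            raise RuntimeError(
                f"acceptance rate {total_accepted / total_draws:.4f} below 1%; "
                "raise the bias floor or adjust the acceptance curve"
            )

    cidx = np.concatenate(acc_contig)[:n]
    pos = np.concatenate(acc_start)[:n]
    ls = np.concatenate(acc_len)[:n]
    gcb = np.concatenate(acc_gc)[:n]

    order = np.lexsort((pos, cidx))
    cidx, pos, ls, gcb = cidx[order], pos[order], ls[order], gcb[order]

    sam_path = out_bam + ".tmp.sam"
    qual = "I" * read_len
    with open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cname, clen in ref.contig_lengths.items():
            sam.write(f"@SQ\tSN:{cname}\tLN:{clen}\n")
        for i in range(n):
            cname = contig_names[cidx[i]]
            seq = ref.sequence(cname)
            p, l = int(pos[i]), int(ls[i])
            rl = min(read_len, l)
            s1 = seq[p : p + rl].decode()
            s2 = seq[p + l - rl : p + l].decode()
            q = qual[:rl]
            qn = f"f{i}"
            sam.write(
                f"{qn}\t99\t{cname}\t{p + 1}\t60\t{rl}M\t=\t{p + l - rl + 1}\t{l}\t{s1}\t{q}\n"
                f"{qn}\t147\t{cname}\t{p + l - rl + 1}\t60\t{rl}M\t=\t{p + 1}\t{-l}\t{s2}\t{q}\n"
            )
    pysam.sort("-o", out_bam, sam_path)
    pysam.index(out_bam)
    os.remove(sam_path)

    fragments = pd.DataFrame(
        {
            "contig": [contig_names[c] for c in cidx],
            "start": pos,
            "length": ls,
            "gc_bin": gcb,
        }
    )
    return SimTruth(
        fragments=fragments,
        bias=bias,
        cnv=cnv,
        acceptance_rate=total_accepted / total_draws,
    )


def downsample(bam: str, fraction: float, seed: int, out_bam: str) -> int:
    """Pair-consistent Bernoulli thinning of a coordinate-sorted BAM.

    Fragments (query names) are kept independently with probability
    ``fraction``; both mates follow the same draw.  Deterministic for a
    fixed seed.  Returns the number of reads written.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    with pysam.AlignmentFile(bam, "rb") as af:
        qnames = sorted({r.query_name for r in af.fetch(until_eof=True)})
    rng = np.random.default_rng(seed)
    keep = {q for q, u in zip(qnames, rng.random(len(qnames))) if u < fraction}
    written = 0
    with pysam.AlignmentFile(bam, "rb") as src:
        with pysam.AlignmentFile(out_bam, "wb", template=src) as dst:
            for read in src.fetch(until_eof=True):
                if read.query_name in keep:
                    dst.write(read)
                    written += 1
    pysam.index(out_bam)
    return written
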