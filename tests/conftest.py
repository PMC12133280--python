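"""Shared fixtures: synthetic genomes and simulated samples.

All fixtures are generated programmatically at session start; nothing is
stored on disk in the repository.  The "bell" sample reproduces the study
conditions used throughout: a 3 x 300 kb genome whose GC sweeps 30–70% in
5 kb blocks, 500k fragments with a Gaussian(50, 10) GC acceptance curve.
"""

from __future__ import annotations

import warnings

import numpy as np
import pysam
import pytest
from hypothesis import settings

import fraggc as fg
from fraggc.counting import interpolate_matrix, merge_neighbor_lengths

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_genome(tmp_path_factory):
    d = tmp_path_factory.mktemp("tiny")
    fasta, bed = fg.make_reference(
        5,
        str(d / "tiny"),
        contigs=2,
        contig_len=50_000,
        mask_every=20_000,
        mask_len=1_000,
    )
    ref = fg.ReferenceGC(fasta)
    regions = fg.load_regions(bed, ref.contig_lengths)
    return {"fasta": fasta, "bed": bed, "ref": ref, "regions": regions}


@pytest.fixture(scope="session")
def small_sim(tiny_genome, tmp_path_factory):
    """Unbiased 30k-fragment sample on the tiny genome, fully processed."""
    d = tmp_path_factory.mktemp("small_sim")
    bam = str(d / "flat.bam")
    truth = fg.simulate_fragments(
        tiny_genome["fasta"],
        tiny_genome["regions"],
        30_000,
        bam,
        bias=fg.BiasSpec.flat(),
        seed=7,
    )
    exp = fg.expected_counts(tiny_genome["ref"], tiny_genome["regions"])
    obs = fg.observed_counts(bam, tiny_genome["ref"], tiny_genome["regions"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, final = fg.fit_correction(obs, exp)
    return {
        **tiny_genome,
        "bam": bam,
        "truth": truth,
        "exp": exp,
        "obs": obs,
        "table": table,
        "final": final,
    }


@pytest.fixture(scope="session")
def bell_sim(tmp_path_factory):
    """Study-condition sample: 500k fragments, bell GC acceptance."""
    d = tmp_path_factory.mktemp("bell_sim")
    fasta, bed = fg.make_reference(11, str(d / "genome"))
    ref = fg.ReferenceGC(fasta)
    regions = fg.load_regions(bed, ref.contig_lengths)
    bam = str(d / "bell.bam")
    bias = fg.BiasSpec.bell(center=50.0, width=10.0)
    truth = fg.simulate_fragments(fasta, regions, 500_000, bam, bias=bias, seed=12)
    exp = fg.expected_counts(ref, regions)
    obs = fg.observed_counts(bam, ref, regions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, final = fg.fit_correction(obs, exp)
    obs_merged = merge_neighbor_lengths(interpolate_matrix(obs))
    return {
        "fasta": fasta,
        "bed": bed,
        "ref": ref,
        "regions": regions,
        "bam": bam,
        "bias": bias,
        "truth": truth,
        "exp": exp,
        "obs": obs,
        "obs_merged": obs_merged,
        "table": table,
        "final": final,
    }


@pytest.fixture(scope="session")
def flat_big_sim(bell_sim, tmp_path_factory):
    """Null (bias-free) 500k-fragment sample on the same genome as bell_sim."""
    d = tmp_path_factory.mktemp("flat_big")
    bam = str(d / "flat.bam")
    truth = fg.simulate_fragments(
        bell_sim["fasta"], bell_sim["regions"], 500_000, bam,
        bias=fg.BiasSpec.flat(), seed=13,
    )
    obs = fg.observed_counts(bam, bell_sim["ref"], bell_sim["regions"])
    return {
        "bam": bam,
        "truth": truth,
        "obs": obs,
        "exp": bell_sim["exp"],
        "ref": bell_sim["ref"],
        "regions": bell_sim["regions"],
    }


@pytest.fixture(scope="session")
def autosome_sim(tmp_path_factory):
    """Flat sample on a 22-autosome genome for per-autosome diagnostics."""
    d = tmp_path_factory.mktemp("autosomes")
    names = [f"chr{i}" for i in range(1, 23)]
    fasta, bed = fg.make_reference(
        21,
        str(d / "auto"),
        contigs=22,
        contig_len=30_000,
        mask_every=10**9,
        names=names,
    )
    ref = fg.ReferenceGC(fasta)
    regions = fg.load_regions(bed, ref.contig_lengths)
    bam = str(d / "auto.bam")
    fg.simulate_fragments(fasta, regions, 44_000, bam, bias=fg.BiasSpec.flat(), seed=22)
    return {
        "fasta": fasta,
        "ref": ref,
        "regions": regions,
        "bam": bam,
        "lengths": {n: 30_000 for n in names},
    }


@pytest.fixture()
def make_bam(tmp_path):
    """Build a small coordinate-sorted, indexed BAM from fragment specs.

    Each spec is (qname, contig, start, length[, extra-flag dict]); every
    fragment becomes one proper pair (flags 99/147, MAPQ 60, 50 bp reads).
    """

    def _build(fragments, contig_lengths, name="hand.bam", duplicates=()):
        path = str(tmp_path / name)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
        }
        tid = {c: i for i, c in enumerate(contig_lengths)}
        recs = []
        for spec in fragments:
            qname, contig, start, length = spec[:4]
            dup = qname in duplicates
            rl = min(50, length)
            for first in (True, False):
                a = pysam.AlignedSegment()
                a.query_name = qname
                a.query_sequence = "A" * rl
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                a.reference_id = tid[contig]
                a.cigarstring = f"{rl}M"
                a.mapping_quality = 60
                a.next_reference_id = tid[contig]
                if first:
                    a.reference_start = start
                    a.next_reference_start = start + length - rl
                    a.template_length = length
                    a.flag = 99 | (0x400 if dup else 0)
                else:
                    a.reference_start = start + length - rl
                    a.next_reference_start = start
                    a.template_length = -length
                    a.flag = 147 | (0x400 if dup else 0)
                recs.append(a)
        recs.sort(key=lambda r: (r.reference_id, r.reference_start))
        with pysam.AlignmentFile(path, "wb", header=header) as out:
            for r in recs:
                out.write(r)
        pysam.index(path)
        return path

    return _build
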