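"""Valid genomic regions.

Bias estimation and fragment counting are restricted to "valid" regions of
the reference genome — the genome minus blacklisted, low-mappability and
otherwise flagged intervals. The user supplies these as a 3-column BED file
(0-based, half-open); this module loads, validates and merges them into a
:class:`RegionSet` that both the expected-count sweep and the observed-count
BAM pass consult.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = ["GenomicInterval", "RegionSet", "load_regions"]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``contig`` (0-based)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """Sorted, merged, per-contig collection of valid intervals.

    Overlapping or book-ended intervals are merged on construction, so the
    stored intervals within a contig are strictly disjoint and sorted.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        self._by_contig: dict[str, np.ndarray] = {}
        for contig, ivs in by_contig.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._by_contig[contig] = np.asarray(merged, dtype=np.int64)
        if self.total_span == 0:
            raise ValueError("no valid regions")

    @property
    def contigs(self) -> list[str]:
        return list(self._by_contig)

    @property
    def total_span(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._by_contig.values())
        )

    def intervals_for(self, contig: str) -> np.ndarray:
        """(k, 2) array of [start, end) pairs for ``contig`` (may be empty)."""
        return self._by_contig.get(contig, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[GenomicInterval]:
        for contig in self._by_contig:
            for s, e in self._by_contig[contig]:
                yield GenomicInterval(contig, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._by_contig.values())

    def contains_fragment(self, contig: str, start: int, end: int) -> bool:
        """True iff [start, end) lies wholly inside one valid interval."""
        ivs = self._by_contig.get(contig)
        if ivs is None or len(ivs) == 0:
            return False
        i = int(np.searchsorted(ivs[:, 0], start, side="right")) - 1
        return i >= 0 and end <= ivs[i, 1]


def load_regions(
    path: str,
    reference_contigs: Mapping[str, int] | Iterable[str] | None = None,
) -> RegionSet:
    """Load a 3-column BED file into a :class:`RegionSet`.

    Parameters
    ----------
    path
        BED file (0-based, half-open); extra columns beyond the first three
        are ignored.
    reference_contigs
        Contig names (optionally mapping to lengths) present in the reference.
        Intervals on contigs absent from the reference are dropped with a
        warning; when lengths are given, intervals are clipped to them.
    """
    names = None
    lengths: Mapping[str, int] | None = None
    if reference_contigs is not None:
        if isinstance(reference_contigs, Mapping):
            lengths = reference_contigs
            names = set(reference_contigs)
        else:
            names = set(reference_contigs)

    intervals: list[GenomicInterval] = []
    dropped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval "
                    f"{contig}:{start}-{end}"
                )
            if names is not None and contig not in names:
                dropped.add(contig)
                continue
            if lengths is not None:
                end = min(end, lengths[contig])
                if start >= end:
                    continue
            intervals.append(GenomicInterval(contig, start, end))
    if dropped:
        warnings.warn(
            "dropped BED intervals on contigs absent from the reference: "
            + ", ".join(sorted(dropped)),
            stacklevel=2,
        )
    if not intervals:
        raise ValueError("no valid regions")
    return RegionSet(intervals)
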