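"""Evaluation metrics: GC-density divergence and run-of-bins COV.

Two orthogonal views of correction quality:

* **Divergence metric** — for a fragment-length group, convert the
  (optionally correction-weighted) counts per GC bin into a sum-normalized
  density and measure its Jensen–Shannon divergence from the expected
  density derived from the reference genome.  Zero means the sample's GC
  composition is indistinguishable from the no-bias universe.

* **Variation metric** — genomic bins sharing a copy-number state should
  have equal normalized coverage up to noise; GC bias adds waves.  The
  sample COV is the mean, over "runs" of consecutive same-CN bins, of each
  run's coefficient of variation (population SD / mean).  A run is 50
  consecutive 100 kb bins (10 x 1 Mb bins at ultra-low pass), all sharing
  one high-confidence CN label, and successive runs are at least 25 bins
  (5 at 1 Mb) apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import CorrectionTable
from .counting import N_GC_BINS, CountMatrix

__all__ = [
    "GCDensity",
    "gc_density",
    "js_divergence",
    "cn_confidence_filter",
    "find_runs",
    "sample_cov",
]


@dataclass
class GCDensity:
    """Sum-normalized probability distribution over the 101 GC bins."""

    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if (self.p < 0).any():
            raise ValueError("negative probability")
        total = self.p.sum()
        if total <= 0:
            raise ValueError("empty density")
        if not np.isclose(total, 1.0, atol=1e-9):
            self.p = self.p / total


def gc_density(
    counts: CountMatrix,
    length_group: tuple[int, int],
    weights: CorrectionTable | None = None,
) -> GCDensity:
    """Density of fragment counts over GC bins for one length group.

    Sums (optionally correction-weighted) counts over the inclusive length
    range and normalizes.  Pass the expected count matrix to obtain the
    expected density.
    """
    lo, hi = length_group
    if lo < counts.lmin or hi > counts.lmax or lo > hi:
        raise ValueError(
            f"length group [{lo}, {hi}] outside matrix range "
            f"[{counts.lmin}, {counts.lmax}]"
        )
    sub = counts.counts[lo - counts.lmin : hi - counts.lmin + 1]
    if weights is not None:
        wsub = weights.factors[lo - weights.lmin : hi - weights.lmin + 1]
        sub = sub * wsub
    total = sub.sum(axis=0)
    if total.sum() <= 0:
        raise ValueError(f"no counts in length group [{lo}, {hi}]")
    return GCDensity(total)


def _as_prob(x) -> np.ndarray:
    p = x.p if isinstance(x, GCDensity) else np.asarray(x, dtype=np.float64)
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        warnings.warn("renormalizing non-normalized density", stacklevel=3)
        p = p / total
    return p


def js_divergence(p, q) -> float:
    """Jensen–Shannon divergence with base-2 logarithms, bounded in [0, 1].

    JSD(p, q) = KL(p||m)/2 + KL(q||m)/2 with m = (p+q)/2; 0·log 0 := 0.
    Symmetric, zero iff p == q, and 1 for disjoint supports.
    """
    p, q = _as_prob(p), _as_prob(q)
    if p.shape != q.shape:
        raise ValueError("densities must share support length")
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where(p > 0, p * np.log2(np.where(p > 0, p / m, 1.0)), 0.0)
        kl_q = np.where(q > 0, q * np.log2(np.where(q > 0, q / m, 1.0)), 0.0)
    return float(0.5 * kl_p.sum() + 0.5 * kl_q.sum())


# High-confidence CN call rules: (label, keep-predicate on numeric CN).
_CN_RULES = {
    "neutral": lambda cn: (1.5 < cn) & (cn < 2.5),
    "gain": lambda cn: cn > 2.5,
    "loss": lambda cn: cn < 1.5,
}
# caller-label synonyms mapped onto the three states
_LABEL_ALIASES = {
    "neutral": "neutral",
    "neut": "neutral",
    "gain": "gain",
    "amplified": "gain",
    "amp": "gain",
    "highly amplified": "gain",
    "hlamp": "gain",
    "loss": "loss",
    "homozygous deletion": "loss",
    "heterozygous deletion": "loss",
    "homd": "loss",
    "hetd": "loss",
}


def cn_confidence_filter(bins: pd.DataFrame) -> pd.DataFrame:
    """Keep only bins whose numeric CN is consistent with the caller label.

    ``bins`` needs columns ``label`` (neutral/gain/loss or a caller synonym)
    and ``cn``.  Rules: neutral keeps 1.5 < CN < 2.5; gain (amplified,
    highly amplified) keeps CN > 2.5; loss (homo-/heterozygous deletion)
    keeps CN < 1.5.  For healthy samples all bins are labeled neutral.
    """
    labels = bins["label"].astype(str).str.lower().map(_LABEL_ALIASES)
    if labels.isna().any():
        bad = sorted(bins["label"][labels.isna()].unique())
        raise ValueError(f"unknown CN labels: {bad}")
    cn = bins["cn"].to_numpy(dtype=float)
    keep = np.zeros(len(bins), dtype=bool)
    for state, rule in _CN_RULES.items():
        mask = (labels == state).to_numpy()
        keep[mask] = rule(cn[mask])
    out = bins.loc[keep].copy()
    out["label"] = labels[keep].to_numpy()
    return out


def find_runs(
    bins: pd.DataFrame,
    run_len: int = 50,
    min_gap: int = 25,
    bin_size: int = 100_000,
) -> list[np.ndarray]:
    """Greedy left-to-right selection of runs of same-label contiguous bins.

    ``bins`` needs columns contig, start, label and must be sorted by
    (contig, start).  A run is ``run_len`` bins that are coordinate-
    contiguous (consecutive multiples of ``bin_size``), share one label and
    lie on one contig; after emitting a run the scan skips ``min_gap`` bins
    before searching again.  Returns positional index arrays into ``bins``.
    At 1 Mb bins the conventional parameters are run_len=10, min_gap=5.
    """
    bins = bins.reset_index(drop=True)
    runs: list[np.ndarray] = []
    for contig, sub in bins.groupby("contig", sort=False):
        idx = sub.index.to_numpy()
        pos = (sub["start"].to_numpy() // bin_size).astype(np.int64)
        labels = sub["label"].to_numpy()
        n = len(idx)
        i = 0
        while i + run_len <= n:
            window_pos = pos[i : i + run_len]
            window_lab = labels[i : i + run_len]
            contiguous = bool(np.all(np.diff(window_pos) == 1))
            homogeneous = bool(np.all(window_lab == window_lab[0]))
            if contiguous and homogeneous:
                runs.append(idx[i : i + run_len])
                i += run_len + min_gap
            else:
                i += 1
    return runs


def sample_cov(
    bins: pd.DataFrame,
    runs: list[np.ndarray],
    value_col: str = "corrected",
) -> float:
    """Mean over runs of (population SD / mean) of normalized coverage.

    Coverage is normalized by the mean of ``value_col`` over all labeled
    bins (COV itself is scale-invariant; the normalization makes run means
    interpretable).  Runs with zero mean are excluded with a warning; no
    usable runs is an error.
    """
    if not runs:
        raise ValueError("no runs to evaluate")
    values = bins[value_col].to_numpy(dtype=float)
    genome_mean = np.nanmean(values)
    if not np.isfinite(genome_mean) or genome_mean <= 0:
        raise ValueError("coverage values have non-positive mean")
    norm = values / genome_mean
    covs = []
    skipped = 0
    for run in runs:
        v = norm[run]
        m = v.mean()
        if not np.isfinite(m) or m <= 0:
            skipped += 1
            continue
        covs.append(float(v.std() / m))  # population SD
    if skipped:
        warnings.warn(f"excluded {skipped} runs with zero mean", stacklevel=2)
    if not covs:
        raise ValueError("no runs with positive mean coverage")
    return float(np.mean(covs))
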