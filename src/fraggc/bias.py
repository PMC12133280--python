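"""GC-bias estimation and correction-factor derivation.

The bias value b(l, g) for fragment length ``l`` and GC bin ``g`` is the
observed count divided by the expected count — the rate at which fragments
of that composition made it through library prep and sequencing relative to
a uniform sampler.  The estimation chain is:

1. ``fragment_rates`` — ratio on GC bins 10..90 (which hold essentially all
   cfDNA fragments); globally mean-scaled so unbiased data sits near 1.
2. ``clamp_percentiles`` — winsorize each length's values to its 3rd/97th
   percentile to suppress ratio noise from sparse bins.
3. ``normalize_and_smooth`` — per length: mean-normalize, LOESS-smooth
   (span 0.1), keep GC bins 20..80, mean-normalize once more so every final
   row averages exactly 1.  The extra 10..90 margin exists only to give the
   smoother context at the edges of the retained range.
4. ``correction_factors`` — invert: c(l, g) = 1/b(l, g), zero outside
   20..80, capped at 20 (or the sample's 99th percentile when that exceeds
   20, indicating genuinely extreme initial bias).

Weighting every fragment by c(l, g) equalizes representation across GC
content.  A length-agnostic variant (:func:`gc_only_correction`) estimates
one curve from a fixed 400 bp window at the fragment start and broadcasts
it to all lengths; it exists as a comparison configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .counting import (
    N_GC_BINS,
    CountMatrix,
    interpolate_gaps,
    interpolate_matrix,
    merge_neighbor_lengths,
)

__all__ = [
    "BiasTable",
    "CorrectionTable",
    "fragment_rates",
    "clamp_percentiles",
    "normalize_and_smooth",
    "correction_factors",
    "fit_correction",
    "gc_only_correction",
]

EXTRACT_RANGE = (10, 90)   # GC-bin range used during estimation
RETAIN_RANGE = (20, 80)    # GC-bin range kept in the final curves
DEFAULT_CAP = 20.0
LOESS_FRAC = 0.1


@dataclass
class BiasTable:
    """Per-length, per-GC-bin bias values with undefined entries as NaN."""

    lmin: int
    lmax: int
    values: np.ndarray = field(repr=False)  # (n_lengths, 101), NaN = undefined
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.lmax - self.lmin + 1, N_GC_BINS):
            raise ValueError("bias table shape mismatch")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.lmin, self.lmax + 1)

    def row(self, length: int) -> np.ndarray:
        return self.values[length - self.lmin]


@dataclass
class CorrectionTable:
    """Correction factors c(l, g) = 1/b(l, g), zeroed outside GC 20..80."""

    lmin: int
    lmax: int
    factors: np.ndarray = field(repr=False)
    cap: float = DEFAULT_CAP

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=np.float64)
        if self.factors.shape != (self.lmax - self.lmin + 1, N_GC_BINS):
            raise ValueError("correction table shape mismatch")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.lmin, self.lmax + 1)

    def factor(self, length: int, gc_bin: int) -> float:
        """Factor for one fragment; 0.0 outside the modeled length range."""
        if not (self.lmin <= length <= self.lmax and 0 <= gc_bin < N_GC_BINS):
            return 0.0
        return float(self.factors[length - self.lmin, gc_bin])

    def to_csv(self, path: str) -> None:
        """Rows = fragment length, columns = GC percent 0..100, 6 decimals."""
        with open(path, "w") as fh:
            fh.write("length," + ",".join(str(g) for g in range(N_GC_BINS)) + "\n")
            for l, row in zip(self.lengths, self.factors):
                fh.write(f"{l}," + ",".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_csv(cls, path: str) -> "CorrectionTable":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        lengths = df.index.to_numpy()
        factors = df.to_numpy()
        cap = float(np.nanmax(factors)) if np.isfinite(factors).any() else DEFAULT_CAP
        return cls(int(lengths[0]), int(lengths[-1]), factors, cap=max(cap, DEFAULT_CAP))


def fragment_rates(
    observed: CountMatrix,
    expected: CountMatrix,
    min_support_frac: float = 1e-3,
    min_expected_obs: float = 2.0,
) -> BiasTable:
    """Raw bias b = observed/expected on GC bins 10..90 with enough support.

    A bin is estimable only where the ratio carries information:

    * expected must be positive and at least ``min_support_frac`` of the
      row's maximum expected count (the genome offers enough context
      windows of that composition), and
    * at the row's average sampling rate, at least ``min_expected_obs``
      fragments would be expected in the bin even without bias — below
      that, the observed tally is pure shot noise and a single stray
      fragment produces an arbitrarily large ratio.

    Undefined bins are NaN and later surface as correction factor 0.

    The ratio's absolute scale is arbitrary (observed totals count
    fragments, expected totals count genome positions), so the table is
    globally mean-scaled: unbiased data then sits at b ~= 1 everywhere.
    Per-length normalization happens later in :func:`normalize_and_smooth`.
    """
    if observed.shape != expected.shape or observed.lmin != expected.lmin:
        raise ValueError("observed and expected matrices must share the grid")
    lo, hi = EXTRACT_RANGE
    b = np.full_like(observed.counts, np.nan)
    sl = slice(lo, hi + 1)
    exp = expected.counts[:, sl]
    obs = observed.counts[:, sl]
    row_max = expected.counts.max(axis=1, keepdims=True)
    exp_totals = expected.counts.sum(axis=1, keepdims=True)
    obs_totals = observed.counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        row_rate = np.where(exp_totals > 0, obs_totals / exp_totals, 0.0)
    support = (
        (exp >= np.maximum(min_support_frac * row_max, 1e-300))
        & (exp * row_rate >= min_expected_obs)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(support, obs / np.where(support, exp, 1.0), np.nan)
    b[:, sl] = ratio
    dead_rows = np.all(~np.isfinite(b), axis=1)
    if dead_rows.any():
        warnings.warn(
            f"{int(dead_rows.sum())} fragment lengths have no expected "
            "counts; their bias rows are undefined",
            stacklevel=2,
        )
    mean = np.nanmean(b)
    if np.isfinite(mean) and mean > 0:
        b = b / mean
    return BiasTable(observed.lmin, observed.lmax, b, stage="raw")


def clamp_percentiles(
    table: BiasTable, lo_pct: float = 3.0, hi_pct: float = 97.0
) -> BiasTable:
    """Winsorize each length's bias values to its [P_lo, P_hi] range.

    Percentiles are computed per fragment length, over that row's defined
    entries, with linear interpolation between order statistics.  Raw rates
    scale with the fragment-length distribution (abundant lengths sit far
    above rare ones before the per-length normalization), so a joint clamp
    over all entries would shear off the peaks of well-populated curves
    instead of removing noise; the per-length clamp touches only each
    curve's own extremes.
    """
    vals = table.values
    n_defined = int(np.isfinite(vals).sum())
    if n_defined == 0:
        return BiasTable(table.lmin, table.lmax, vals.copy(), stage="clamped")
    if n_defined < 34:
        warnings.warn(
            f"only {n_defined} defined bias entries; percentile clamp "
            "may be unstable",
            stacklevel=2,
        )
    out = vals.copy()
    for i in range(out.shape[0]):
        mask = np.isfinite(out[i])
        if not mask.any():
            continue
        p_lo, p_hi = np.percentile(out[i][mask], [lo_pct, hi_pct])
        out[i][mask] = np.clip(out[i][mask], p_lo, p_hi)
    return BiasTable(table.lmin, table.lmax, out, stage="clamped")


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    xout: np.ndarray,
    frac: float = LOESS_FRAC,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Tricube-weighted local-linear smooth of (x, y) evaluated at ``xout``.

    Single pass (no robustness iterations); the bandwidth at each output
    point is the distance to the k-th nearest input point with
    k = max(3, ceil(frac * n)).  Optional ``weights`` multiply the tricube
    kernel — passing precision weights (e.g. expected counts, since the
    variance of an observed/expected ratio scales as 1/expected) keeps
    sparsely supported bins from steering the local fits.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xout = np.asarray(xout, dtype=np.float64)
    w_prec = np.ones_like(x) if weights is None else np.asarray(weights, np.float64)
    n = len(x)
    k = max(3, math.ceil(frac * n))
    d = np.abs(x[None, :] - xout[:, None])
    h = np.maximum(np.sort(d, axis=1)[:, min(k, n) - 1], 1e-9)
    t = np.clip(d / h[:, None], 0.0, 1.0)
    w = (1.0 - t**3) ** 3 * w_prec[None, :]
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    swxy = (w * x * y).sum(axis=1)
    denom = sw * swxx - swx**2
    ok = denom > 1e-12
    safe = np.where(ok, denom, 1.0)
    slope = np.where(ok, (sw * swxy - swx * swy) / safe, 0.0)
    intercept = np.where(
        ok, (swxx * swy - swx * swxy) / safe, swy / np.maximum(sw, 1e-12)
    )
    return intercept + slope * xout


def normalize_and_smooth(
    table: BiasTable,
    loess_frac: float = LOESS_FRAC,
    retain: tuple[int, int] = RETAIN_RANGE,
    weights: np.ndarray | None = None,
) -> BiasTable:
    """Per-length mean normalization, LOESS smoothing, and retention of the
    GC 20..80 range, ending with a second mean normalization so every final
    row averages exactly 1.

    LOESS span is ``loess_frac`` of the row's defined points (at least 3);
    rows with fewer than 3 defined points pass through unsmoothed with a
    warning.  ``weights`` (same shape as the table; typically the merged
    expected counts) act as precision weights inside the smoother.
    Smoothed values are floored at 0 (bias cannot be negative).
    """
    lo, hi = retain
    xout = np.arange(lo, hi + 1)
    out = np.full_like(table.values, np.nan)
    thin_rows = 0
    for i, row in enumerate(table.values):
        g = np.flatnonzero(np.isfinite(row))
        if g.size == 0:
            continue
        row_mean = np.mean(row[g])
        if row_mean <= 0:
            continue  # no observed mass at this length: leave undefined
        v = row[g] / row_mean
        if g.size < 3:
            thin_rows += 1
            keep = g[(g >= lo) & (g <= hi)]
            out[i, keep] = v[(g >= lo) & (g <= hi)]
        else:
            w = None
            if weights is not None:
                w = weights[i][g]
                wm = w.mean()
                w = w / wm if wm > 0 else None
            sm = loess_smooth(g, v, xout, loess_frac, w)
            inside = (xout >= g[0]) & (xout <= g[-1])
            out[i, xout[inside]] = np.maximum(sm[inside], 0.0)
        final = out[i]
        defined = np.isfinite(final)
        m = final[defined].mean() if defined.any() else 0.0
        if m > 0:
            out[i, defined] = final[defined] / m
        elif defined.any():
            out[i, defined] = np.nan
    if thin_rows:
        warnings.warn(
            f"{thin_rows} fragment lengths had < 3 defined bias points and "
            "were passed through unsmoothed",
            stacklevel=2,
        )
    return BiasTable(table.lmin, table.lmax, out, stage="final")


def correction_factors(
    table: BiasTable, default_cap: float = DEFAULT_CAP
) -> CorrectionTable:
    """Invert final bias values into capped correction factors.

    c(l, g) = 1/b(l, g) on GC bins 20..80 where b > 0, else 0 (never
    infinity).  The cap is ``default_cap`` unless the 99th percentile of the
    positive factors exceeds it, in which case that percentile becomes the
    cap — a sample with genuinely extreme bias is allowed stronger
    correction.
    """
    vals = table.values
    c = np.zeros_like(vals)
    pos = np.isfinite(vals) & (vals > 0)
    c[pos] = 1.0 / vals[pos]
    lo, hi = RETAIN_RANGE
    c[:, :lo] = 0.0
    c[:, hi + 1 :] = 0.0
    undefined_rows = ~np.isfinite(vals).any(axis=1)
    if undefined_rows.any():
        warnings.warn(
            f"{int(undefined_rows.sum())} fragment lengths have undefined "
            "bias; their correction factors are emitted as zero",
            stacklevel=2,
        )
    positive = c[c > 0]
    cap = default_cap
    if positive.size:
        p99 = float(np.percentile(positive, 99))
        if p99 > default_cap:
            cap = p99
    np.minimum(c, cap, out=c)
    return CorrectionTable(table.lmin, table.lmax, c, cap=cap)


def fit_correction(
    observed: CountMatrix,
    expected: CountMatrix,
    halfwidth: int = 2,
    loess_frac: float = LOESS_FRAC,
    default_cap: float = DEFAULT_CAP,
    clip: int = 10,
) -> tuple[CorrectionTable, BiasTable]:
    """Full chain from raw count matrices to a correction table.

    Interpolates unattainable GC bins in both matrices (``clip`` determines
    each length's window size and hence its attainable bins), pools counts
    across +/- ``halfwidth`` neighboring lengths, computes rates, clamps,
    smooths and inverts.  Returns (correction table, final bias table).
    """
    obs = merge_neighbor_lengths(interpolate_matrix(observed, clip), halfwidth)
    exp = merge_neighbor_lengths(interpolate_matrix(expected, clip), halfwidth)
    final = normalize_and_smooth(
        clamp_percentiles(fragment_rates(obs, exp)),
        loess_frac,
        weights=exp.counts,
    )
    return correction_factors(final, default_cap), final


def gc_only_correction(
    observed_curve: np.ndarray,
    expected_curve: np.ndarray,
    lengths: tuple[int, int] = (51, 400),
    loess_frac: float = LOESS_FRAC,
    default_cap: float = DEFAULT_CAP,
) -> tuple[CorrectionTable, BiasTable]:
    """Length-agnostic correction from fixed-window GC-bin curves.

    ``observed_curve`` and ``expected_curve`` are 101-bin counts produced
    with a fixed-size window anchored at the fragment start (see
    :func:`fraggc.counting.fixed_window_observed`).  One bias curve is
    estimated through the same clamp/normalize/smooth/invert chain and
    broadcast to every fragment length.
    """
    from .counting import attainable_bins

    sup = attainable_bins(400)
    obs = CountMatrix(0, 0, interpolate_gaps(np.asarray(observed_curve, float), sup)[None, :])
    exp = CountMatrix(0, 0, interpolate_gaps(np.asarray(expected_curve, float), sup)[None, :])
    final1 = normalize_and_smooth(
        clamp_percentiles(fragment_rates(obs, exp)),
        loess_frac,
        weights=exp.counts,
    )
    lmin, lmax = lengths
    n = lmax - lmin + 1
    vals = np.repeat(final1.values, n, axis=0)
    final = BiasTable(lmin, lmax, vals, stage="final")
    return correction_factors(final, default_cap), final
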