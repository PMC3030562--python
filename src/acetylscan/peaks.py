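"""Strand-specific tag extension, coverage tracks and FDR-thresholded peak calling.

Mapped ChIP tags are stored as (chromosome, 5'-end, strand) records.  Each tag
is extended strand-specifically to the expected fragment length L (default
200 bp), per-base coverage is the number of extended fragments overlapping a
base, and peaks are maximal runs of coverage at or above a height threshold h.
h is chosen so that the estimated false discovery rate — expected false peaks
under a uniform-tag null divided by the number of observed peaks at that
height — does not exceed ``peak_fdr`` (default 0.05).  The null is either an
analytic Poisson approximation (coverage at a base ~ Poisson(library_size *
L / genome_length), ~genome_length/L independent windows) or a Monte-Carlo
simulation of uniform tag placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TagSet:
    """One sample's mapped tags: 5'-end coordinate and strand per record.

    ``records`` has columns ``chrom`` (str), ``pos`` (0-based 5'-end, int)
    and ``strand`` ('+' or '-').  ``library_size`` is the record count.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"TagSet records missing columns: {sorted(missing)}")

    @property
    def library_size(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Peak:
    """Maximal run of coverage >= h; half-open [start, end); summit is the
    leftmost base attaining the run maximum."""

    chrom: str
    start: int
    end: int
    summit: int
    height: int


@dataclass
class PeakCallParams:
    extension: int = 200
    peak_fdr: float = 0.05
    null_mode: str = "poisson"  # "poisson" | "montecarlo"
    mc_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.peak_fdr <= 1.0):
            raise ValueError("peak_fdr must be in (0, 1]")
        if self.null_mode not in ("poisson", "montecarlo"):
            raise ValueError(f"unknown null_mode {self.null_mode!r}")
        if self.extension < 1:
            raise ValueError("extension must be >= 1")


def extend_tags(
    tags: TagSet, L: int, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Extend each tag strand-specifically to L bp.

    Forward tag at p covers [p, p+L); reverse tag at p covers [p-L+1, p+1).
    Intervals are clipped to chromosome bounds.  Returns per-chromosome
    (n, 2) arrays of half-open [start, end) intervals.
    """
    if L < 1:
        raise ValueError("extension length L must be >= 1")
    out: dict[str, np.ndarray] = {}
    for chrom, grp in tags.records.groupby("chrom", sort=True):
        clen = chrom_lengths[chrom]
        pos = grp["pos"].to_numpy(dtype=np.int64)
        fwd = (grp["strand"] == "+").to_numpy()
        starts = np.where(fwd, pos, pos - L + 1)
        ends = np.where(fwd, pos + L, pos + 1)
        starts = np.clip(starts, 0, clen)
        ends = np.clip(ends, 0, clen)
        keep = ends > starts
        out[chrom] = np.column_stack([starts[keep], ends[keep]])
    return out


def build_coverage(
    intervals: Mapping[str, np.ndarray], chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base coverage: height at base b = number of intervals containing b."""
    cov: dict[str, np.ndarray] = {}
    for chrom, clen in chrom_lengths.items():
        delta = np.zeros(clen + 1, dtype=np.int64)
        ivs = intervals.get(chrom)
        if ivs is not None and len(ivs):
            np.add.at(delta, ivs[:, 0], 1)
            np.add.at(delta, ivs[:, 1], -1)
        cov[chrom] = np.cumsum(delta[:-1])
    return cov


def peak_counts_by_height(coverage: Mapping[str, np.ndarray]) -> np.ndarray:
    """Number of maximal runs of coverage >= h, for h = 1..max height.

    Returns an array ``counts`` where ``counts[h-1]`` is the peak count at
    threshold h.  A run at level h begins at every upcrossing into >= h, so
    each rising step from a to b contributes one run to all h in (a, b].
    """
    hmax = max((int(c.max()) if len(c) else 0) for c in coverage.values()) if coverage else 0
    if hmax == 0:
        return np.zeros(0, dtype=np.int64)
    delta = np.zeros(hmax + 2, dtype=np.int64)
    for cov in coverage.values():
        if not len(cov):
            continue
        prev = np.concatenate([[0], cov[:-1]])
        rise = cov > prev
        np.add.at(delta, prev[rise] + 1, 1)
        np.add.at(delta, cov[rise] + 1, -1)
    return np.cumsum(delta)[1 : hmax + 1]


def _fdr_curve_poisson(
    library_size: int, genome_length: int, L: int, heights: np.ndarray
) -> np.ndarray:
    lam = library_size * L / genome_length
    n_windows = genome_length / L
    return n_windows * stats.poisson.sf(heights - 1, lam)


def _expected_false_montecarlo(
    library_size: int,
    genome_length: int,
    L: int,
    mc_iterations: int,
    seed: int,
    hmax: int,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    acc = np.zeros(hmax, dtype=np.float64)
    lengths = {"null": genome_length}
    for _ in range(mc_iterations):
        pos = rng.integers(0, genome_length, size=library_size)
        strand = rng.random(library_size) < 0.5
        starts = np.where(strand, pos, pos - L + 1)
        ends = np.where(strand, pos + L, pos + 1)
        ivs = {"null": np.column_stack(
            [np.clip(starts, 0, genome_length), np.clip(ends, 0, genome_length)]
        )}
        counts = peak_counts_by_height(build_coverage(ivs, lengths))
        k = min(len(counts), hmax)
        acc[:k] += counts[:k]
    return acc / mc_iterations


def height_threshold(
    library_size: int,
    genome_length: int,
    L: int,
    peak_fdr: float,
    null_mode: str = "poisson",
    mc_iterations: int = 200,
    seed: int = 0,
    observed_peak_counts: Sequence[int] | np.ndarray | None = None,
) -> int:
    """Minimal height h with estimated FDR <= peak_fdr.

    FDR(h) = min(1, E[false peaks at h under uniform null] /
    max(1, observed peaks at h)).  ``observed_peak_counts[h-1]`` gives the
    observed count; None uses a denominator of 1 (the pure expected-count
    bound).  Estimates are capped at 1, so peak_fdr = 1 always yields h = 1.
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    if genome_length <= L:
        raise ValueError("genome_length must exceed the extension length L")

    lam = library_size * L / genome_length
    hmax = int(lam + 10 * np.sqrt(lam) + 50)
    if observed_peak_counts is not None:
        hmax = max(hmax, len(observed_peak_counts))
    heights = np.arange(1, hmax + 1)

    if null_mode == "poisson":
        expected = _fdr_curve_poisson(library_size, genome_length, L, heights)
    elif null_mode == "montecarlo":
        expected = _expected_false_montecarlo(
            library_size, genome_length, L, mc_iterations, seed, hmax
        )
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")

    if observed_peak_counts is None:
        observed = np.ones(hmax)
    else:
        observed = np.zeros(hmax)
        obs = np.asarray(observed_peak_counts, dtype=np.float64)
        observed[: len(obs)] = obs
    fdr = np.minimum(1.0, expected / np.maximum(1.0, observed))
    ok = np.nonzero(fdr <= peak_fdr)[0]
    if len(ok) == 0:
        return hmax + 1
    return int(heights[ok[0]])


def call_peaks(
    tags: TagSet,
    params: PeakCallParams,
    chrom_lengths: Mapping[str, int],
) -> list[Peak]:
    """Call peaks as maximal runs of coverage >= h at the FDR-derived h.

    Peaks are sorted by (chrom, start); the summit is the leftmost coordinate
    attaining the run maximum; adjacent runs separated by >= 1 base below h
    are distinct peaks.
    """
    if tags.library_size == 0:
        return []
    intervals = extend_tags(tags, params.extension, chrom_lengths)
    coverage = build_coverage(intervals, chrom_lengths)
    counts = peak_counts_by_height(coverage)
    genome_length = int(sum(chrom_lengths.values()))
    h = height_threshold(
        tags.library_size,
        genome_length,
        params.extension,
        params.peak_fdr,
        null_mode=params.null_mode,
        mc_iterations=params.mc_iterations,
        seed=params.seed,
        observed_peak_counts=counts,
    )
    return peaks_above(coverage, h)


def peaks_above(coverage: Mapping[str, np.ndarray], h: int) -> list[Peak]:
    """Extract maximal runs of coverage >= h as Peak records."""
    peaks: list[Peak] = []
    for chrom in sorted(coverage):
        cov = coverage[chrom]
        mask = (cov >= h).astype(np.int8)
        edges = np.diff(mask, prepend=0, append=0)
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        for s, e in zip(starts, ends):
            seg = cov[s:e]
            summit = int(s + np.argmax(seg))
            peaks.append(Peak(chrom, int(s), int(e), summit, int(seg.max())))
    return peaks
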