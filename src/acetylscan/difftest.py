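"""Bayesian-regularized differential testing of region scores.

With only a handful of replicates per group, per-region variance estimates
are unstable.  Following the Cyber-T scheme, each region's within-group
sample variance s^2 is shrunk toward a background variance sigma0^2 — the
mean sample variance of the w regions with the closest within-group mean
signal — via

    s_tilde^2 = (nu0 * sigma0^2 + (n - 1) * s^2) / (nu0 + n - 1)

where nu0 acts as a prior pseudo-replicate count.  The test statistic is a
two-sample t with the shrunken variances,

    t = (mean_B - mean_A) / sqrt(s_tilde_A^2 / nA + s_tilde_B^2 / nB),

with two-sided p-values from Student's t on nA + nB - 2 + 2*nu0 degrees of
freedom by default.  nu0 = 0 recovers the ordinary two-sample t-test
exactly.  Significant regions (p <= threshold) are partitioned into
"enriched" (higher in group B, the leukaemic group) and "deprived" (lower).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs >= 2 replicates")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")


@dataclass
class RegTTestParams:
    prior_df: float = 10.0  # nu0, prior pseudo-replicates
    window: int = 101       # rank-neighbourhood size for sigma0^2
    p_threshold: float = 0.05
    df_mode: str = "augmented"        # "augmented": nA+nB-2+2*nu0; "classical": nA+nB-2
    variance_denominator: str = "n-1"  # "n-1" (nu0+n-1) or "n-2" (nu0+n-2, Cyber-T classic)

    def __post_init__(self) -> None:
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.df_mode not in ("augmented", "classical"):
            raise ValueError(f"unknown df_mode {self.df_mode!r}")
        if self.variance_denominator not in ("n-1", "n-2"):
            raise ValueError("variance_denominator must be 'n-1' or 'n-2'")


def background_variance(scores: pd.DataFrame, w: int) -> pd.Series:
    """Windowed background variance per region for one group.

    Regions are ranked by within-group mean; sigma0^2 for a region is the
    mean of the sample variances (ddof=1) over the w rank-nearest regions
    (the window is clamped at the rank edges so it always holds w regions;
    with w equal to the region count every window is the full set and
    sigma0^2 is the grand mean variance).
    """
    if scores.shape[1] < 2:
        raise ValueError("background variance needs >= 2 replicates")
    n = len(scores)
    if n < w:
        raise ValueError(f"need >= {w} regions for window {w}")
    means = scores.mean(axis=1).to_numpy()
    variances = scores.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(means, kind="stable")
    v_sorted = variances[order]
    half = (w - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(v_sorted)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n - w)
    hi = lo + w
    sigma0_sorted = (csum[hi] - csum[lo]) / (hi - lo)
    sigma0 = np.empty(n)
    sigma0[order] = sigma0_sorted
    return pd.Series(sigma0, index=scores.index, name="sigma0_sq")


def _shrunken_variance(
    s2: np.ndarray, sigma0: np.ndarray, n: int, nu0: float, denominator: str
) -> np.ndarray:
    denom = nu0 + n - (1 if denominator == "n-1" else 2)
    if denom <= 0:
        raise ValueError("degenerate shrinkage denominator")
    return (nu0 * sigma0 + (n - 1) * s2) / denom


def regularized_t(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    sigma0_a: pd.Series | np.ndarray,
    sigma0_b: pd.Series | np.ndarray,
    params: RegTTestParams,
) -> pd.DataFrame:
    """Per-region regularized t and two-sided p (sign convention: B - A)."""
    na, nb = scores_a.shape[1], scores_b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    mean_a = scores_a.mean(axis=1).to_numpy()
    mean_b = scores_b.mean(axis=1).to_numpy()
    s2a = scores_a.var(axis=1, ddof=1).to_numpy()
    s2b = scores_b.var(axis=1, ddof=1).to_numpy()
    st2a = _shrunken_variance(
        s2a, np.asarray(sigma0_a, dtype=float), na, params.prior_df,
        params.variance_denominator,
    )
    st2b = _shrunken_variance(
        s2b, np.asarray(sigma0_b, dtype=float), nb, params.prior_df,
        params.variance_denominator,
    )
    se = np.sqrt(st2a / na + st2b / nb)
    diff = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    if params.df_mode == "augmented":
        df = na + nb - 2 + 2 * params.prior_df
    else:
        df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return pd.DataFrame(
        {"mean_A": mean_a, "mean_B": mean_b, "t": t, "p": p},
        index=scores_a.index,
    )


def classify_regions(results: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Partition into stable / enriched / deprived at p <= p_threshold.

    Enriched: significantly higher in group B (the leukaemic side); deprived:
    significantly lower.  A significant region with exactly equal means is
    left stable (no direction).
    """
    cls = np.full(len(results), "stable", dtype=object)
    sig = results["p"].to_numpy() <= p_threshold
    up = results["mean_B"].to_numpy() > results["mean_A"].to_numpy()
    down = results["mean_B"].to_numpy() < results["mean_A"].to_numpy()
    cls[sig & up] = "enriched"
    cls[sig & down] = "deprived"
    out = results.copy()
    out["class"] = cls
    return out


def differential_test(
    scores: pd.DataFrame,
    comparison: GroupComparison,
    params: RegTTestParams | None = None,
) -> pd.DataFrame:
    """Full pipeline: background variance -> regularized t -> classification.

    ``scores`` is the normalised region-score matrix (regions x samples);
    only the comparison's samples are used.
    """
    params = params or RegTTestParams()
    a = scores[comparison.group_a]
    b = scores[comparison.group_b]
    if params.prior_df == 0:
        sigma0_a = np.zeros(len(scores))
        sigma0_b = np.zeros(len(scores))
    else:
        w = min(params.window, len(scores) if len(scores) % 2 == 1 else len(scores) - 1)
        w = max(w, 3)
        sigma0_a = background_variance(a, w)
        sigma0_b = background_variance(b, w)
    res = regularized_t(a, b, sigma0_a, sigma0_b, params)
    return classify_regions(res, params.p_threshold)


def class_counts(results: pd.DataFrame) -> dict[str, int]:
    counts = results["class"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("stable", "enriched", "deprived")}


def replicate_density_grid(
    scores_x: Sequence[float] | np.ndarray,
    scores_y: Sequence[float] | np.ndarray,
    grid_size: int = 64,
    bandwidth: float | None = None,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-kernel density of replicate score pairs on a log-score grid.

    Returns (x_grid, y_grid, density); cell masses (density x cell area) sum
    to 1.  Used to visualise replicate concordance: well-correlated
    replicates put nearly all mass along the diagonal.
    """
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("score vectors must be equal-length and non-empty")
    if log_transform:
        x = np.log2(x + pseudocount)
        y = np.log2(y + pseudocount)
    if bandwidth is None:
        spread = max(np.std(np.concatenate([x, y])), 1e-3)
        bandwidth = 1.06 * spread * max(x.size, 2) ** (-1 / 5)  # Silverman
    lo = min(x.min(), y.min()) - 3 * bandwidth
    hi = max(x.max(), y.max()) + 3 * bandwidth
    gx = np.linspace(lo, hi, grid_size)
    gy = np.linspace(lo, hi, grid_size)
    dx = gx[1] - gx[0] if grid_size > 1 else 1.0
    # separable Gaussian kernels: density_ij = mean_k K(gx_i - x_k) K(gy_j - y_k)
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / bandwidth) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / bandwidth) ** 2)
    density = (kx @ ky.T) / (x.size * 2 * np.pi * bandwidth**2)
    mass = density.sum() * dx * dx
    if mass > 0:
        density = density / mass
    return gx, gy, density
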