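"""Expression-side pipeline: detection filtering, moderated per-transition
differential expression, non-redundant DE sets and the cross-model
intersection defining shared progression gene sets.

Differential calls use the same in-repo regularized t-statistic as the
acetylation side, with Benjamini-Hochberg adjustment across all tested
probes and calls at adjusted p <= 0.001 by default.  No fidelity to limma's
exact numbers is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .difftest import RegTTestParams, background_variance, regularized_t
from .synthetic import ExpressionMatrix


@dataclass(frozen=True)
class TransitionComparison:
    """One pairwise comparison; log-fc sign convention is to - from."""

    name: str
    condition_from: str
    condition_to: str


def detection_filter(
    matrix: ExpressionMatrix,
    threshold: float = 0.01,
    convention: str = "greater",
) -> list[str]:
    """Probes detected in at least one sample.

    ``convention='greater'`` counts a cell as detected when its detection
    score exceeds the threshold; ``'less'`` inverts the comparison for chips
    whose detection p-values are small when a probe is present.
    """
    if convention == "greater":
        detected = (matrix.detection > threshold).any(axis=1)
    elif convention == "less":
        detected = (matrix.detection < threshold).any(axis=1)
    else:
        raise ValueError(f"unknown detection convention {convention!r}")
    return matrix.detection.index[detected].tolist()


def moderated_de(
    matrix: ExpressionMatrix,
    comparison: TransitionComparison,
    fdr_threshold: float = 0.001,
    params: RegTTestParams | None = None,
    probes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-probe moderated test for one transition with BH adjustment.

    Returns a frame indexed by probe with log_fc (to - from), p, adjusted_p
    and call in {up, down, ns}; calls require adjusted_p <= fdr_threshold.
    """
    params = params or RegTTestParams()
    samples_from = [
        s for s, c in matrix.conditions.items() if c == comparison.condition_from
    ]
    samples_to = [
        s for s, c in matrix.conditions.items() if c == comparison.condition_to
    ]
    if not samples_from or not samples_to:
        raise ValueError(
            f"conditions {comparison.condition_from!r}/{comparison.condition_to!r} "
            "not present in the matrix"
        )
    data = matrix.intensities if probes is None else matrix.intensities.loc[list(probes)]
    a = data[samples_from]
    b = data[samples_to]
    if params.prior_df == 0:
        sigma0_a = np.zeros(len(data))
        sigma0_b = np.zeros(len(data))
    else:
        w = min(params.window, len(data) if len(data) % 2 == 1 else len(data) - 1)
        w = max(w, 3)
        sigma0_a = background_variance(a, w)
        sigma0_b = background_variance(b, w)
    res = regularized_t(a, b, sigma0_a, sigma0_b, params)
    out = pd.DataFrame(index=data.index)
    out["transition"] = comparison.name
    out["log_fc"] = res["mean_B"] - res["mean_A"]
    out["p"] = res["p"]
    out["adjusted_p"] = benjamini_hochberg(res["p"].to_numpy())
    call = np.full(len(out), "ns", dtype=object)
    sig = out["adjusted_p"].to_numpy() <= fdr_threshold
    call[sig & (out["log_fc"].to_numpy() > 0)] = "up"
    call[sig & (out["log_fc"].to_numpy() < 0)] = "down"
    out["call"] = call
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (scipy's step-up false discovery control)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def nonredundant_de(de_lists: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of probes called in >= 1 transition, with their calls collected.

    Returns a frame indexed by probe with a ``calls`` column holding the
    sorted list of (transition, direction) pairs.
    """
    calls: dict[str, list[tuple[str, str]]] = {}
    for name, de in de_lists.items():
        hit = de[de["call"] != "ns"]
        for probe, direction in zip(hit.index, hit["call"]):
            calls.setdefault(probe, []).append((name, str(direction)))
    probes = sorted(calls)
    return pd.DataFrame(
        {"calls": [sorted(calls[p]) for p in probes]}, index=pd.Index(probes)
    )


def shared_progression_sets(
    de_me_initiation: pd.DataFrame, de_mt_progression: pd.DataFrame
) -> tuple[set[str], set[str]]:
    """Direction-matched intersection across the two oncogene time courses.

    shared_up: probes called up in the MLL-ENL baseline->initiation
    comparison AND in the MOZ-TIF2 initiation->progression comparison;
    shared_down likewise for down.  Discordant directions are excluded.
    """
    me_up = set(de_me_initiation.index[de_me_initiation["call"] == "up"])
    me_down = set(de_me_initiation.index[de_me_initiation["call"] == "down"])
    mt_up = set(de_mt_progression.index[de_mt_progression["call"] == "up"])
    mt_down = set(de_mt_progression.index[de_mt_progression["call"] == "down"])
    return me_up & mt_up, me_down & mt_down


def collapse_to_genes(
    probe_set: set[str], probe_to_gene: Mapping[str, str]
) -> set[str]:
    """Collapse a probe set to unique genes via a user-supplied mapping;
    probes without a mapping are kept under their own ids."""
    return {probe_to_gene.get(p, p) for p in probe_set}
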