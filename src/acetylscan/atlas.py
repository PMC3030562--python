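"""Non-redundant atlas of fixed-width summit-centred candidate regions.

Each significant peak contributes a 400 bp window centred on its summit; the
windows from all samples are merged into a non-redundant atlas by greedy
height-ranked selection (strongest summit wins, overlapping windows are
dropped), so the atlas regions are pairwise disjoint and of constant width.
Every atlas region is then scored in every sample by counting the sample's
extended tags overlapping the region, normalised to reads per million.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import Peak, TagSet, extend_tags


@dataclass(frozen=True)
class CandidateWindow:
    chrom: str
    start: int
    end: int
    source_sample: str
    source_summit: int
    source_height: int


@dataclass
class RegionAtlas:
    """Disjoint fixed-width regions with provenance, sorted by (chrom, start).

    ``regions`` columns: chrom, start, end, region_id, source_sample,
    source_summit, source_height.
    """

    regions: pd.DataFrame
    width: int

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return self.regions["region_id"].tolist()


@dataclass
class RegionScoreMatrix:
    """regions x samples raw extended-read counts and RPM-normalised scores."""

    raw: pd.DataFrame
    rpm: pd.DataFrame
    library_sizes: pd.Series


def summit_windows(
    peaks: Sequence[Peak],
    W: int,
    chrom_lengths: Mapping[str, int],
    sample_id: str = "",
) -> list[CandidateWindow]:
    """Fixed-width windows [summit - W/2, summit + W/2), clipped at ends."""
    if W < 2 or W % 2 != 0:
        raise ValueError("window width W must be even and >= 2")
    windows = []
    for p in peaks:
        clen = chrom_lengths[p.chrom]
        start = max(0, p.summit - W // 2)
        end = min(clen, p.summit + W // 2)
        windows.append(
            CandidateWindow(p.chrom, start, end, sample_id, p.summit, p.height)
        )
    return windows


def build_atlas(
    per_sample_windows: Mapping[str, Sequence[CandidateWindow]], W: int
) -> RegionAtlas:
    """Greedy height-ranked non-overlapping selection across all samples.

    Windows are ranked by descending source height, ties broken by
    (chrom, start, sample id); a window is accepted iff it overlaps no
    previously accepted window by >= 1 bp.  The result is independent of the
    input ordering.
    """
    ranked = sorted(
        (
            w
            for sample, windows in per_sample_windows.items()
            for w in windows
        ),
        key=lambda w: (-w.source_height, w.chrom, w.start, w.source_sample),
    )
    accepted: dict[str, tuple[list[int], list[int], list[CandidateWindow]]] = {}
    for w in ranked:
        starts, ends, kept = accepted.setdefault(w.chrom, ([], [], []))
        i = bisect.bisect_left(starts, w.start)
        # overlap possible only with the interval starting at or after w.start
        # (starts[i]) or the one just before it (ends[i-1])
        if i < len(starts) and starts[i] < w.end:
            continue
        if i > 0 and ends[i - 1] > w.start:
            continue
        starts.insert(i, w.start)
        ends.insert(i, w.end)
        kept.insert(i, w)

    rows = []
    for chrom in sorted(accepted):
        rows.extend(accepted[chrom][2])
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in rows],
            "start": [w.start for w in rows],
            "end": [w.end for w in rows],
            "region_id": [f"R{i:06d}" for i in range(len(rows))],
            "source_sample": [w.source_sample for w in rows],
            "source_summit": [w.source_summit for w in rows],
            "source_height": [w.source_height for w in rows],
        }
    )
    return RegionAtlas(df, W)


def score_regions(
    atlas: RegionAtlas,
    tag_sets: Mapping[str, TagSet],
    L: int,
    chrom_lengths: Mapping[str, int],
    mode: str = "overlap",
) -> RegionScoreMatrix:
    """Count extended tags per (region, sample) and normalise to RPM.

    ``mode='overlap'`` (default) counts extended intervals overlapping the
    region by >= 1 bp; ``mode='containment'`` requires the whole interval
    inside the region.
    """
    if len(atlas) == 0:
        raise ValueError("empty atlas")
    if mode not in ("overlap", "containment"):
        raise ValueError(f"unknown counting mode {mode!r}")
    for sid, ts in tag_sets.items():
        if ts.library_size < 1:
            raise ValueError(f"sample {sid} has an empty tag set")

    region_df = atlas.regions
    raw = pd.DataFrame(
        0, index=region_df["region_id"].to_numpy(), columns=list(tag_sets)
    )
    for sample_id, tags in tag_sets.items():
        intervals = extend_tags(tags, L, chrom_lengths)
        for chrom, grp in region_df.groupby("chrom", sort=False):
            ivs = intervals.get(chrom)
            if ivs is None or not len(ivs):
                continue
            starts = np.sort(ivs[:, 0])
            ends = np.sort(ivs[:, 1])
            rs = grp["start"].to_numpy()
            re_ = grp["end"].to_numpy()
            if mode == "overlap":
                # (# interval starts < region end) - (# interval ends <= region start)
                cnt = np.searchsorted(starts, re_, side="left") - np.searchsorted(
                    ends, rs, side="right"
                )
            else:
                cnt = _containment_counts(ivs, rs, re_)
            raw.loc[grp["region_id"].to_numpy(), sample_id] = cnt

    library_sizes = pd.Series(
        {sid: ts.library_size for sid, ts in tag_sets.items()}, name="library_size"
    )
    rpm = raw / library_sizes * 1e6
    return RegionScoreMatrix(raw, rpm, library_sizes)


def _containment_counts(
    ivs: np.ndarray, rs: np.ndarray, re_: np.ndarray
) -> np.ndarray:
    order = np.argsort(ivs[:, 0], kind="stable")
    starts = ivs[order, 0]
    ends = ivs[order, 1]
    out = np.empty(len(rs), dtype=np.int64)
    for i, (a, b) in enumerate(zip(rs, re_)):
        lo = np.searchsorted(starts, a, side="left")
        hi = np.searchsorted(starts, b, side="left")
        out[i] = int(np.count_nonzero(ends[lo:hi] <= b))
    return out
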