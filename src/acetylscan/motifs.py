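"""Consensus-motif counting and bootstrap enrichment Z-scores.

Motifs are IUPAC consensus strings (e.g. the GATA family consensus WGATAR).
A target region set's observed occurrence total is compared against an
empirical null built by repeatedly drawing equally sized region sets from
the full atlas (1000 resamples by default), giving a mean and SD of expected
occurrences and hence a Z-score; |Z| >= 3 calls over/under-representation.

The shipped default motif set contains editable IUPAC stand-ins for six
haematopoietic factors (Gata2, Gfi1, Lyl1, Sfpi1/Pu.1, Cebpa, Meis1); only
the GATA consensus WGATAR is a field-standard string, the others are
placeholders to be replaced with database-derived consensi.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .atlas import RegionAtlas
    from .synthetic import GenomeSequence

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

#: Editable IUPAC stand-ins for the six factors tested by default.
DEFAULT_MOTIFS: dict[str, str] = {
    "Gata2": "WGATAR",
    "Gfi1": "AAATCW",
    "Lyl1": "CAGCTG",
    "Sfpi1": "RGAGGAAG",
    "Cebpa": "TTGCNNAA",
    "Meis1": "TGACAG",
}


@dataclass(frozen=True)
class ConsensusMotif:
    motif_id: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty consensus string")
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC letters: {sorted(bad)}")

    @property
    def reverse_complement(self) -> str:
        return "".join(_COMPLEMENT[b] for b in reversed(self.iupac.upper()))

    @property
    def is_palindromic(self) -> bool:
        return self.iupac.upper() == self.reverse_complement


@dataclass
class BootstrapNull:
    motif_id: str
    B: int
    set_size: int
    mean: float
    sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    observed: int
    expected_mean: float
    expected_sd: float
    z_score: float
    call: str  # over | under | ns


def sample_iupac_instance(iupac: str, rng: np.random.Generator) -> str:
    """Concrete A/C/G/T string drawn uniformly from an IUPAC pattern."""
    return "".join(
        IUPAC_CODES[b][rng.integers(0, len(IUPAC_CODES[b]))]
        for b in iupac.upper()
    )


def _iupac_regex(iupac: str) -> re.Pattern[str]:
    # classes contain only A/C/G/T, so an N in the scanned sequence can never
    # match anything — exactly the required behaviour
    parts = []
    for b in iupac.upper():
        opts = IUPAC_CODES[b]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(f"(?=({''.join(parts)}))")  # lookahead: overlapping hits


def scan_sequence(sequence: str, motif: ConsensusMotif) -> int:
    """Count motif occurrences on both strands of ``sequence``.

    Forward-strand matches of the pattern plus forward-strand matches of its
    reverse complement; overlapping matches all count; a palindromic pattern
    is counted once per position.
    """
    seq = sequence.upper()
    if len(motif.iupac) > len(seq):
        return 0
    n = len(_iupac_regex(motif.iupac).findall(seq))
    if not motif.is_palindromic:
        n += len(_iupac_regex(motif.reverse_complement).findall(seq))
    return n


def region_sequences(
    atlas: "RegionAtlas", genome: "GenomeSequence",
    region_ids: Iterable[str] | None = None,
) -> dict[str, str]:
    """Genomic sequence of each (or the selected) atlas regions."""
    df = atlas.regions
    if region_ids is not None:
        wanted = list(region_ids)
        missing = set(wanted) - set(df["region_id"])
        if missing:
            raise KeyError(f"region ids not in atlas: {sorted(missing)[:5]}")
        df = df[df["region_id"].isin(wanted)]
    out: dict[str, str] = {}
    lengths = genome.lengths
    for row in df.itertuples(index=False):
        if row.start < 0 or row.end > lengths[row.chrom]:
            raise ValueError(f"region {row.region_id} outside genome bounds")
        out[row.region_id] = genome.fetch(row.chrom, row.start, row.end)
    return out


def region_count_table(
    atlas: "RegionAtlas",
    genome: "GenomeSequence",
    motifs: Sequence[ConsensusMotif],
    presence: bool = False,
) -> pd.DataFrame:
    """Per-region, per-motif occurrence counts (or 0/1 presence flags)."""
    seqs = region_sequences(atlas, genome)
    data = {
        m.motif_id: [scan_sequence(s, m) for s in seqs.values()] for m in motifs
    }
    table = pd.DataFrame(data, index=list(seqs.keys()))
    if presence:
        table = (table > 0).astype(int)
    return table


def observed_counts(
    region_ids: Iterable[str],
    atlas: "RegionAtlas",
    genome: "GenomeSequence",
    motifs: Sequence[ConsensusMotif],
    presence: bool = False,
) -> dict[str, int]:
    """Total motif occurrences over the selected regions."""
    ids = list(region_ids)
    if not ids:
        return {m.motif_id: 0 for m in motifs}
    seqs = region_sequences(atlas, genome, ids)
    totals: dict[str, int] = {}
    for m in motifs:
        counts = [scan_sequence(s, m) for s in seqs.values()]
        if presence:
            counts = [1 if c > 0 else 0 for c in counts]
        totals[m.motif_id] = int(sum(counts))
    return totals


def bootstrap_null(
    atlas: "RegionAtlas",
    genome: "GenomeSequence",
    motifs: Sequence[ConsensusMotif],
    set_size: int,
    B: int = 1000,
    seed: int = 0,
    replace: bool = True,
    presence: bool = False,
    count_table: pd.DataFrame | None = None,
) -> dict[str, BootstrapNull]:
    """Bootstrap distribution of occurrence totals over random region sets.

    Draws ``B`` sets of ``set_size`` regions uniformly (with replacement by
    default) from the full atlas; the per-motif mean and SD (denominator
    B - 1) of the set totals form the null.  ``count_table`` may carry
    precomputed per-region counts to avoid rescanning.
    """
    n = len(atlas.regions)
    if n == 0:
        raise ValueError("empty atlas")
    if set_size > n and not replace:
        raise ValueError("set_size exceeds atlas size for sampling without replacement")
    if B < 2:
        raise ValueError("B must be >= 2")
    if count_table is None:
        count_table = region_count_table(atlas, genome, motifs, presence=presence)
    counts = count_table[[m.motif_id for m in motifs]].to_numpy()

    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, n, size=(B, set_size))
    else:
        idx = np.stack([rng.choice(n, size=set_size, replace=False) for _ in range(B)])
    totals = counts[idx].sum(axis=1)  # B x n_motifs
    means = totals.mean(axis=0)
    sds = totals.std(axis=0, ddof=1)
    return {
        m.motif_id: BootstrapNull(m.motif_id, B, set_size, float(mu), float(sd), seed)
        for m, mu, sd in zip(motifs, means, sds)
    }


def z_scores(
    observed: Mapping[str, int],
    nulls: Mapping[str, BootstrapNull],
    z_threshold: float = 3.0,
) -> list[MotifEnrichmentResult]:
    """Z = (observed - mean) / sd with calls at |Z| >= z_threshold (inclusive).

    A degenerate null (sd = 0) yields z = 0 when observed equals the mean and
    a signed infinity sentinel otherwise, with the call taken from the sign.
    """
    if set(observed) != set(nulls):
        raise ValueError("observed and null motif sets differ")
    results = []
    for motif_id in observed:
        null = nulls[motif_id]
        obs = observed[motif_id]
        if null.sd == 0:
            z = 0.0 if obs == null.mean else math.copysign(math.inf, obs - null.mean)
        else:
            z = (obs - null.mean) / null.sd
        if z >= z_threshold:
            call = "over"
        elif z <= -z_threshold:
            call = "under"
        else:
            call = "ns"
        results.append(
            MotifEnrichmentResult(motif_id, int(obs), null.mean, null.sd, z, call)
        )
    return results


def enrichment_table(results: Sequence[MotifEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "observed": [r.observed for r in results],
            "expected_mean": [r.expected_mean for r in results],
            "expected_sd": [r.expected_sd for r in results],
            "z_score": [r.z_score for r in results],
            "call": [r.call for r in results],
        }
    ).set_index("motif_id")
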