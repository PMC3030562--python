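"""Synthetic genomes, ChIP tag sets and expression matrices with known truth.

The generators emulate the statistical structure of a six-condition AML
progression study: a baseline group (WT, FDCP, MT-I) and a leukaemic group
(ME-I, ME-L, MT-L), two ChIP replicates and three expression replicates per
condition.  Planted regulatory regions carry elevated tag density, a subset
carry a multiplicative group effect (fold < 1 models loss of acetylation in
the leukaemic group), and consensus motifs are written into the genome at a
higher rate inside the affected regions.  Every generator is a pure function
of its arguments and a seed, and returns enough truth to score recovery.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import sample_iupac_instance
from .peaks import TagSet

DEFAULT_CONDITIONS = ("WT", "FDCP", "MT-I", "ME-I", "ME-L", "MT-L")
DEFAULT_PARTITION = {
    "WT": "A",
    "FDCP": "A",
    "MT-I": "A",
    "ME-I": "B",
    "ME-L": "B",
    "MT-L": "B",
}
# Baseline -> initiation and initiation -> progression for each oncogene.
DEFAULT_TRANSITIONS = (
    ("WT", "ME-I"),
    ("FDCP", "ME-I"),
    ("ME-I", "ME-L"),
    ("WT", "MT-I"),
    ("FDCP", "MT-I"),
    ("MT-I", "MT-L"),
)
# ME baseline->initiation intersected with MT initiation->progression defines
# the shared progression sets.
SHARED_TRANSITIONS = (("FDCP", "ME-I"), ("MT-I", "MT-L"))


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stream seed: first 4 bytes of SHA-256(master:label)."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class GenomeSequence:
    """In-memory genome: ordered chromosomes of A/C/G/T sequence."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            seq = self.sequences[name]
            extra = set(seq) - set("ACGT")
            if extra:
                raise ValueError(f"{name}: alphabet outside A/C/G/T: {sorted(extra)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass
class SampleDesign:
    """Condition layout and the two-group partition used for testing."""

    condition_names: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 2
    group_partition: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PARTITION)
    )

    def __post_init__(self) -> None:
        missing = set(self.condition_names) - set(self.group_partition)
        if missing:
            raise ValueError(f"partition does not cover conditions: {sorted(missing)}")

    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_r{i + 1}"
            for cond in self.condition_names
            for i in range(self.replicates_per_condition)
        ]

    def condition_of(self, sample_id: str) -> str:
        return sample_id.rsplit("_r", 1)[0]

    def group_of(self, sample_id: str) -> str:
        return self.group_partition[self.condition_of(sample_id)]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids() if self.group_of(s) == group]

    def samples_of_condition(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids() if self.condition_of(s) == condition]


@dataclass
class PlantedRegion:
    """Ground-truth enriched region; group_effect != 1 marks differential."""

    chrom: str
    center: int
    width: int
    base_enrichment: float
    group_effect: float
    motif_placements: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.base_enrichment < 1:
            raise ValueError("base_enrichment must be >= 1")
        for _, pos, instance in self.motif_placements:
            if not (self.start <= pos and pos + len(instance) <= self.end):
                raise ValueError("motif placement outside region")

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def is_differential(self) -> bool:
        return self.group_effect != 1.0


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of planted structure."""

    planted_regions: list[PlantedRegion] = field(default_factory=list)
    de_probe_labels: pd.DataFrame | None = None  # probes x transitions, {up,down,null}
    seed: int | None = None


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement fails after bounded retries."""


def generate_genome(
    n_chroms: int, length_per_chrom: int, gc_fraction: float, seed: int
) -> GenomeSequence:
    """I.i.d. random genome with P(G) + P(C) = gc_fraction."""
    if length_per_chrom < 10_000:
        raise ValueError("length_per_chrom must be >= 10,000")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must be in (0, 1)")
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = np.array(list("ACGT"))
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs = {
        name: "".join(
            bases[rng.choice(4, size=length_per_chrom, p=[at, gc, gc, at])]
        )
        for name in names
    }
    return GenomeSequence(names, seqs)


def plant_regions(
    genome: GenomeSequence,
    n_regions: int,
    width: int,
    motif_spec: Mapping[str, tuple[str, float, float]],
    fraction_group_effect: float,
    effect_fold: float,
    seed: int,
    base_enrichment: float = 10.0,
    max_tries: int = 1000,
) -> tuple[GenomeSequence, list[PlantedRegion]]:
    """Place non-overlapping regions and write motif instances into them.

    ``motif_spec`` maps motif id -> (IUPAC string, planting rate per affected
    region, planting rate per other region); rates are expected counts (the
    integer part is planted deterministically, the fractional part as a
    Bernoulli extra).  A ``fraction_group_effect`` subset of regions carries
    ``group_effect = effect_fold`` (fold < 1: acetylation deprived in group B;
    fold > 1: enriched); the rest have group_effect 1.
    """
    if effect_fold <= 0:
        raise ValueError("effect_fold must be > 0")
    if not (0.0 <= fraction_group_effect <= 1.0):
        raise ValueError("fraction_group_effect must be in [0, 1]")
    if n_regions == 0:
        return genome, []

    rng = np.random.default_rng(seed)
    margin = width  # keep clear of chromosome ends so windows never clip
    lengths = genome.lengths
    placeable = [c for c in genome.chrom_names if lengths[c] >= width + 2 * margin]
    if not placeable:
        raise PlacementError("no chromosome long enough for requested width")
    weights = np.array([lengths[c] for c in placeable], dtype=float)
    weights /= weights.sum()

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in placeable}
    placed: list[tuple[str, int]] = []
    tries = 0
    while len(placed) < n_regions:
        if tries >= max_tries * n_regions:
            raise PlacementError(
                f"could not place {n_regions} non-overlapping regions"
            )
        tries += 1
        chrom = placeable[rng.choice(len(placeable), p=weights)]
        center = int(rng.integers(margin + width // 2, lengths[chrom] - margin - width // 2))
        start, end = center - width // 2, center - width // 2 + width
        if any(start < e and end > s for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        placed.append((chrom, center))

    n_effect = int(round(fraction_group_effect * n_regions))
    effect_idx = set(rng.choice(n_regions, size=n_effect, replace=False).tolist())

    seqs = {c: bytearray(genome.sequences[c], "ascii") for c in genome.chrom_names}
    regions: list[PlantedRegion] = []
    for i, (chrom, center) in enumerate(placed):
        affected = i in effect_idx
        region = PlantedRegion(
            chrom=chrom,
            center=center,
            width=width,
            base_enrichment=base_enrichment,
            group_effect=effect_fold if affected else 1.0,
        )
        taken: list[tuple[int, int]] = []
        for motif_id, (iupac, rate_affected, rate_other) in motif_spec.items():
            rate = rate_affected if affected else rate_other
            count = int(np.floor(rate))
            if rng.random() < rate - count:
                count += 1
            for _ in range(count):
                instance = sample_iupac_instance(iupac, rng)
                m = len(instance)
                for _attempt in range(200):
                    pos = int(rng.integers(region.start, region.end - m + 1))
                    if all(pos + m <= s or pos >= e for s, e in taken):
                        break
                else:
                    raise PlacementError("could not place motif inside region")
                taken.append((pos, pos + m))
                seqs[chrom][pos : pos + m] = instance.encode("ascii")
                region.motif_placements.append((motif_id, pos, instance))
        regions.append(region)

    new_genome = GenomeSequence(
        list(genome.chrom_names),
        {c: seqs[c].decode("ascii") for c in genome.chrom_names},
    )
    return new_genome, regions


def simulate_chip_tags(
    genome: GenomeSequence,
    regions: Sequence[PlantedRegion],
    design: SampleDesign,
    depth: int,
    fragment_len: int = 200,
    seed: int = 0,
) -> dict[str, TagSet]:
    """Simulate one TagSet per sample with exactly ``depth`` tags.

    Background tags have uniform 5' ends and random strand over the whole
    genome.  Each planted region additionally attracts enriched tags so that
    its mean density is base_enrichment x (group_effect in group-B samples)
    times background.  Enriched fragments centre near the region midpoint;
    forward tags sit a half fragment upstream of the midpoint and reverse
    tags a half fragment downstream, reproducing the strand asymmetry that
    strand-specific extension corrects.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    lengths = genome.lengths
    chroms = list(genome.chrom_names)
    clens = np.array([lengths[c] for c in chroms], dtype=np.int64)
    G = int(clens.sum())
    offsets = np.concatenate([[0], np.cumsum(clens)])

    out: dict[str, TagSet] = {}
    for sample_id in design.sample_ids():
        rng = np.random.default_rng(derive_seed(seed, sample_id))
        in_b = design.group_of(sample_id) == "B"
        extra = np.array(
            [
                r.width * max(r.base_enrichment * (r.group_effect if in_b else 1.0) - 1.0, 0.0)
                for r in regions
            ],
            dtype=np.float64,
        )
        weights = np.concatenate([[float(G)], extra])
        counts = rng.multinomial(depth, weights / weights.sum())

        chrom_col: list[np.ndarray] = []
        pos_col: list[np.ndarray] = []
        strand_col: list[np.ndarray] = []

        # background: uniform over the concatenated genome
        n_bg = counts[0]
        flat = rng.integers(0, G, size=n_bg)
        ci = np.searchsorted(offsets, flat, side="right") - 1
        chrom_col.append(ci.astype(np.int64))
        pos_col.append(flat - offsets[ci])
        strand_col.append(rng.random(n_bg) < 0.5)

        chrom_index = {c: i for i, c in enumerate(chroms)}
        for r, n_r in zip(regions, counts[1:]):
            if n_r == 0:
                continue
            mid = rng.normal(r.center, r.width / 4.0, size=n_r)
            mid = np.clip(np.rint(mid), r.start, r.end - 1).astype(np.int64)
            fwd = rng.random(n_r) < 0.5
            pos = np.where(fwd, mid - fragment_len // 2, mid + fragment_len // 2)
            pos = np.clip(pos, 0, lengths[r.chrom] - 1)
            chrom_col.append(np.full(n_r, chrom_index[r.chrom], dtype=np.int64))
            pos_col.append(pos)
            strand_col.append(fwd)

        ci_all = np.concatenate(chrom_col)
        records = pd.DataFrame(
            {
                "chrom": pd.Categorical.from_codes(
                    ci_all, categories=chroms
                ).astype(str),
                "pos": np.concatenate(pos_col).astype(np.int64),
                "strand": np.where(np.concatenate(strand_col), "+", "-"),
            }
        )
        out[sample_id] = TagSet(sample_id, records)
    return out


@dataclass
class ExpressionMatrix:
    """Log-scale intensities and detection scores, probes x samples."""

    intensities: pd.DataFrame
    detection: pd.DataFrame
    conditions: dict[str, str]  # sample id -> condition

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.detection.columns):
            raise ValueError("intensity and detection sample sets differ")
        if not self.intensities.index.equals(self.detection.index):
            raise ValueError("intensity and detection probe sets differ")


def simulate_expression(
    design: SampleDesign,
    n_probes: int,
    n_de_per_transition: int,
    log_fc: float = 2.0,
    noise_sd: float = 0.5,
    detection_fraction: float = 0.458,
    seed: int = 0,
    transitions: Sequence[tuple[str, str]] = DEFAULT_TRANSITIONS,
    n_shared_up: int = 0,
    n_shared_down: int = 0,
    shared_transitions: Sequence[tuple[str, str]] = SHARED_TRANSITIONS,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Gaussian log-intensity matrix with planted per-transition DE probes.

    For a DE probe in transition (from, to), the ``to`` condition mean is
    shifted by +/- log_fc.  ``n_shared_up``/``n_shared_down`` probes are
    additionally planted concordantly in both ``shared_transitions`` —
    the intersection that defines the shared progression gene sets.  A
    (1 - detection_fraction) subset of probes is undetected in all samples.
    """
    if n_de_per_transition > n_probes:
        raise ValueError("n_de_per_transition exceeds n_probes")
    rng = np.random.default_rng(seed)

    probe_ids = [f"probe_{i:06d}" for i in range(n_probes)]
    tnames = [f"{a}_vs_{b}" for a, b in transitions]
    labels = pd.DataFrame("null", index=probe_ids, columns=tnames, dtype=object)
    cond_shift = np.zeros((n_probes, len(design.condition_names)))
    cond_index = {c: j for j, c in enumerate(design.condition_names)}

    available = rng.permutation(n_probes).tolist()

    def take(k: int) -> list[int]:
        if len(available) < k:
            raise ValueError("not enough free probes to plant requested effects")
        picked = available[:k]
        del available[:k]
        return picked

    # shared progression probes: concordant DE in both shared transitions
    shared_names = [f"{a}_vs_{b}" for a, b in shared_transitions]
    for count, sign in ((n_shared_up, +1.0), (n_shared_down, -1.0)):
        for i in take(count):
            for (frm, to), tname in zip(shared_transitions, shared_names):
                cond_shift[i, cond_index[to]] += sign * log_fc
                labels.iloc[i, tnames.index(tname)] = "up" if sign > 0 else "down"

    # independent per-transition DE probes (disjoint from the shared sets)
    for (frm, to), tname in zip(transitions, tnames):
        for i in take(n_de_per_transition):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            cond_shift[i, cond_index[to]] += sign * log_fc
            labels.iloc[i, tnames.index(tname)] = "up" if sign > 0 else "down"

    sample_ids: list[str] = []
    cols: list[np.ndarray] = []
    base = rng.normal(7.0, 1.0, size=n_probes)
    for cond in design.condition_names:
        j = cond_index[cond]
        for r in range(design.replicates_per_condition):
            sample_ids.append(f"{cond}_r{r + 1}")
            cols.append(
                base + cond_shift[:, j] + rng.normal(0.0, noise_sd, size=n_probes)
            )
    intensities = pd.DataFrame(
        np.column_stack(cols), index=probe_ids, columns=sample_ids
    )

    # detection: exactly round(detection_fraction * n_probes) probes are
    # detected; planted DE probes are expressed by construction, so they fill
    # the quota first and the remainder is drawn from the unplanted pool
    n_detected = int(round(detection_fraction * n_probes))
    planted_mask = (labels != "null").any(axis=1).to_numpy()
    planted_idx = np.nonzero(planted_mask)[0]
    if len(planted_idx) > n_detected:
        raise ValueError("more planted DE probes than the detection quota")
    other_idx = np.nonzero(~planted_mask)[0]
    fill = rng.choice(other_idx, size=n_detected - len(planted_idx), replace=False)
    detected = np.zeros(n_probes, dtype=bool)
    detected[planted_idx] = True
    detected[fill] = True
    det = np.zeros((n_probes, len(sample_ids)))
    per_sample = rng.random((n_probes, len(sample_ids))) < 0.7
    none_on = ~per_sample.any(axis=1)
    per_sample[none_on, rng.integers(0, len(sample_ids), size=int(none_on.sum()))] = True
    det[detected] = np.where(
        per_sample[detected],
        rng.uniform(0.5, 1.0, size=(int(detected.sum()), len(sample_ids))),
        rng.uniform(0.0, 0.009, size=(int(detected.sum()), len(sample_ids))),
    )
    detection = pd.DataFrame(det, index=probe_ids, columns=sample_ids)

    conditions = {s: s.rsplit("_r", 1)[0] for s in sample_ids}
    matrix = ExpressionMatrix(intensities, detection, conditions)
    truth = SyntheticTruth(planted_regions=[], de_probe_labels=labels, seed=seed)
    return matrix, truth
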