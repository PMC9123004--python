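"""Per-tract microsatellite instability calling from aligned reads.

Each mononucleotide tract (13-30 bp homopolymer) is genotyped by seed-based
local realignment of the reads that span it: the repeat segment between two
exact-matching flanking anchors is measured, PCR-stutter noise is corrected
by peak finding on the error-corrected indel-length histogram, and a tract
is unstable when a supported allele is at least 2 bp shorter than the
reference run.  A sample is MSI-high when more than 10 of the 68 panel
tracts are unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval, ReadRecord

MAX_INDEL_OFFSET = 12       # |indel| must be <= 12 bp from the reference length
MIN_FLANK_INSIDE = 8        # tract must be more than 8 bases inside read ends
REQUIRED_MAPQ = 60
MAX_SOFTCLIP = 20
MIN_ALLELE_FRAGMENTS = 5    # strict: need >5 distinct fragments
MIN_ALLELE_FRACTION = 0.08  # >=8% of the absolute coverage
UNSTABLE_OFFSET = -2        # allele >=2 bp shorter than reference
MSIH_MIN_UNSTABLE = 10      # MSI-H when more than 10 of 68 tracts unstable


@dataclass(frozen=True)
class TractDefinition:
    """A mononucleotide tract with its flanking realignment anchors."""

    interval: GenomicInterval
    base: str
    ref_length: int
    seed5: str
    seed3: str

    def __post_init__(self) -> None:
        if not 13 <= self.ref_length <= 30:
            raise ValueError(f"ref_length must be in [13, 30], got {self.ref_length}")
        if len(self.interval) != self.ref_length:
            raise ValueError("interval length must equal ref_length")
        if len(self.seed5) < 8 or len(self.seed3) < 8:
            raise ValueError("seeds must be at least 8 bp")
        if len(self.base) != 1:
            raise ValueError("base must be a single nucleotide")

    @property
    def tract_id(self) -> str:
        return self.interval.label or (
            f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
        )


@dataclass(frozen=True)
class TractObservation:
    """One read's measurement at one tract."""

    read_id: str
    indel_offset: int | None
    eligible: bool
    reason: str = ""


@dataclass
class LengthDistribution:
    """Error-corrected indel-length histogram of distinct fragments."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def absolute_coverage(self) -> int:
        return sum(self.counts.values())


@dataclass
class TractCall:
    tract: TractDefinition
    alleles: list[int]
    unstable: bool
    n_fragments: int = 0


@dataclass(frozen=True)
class MsiTractResult:
    n_evaluated: int
    n_unstable: int

    @property
    def fraction_unstable(self) -> float:
        return self.n_unstable / self.n_evaluated

    @property
    def tract_msih(self) -> bool:
        return self.n_unstable > MSIH_MIN_UNSTABLE


# ---------------------------------------------------------------------------
# read-level measurement
# ---------------------------------------------------------------------------


def _locate_segment(read: ReadRecord, tract: TractDefinition):
    """Exact-match both seeds in the read; return (i5, i3, segment) or None.

    i5/i3 are the read-sequence indices where seed5 ends and seed3 starts;
    the repeat segment lies between them.
    """
    seq = read.sequence
    p5 = seq.find(tract.seed5)
    if p5 < 0:
        return None
    i5 = p5 + len(tract.seed5)
    p3 = seq.find(tract.seed3, i5)
    if p3 < 0:
        return None
    return i5, p3, seq[i5:p3]


def measure_tract_length(read: ReadRecord, tract: TractDefinition) -> int:
    """Indel offset of the realigned repeat segment vs the reference length.

    Seeds are located by exact string match; the offset is the segment
    length minus the reference tract length (negative = contraction).
    Raises ValueError when a seed cannot be located.
    """
    loc = _locate_segment(read, tract)
    if loc is None:
        raise ValueError("seed sequences not found in read")
    _, _, segment = loc
    return len(segment) - tract.ref_length


def filter_read(read: ReadRecord, tract: TractDefinition) -> TractObservation:
    """Apply the five eligibility criteria to one read at one tract.

    A read contributes to the indel-length distribution only if (i) the
    tract sits more than 8 bases inside both read ends, (ii) the measured
    indel is within 12 bp of the reference length, (iii) the repeat segment
    carries no single-base change, (iv) mapping quality is exactly the
    required value, and (v) at most 20 bases are soft clipped.  The
    rejection reason records the first criterion that failed.
    """
    read_iv = GenomicInterval(read.chrom, read.pos, max(read.reference_end, read.pos + 1))
    if not read_iv.overlaps(tract.interval):
        raise ValueError("read does not overlap the tract")

    loc = _locate_segment(read, tract)
    if loc is None:
        return TractObservation(read.read_id, None, False, "seed")
    i5, i3, segment = loc

    # (i) tract more than 8 bases inside both read ends
    if i5 <= MIN_FLANK_INSIDE or (len(read.sequence) - i3) <= MIN_FLANK_INSIDE:
        return TractObservation(read.read_id, None, False, "flank")
    offset = len(segment) - tract.ref_length
    # (ii) indel within 12 bp of the reference length
    if abs(offset) > MAX_INDEL_OFFSET:
        return TractObservation(read.read_id, offset, False, "indel")
    # (iii) no single-base change within the realigned repeat segment
    if any(b != tract.base for b in segment):
        return TractObservation(read.read_id, offset, False, "basechange")
    # (iv) exact mapping score
    if read.mapq != REQUIRED_MAPQ:
        return TractObservation(read.read_id, offset, False, "mapq")
    # (v) soft clipping
    if read.softclip_total > MAX_SOFTCLIP:
        return TractObservation(read.read_id, offset, False, "softclip")
    return TractObservation(read.read_id, offset, True)


def build_length_distribution(
    reads: Iterable[ReadRecord], tract: TractDefinition
) -> LengthDistribution:
    """Eligible reads -> distinct-fragment indel-length histogram.

    Fragment identity is (alignment start, alignment end, indel offset), so
    re-adding a duplicate fragment never changes the histogram.
    """
    counts: dict[int, int] = {}
    seen: set[tuple] = set()
    for read in reads:
        obs = filter_read(read, tract)
        if not obs.eligible:
            continue
        key = (read.pos, read.reference_end, obs.indel_offset)
        if key in seen:
            continue
        seen.add(key)
        counts[obs.indel_offset] = counts.get(obs.indel_offset, 0) + 1
    return LengthDistribution(counts)


# ---------------------------------------------------------------------------
# peak finding and classification
# ---------------------------------------------------------------------------


def find_alleles(
    dist: LengthDistribution,
    min_fragments: int = MIN_ALLELE_FRAGMENTS,
    min_fraction: float = MIN_ALLELE_FRACTION,
) -> list[int]:
    """Peak-find allele offsets in an indel-length histogram.

    An offset L is an allele iff its count strictly exceeds the counts at
    L±1 and L±2 (absent lengths count as 0), exceeds ``min_fragments``
    distinct fragments, and is at least ``min_fraction`` of the absolute
    coverage.  Ties with a neighbour disqualify both (conservative).
    """
    total = dist.absolute_coverage
    if total == 0:
        raise ValueError("no eligible fragments")
    counts = dist.counts
    alleles = []
    for offset in sorted(counts):
        c = counts[offset]
        if c <= min_fragments:
            continue
        if c / total < min_fraction:
            continue
        neighbours = (
            counts.get(offset - 2, 0),
            counts.get(offset - 1, 0),
            counts.get(offset + 1, 0),
            counts.get(offset + 2, 0),
        )
        if all(c > nb for nb in neighbours):
            alleles.append(offset)
    return alleles


def classify_tract(alleles: Sequence[int], tract: TractDefinition) -> TractCall:
    """Unstable iff any supported allele is >=2 bp shorter than reference.

    Insertions never mark instability; only contractions do.
    """
    unstable = any(a <= UNSTABLE_OFFSET for a in alleles)
    return TractCall(tract=tract, alleles=list(alleles), unstable=unstable)


def call_tract(reads: Iterable[ReadRecord], tract: TractDefinition) -> TractCall:
    """Full per-tract pipeline: filter, realign, peak-find, classify.

    A tract with zero eligible fragments is treated as stable and carries
    an empty allele list.
    """
    dist = build_length_distribution(reads, tract)
    if dist.absolute_coverage == 0:
        call = TractCall(tract=tract, alleles=[], unstable=False)
    else:
        call = classify_tract(find_alleles(dist), tract)
    call.n_fragments = dist.absolute_coverage
    return call


def score_sample(calls: Sequence[TractCall]) -> MsiTractResult:
    """Sample-level tract score: count unstable tracts over the panel."""
    if not calls:
        raise ValueError("no evaluated tracts")
    n_unstable = sum(1 for c in calls if c.unstable)
    return MsiTractResult(n_evaluated=len(calls), n_unstable=n_unstable)


# ---------------------------------------------------------------------------
# tract panel selection
# ---------------------------------------------------------------------------


def select_tracts(
    candidates: Sequence[TractDefinition],
    distributions: Mapping[str, Mapping[str, LengthDistribution]],
    labels: Mapping[str, str],
    min_coverage: int = 20,
    max_low_coverage_fraction: float = 0.5,
    min_effect: float = 0.3,
) -> list[TractDefinition]:
    """Select discriminative tracts from a labelled training cohort.

    ``distributions`` maps tract_id -> sample -> LengthDistribution and
    ``labels`` maps sample -> "MSI" | "MSS".  A tract is dropped when (a)
    its coverage is below ``min_coverage`` in more than
    ``max_low_coverage_fraction`` of samples, (b) it is polymorphic (more
    than one supported allele) in any MSS sample, or (c) the difference in
    unstable-call rate between classes is below ``min_effect``.
    """
    classes = set(labels.values())
    if not {"MSI", "MSS"} <= classes:
        raise ValueError("labelled cohort must contain both MSI and MSS samples")

    retained: list[TractDefinition] = []
    for tract in candidates:
        per_sample = distributions.get(tract.tract_id, {})
        covs = [per_sample.get(s, LengthDistribution()).absolute_coverage
                for s in labels]
        if not covs:
            continue
        low = sum(1 for c in covs if c < min_coverage) / len(covs)
        if low > max_low_coverage_fraction:
            continue

        def unstable_rate(cls: str) -> float:
            flags = []
            for sample, label in labels.items():
                if label != cls:
                    continue
                dist = per_sample.get(sample)
                if dist is None or dist.absolute_coverage == 0:
                    continue
                alleles = find_alleles(dist)
                flags.append(any(a <= UNSTABLE_OFFSET for a in alleles))
            return float(np.mean(flags)) if flags else 0.0

        polymorphic = False
        for sample, label in labels.items():
            if label != "MSS":
                continue
            dist = per_sample.get(sample)
            if dist is not None and dist.absolute_coverage > 0:
                if len(find_alleles(dist)) > 1:
                    polymorphic = True
                    break
        if polymorphic:
            continue
        if unstable_rate("MSI") - unstable_rate("MSS") < min_effect:
            continue
        retained.append(tract)
    return retained
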