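"""Readers, writers and shared genomic containers.

Coordinate conventions
----------------------
BED-derived intervals are 0-based half-open.  Variant records follow the
VCF convention: 1-based positions with anchored indels.  Every function
that mixes the two says which frame it works in.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
import yaml

logger = logging.getLogger("panelprof")

VALID_CONSEQUENCES = frozenset(
    {"synonymous", "nonsynonymous", "splice", "insertion", "deletion"}
)


def setup_logging(verbosity: int = 0) -> None:
    """Configure stderr logging. verbosity 0=WARNING, 1=INFO, 2+=DEBUG."""
    level = logging.WARNING - min(verbosity, 2) * 10
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ReadRecord:
    """One aligned read, SAM-convention fields with 0-based ``pos``."""

    read_id: str
    chrom: str
    pos: int
    cigar: str
    mapq: int
    sequence: str
    mate_chrom: str = ""
    mate_pos: int = -1
    is_proper_pair: bool = True
    softclip_total: int = 0

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")

    @property
    def reference_end(self) -> int:
        """0-based exclusive end on the reference, from the CIGAR."""
        return self.pos + cigar_reference_span(self.cigar)

    @classmethod
    def from_aligned_segment(cls, seg: pysam.AlignedSegment) -> "ReadRecord":
        cigar = seg.cigarstring or ""
        soft = sum(ln for op, ln in (seg.cigartuples or []) if op == 4)
        return cls(
            read_id=seg.query_name or "",
            chrom=seg.reference_name or "",
            pos=seg.reference_start,
            cigar=cigar,
            mapq=seg.mapping_quality,
            sequence=seg.query_sequence or "",
            mate_chrom=seg.next_reference_name or "",
            mate_pos=seg.next_reference_start,
            is_proper_pair=seg.is_proper_pair,
            softclip_total=soft,
        )


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _REF_CONSUMING)


def cigar_softclip_total(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op == "S")


@dataclass
class VariantRecord:
    """An annotated somatic variant call (VCF convention, 1-based pos).

    ``quality_score`` is the caller's confidence in [0, 1]; it is an input
    annotation, never computed here.  ``context11`` is the 11-base reference
    window centred on the variant and is only meaningful for substitutions.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    n_obs: int
    consequence: str
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    cancer_db_count: int = 0
    quality_score: float = 1.0
    context11: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf out of [0,1]: {self.maf}")
        if self.n_obs < 0:
            raise ValueError("n_obs must be >= 0")
        if self.consequence not in VALID_CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.context11:
            if len(self.context11) != 11:
                raise ValueError("context11 must have length 11")
            if (
                len(self.ref) == 1
                and len(self.alt) == 1
                and self.context11[5].upper() != self.ref.upper()
            ):
                raise ValueError("context11 centre base must equal ref")

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class CoverageSummary:
    """Mean total and fragment-deduplicated read depth over ROIs."""

    total_coverage: float
    distinct_coverage: float

    def __post_init__(self) -> None:
        if self.distinct_coverage > self.total_coverage + 1e-9:
            raise ValueError("distinct coverage cannot exceed total coverage")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into GenomicIntervals (file order kept)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            label = fields[3] if len(fields) > 3 else ""
            try:
                intervals.append(GenomicInterval(fields[0], start, end, label))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ["CHROM", "POS", "REF", "ALT", "MAF", "N_OBS", "CONSEQUENCE"]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a VCF-convention TSV with flattened annotation columns.

    Mandatory columns: CHROM POS REF ALT MAF N_OBS CONSEQUENCE.  Optional:
    COSMIC_N, QUAL_SCORE, CONTEXT11 and any number of POP_* population
    frequency columns.  Missing optional annotations stay absent; they are
    never coerced to a 0 frequency.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    pop_cols = [c for c in df.columns if c.startswith("POP_")]
    records: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pop = {
            c[len("POP_") :].lower(): float(d[c])
            for c in pop_cols
            if pd.notna(d[c])
        }
        records.append(
            VariantRecord(
                chrom=str(d["CHROM"]),
                pos=int(d["POS"]),
                ref=str(d["REF"]),
                alt=str(d["ALT"]),
                maf=float(d["MAF"]),
                n_obs=int(d["N_OBS"]),
                consequence=str(d["CONSEQUENCE"]),
                pop_freqs=pop,
                cancer_db_count=int(d.get("COSMIC_N", 0) or 0),
                quality_score=(
                    float(d["QUAL_SCORE"]) if pd.notna(d.get("QUAL_SCORE")) else 1.0
                ),
                context11=(
                    str(d["CONTEXT11"]) if pd.notna(d.get("CONTEXT11")) else ""
                ),
            )
        )
    return records


def write_variant_table(
    variants: Sequence[VariantRecord], path: str | Path
) -> None:
    """Write variants in the TSV layout ``read_variant_table`` accepts."""
    pop_names = sorted({k for v in variants for k in v.pop_freqs})
    rows = []
    for v in variants:
        row = {
            "CHROM": v.chrom,
            "POS": v.pos,
            "REF": v.ref,
            "ALT": v.alt,
            "MAF": v.maf,
            "N_OBS": v.n_obs,
            "CONSEQUENCE": v.consequence,
            "COSMIC_N": v.cancer_db_count,
            "QUAL_SCORE": v.quality_score,
            "CONTEXT11": v.context11 or None,
        }
        for name in pop_names:
            row[f"POP_{name.upper()}"] = v.pop_freqs.get(name)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sam_records(path: str | Path) -> list[ReadRecord]:
    """Read a SAM text file into ReadRecords."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        return [ReadRecord.from_aligned_segment(seg) for seg in sam]


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def _fragment_key(read: ReadRecord) -> tuple:
    # coordinate-based fragment identity; no molecular barcodes in inputs
    return (read.chrom, read.pos, read.reference_end)


def compute_coverage_summary(
    reads: Sequence[ReadRecord],
    rois: Sequence[GenomicInterval],
    dedupe_key=None,
) -> CoverageSummary:
    """Mean per-base depth over ROIs, total and after fragment dedup.

    ``dedupe_key`` maps a ReadRecord to a hashable fragment identity; the
    default is (chrom, start, reference end).
    """
    if not rois:
        raise ValueError("ROI set is empty")
    key = dedupe_key or _fragment_key

    def mean_depth(subset: Iterable[ReadRecord]) -> float:
        covered = 0
        subset = list(subset)
        for roi in rois:
            for r in subset:
                if r.chrom != roi.chrom:
                    continue
                lo = max(r.pos, roi.start)
                hi = min(r.reference_end, roi.end)
                if hi > lo:
                    covered += hi - lo
        total_bases = sum(len(roi) for roi in rois)
        return covered / total_bases

    seen: dict[tuple, ReadRecord] = {}
    for r in reads:
        seen.setdefault(key(r), r)
    return CoverageSummary(mean_depth(reads), mean_depth(seen.values()))


# ---------------------------------------------------------------------------
# repeat tract discovery
# ---------------------------------------------------------------------------


def find_repeat_tracts(
    sequence: str,
    min_len: int,
    max_len: int,
    unit: int = 1,
    chrom: str = "seq",
) -> list[GenomicInterval]:
    """Find maximal tandem repeat runs of the given unit size (1, 2 or 3).

    A run is reported when its maximal extent has total length within
    [min_len, max_len] bases.  Runs whose repeat unit collapses to a
    smaller period (e.g. "AAAAAA" scanned at unit 2) are left to the
    smaller unit size.  Coordinates are 0-based half-open on the forward
    strand of ``sequence``.
    """
    if unit not in (1, 2, 3):
        raise ValueError("unit must be 1, 2 or 3")
    if not sequence:
        return []
    seq = sequence.upper()
    n = len(seq)
    out: list[GenomicInterval] = []
    i = 0
    while i + unit <= n:
        j = i + unit
        while j < n and seq[j] == seq[j - unit]:
            j += 1
        run_len = j - i
        if run_len >= 2 * unit:  # at least two copies of the unit
            motif = seq[i : i + unit]
            smaller_period = any(
                all(motif[k] == motif[k % p] for k in range(unit))
                for p in range(1, unit)
                if unit % p == 0
            )
            if not smaller_period and min_len <= run_len <= max_len:
                out.append(
                    GenomicInterval(chrom, i, j, f"{motif}x{run_len // unit}")
                )
            # jump past the whole run to keep runs maximal and non-overlapping
            i = j
        else:
            i += 1
    return out
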