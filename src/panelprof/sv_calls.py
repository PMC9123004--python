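"""Simplified amplification and translocation calling.

Amplifications follow a digital-karyotyping-style rule: per-ROI coverage
normalized to the sample total is compared against a panel of non-cancer
controls, purity-adjusted to a copy-number estimate, and a gene is called
amplified when the fold change from diploid exceeds a gene-specific
threshold in more than 25% of its evaluable ROIs.  Translocations follow a
rearranged-ends-style rule on discordant read pairs: distant or
inter-chromosomal mates are clustered by breakpoint proximity and reported
when the fusion is productive, not in a control database, and supported by
enough distinct fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core_io import ReadRecord

MIN_DISTANT_BP = 2000
DEFAULT_CLUSTER_WINDOW = 500
DEFAULT_MIN_SUPPORT = 5
DEFAULT_FOLD_THRESHOLD = 2.0
AMPLIFIED_ROI_FRACTION = 0.25     # strict: > 25% of evaluated ROIs
HYPOTHETICAL_PURITY = 0.20


@dataclass
class CoverageProfile:
    """Per-ROI sample-normalized coverage with a gene label per ROI."""

    roi_ids: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("normalized coverage must be >= 0")


@dataclass
class NormalBaseline:
    """Per-ROI mean/dispersion over control profiles plus low-coverage mask."""

    roi_ids: list[str]
    genes: list[str]
    mean: np.ndarray
    dispersion: np.ndarray
    low_coverage: np.ndarray

    @classmethod
    def from_controls(
        cls,
        profiles: Sequence[CoverageProfile],
        low_coverage_quantile: float = 0.05,
    ) -> "NormalBaseline":
        if len(profiles) < 2:
            raise ValueError("need at least 2 control profiles")
        mat = np.vstack([p.values for p in profiles])
        mean = mat.mean(axis=0)
        disp = mat.std(axis=0, ddof=1)
        low = mean < np.quantile(mean, low_coverage_quantile)
        return cls(
            roi_ids=list(profiles[0].roi_ids),
            genes=list(profiles[0].genes),
            mean=mean,
            dispersion=disp,
            low_coverage=low,
        )


@dataclass
class AmplificationCall:
    gene: str
    purity_used: float | None
    fold_changes: list[float]
    fraction_above: float
    status: str            # amplified | not_amplified | indeterminate | no_call
    reason: str = ""


@dataclass
class TranslocationCall:
    gene_a: str
    gene_b: str
    breakpoint_a: tuple[str, int]
    breakpoint_b: tuple[str, int]
    n_support: int
    fusion_productive: bool
    status: str            # reported | suppressed
    reason: str = ""


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------


def estimate_purity(
    somatic_mafs: Sequence[float], min_variants: int = 5
) -> float | None:
    """In-silico tumor purity from somatic MAFs.

    Under the diploid-heterozygous assumption a clonal somatic variant sits
    at MAF = purity / 2, so purity = min(1, 2 * median MAF).  Returns None
    (undetermined) with fewer than ``min_variants`` usable variants.
    """
    mafs = [m for m in somatic_mafs if 0 < m <= 1]
    if len(mafs) < min_variants:
        return None
    return min(1.0, 2.0 * float(np.median(mafs)))


# ---------------------------------------------------------------------------
# amplifications
# ---------------------------------------------------------------------------


def fold_change_from_ratio(ratio: float, purity: float) -> float:
    """Purity-adjusted fold change from a coverage ratio.

    Observed coverage mixes tumor and normal: ratio = (p*CN + 2(1-p)) / 2,
    so CN = (2*ratio - 2(1-p)) / p and the fold change from diploid is
    CN / 2.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    cn = (2.0 * ratio - 2.0 * (1.0 - purity)) / purity
    return cn / 2.0


def call_amplification(
    sample: CoverageProfile,
    baseline: NormalBaseline,
    purity: float | None,
    thresholds: Mapping[str, float] | None = None,
    alpha: float = 0.01,
) -> list[AmplificationCall]:
    """Per-gene amplification calls from normalized coverage.

    ROIs are masked when the baseline flags them low-coverage or when the
    sample's deviation from the control mean is insignificant under a
    z-test at ``alpha`` (two-sided) against the control dispersion; masked
    ROIs still count significant only toward evaluation, never the call.
    With undetermined purity, genes whose rule would pass at a
    hypothetical 20% purity are reported indeterminate.
    """
    thresholds = thresholds or {}
    z_crit = sps.norm.ppf(1 - alpha / 2)
    calls: list[AmplificationCall] = []
    genes = sorted(set(sample.genes))
    for gene in genes:
        idx = [i for i, g in enumerate(sample.genes) if g == gene]
        threshold = thresholds.get(gene, DEFAULT_FOLD_THRESHOLD)

        ratios, significant = [], []
        for i in idx:
            if baseline.low_coverage[i] or baseline.mean[i] <= 0:
                continue
            r = sample.values[i] / baseline.mean[i]
            disp = baseline.dispersion[i]
            z = np.inf if disp == 0 else abs(sample.values[i] - baseline.mean[i]) / disp
            ratios.append(r)
            significant.append(z > z_crit)

        if not ratios:
            calls.append(
                AmplificationCall(gene, purity, [], 0.0, "no_call", "all ROIs masked")
            )
            continue

        def rule(p: float) -> tuple[list[float], float, bool]:
            folds = [fold_change_from_ratio(r, p) for r in ratios]
            above = [
                f > threshold and sig for f, sig in zip(folds, significant)
            ]
            frac = sum(above) / len(folds)
            return folds, frac, frac > AMPLIFIED_ROI_FRACTION

        if purity is None:
            folds, frac, passes = rule(HYPOTHETICAL_PURITY)
            status = "indeterminate" if passes else "not_amplified"
            reason = "purity undetermined" if passes else ""
            calls.append(AmplificationCall(gene, None, folds, frac, status, reason))
        else:
            folds, frac, passes = rule(purity)
            status = "amplified" if passes else "not_amplified"
            calls.append(AmplificationCall(gene, purity, folds, frac, status))
    return calls


# ---------------------------------------------------------------------------
# translocations
# ---------------------------------------------------------------------------


@dataclass
class DiscordantCluster:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    read_ids: set[str] = field(default_factory=set)

    @property
    def n_support(self) -> int:
        return len(self.read_ids)


def _is_discordant(read: ReadRecord) -> bool:
    if read.mate_chrom and read.mate_chrom != read.chrom:
        return True
    if read.mate_pos >= 0 and abs(read.mate_pos - read.pos) > MIN_DISTANT_BP:
        return True
    # orientation-only anomalies below 2 kb are flagged by the aligner
    return not read.is_proper_pair


def collect_discordant_pairs(
    reads: Sequence[ReadRecord],
    min_mapq: int = 30,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> list[DiscordantCluster]:
    """Cluster discordant read pairs by breakpoint proximity.

    Pairs with mates on different chromosomes, more than 2 kb apart, or
    flagged improper are retained; low-mapq reads are removed first.
    Clustering is greedy over (sorted) candidate pairs: a pair joins an
    existing cluster when both of its breakpoints are within
    ``cluster_window`` of the cluster's.
    """
    candidates = [
        r for r in reads if r.mapq >= min_mapq and _is_discordant(r)
    ]
    # canonical orientation so (A,B) and (B,A) mates land together
    keyed = []
    for r in candidates:
        a = (r.chrom, r.pos)
        b = (r.mate_chrom or r.chrom, r.mate_pos)
        if b < a:
            a, b = b, a
        keyed.append((a, b, r.read_id))
    keyed.sort()
    clusters: list[DiscordantCluster] = []
    for (ca, pa), (cb, pb), rid in keyed:
        placed = False
        for cl in clusters:
            if (
                cl.chrom_a == ca
                and cl.chrom_b == cb
                and abs(cl.pos_a - pa) <= cluster_window
                and abs(cl.pos_b - pb) <= cluster_window
            ):
                cl.read_ids.add(rid)
                placed = True
                break
        if not placed:
            clusters.append(DiscordantCluster(ca, pa, cb, pb, {rid}))
    return clusters


@dataclass(frozen=True)
class GeneAnnotation:
    """Interval -> gene map with coding strand per gene."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def call_translocation(
    clusters: Sequence[DiscordantCluster],
    gene_annotation: Sequence[GeneAnnotation],
    control_db: Sequence[tuple[str, str]] = (),
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[TranslocationCall]:
    """Report gene fusions from discordant clusters.

    A cluster is reported only when both breakpoints land in annotated
    genes, the join keeps the coding strand (same-strand partners),
    the gene pair is absent from the germline/control event database, and
    support reaches ``min_support`` distinct fragments.
    """
    control = {tuple(sorted(pair)) for pair in control_db}
    calls: list[TranslocationCall] = []
    for cl in clusters:
        ann_a = next(
            (a for a in gene_annotation if a.covers(cl.chrom_a, cl.pos_a)), None
        )
        ann_b = next(
            (a for a in gene_annotation if a.covers(cl.chrom_b, cl.pos_b)), None
        )
        if ann_a is None or ann_b is None:
            continue  # not a fusion of selected genes
        productive = ann_a.strand == ann_b.strand
        pair = tuple(sorted((ann_a.gene, ann_b.gene)))
        status, reason = "reported", ""
        if pair in control:
            status, reason = "suppressed", "control database"
        elif not productive:
            status, reason = "suppressed", "coding strand not maintained"
        elif cl.n_support < min_support:
            status, reason = "suppressed", "insufficient support"
        calls.append(
            TranslocationCall(
                gene_a=ann_a.gene,
                gene_b=ann_b.gene,
                breakpoint_a=(cl.chrom_a, cl.pos_a),
                breakpoint_b=(cl.chrom_b, cl.pos_b),
                n_support=cl.n_support,
                fusion_productive=productive,
                status=status,
                reason=reason,
            )
        )
    return calls
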