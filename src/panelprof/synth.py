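"""Synthetic-data generators with machine-readable ground truth.

Every generator is deterministic under a fixed seed and emits exactly the
containers the analysis modules consume, so end-to-end behaviour can be
checked against planted truth: tract reads with planted contractions and
PCR-stutter noise, substitution catalogs with analytically known context
distributions, weighted pan-cancer tumor cohorts with log-normal TMB, and
coverage profiles with planted gene amplifications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval, ReadRecord
from .msi_signature import BASES, SubstitutionEvent, canonicalize
from .msi_tract import TractDefinition
from .panel_sim import (
    DEFAULT_EXOME_MB,
    ExonCatalog,
    POPULATION_WEIGHTS,
    TumorCatalog,
)
from .sv_calls import CoverageProfile, NormalBaseline

SEED_LEN = 10


# ---------------------------------------------------------------------------
# tract reads
# ---------------------------------------------------------------------------


@dataclass
class TractReadSimConfig:
    """Read simulation for one tract at a given tumor purity.

    A fraction ``purity * unstable_fraction_in_tumor`` of fragments carry
    the planted contraction; ``stutter_rate`` is the per-read probability
    of a +/-1 bp slippage error (``stutter_del_bias`` shifts it toward
    deletions; 0.5 = symmetric).
    """

    tract: TractDefinition
    depth: int = 500
    purity: float = 1.0
    unstable_offset: int = -3
    unstable_fraction_in_tumor: float = 0.6
    stutter_rate: float = 0.05
    stutter_del_bias: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must be in [0, 1]")
        if not 0 <= self.stutter_rate < 0.5:
            raise ValueError("stutter_rate must be in [0, 0.5)")


def random_tract(
    rng: np.random.Generator | int = 0,
    base: str = "A",
    ref_length: int = 15,
    chrom: str = "chr1",
    start: int = 1000,
    label: str = "tract",
) -> TractDefinition:
    """A tract definition with random non-repeat flanking seeds."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    others = [b for b in BASES if b != base]

    def seed() -> str:
        s = "".join(rng.choice(others, size=SEED_LEN))
        return s

    s5, s3 = seed(), seed()
    # seeds must abut the repeat without extending it
    if s5.endswith(base):
        s5 = s5[:-1] + others[0]
    if s3.startswith(base):
        s3 = others[0] + s3[1:]
    return TractDefinition(
        interval=GenomicInterval(chrom, start, start + ref_length, label),
        base=base,
        ref_length=ref_length,
        seed5=s5,
        seed3=s3,
    )


def simulate_tract_reads(
    cfg: TractReadSimConfig,
) -> tuple[list[ReadRecord], dict]:
    """Simulate spanning reads over one tract.

    Reads carry variable random flanks outside the seeds so that fragment
    coordinates (and hence dedup identities) vary.  Returns the reads and
    a truth record with the planted allele and the expected instability of
    the tract under the peak-finding rules.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    tract = cfg.tract
    p_planted = cfg.purity * cfg.unstable_fraction_in_tumor
    others = [b for b in BASES if b != tract.base]
    reads: list[ReadRecord] = []
    for i in range(cfg.depth):
        offset = cfg.unstable_offset if rng.random() < p_planted else 0
        if rng.random() < cfg.stutter_rate:
            offset += -1 if rng.random() < cfg.stutter_del_bias else 1
        tract_len = max(0, tract.ref_length + offset)
        left_extra = int(rng.integers(1, 31))
        right_extra = int(rng.integers(1, 31))
        left = "".join(rng.choice(others, size=left_extra))
        right = "".join(rng.choice(others, size=right_extra))
        seq = left + tract.seed5 + tract.base * tract_len + tract.seed3 + right
        pos = tract.interval.start - len(tract.seed5) - left_extra
        reads.append(
            ReadRecord(
                read_id=f"{tract.tract_id}:r{i}",
                chrom=tract.interval.chrom,
                pos=pos,
                cigar=f"{len(seq)}M",
                mapq=60,
                sequence=seq,
                mate_chrom=tract.interval.chrom,
                mate_pos=pos,
                softclip_total=0,
            )
        )
    truth = {
        "planted_offset": cfg.unstable_offset,
        "planted_fraction": p_planted,
        "expect_unstable": bool(
            cfg.unstable_offset <= -2 and p_planted >= 0.08
        ),
    }
    return reads, truth


# ---------------------------------------------------------------------------
# substitution catalogs
# ---------------------------------------------------------------------------

# per-signature flanking-base distribution (order A, C, G, T) and class mix
SIGNATURE_PROFILES: dict[str, dict] = {
    "flat": {
        "base_probs": (0.25, 0.25, 0.25, 0.25),
        "class_probs": {
            "C>A": 1 / 6, "C>G": 1 / 6, "C>T": 1 / 6,
            "T>A": 1 / 6, "T>C": 1 / 6, "T>G": 1 / 6,
        },
    },
    # MMR deficiency: A-rich flanks (slipped-strand context), C>T / T>C heavy
    "mmr": {
        "base_probs": (0.55, 0.15, 0.15, 0.15),
        "class_probs": {
            "C>A": 0.05, "C>G": 0.05, "C>T": 0.40,
            "T>A": 0.05, "T>C": 0.40, "T>G": 0.05,
        },
    },
    # UV: C>T dominant with pyrimidine-rich 5' flanks
    "uv_like": {
        "base_probs": (0.10, 0.35, 0.10, 0.45),
        "class_probs": {
            "C>A": 0.02, "C>G": 0.05, "C>T": 0.85,
            "T>A": 0.02, "T>C": 0.04, "T>G": 0.02,
        },
    },
    # POLE exonuclease-domain hypermutation: C>A heavy, G/C-rich flanks
    "pole_like": {
        "base_probs": (0.10, 0.40, 0.40, 0.10),
        "class_probs": {
            "C>A": 0.60, "C>G": 0.05, "C>T": 0.20,
            "T>A": 0.05, "T>C": 0.05, "T>G": 0.05,
        },
    },
}


@dataclass
class MutationSimConfig:
    n_mutations: int = 1000
    signature: str = "flat"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.signature not in SIGNATURE_PROFILES:
            raise ValueError(f"unknown signature {self.signature!r}")


def simulate_mutation_catalog(
    cfg: MutationSimConfig,
) -> tuple[list[SubstitutionEvent], dict]:
    """Draw canonicalized substitutions from a signature's distributions.

    Flanking window bases are i.i.d. from the signature's base
    distribution, so the triplet probability at any window position is a
    product of base probabilities (deterministic at positions pinned by
    the centre base) — the trained PWM log-ratios are therefore
    analytically known.  The truth record carries both distributions.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    prof = SIGNATURE_PROFILES[cfg.signature]
    base_probs = np.asarray(prof["base_probs"])
    classes = list(prof["class_probs"])
    class_probs = np.asarray([prof["class_probs"][c] for c in classes])
    events: list[SubstitutionEvent] = []
    cls_draw = rng.choice(len(classes), size=cfg.n_mutations, p=class_probs)
    flanks = rng.choice(list(BASES), size=(cfg.n_mutations, 10), p=base_probs)
    for k in range(cfg.n_mutations):
        ref, alt = classes[cls_draw[k]].split(">")
        w = "".join(flanks[k][:5]) + ref + "".join(flanks[k][5:])
        events.append(canonicalize(ref, alt, w))
    truth = {
        "signature": cfg.signature,
        "base_probs": dict(zip(BASES, base_probs.tolist())),
        "class_probs": dict(prof["class_probs"]),
    }
    return events, truth


def analytic_triplet_probs(
    base_probs: Mapping[str, float], position: int, centre_base: str
) -> dict[str, float]:
    """Exact triplet distribution at a window start offset (0-8).

    Positions 3-5 overlap the pinned centre base (window index 5); all
    other window indices are i.i.d. from ``base_probs``.
    """
    from itertools import product

    probs: dict[str, float] = {}
    for t in product(BASES, repeat=3):
        p = 1.0
        ok = True
        for j, b in enumerate(t):
            widx = position + j
            if widx == 5:
                if b != centre_base:
                    ok = False
                    break
            else:
                p *= base_probs[b]
        probs["".join(t)] = p if ok else 0.0
    return probs


# ---------------------------------------------------------------------------
# tumor cohorts
# ---------------------------------------------------------------------------


def make_exon_catalog(
    total_mb: float = 30.0,
    exon_bp: int = 300,
    chrom: str = "genome",
) -> ExonCatalog:
    """A regular synthetic exon catalog laid out on one coordinate frame."""
    n = int(round(total_mb * 1e6 / exon_bp))
    gap = 50  # intronic spacer; positions are catalog-frame, not hg19
    exons = [
        GenomicInterval(chrom, i * (exon_bp + gap), i * (exon_bp + gap) + exon_bp,
                        f"exon{i}")
        for i in range(n)
    ]
    return ExonCatalog(exons)


@dataclass
class CohortSimConfig:
    """Weighted pan-cancer cohort with per-type log-normal TMB.

    Defaults emulate a metastatic solid-tumor mix: TMB median 4 muts/Mb
    with 0.6 log10 dex of spread, doubled medians for the
    smoking/UV-driven types (lung, melanoma), and a heavy right tail of
    hypermutators.
    """

    n_tumors: int = 4000
    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(POPULATION_WEIGHTS)
    )
    tmb_median: float = 4.0
    tmb_log10_sd: float = 0.6
    boosted_types: tuple = ("lung", "melanoma")
    boost_factor: float = 2.0
    exome_mb: float = DEFAULT_EXOME_MB
    rng_seed: int = 0


def simulate_tumor_cohort(
    cfg: CohortSimConfig, catalog: ExonCatalog
) -> list[TumorCatalog]:
    """Draw tumors with weighted types, log-normal TMB and uniform positions.

    Mutation counts are Poisson around the drawn target TMB x exome size;
    positions are uniform over the exon catalog; MAFs uniform on
    [0.1, 0.9]; all mutations are nonsynonymous (the class the panel
    counts).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    types = list(cfg.weights)
    probs = np.asarray([cfg.weights[t] for t in types], dtype=float)
    probs /= probs.sum()
    type_draw = rng.choice(len(types), size=cfg.n_tumors, p=probs)

    n_exons = len(catalog.exons)
    tumors: list[TumorCatalog] = []
    for i in range(cfg.n_tumors):
        ct = types[type_draw[i]]
        median = cfg.tmb_median * (
            cfg.boost_factor if ct in cfg.boosted_types else 1.0
        )
        target_tmb = 10 ** rng.normal(math.log10(median), cfg.tmb_log10_sd)
        n_mut = int(rng.poisson(target_tmb * cfg.exome_mb))
        exon_idx = rng.integers(0, n_exons, size=n_mut)
        offsets = (
            rng.integers(0, catalog.lengths[exon_idx])
            if n_mut
            else np.array([], dtype=np.int64)
        )
        positions = catalog.starts[exon_idx] + offsets
        tumors.append(
            TumorCatalog(
                tumor_id=f"T{i:05d}",
                cancer_type=ct,
                positions=np.asarray(positions, dtype=np.int64),
                mafs=rng.uniform(0.1, 0.9, size=n_mut),
                nonsynonymous=np.ones(n_mut, dtype=bool),
                exome_mb=cfg.exome_mb,
            )
        )
    return tumors


# ---------------------------------------------------------------------------
# coverage profiles
# ---------------------------------------------------------------------------


def simulate_coverage_profiles(
    genes: Sequence[str],
    planted_amplifications: Mapping[str, float],
    purity: float = 0.6,
    noise_cv: float = 0.05,
    n_controls: int = 20,
    rois_per_gene: int = 8,
    rng_seed: int = 0,
) -> tuple[CoverageProfile, NormalBaseline, dict]:
    """Sample + control coverage profiles with planted amplifications.

    Control ROI values are log-normal around 1; amplified-gene ROIs in the
    sample are scaled by the purity-mixed ratio (p*CN + 2(1-p)) / 2.
    """
    rng = np.random.default_rng(rng_seed)
    roi_ids, gene_labels = [], []
    for g in genes:
        for k in range(rois_per_gene):
            roi_ids.append(f"{g}_roi{k}")
            gene_labels.append(g)
    n_rois = len(roi_ids)
    sigma = math.sqrt(math.log(1 + noise_cv**2))

    control_values = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma,
                                   size=(n_controls, n_rois))
    controls = [
        CoverageProfile(roi_ids, gene_labels, control_values[i])
        for i in range(n_controls)
    ]
    baseline = NormalBaseline.from_controls(controls, low_coverage_quantile=0.0)

    scale = np.ones(n_rois)
    for g, cn in planted_amplifications.items():
        ratio = (purity * cn + 2 * (1 - purity)) / 2.0
        scale[[i for i, gl in enumerate(gene_labels) if gl == g]] = ratio
    sample_values = scale * rng.lognormal(
        mean=-sigma**2 / 2, sigma=sigma, size=n_rois
    )
    sample = CoverageProfile(roi_ids, gene_labels, sample_values)
    truth = {
        "planted": dict(planted_amplifications),
        "purity": purity,
        "expected_fold_changes": {
            g: cn / 2.0 for g, cn in planted_amplifications.items()
        },
    }
    return sample, baseline, truth
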