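"""Tumor mutational burden: variant eligibility, panel TMB, exome-equivalent
TMB, reporting thresholds and the limit of blank.

Panel TMB (pTMB) is the count of eligible coding variants divided by the
1.3 Mb of coding sequence evaluated.  The exome-equivalent TMB follows the
shipped log-log regression

    eTMB = 10 ** (-0.944 + 1.397 * log10(pTMB)),

with eTMB defined as 0 for a mutation-free panel.  The limit of blank uses
the CLSI EP17-A non-parametric 95th-percentile rank formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core_io import VariantRecord

CODING_CONSEQUENCES = frozenset(
    {"synonymous", "nonsynonymous", "splice", "insertion", "deletion"}
)


@dataclass
class TmbFilterConfig:
    """Eligibility thresholds for TMB candidate variants.

    Defaults are the shipped assay settings: coding variants above 5% MAF
    with more than 3 supporting observations, with COSMIC-frequent,
    population-frequent and VAF-inferred private germline variants removed.
    """

    min_maf: float = 0.05                 # strict: maf must exceed this
    min_obs: int = 3                      # strict: n_obs must exceed this
    min_quality: float = 0.5
    cosmic_max: int = 25                  # >=25 COSMIC observations -> hotspot, removed
    pop_freq_max: float = 0.01            # common germline cutoff per database
    private_germline_maf_band: tuple = ((0.40, 0.60), (0.90, 1.00))
    consequences: frozenset = CODING_CONSEQUENCES

    def __post_init__(self) -> None:
        if not 0 < self.min_maf < 1:
            raise ValueError("min_maf must be in (0, 1)")


@dataclass(frozen=True)
class EtmbModel:
    """Log-log regression from panel TMB to exome-equivalent TMB."""

    intercept: float = -0.944
    slope: float = 1.397
    coding_panel_mb: float = 1.3

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")


@dataclass(frozen=True)
class TmbResult:
    n_eligible: int
    ptmb: float
    etmb: float
    filter_tally: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LobResult:
    n: int
    percentile_rank: float
    lob: float


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _in_germline_band(maf: float, bands) -> bool:
    return any(lo <= maf <= hi for lo, hi in bands)


def filter_tmb_variants(
    variants: Sequence[VariantRecord],
    cfg: TmbFilterConfig | None = None,
    tally: dict | None = None,
) -> list[VariantRecord]:
    """Keep TMB-eligible variants, preserving input order.

    A variant survives when it is coding (synonymous and nonsynonymous
    classes both count), its caller quality passes, it has more than
    ``min_obs`` observations and a MAF above ``min_maf``, it is not a
    frequent cancer-database entry, not common in any population database,
    and its MAF does not fall in the private-germline VAF band.  Pass a
    dict as ``tally`` to receive per-rule removal counts.
    """
    cfg = cfg or TmbFilterConfig()
    kept: list[VariantRecord] = []
    counts = {
        "consequence": 0, "quality": 0, "n_obs": 0, "maf": 0,
        "cosmic": 0, "population": 0, "private_germline": 0,
    }
    for v in variants:
        if v.consequence not in cfg.consequences:
            counts["consequence"] += 1
        elif v.quality_score < cfg.min_quality:
            counts["quality"] += 1
        elif v.n_obs <= cfg.min_obs:
            counts["n_obs"] += 1
        elif v.maf <= cfg.min_maf:
            counts["maf"] += 1
        elif v.cancer_db_count >= cfg.cosmic_max:
            counts["cosmic"] += 1
        elif any(f >= cfg.pop_freq_max for f in v.pop_freqs.values()):
            counts["population"] += 1
        elif _in_germline_band(v.maf, cfg.private_germline_maf_band):
            counts["private_germline"] += 1
        else:
            kept.append(v)
    if tally is not None:
        tally.update(counts)
    return kept


def compute_ptmb(n_eligible: int, coding_panel_mb: float = 1.3) -> float:
    """Panel TMB in mutations/Mb over the evaluated coding territory."""
    if coding_panel_mb <= 0:
        raise ValueError("coding_panel_mb must be > 0")
    if n_eligible < 0:
        raise ValueError("n_eligible must be >= 0")
    return n_eligible / coding_panel_mb


def ptmb_to_etmb(ptmb: float, model: EtmbModel | None = None) -> float:
    """Exome-equivalent TMB via the log-log regression; 0 maps to 0."""
    model = model or EtmbModel()
    if ptmb < 0:
        raise ValueError("ptmb must be >= 0")
    if ptmb == 0:
        return 0.0
    return float(10 ** (model.intercept + model.slope * np.log10(ptmb)))


def compute_tmb(
    variants: Sequence[VariantRecord],
    cfg: TmbFilterConfig | None = None,
    model: EtmbModel | None = None,
) -> TmbResult:
    """Filter variants and report panel and exome-equivalent TMB."""
    model = model or EtmbModel()
    tally: dict = {}
    eligible = filter_tmb_variants(variants, cfg, tally=tally)
    ptmb = compute_ptmb(len(eligible), model.coding_panel_mb)
    return TmbResult(
        n_eligible=len(eligible),
        ptmb=ptmb,
        etmb=ptmb_to_etmb(ptmb, model),
        filter_tally=tally,
    )


def fit_etmb_model(
    pairs: Sequence[tuple[float, float]],
    coding_panel_mb: float = 1.3,
) -> EtmbModel:
    """OLS of log10(exome TMB) on log10(panel TMB).

    Pairs with a non-positive value on either side are excluded with a
    warning; at least three usable pairs are required.
    """
    usable = [(p, w) for p, w in pairs if p > 0 and w > 0]
    if len(usable) < len(pairs):
        warnings.warn(
            f"excluded {len(pairs) - len(usable)} pairs with non-positive values"
        )
    if len(usable) < 3:
        raise ValueError("need at least 3 pairs with positive values")
    x = np.log10([p for p, _ in usable])
    y = np.log10([w for _, w in usable])
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return EtmbModel(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        coding_panel_mb=coding_panel_mb,
    )


# ---------------------------------------------------------------------------
# variant reporting thresholds
# ---------------------------------------------------------------------------

HIGH_EVIDENCE_TIER = "high"
REPORTING_THRESHOLDS = {
    # tier -> (min observations, MAF must exceed this fraction)
    HIGH_EVIDENCE_TIER: (4, 0.004),
    "other": (6, 0.050),
}
BRCA_GENES = frozenset({"BRCA1", "BRCA2"})


def apply_reporting_filters(
    variants: Sequence[dict],
) -> list[dict]:
    """Tiered reporting filter for clinically actionable variants.

    Each variant dict needs keys ``tier`` ("high" or "other"), ``n_obs``,
    ``maf``, and optionally ``gene``, ``deleterious`` and ``germline``.
    High-evidence variants report at >=4 observations and MAF above 0.4%;
    all others need >=6 observations and MAF above 5.0%.  Deleterious
    BRCA1/BRCA2 variants bypass germline exclusion but still must meet the
    observation and MAF thresholds.
    """
    reported = []
    for v in variants:
        tier = v.get("tier", "other")
        if tier not in REPORTING_THRESHOLDS:
            raise ValueError(f"unknown actionability tier {tier!r}")
        min_obs, min_maf = REPORTING_THRESHOLDS[tier]
        if v["n_obs"] < min_obs or v["maf"] <= min_maf:
            continue
        if v.get("germline", False):
            brca_rescue = v.get("gene") in BRCA_GENES and v.get("deleterious", False)
            if not brca_rescue:
                continue
        reported.append(v)
    return reported


# ---------------------------------------------------------------------------
# limit of blank
# ---------------------------------------------------------------------------


def compute_lob(values: Sequence[float], percentile: float = 95.0) -> LobResult:
    """CLSI EP17-A non-parametric percentile of blank-sample measurements.

    Rank = 0.5 + (percentile/100) * n on the ascending order statistics,
    with linear interpolation between bracketing values and clamping to
    the observed extremes.
    """
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 blank measurements")
    ordered = np.sort(np.asarray(values, dtype=float))
    rank = 0.5 + (percentile / 100.0) * n
    if rank <= 1:
        lob = float(ordered[0])
    elif rank >= n:
        lob = float(ordered[-1])
    else:
        lo = int(np.floor(rank))
        frac = rank - lo
        lob = float(ordered[lo - 1] + frac * (ordered[lo] - ordered[lo - 1]))
    return LobResult(n=n, percentile_rank=rank, lob=lob)
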