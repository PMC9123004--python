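"""In silico evaluation of TMB accuracy versus targeted-panel size.

Random panels are assembled from an exon catalog, mutations of a tumor
cohort are counted inside each panel, and the panel mutation rate is
correlated against the reference exome TMB (alterations / exome Mb).
Cohort-level results can be reweighted to the metastatic solid-tumor
population using the shipped incidence weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import GenomicInterval

# Relative yearly incidence of distant-stage disease for the weighted types.
POPULATION_WEIGHTS: dict[str, float] = {
    "lung": 0.643,
    "colorectal": 0.150,
    "melanoma": 0.018,
    "bladder": 0.016,
    "head_neck": 0.059,
    "liver": 0.037,
    "gastric": 0.026,
    "uterine": 0.051,
}
assert abs(sum(POPULATION_WEIGHTS.values()) - 1.0) < 1e-9

DEFAULT_EXOME_MB = 33.4


@dataclass
class ExonCatalog:
    """Sorted, non-overlapping exon intervals on a single coordinate frame."""

    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.starts = np.array([e.start for e in self.exons])
        self.ends = np.array([e.end for e in self.exons])
        self.lengths = self.ends - self.starts

    @property
    def total_mb(self) -> float:
        return float(self.lengths.sum()) / 1e6


@dataclass
class TumorCatalog:
    """One tumor's exonic mutation set with its exome-wide reference TMB."""

    tumor_id: str
    cancer_type: str
    positions: np.ndarray            # 0-based positions inside the exon catalog
    mafs: np.ndarray
    nonsynonymous: np.ndarray        # boolean per mutation
    exome_mb: float = DEFAULT_EXOME_MB

    @property
    def exome_tmb(self) -> float:
        qualified = (self.mafs >= 0.10) & self.nonsynonymous
        return float(qualified.sum()) / self.exome_mb


@dataclass
class PanelSimResult:
    panel_size_mb: float
    replicate_index: int
    pearson: float
    spearman: float
    per_type_metrics: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# panel assembly and counting
# ---------------------------------------------------------------------------


def build_random_panel(
    catalog: ExonCatalog, target_mb: float, rng: np.random.Generator | int
) -> list[GenomicInterval]:
    """Sample exons without replacement until the panel first reaches target.

    The final exon may overshoot the target; downstream rates use the
    realized size, so the overshoot does not bias the mutation rate.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if target_mb > catalog.total_mb:
        raise ValueError(
            f"target {target_mb} Mb exceeds catalog total {catalog.total_mb:.2f} Mb"
        )
    order = rng.permutation(len(catalog.exons))
    cum = np.cumsum(catalog.lengths[order])
    n_take = int(np.searchsorted(cum, target_mb * 1e6, side="left")) + 1
    n_take = min(n_take, len(order))
    chosen = np.sort(order[:n_take])
    return [catalog.exons[i] for i in chosen]


def panel_size_mb(panel: Sequence[GenomicInterval]) -> float:
    return sum(len(iv) for iv in panel) / 1e6


def _panel_arrays(panel: Sequence[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    starts = np.array([iv.start for iv in panel])
    ends = np.array([iv.end for iv in panel])
    order = np.argsort(starts)
    return starts[order], ends[order]


def _count_in_arrays(
    tumor: TumorCatalog,
    starts: np.ndarray,
    ends: np.ndarray,
    min_maf: float,
    nonsynonymous_only: bool,
) -> int:
    keep = tumor.mafs >= min_maf
    if nonsynonymous_only:
        keep &= tumor.nonsynonymous
    pos = tumor.positions[keep]
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    return int(inside.sum())


def count_panel_mutations(
    tumor: TumorCatalog,
    panel: Sequence[GenomicInterval],
    min_maf: float = 0.10,
    nonsynonymous_only: bool = True,
) -> int:
    """Count qualifying mutations whose position falls inside the panel."""
    if not panel:
        return 0
    starts, ends = _panel_arrays(panel)
    return _count_in_arrays(tumor, starts, ends, min_maf, nonsynonymous_only)


# ---------------------------------------------------------------------------
# size sweep
# ---------------------------------------------------------------------------


def _safe_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    return (
        float(stats.pearsonr(x, y).statistic),
        float(stats.spearmanr(x, y).statistic),
    )


def evaluate_panel(
    cohort: Sequence[TumorCatalog],
    panel: Sequence[GenomicInterval],
    min_maf: float = 0.10,
) -> tuple[float, float, dict[str, float]]:
    """Pearson/Spearman of panel mutation rate vs exome TMB for one panel."""
    size = panel_size_mb(panel)
    starts, ends = _panel_arrays(panel)
    panel_tmb = np.array(
        [
            _count_in_arrays(t, starts, ends, min_maf, True) / size
            for t in cohort
        ]
    )
    exome_tmb = np.array([t.exome_tmb for t in cohort])
    pearson, spearman = _safe_corr(panel_tmb, exome_tmb)
    per_type: dict[str, float] = {}
    types = {t.cancer_type for t in cohort}
    for ct in sorted(types):
        mask = np.array([t.cancer_type == ct for t in cohort])
        if mask.sum() >= 3:
            per_type[ct], _ = _safe_corr(panel_tmb[mask], exome_tmb[mask])
    return pearson, spearman, per_type


def evaluate_panel_sizes(
    cohort: Sequence[TumorCatalog],
    catalog: ExonCatalog,
    sizes_mb: Sequence[float] | None = None,
    models_per_size: int = 100,
    rng_seed: int = 0,
    min_maf: float = 0.10,
) -> list[PanelSimResult]:
    """Sweep panel sizes, evaluating ``models_per_size`` random panels each.

    Returns one PanelSimResult per (size, replicate).  Sizes default to
    0.1-2.5 Mb in 0.1 Mb steps.  Constant-TMB cohorts yield NaN
    correlations, flagging the undefined case rather than silently
    reporting 0.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if sizes_mb is None:
        sizes_mb = [round(0.1 * k, 1) for k in range(1, 26)]
    rng = np.random.default_rng(rng_seed)
    results: list[PanelSimResult] = []
    for size in sizes_mb:
        for rep in range(1, models_per_size + 1):
            panel = build_random_panel(catalog, size, rng)
            pearson, spearman, per_type = evaluate_panel(cohort, panel, min_maf)
            results.append(
                PanelSimResult(
                    panel_size_mb=size,
                    replicate_index=rep,
                    pearson=pearson,
                    spearman=spearman,
                    per_type_metrics=per_type,
                )
            )
    return results


def summarize_by_size(
    results: Sequence[PanelSimResult],
) -> list[dict]:
    """Median and 5th-95th percentile band of correlations per panel size."""
    out = []
    for size in sorted({r.panel_size_mb for r in results}):
        rs = [r.pearson for r in results if r.panel_size_mb == size]
        ss = [r.spearman for r in results if r.panel_size_mb == size]
        out.append(
            {
                "panel_size_mb": size,
                "pearson_median": float(np.nanmedian(rs)),
                "pearson_p5": float(np.nanpercentile(rs, 5)),
                "pearson_p95": float(np.nanpercentile(rs, 95)),
                "spearman_median": float(np.nanmedian(ss)),
                "spearman_p5": float(np.nanpercentile(ss, 5)),
                "spearman_p95": float(np.nanpercentile(ss, 95)),
            }
        )
    return out


# ---------------------------------------------------------------------------
# population reweighting
# ---------------------------------------------------------------------------


def reweight_population(
    per_type_metrics: Mapping[str, float] | None = None,
    weights: Mapping[str, float] | None = None,
    mode: str = "mean",
    cohort: Sequence[TumorCatalog] | None = None,
    panel: Sequence[GenomicInterval] | None = None,
    rng_seed: int = 0,
    n_resample: int | None = None,
) -> float:
    """Reweight panel-vs-exome performance to the metastatic population.

    ``mode="mean"`` takes the weighted mean of per-type Pearson
    correlations; ``mode="resample"`` draws a cohort resampled to the
    stated type proportions and returns its pooled correlation (requires
    ``cohort`` and ``panel``).
    """
    weights = dict(weights or POPULATION_WEIGHTS)
    if mode == "mean":
        if per_type_metrics is None:
            raise ValueError("mean mode requires per_type_metrics")
        missing = [t for t in weights if t not in per_type_metrics]
        if missing:
            raise ValueError(f"missing per-type metrics for: {missing}")
        total = sum(weights.values())
        return float(
            sum(w * per_type_metrics[t] for t, w in weights.items()) / total
        )
    if mode == "resample":
        if cohort is None or panel is None:
            raise ValueError("resample mode requires cohort and panel")
        by_type: dict[str, list[TumorCatalog]] = {}
        for t in cohort:
            by_type.setdefault(t.cancer_type, []).append(t)
        missing = [t for t in weights if t not in by_type]
        if missing:
            raise ValueError(f"missing cohort types: {missing}")
        rng = np.random.default_rng(rng_seed)
        n = n_resample or len(cohort)
        types = list(weights)
        probs = np.array([weights[t] for t in types])
        probs = probs / probs.sum()
        drawn: list[TumorCatalog] = []
        for ct, k in zip(types, rng.multinomial(n, probs)):
            pool = by_type[ct]
            drawn.extend(pool[i] for i in rng.integers(0, len(pool), size=k))
        pearson, _, _ = evaluate_panel(drawn, panel)
        return pearson
    raise ValueError(f"unknown mode {mode!r}")
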