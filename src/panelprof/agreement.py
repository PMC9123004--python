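"""Validation statistics: percent agreement, Wilson intervals, replicate
precision, dilution purity and clonality.

These are the assay-validation statistics: positive/negative percent
agreement against an orthogonal method with continuity-corrected Wilson
score intervals, average pairwise agreement across replicate runs,
variance-component coefficients of variation for nested precision designs,
and the dilution-series purity and clonality summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

POSITIVE_LABELS = {"MSI-H", "positive", "pos", "1", 1, True}


@dataclass(frozen=True)
class AgreementTable:
    """2x2 concordance counts against an orthogonal reference."""

    tp: int
    fn: int
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


def ppa_npa(table: AgreementTable) -> tuple[float | None, float | None]:
    """Positive and negative percent agreement, in percent.

    An undefined metric (no reference positives / negatives) is returned
    as None, never as 0.
    """
    ppa = 100.0 * table.tp / (table.tp + table.fn) if table.tp + table.fn else None
    npa = 100.0 * table.tn / (table.tn + table.fp) if table.tn + table.fp else None
    return ppa, npa


def wilson_ci(
    k: int, n: int, conf: float = 0.95, continuity: bool = True
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, on [0, 1].

    With ``continuity=True`` applies the standard continuity correction;
    bounds are clamped to [0, 1] and degenerate k=0 / k=n cases pin the
    corresponding bound to the extreme.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    p = k / n
    if not continuity:
        denom = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = centre - half, centre + half
    else:
        denom = 2 * (n + z * z)
        lo_arg = max(0.0, z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
        hi_arg = max(0.0, z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
        lo = (2 * n * p + z * z - 1 - z * math.sqrt(lo_arg)) / denom
        hi = (2 * n * p + z * z + 1 + z * math.sqrt(hi_arg)) / denom
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return max(0.0, lo), min(1.0, hi)


# ---------------------------------------------------------------------------
# average pairwise agreement
# ---------------------------------------------------------------------------


def average_agreement(
    calls: pd.DataFrame,
    sample_col: str = "sample",
    call_col: str = "call",
    positive: str = "MSI-H",
) -> tuple[float | None, float | None]:
    """Average positive/negative agreement over all replicate pairs.

    For every sample, every unordered pair of replicate calls is compared;
    both directions of each pair are averaged, which pools to the
    symmetric forms APA = 2a/(2a+d) and ANA = 2c/(2c+d) where a pairs are
    both-positive, c both-negative and d discordant.  Returned in percent;
    a metric with no qualifying pairs is None.
    """
    n_pp = n_nn = n_disc = 0
    for _, grp in calls.groupby(sample_col):
        vals = [c == positive for c in grp[call_col]]
        if len(vals) < 2:
            raise ValueError("need >=2 replicates per sample")
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                if vals[i] and vals[j]:
                    n_pp += 1
                elif not vals[i] and not vals[j]:
                    n_nn += 1
                else:
                    n_disc += 1
    apa = (
        100.0 * 2 * n_pp / (2 * n_pp + n_disc) if (n_pp or n_disc) else None
    )
    ana = (
        100.0 * 2 * n_nn / (2 * n_nn + n_disc) if (n_nn or n_disc) else None
    )
    return apa, ana


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------


def variance_component_cv(
    values: pd.DataFrame,
    factors: Sequence[str] = ("site", "operator", "day"),
    value_col: str = "value",
) -> dict[str, float]:
    """Method-of-moments variance-component CVs for a nested design.

    ``factors`` are ordered outermost to innermost (e.g. site > operator >
    day); replicates within the innermost level estimate the within-run
    component.  Expected mean squares for the balanced nested layout are
    solved top-down; negative moment estimates are truncated to 0.  Each
    CV is 100 * sigma_component / grand mean; ``overall`` uses the total
    of the truncated components.  A factor with a single level is marked
    inestimable (NaN).
    """
    df = values.copy()
    if df[value_col].isna().any():
        raise ValueError("missing values in replicate table")
    grand_mean = df[value_col].mean()
    if grand_mean == 0:
        raise ValueError("grand mean is 0; CV undefined")

    levels = list(factors)
    # nested group keys, outermost-first
    keys = [levels[: i + 1] for i in range(len(levels))]

    n_total = len(df)
    ss = []
    dfree = []
    prev_groups = 1
    prev_means = pd.Series([grand_mean] * n_total, index=df.index)
    for key in keys:
        gm = df.groupby(key)[value_col].transform("mean")
        ss.append(((gm - prev_means) ** 2).sum())
        n_groups = df.groupby(key).ngroups
        dfree.append(n_groups - prev_groups)
        prev_groups = n_groups
        prev_means = gm
    ss_within = ((df[value_col] - prev_means) ** 2).sum()
    df_within = n_total - prev_groups

    ms = [s / d if d > 0 else np.nan for s, d in zip(ss, dfree)]
    ms_within = ss_within / df_within if df_within > 0 else np.nan

    # average replication below each stratum (balanced-design coefficients)
    coefs = []
    for key in keys:
        coefs.append(n_total / df.groupby(key).ngroups)

    def inner_contribution(idx: int) -> float:
        """Expected inner-component contribution to stratum idx's MS."""
        acc = sigma2.get("within_run", 0.0)
        for j in range(idx + 1, len(levels)):
            v = sigma2.get(levels[j], 0.0)
            if np.isfinite(v):
                acc += coefs[j] * v
        return acc

    # solve expected mean squares from the innermost level outwards
    sigma2: dict[str, float] = {}
    sigma2["within_run"] = max(ms_within, 0.0) if np.isfinite(ms_within) else np.nan
    for idx in range(len(levels) - 1, -1, -1):
        m = ms[idx]
        if not np.isfinite(m):
            sigma2[levels[idx]] = np.nan
            continue
        sigma2[levels[idx]] = max((m - inner_contribution(idx)) / coefs[idx], 0.0)
    total = sum(v for v in sigma2.values() if np.isfinite(v))
    out = {
        f"cv_{k}": (
            100.0 * math.sqrt(v) / abs(grand_mean) if np.isfinite(v) else float("nan")
        )
        for k, v in sigma2.items()
    }
    out["cv_overall"] = 100.0 * math.sqrt(total) / abs(grand_mean)
    return out


# ---------------------------------------------------------------------------
# dilution purity and clonality
# ---------------------------------------------------------------------------


def observed_dilution_purity(
    diluted_mafs: Sequence[float],
    undiluted_mafs: Sequence[float],
    pathological_purity: float = 1.0,
) -> float:
    """Observed purity of a dilution replicate from matched variant MAFs.

    Median ratio of diluted to undiluted MAF, scaled by the pathological
    purity of the undiluted specimen.  Variants with an undiluted MAF of 0
    are excluded.
    """
    if len(diluted_mafs) != len(undiluted_mafs):
        raise ValueError("MAF lists must be matched")
    ratios = [d / u for d, u in zip(diluted_mafs, undiluted_mafs) if u > 0]
    if not ratios:
        raise ValueError("no shared variants with non-zero undiluted MAF")
    return float(np.median(ratios)) * pathological_purity


def clonality_score(mafs: Sequence[float], pathological_purity: float) -> float:
    """Median somatic MAF divided by the pathologic tumor purity."""
    if pathological_purity <= 0:
        raise ValueError("purity must be > 0")
    if not len(mafs):
        raise ValueError("no variant MAFs supplied")
    return float(np.median(mafs)) / pathological_purity
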