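"""Mutation-context signature scoring and the ensemble MSI classifier.

Mismatch-repair deficiency leaves a characteristic substitution-context
signature.  It is captured here with a position-weight-matrix model: for
each of the six pyrimidine-centred substitution classes, triplet
probabilities are estimated at the nine overlapping triplet positions of
an 11-base window (5 bases either side of the mutated site) in an
MMR-deficient and an MMR-proficient catalog, and their elementwise
log-ratio scores new substitutions.  Positive scores favour MMR
deficiency.  A sample's signature score is the plain sum over its
substitutions, and the final MSI call combines that sum with the unstable
tract fraction through a maximum-margin linear boundary in the 2-D plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .msi_tract import MsiTractResult

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")
CANONICAL_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
WINDOW = 11
N_TRIPLET_POSITIONS = WINDOW - 2  # 9 overlapping triplets, start offsets 0..8
TRIPLETS = ["".join(t) for t in product(BASES, repeat=3)]
TRIPLET_INDEX = {t: i for i, t in enumerate(TRIPLETS)}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SubstitutionEvent:
    """A canonicalized substitution with its 11-base context window."""

    ref: str
    alt: str
    window11: str

    def __post_init__(self) -> None:
        if len(self.window11) != WINDOW:
            raise ValueError("window must be 11 bases")
        if self.window11[5] != self.ref:
            raise ValueError("window centre must equal ref")

    @property
    def canonical_class(self) -> str:
        return f"{self.ref}>{self.alt}"


def canonicalize(ref: str, alt: str, window11: str) -> SubstitutionEvent:
    """Fold a substitution onto the pyrimidine-centred strand.

    Purine-reference events are reverse-complemented (ref, alt and window)
    so every event falls into one of C>A, C>G, C>T, T>A, T>C, T>G.
    Idempotent by construction.
    """
    ref, alt, window11 = ref.upper(), alt.upper(), window11.upper()
    if ref == alt:
        raise ValueError("ref and alt must differ")
    for b in (ref, alt):
        if b not in BASES:
            raise ValueError(f"non-ACGT base {b!r}")
    if any(b not in BASES for b in window11):
        raise ValueError("window contains non-ACGT base")
    if len(window11) != WINDOW or window11[5] != ref:
        raise ValueError("window must be 11 bases centred on ref")
    if ref in "AG":  # purine: flip to the pyrimidine strand
        ref, alt = ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
        window11 = reverse_complement(window11)
    return SubstitutionEvent(ref, alt, window11)


# ---------------------------------------------------------------------------
# PWM model
# ---------------------------------------------------------------------------


@dataclass
class PwmModel:
    """Six per-class grids of triplet log-likelihood ratios.

    ``matrices[cls]`` is a (9, 64) array: rows are triplet start offsets
    0-8 within the 11-base window, columns the 64 triplets; each entry is
    log(P_dMMR / P_pMMR) under additive smoothing.
    """

    matrices: dict[str, np.ndarray]
    pseudocount: float = 0.5
    log_base: float = np.e
    training_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in CANONICAL_CLASSES:
            m = self.matrices.get(cls)
            if m is None or m.shape != (N_TRIPLET_POSITIONS, 64):
                raise ValueError(f"matrix for {cls} must have shape (9, 64)")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"matrix for {cls} has non-finite entries")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pseudocount": self.pseudocount,
            "log_base": self.log_base,
            "training_counts": {k: list(v) for k, v in self.training_counts.items()},
            "triplets": TRIPLETS,
            "matrices": {c: m.tolist() for c, m in self.matrices.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PwmModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            matrices={c: np.asarray(m) for c, m in payload["matrices"].items()},
            pseudocount=payload["pseudocount"],
            log_base=payload["log_base"],
            training_counts={
                k: tuple(v) for k, v in payload.get("training_counts", {}).items()
            },
        )


def _triplet_count_grid(events: Iterable[SubstitutionEvent]) -> dict[str, np.ndarray]:
    grids = {c: np.zeros((N_TRIPLET_POSITIONS, 64)) for c in CANONICAL_CLASSES}
    for ev in events:
        grid = grids[ev.canonical_class]
        w = ev.window11
        for p in range(N_TRIPLET_POSITIONS):
            grid[p, TRIPLET_INDEX[w[p : p + 3]]] += 1
    return grids


def train_pwm(
    dmmr_catalog: Iterable[SubstitutionEvent],
    pmmr_catalog: Iterable[SubstitutionEvent],
    pseudocount: float = 0.5,
) -> PwmModel:
    """Train the six per-class PWMs from two mutation catalogs.

    Both catalogs must already be canonicalized; the MMR-proficient catalog
    should exclude POLE/POLD1-mutant hypermutators so the matrices measure
    the MMR signature rather than raw mutation load.  Triplet probabilities
    are class-conditional with additive smoothing of ``pseudocount`` per
    triplet per position; entries are natural-log ratios.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    d_counts = _triplet_count_grid(dmmr_catalog)
    p_counts = _triplet_count_grid(pmmr_catalog)
    matrices: dict[str, np.ndarray] = {}
    training_counts: dict[str, tuple[int, int]] = {}
    for cls in CANONICAL_CLASSES:
        d = d_counts[cls] + pseudocount
        p = p_counts[cls] + pseudocount
        d_prob = d / d.sum(axis=1, keepdims=True)
        p_prob = p / p.sum(axis=1, keepdims=True)
        matrices[cls] = np.log(d_prob / p_prob)
        training_counts[cls] = (
            int(d_counts[cls].sum(axis=1)[0]),
            int(p_counts[cls].sum(axis=1)[0]),
        )
    return PwmModel(matrices, pseudocount=pseudocount, training_counts=training_counts)


def score_substitution(model: PwmModel, event: SubstitutionEvent) -> float:
    """Sum the class matrix over the 9 overlapping triplets of the window."""
    grid = model.matrices[event.canonical_class]
    w = event.window11
    return float(
        sum(grid[p, TRIPLET_INDEX[w[p : p + 3]]] for p in range(N_TRIPLET_POSITIONS))
    )


@dataclass(frozen=True)
class SignatureScore:
    total: float
    n_substitutions: int

    @property
    def mean_per_substitution(self) -> float:
        """Diagnostic only; the classifier consumes the unnormalized total."""
        return self.total / self.n_substitutions if self.n_substitutions else 0.0


def score_sample_signature(
    model: PwmModel, events: Iterable[SubstitutionEvent]
) -> SignatureScore:
    """Signature score of a sample: plain sum of per-substitution scores.

    Events whose window contains a base outside ACGT are skipped with a
    warning rather than scored.
    """
    total, n = 0.0, 0
    for ev in events:
        if any(b not in BASES for b in ev.window11):
            warnings.warn(f"skipping event with ambiguous window {ev.window11!r}")
            continue
        total += score_substitution(model, ev)
        n += 1
    return SignatureScore(total=total, n_substitutions=n)


# ---------------------------------------------------------------------------
# ensemble boundary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryModel:
    """Linear decision boundary in the (tract fraction, signature) plane."""

    w_tract: float
    w_sig: float
    intercept: float

    def __post_init__(self) -> None:
        if self.w_tract == 0 and self.w_sig == 0:
            raise ValueError("boundary weights cannot both be zero")

    def combined_score(self, fraction_unstable: float, signature_total: float) -> float:
        return (
            self.w_tract * fraction_unstable
            + self.w_sig * signature_total
            + self.intercept
        )


@dataclass(frozen=True)
class MsiResult:
    fraction_unstable: float
    signature_total: float
    combined_score: float

    @property
    def call(self) -> str:
        # ties (score exactly 0) resolve to MSS, favouring specificity
        return "MSI-H" if self.combined_score > 0 else "MSS"


def fit_boundary(
    points: Sequence[tuple[float, float]],
    labels: Sequence[str],
    mmr_deleterious: Sequence[bool] | None = None,
    relabel_band: float = 0.10,
    C: float = 1e6,
) -> BoundaryModel:
    """Fit a maximum-margin linear separator on the 2-D score plane.

    Features are standardized internally; the returned weights act on the
    raw (fraction_unstable, signature_total) scale with MSI-H on the
    positive side.  When ``mmr_deleterious`` flags are given, samples
    lying within ``relabel_band`` of the training margin around the
    initial boundary are relabelled by their MMR-gene mutation status and
    the boundary refit once.  Non-separable data yields a soft-margin fit
    with a warning naming the margin violators.
    """
    X = np.asarray(points, dtype=float)
    y = np.asarray([1 if l == "MSI-H" else 0 for l in labels])
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")

    mu, sigma = X.mean(axis=0), X.std(axis=0)
    sigma[sigma == 0] = 1.0

    def _fit(yy: np.ndarray) -> tuple[BoundaryModel, SVC]:
        svc = SVC(kernel="linear", C=C)
        svc.fit((X - mu) / sigma, yy)
        w_std = svc.coef_[0]
        b_std = svc.intercept_[0]
        w_raw = w_std / sigma
        b_raw = b_std - float(np.dot(w_std, mu / sigma))
        return BoundaryModel(float(w_raw[0]), float(w_raw[1]), float(b_raw)), svc

    boundary, svc = _fit(y)

    if mmr_deleterious is not None:
        dec = svc.decision_function((X - mu) / sigma)  # margin units
        near = np.abs(dec) <= relabel_band
        y2 = y.copy()
        y2[near] = np.asarray(mmr_deleterious, dtype=int)[near]
        if len(set(y2)) == 2 and not np.array_equal(y2, y):
            boundary, svc = _fit(y2)
            y = y2

    scores = np.array(
        [boundary.combined_score(p[0], p[1]) for p in X]
    )
    predicted = (scores > 0).astype(int)
    violators = np.nonzero(predicted != y)[0]
    if violators.size:
        warnings.warn(
            "classes not linearly separable; soft-margin fit with margin "
            f"violators at indices {violators.tolist()}"
        )
    return boundary


def classify_msi(
    tract_result: MsiTractResult,
    signature: SignatureScore,
    boundary: BoundaryModel,
) -> MsiResult:
    """Combine tract fraction and signature total into the final MSI call."""
    frac = tract_result.fraction_unstable
    score = boundary.combined_score(frac, signature.total)
    return MsiResult(
        fraction_unstable=frac,
        signature_total=signature.total,
        combined_score=score,
    )
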