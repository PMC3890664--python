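"""Climate-envelope niche models and niche-comparison statistics.

The envelope model is a percentile-clamped rectilinear (BIOCLIM-style)
climate envelope: per layer a cell scores 1 between the lower and upper
calibration percentiles of the training values, decays linearly to 0 at
the training minimum/maximum, and is 0 beyond; cell suitability is the
mean of per-layer scores.  The model is deterministic given its training
matrix and exposes the scikit-learn estimator protocol so it can slot
into sklearn tooling; any engine with the same ``fit``/``predict``
surface (e.g. a maximum-entropy model) can be substituted — the overlap
and identity statistics below are engine-agnostic.

Comparison statistics:

* Schoener's D = 1 - 0.5 * sum_i |a_i - b_i| over normalized per-cell
  suitabilities; 0 = no overlap, 1 = identical niches.
* The niche identity test pools the two taxa's occurrence records,
  repartitions them at random, refits both envelopes and asks whether
  the observed D is lower than expected were the taxa drawing from one
  niche (one-tailed, add-one permutation p-value).
* Minimum-training-presence range maps, rank-based AUC, and permutation
  variable importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .datatypes import (
    ClimateStack,
    OccurrenceSet,
    SuitabilitySurface,
    ValidationError,
)
from .io import deduplicate

__all__ = [
    "ClimateEnvelope",
    "IdentityTestResult",
    "RangeMap",
    "extract_climate",
    "predict_surface",
    "normalize",
    "schoener_D",
    "identity_test",
    "range_map",
    "ranges_disjoint",
    "auc",
    "variable_importance",
]


def extract_climate(occ: OccurrenceSet, stack: ClimateStack) -> np.ndarray:
    """Layer values at each deduplicated occurrence record.

    Returns one row per retained record (records outside the extent or
    on nodata cells are dropped by deduplication); raises when no record
    remains.
    """
    occ = deduplicate(occ, stack)
    if len(occ) == 0:
        raise ValidationError(f"{occ.taxon}: no occurrence record on a valid cell")
    cells = [stack.cell_of(lon, lat) for lon, lat in occ.records]
    rows = np.array([[stack.values[k, r, c] for k in range(stack.n_layers)] for r, c in cells])
    return rows


class ClimateEnvelope(BaseEstimator):
    """Percentile-clamped climate envelope (presence-only).

    Parameters
    ----------
    q_lower, q_upper
        Calibration percentiles (as proportions, default 0.05/0.95)
        between which a layer scores 1.

    Attributes (after ``fit``)
    --------------------------
    q_lower_, q_upper_ : per-layer calibration percentile values
    min_, max_ : per-layer training minima / maxima
    n_features_in_ : number of climate layers
    """

    def __init__(self, q_lower: float = 0.05, q_upper: float = 0.95):
        self.q_lower = q_lower
        self.q_upper = q_upper

    def fit(self, X, y=None) -> "ClimateEnvelope":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("training matrix must be 2-D (records x layers)")
        if len(X) < 5:
            raise ValidationError(f"envelope fitting needs >= 5 training records, got {len(X)}")
        if not 0.0 <= self.q_lower < self.q_upper <= 1.0:
            raise ValidationError("require 0 <= q_lower < q_upper <= 1")
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        self.q_lower_ = np.quantile(X, self.q_lower, axis=0)
        self.q_upper_ = np.quantile(X, self.q_upper, axis=0)
        # widen degenerate (constant) layers by a machine tolerance so a
        # cell at the single training value scores 1 without a 0/0
        span = self.max_ - self.min_
        eps = 1e-9 * np.maximum(1.0, np.abs(self.min_))
        degenerate = span <= eps
        self.min_ = np.where(degenerate, self.min_ - eps, self.min_)
        self.max_ = np.where(degenerate, self.max_ + eps, self.max_)
        self.q_lower_ = np.where(degenerate, self.min_, self.q_lower_)
        self.q_upper_ = np.where(degenerate, self.max_, self.q_upper_)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "min_"):
            raise ValidationError("envelope model is not fitted")

    def score_layers(self, X) -> np.ndarray:
        """Per-layer piecewise-linear scores for each row of X."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValidationError("prediction matrix does not match the fitted layers")
        lo_w = self.q_lower_ - self.min_
        hi_w = self.max_ - self.q_upper_
        left = np.where(lo_w > 0, (X - self.min_) / np.where(lo_w > 0, lo_w, 1.0), 1.0)
        right = np.where(hi_w > 0, (self.max_ - X) / np.where(hi_w > 0, hi_w, 1.0), 1.0)
        score = np.clip(np.minimum(left, right), 0.0, 1.0)
        outside = (X < self.min_) | (X > self.max_)
        return np.where(outside, 0.0, score)

    def predict(self, X) -> np.ndarray:
        """Cell suitability in [0, 1]: mean of per-layer scores."""
        return self.score_layers(X).mean(axis=1)


def predict_surface(model: ClimateEnvelope, stack: ClimateStack) -> SuitabilitySurface:
    """Raw (unnormalized) suitability over every valid cell of a stack."""
    mask = stack.mask
    values = np.zeros(stack.shape, dtype=float)
    X = stack.values[:, mask].T  # (n_valid, n_layers)
    values[mask] = model.predict(X)
    return SuitabilitySurface(values=values, mask=mask)


def normalize(surface: SuitabilitySurface) -> SuitabilitySurface:
    """Rescale so values over valid cells sum to 1 (a distribution)."""
    total = surface.values[surface.mask].sum()
    if total <= 0:
        raise ValidationError("cannot normalize an all-zero suitability surface")
    values = np.where(surface.mask, surface.values / total, 0.0)
    return SuitabilitySurface(values=values, mask=surface.mask.copy())


def schoener_D(a: SuitabilitySurface, b: SuitabilitySurface) -> float:
    """Schoener's niche-overlap D between two normalized surfaces.

    D = 1 - 0.5 * sum |a_i - b_i| over the shared valid mask; symmetric
    and in [0, 1].
    """
    if a.values.shape != b.values.shape:
        raise ValidationError("surfaces live on different lattices")
    if not (a.is_normalized and b.is_normalized):
        raise ValidationError("schoener_D requires normalized surfaces")
    mask = a.mask & b.mask
    d = 1.0 - 0.5 * np.abs(a.values[mask] - b.values[mask]).sum()
    return float(min(1.0, max(0.0, d)))


@dataclass
class IdentityTestResult:
    """Outcome of the niche identity randomization test (one-tailed lower)."""

    D_obs: float
    null_Ds: np.ndarray
    reps: int
    seed: int

    @property
    def p_value(self) -> float:
        return (1 + int(np.sum(self.null_Ds <= self.D_obs))) / (self.reps + 1)


def _surface_from_rows(rows: np.ndarray, stack: ClimateStack,
                       q: tuple[float, float]) -> SuitabilitySurface:
    model = ClimateEnvelope(q_lower=q[0], q_upper=q[1]).fit(rows)
    return normalize(predict_surface(model, stack))


def identity_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    stack: ClimateStack,
    reps: int = 100,
    seed: int = 0,
    q: tuple[float, float] = (0.05, 0.95),
) -> IdentityTestResult:
    """Niche identity randomization test between two taxa.

    D_obs comes from envelopes fit to each observed record set.  Each of
    ``reps`` pseudoreplicates pools the (per-cell deduplicated) records
    of both taxa, partitions the pool at random without replacement into
    two pseudo-taxa of the observed sizes, refits both envelopes and
    records D.  Identity is rejected when D_obs is unusually *low*:
    p = (1 + #(null <= D_obs)) / (reps + 1).
    """
    if reps < 1:
        raise ValidationError("identity_test needs reps >= 1")
    Xa = extract_climate(occ_a, stack)
    Xb = extract_climate(occ_b, stack)
    if len(Xa) + len(Xb) < 10:
        raise ValidationError("pooled sample too small to fit two envelopes (< 10)")
    D_obs = schoener_D(_surface_from_rows(Xa, stack, q), _surface_from_rows(Xb, stack, q))
    # pool unique cells across both taxa so a pseudo-taxon can never hold
    # the same cell twice; sizes stay (|a|, |b|) unless cells are shared
    pool = np.unique(np.vstack([Xa, Xb]), axis=0)
    na = min(len(Xa), len(pool) - 1)
    rng = np.random.default_rng(seed)
    null_Ds = np.empty(reps)
    for i in range(reps):
        perm = rng.permutation(len(pool))
        null_Ds[i] = schoener_D(
            _surface_from_rows(pool[perm[:na]], stack, q),
            _surface_from_rows(pool[perm[na:]], stack, q),
        )
    return IdentityTestResult(D_obs=D_obs, null_Ds=null_Ds, reps=reps, seed=seed)


@dataclass
class RangeMap:
    """Binary range map: suitability >= threshold on valid cells."""

    suitable: np.ndarray  # boolean grid
    threshold: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def range_map(
    model: ClimateEnvelope,
    stack: ClimateStack,
    occ_train: OccurrenceSet,
    k_folds: int = 10,
) -> RangeMap:
    """Binary range map thresholded at the mean minimum training presence.

    Training presences are split into ``k_folds`` deterministic
    contiguous folds (a fold with < 2 presences is merged into the
    previous one); the threshold is the mean over folds of the minimum
    model suitability among that fold's presences.
    """
    if k_folds < 1:
        raise ValidationError("k_folds must be >= 1")
    scores = model.predict(extract_climate(occ_train, stack))
    bounds = np.linspace(0, len(scores), min(k_folds, len(scores)) + 1).astype(int)
    folds = [scores[lo:hi] for lo, hi in zip(bounds[:-1], bounds[1:]) if hi > lo]
    merged: list[np.ndarray] = []
    for f in folds:
        if len(f) < 2 and merged:
            merged[-1] = np.concatenate([merged[-1], f])
        else:
            merged.append(f)
    threshold = float(np.mean([f.min() for f in merged]))
    surface = predict_surface(model, stack)
    suitable = surface.mask & (surface.values >= threshold)
    return RangeMap(suitable=suitable, threshold=threshold, mask=surface.mask)


def ranges_disjoint(a: RangeMap, b: RangeMap) -> bool:
    """True iff no cell is suitable in both range maps."""
    if a.suitable.shape != b.suitable.shape:
        raise ValidationError("range maps live on different lattices")
    return not bool(np.any(a.suitable & b.suitable))


def auc(model: ClimateEnvelope, presences: np.ndarray, background: np.ndarray) -> float:
    """Rank-based AUC: P(score(presence) > score(background)) + 0.5 P(tie)."""
    sp = model.predict(np.asarray(presences, dtype=float))
    sb = model.predict(np.asarray(background, dtype=float))
    if len(sp) == 0 or len(sb) == 0:
        raise ValidationError("auc needs >= 1 presence and >= 1 background row")
    ranks = rankdata(np.concatenate([sp, sb]))
    n_p, n_b = len(sp), len(sb)
    return float((ranks[:n_p].sum() - n_p * (n_p + 1) / 2) / (n_p * n_b))


def background_sample(stack: ClimateStack, n: int = 10000, seed: int = 0) -> np.ndarray:
    """Seeded sample of n random valid cells' climate rows (all if fewer)."""
    X = stack.values[:, stack.mask].T
    if len(X) <= n:
        return X
    rng = np.random.default_rng(seed)
    return X[rng.choice(len(X), size=n, replace=False)]


def variable_importance(
    model: ClimateEnvelope,
    stack: ClimateStack,
    occ: OccurrenceSet,
    seed: int = 0,
    n_background: int = 10000,
) -> dict:
    """Permutation importance of each climate layer, summing to 100.

    Importance of layer j is the drop in AUC (against a fixed seeded
    background sample) when layer j's values are permuted across the
    presence and background rows; negative drops are clipped at 0 and
    the drops are normalized to percentages.
    """
    rng = np.random.default_rng(seed)
    Xp = extract_climate(occ, stack)
    Xb = background_sample(stack, n_background, seed=seed)
    base = auc(model, Xp, Xb)
    drops = np.zeros(stack.n_layers)
    for j in range(stack.n_layers):
        Xp_perm, Xb_perm = Xp.copy(), Xb.copy()
        combined = np.concatenate([Xp[:, j], Xb[:, j]])
        combined = combined[rng.permutation(len(combined))]
        Xp_perm[:, j] = combined[: len(Xp)]
        Xb_perm[:, j] = combined[len(Xp):]
        drops[j] = max(0.0, base - auc(model, Xp_perm, Xb_perm))
    if drops.sum() <= 0:
        drops[:] = 1.0  # uninformative model: spread evenly
    drops = 100.0 * drops / drops.sum()
    return dict(zip(stack.names, drops))
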