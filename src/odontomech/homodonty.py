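"""Functional-homodonty analysis of a dentition.

A dentition is functionally homodont when every tooth transmits
statistically indistinguishable stress. Per jaw (side), tooth stresses are
normalized by the jaw's median stress to give dimensionless residuals. A
null distribution of residuals is built by repeatedly subsampling half the
teeth without replacement and renormalizing by the subsample median
(10 000 repetitions by default). A 2-cluster k-medoids analysis on random
subsamples of 5000 pooled residuals, repeated 100 times, sets the
heterodonty threshold as the mean of the two cluster medoids. Teeth whose
residual falls outside the threshold band are functional heterodonts.

Two dentition-level summaries are reported: the average squared residual
(degree of functional divergence) and the proportion of functionally
heterodont teeth (few unique teeth vs regionalization).

The k-medoids step is solved exactly: in one dimension the optimal
2-medoid partition is contiguous in sorted order, so scanning all split
points with prefix sums finds the global optimum deterministically.
"""
from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_REPS = 10_000
DEFAULT_SUBSAMPLE = 5_000
DEFAULT_KMEDOIDS_REPEATS = 100
#: relative spread below which a residual pool counts as all-identical
DEGENERATE_RTOL = 1e-9


@dataclass
class HomodontyResult:
    """Per-jaw outcome of the functional-homodonty analysis."""

    group: object
    tooth_names: list
    residuals: np.ndarray
    upper_threshold: float
    lower_threshold: float
    classes: np.ndarray  # "homodont" / "heterodont" per tooth
    avg_squared_residual: float
    proportion_heterodont: float
    pool: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)
    degenerate: bool = False


def residual_stress(stresses) -> np.ndarray:
    """Stresses divided by their median: dimensionless residuals.

    Scale-invariant: multiplying every stress by c > 0 leaves the
    residuals unchanged. Requires n >= 2 strictly positive stresses.
    """
    s = np.asarray(stresses, dtype=float)
    if s.ndim != 1 or len(s) < 2:
        raise ValidationError("residual_stress needs a flat list of >= 2 stresses")
    if not np.all(s > 0):
        raise ValidationError("all stresses must be strictly positive")
    return s / np.median(s)


def bootstrap_null(stresses, reps: int = DEFAULT_BOOTSTRAP_REPS,
                   seed=None, rng=None) -> np.ndarray:
    """Null distribution of residuals under within-jaw resampling.

    Each repetition draws ⌊n/2⌋ teeth without replacement and divides them
    by their own median; all subsampled residuals are pooled (pool size =
    reps · ⌊n/2⌋). Bit-reproducible for a fixed seed.
    """
    s = np.asarray(stresses, dtype=float)
    n = len(s)
    if n < 4:
        raise ValidationError(f"bootstrap needs >= 4 teeth (got {n}); "
                              f"half-subsampling is degenerate")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if not np.all(s > 0):
        raise ValidationError("all stresses must be strictly positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    half = n // 2
    idx = rng.permuted(np.tile(np.arange(n), (reps, 1)), axis=1)[:, :half]
    draws = s[idx]
    med = np.median(draws, axis=1, keepdims=True)
    return (draws / med).ravel()


def _two_medoids_sorted(x: np.ndarray):
    """Exact 1-D 2-medoids on each row of a sorted batch.

    For sorted data the optimal two clusters are contiguous, and the best
    medoid of a contiguous run is its (lower) median element. Scanning
    every split point with prefix sums yields the global optimum of the
    k-medoids objective (sum of absolute distances to the nearest medoid).

    Parameters: ``x`` of shape (R, m), each row sorted ascending, m >= 2.
    Returns ``(medoids, cost)``: medoids (R, 2) and total cost (R,). Ties
    break toward the smallest split index.
    """
    R, m = x.shape
    S = np.zeros((R, m + 1))
    np.cumsum(x, axis=1, out=S[:, 1:])
    s = np.arange(m - 1)  # split: left = [0..s], right = [s+1..m-1]

    def seg_cost(i, j):
        # cost and medoid index of segment [i, j] per row; i, j are arrays
        c = i + (j - i) // 2  # lower median index
        xc = np.take_along_axis(x, np.broadcast_to(c, (R, len(s))), axis=1)
        Si = np.take_along_axis(S, np.broadcast_to(i, (R, len(s))), axis=1)
        Sc1 = np.take_along_axis(S, np.broadcast_to(c + 1, (R, len(s))), axis=1)
        Sj1 = np.take_along_axis(S, np.broadcast_to(j + 1, (R, len(s))), axis=1)
        left = xc * (c - i + 1) - (Sc1 - Si)
        right = (Sj1 - Sc1) - xc * (j - c)
        return left + right, c

    cost_l, c_l = seg_cost(np.zeros_like(s), s)
    cost_r, c_r = seg_cost(s + 1, np.full_like(s, m - 1))
    total = cost_l + cost_r
    best = np.argmin(total, axis=1)
    rows = np.arange(R)
    med_lo = x[rows, c_l[best]]
    med_hi = x[rows, c_r[best]]
    return np.stack([med_lo, med_hi], axis=1), total[rows, best]


def two_medoids(values):
    """Exact 2-medoids of a 1-D sample: returns the two medoid values."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) < 2:
        raise ValidationError("k-medoids needs >= 2 points")
    medoids, _ = _two_medoids_sorted(v[None, :])
    return float(medoids[0, 0]), float(medoids[0, 1])


def _upper_from_pool(pool, subsample, repeats, rng):
    m = min(int(subsample), len(pool))
    if m < 2:
        raise ValidationError("pool too small for k-medoids")
    if m == len(pool):
        draws = np.tile(np.sort(pool), (repeats, 1))
    else:
        idx = np.argsort(rng.random((repeats, len(pool))), axis=1)[:, :m]
        draws = np.sort(pool[idx], axis=1)
    medoids, _ = _two_medoids_sorted(draws)
    return float(medoids.mean(axis=1).mean())


def kmedoids_threshold(pool, subsample: int = DEFAULT_SUBSAMPLE,
                       repeats: int = DEFAULT_KMEDOIDS_REPEATS, k: int = 2,
                       seed=None, rng=None, two_sided: str = "mirror_log"):
    """Heterodonty thresholds from the pooled null residuals.

    For each of *repeats* rounds, *subsample* residuals are drawn without
    replacement (clipped to the pool size), the exact 1-D 2-medoid
    partition is computed, and the mean of the two medoids recorded; the
    upper threshold is the mean over rounds. The lower threshold follows
    the *two_sided* mode: ``"reciprocal"`` runs the identical procedure on
    the reciprocals of the pool and inverts the cutoff, ``"mirror_log"``
    mirrors the upper cutoff on the log scale (lower = 1/upper), ``"off"``
    sets it to 0 (nothing is flagged below).

    An all-identical pool is degenerate: both thresholds collapse to the
    common value (every tooth homodont) with a warning.
    """
    if k != 2:
        raise ValidationError("only k = 2 clusters are supported")
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 1 or len(pool) < 2:
        raise ValidationError("pool must be a flat list of >= 2 residuals")
    if two_sided not in ("reciprocal", "mirror_log", "off"):
        raise ValidationError(f"unknown two_sided mode {two_sided!r}")
    span = float(np.ptp(pool))
    scale = max(float(np.abs(pool).max()), 1e-300)
    if span <= DEGENERATE_RTOL * scale:
        warnings.warn("residual pool is degenerate (all identical up to "
                      "rounding); thresholds collapse and every tooth is homodont")
        if span == 0:
            return float(pool[0]), float(pool[0])
        # keep rounding-level spread inside the band
        pad = DEGENERATE_RTOL * scale
        return float(pool.max() + pad), float(pool.min() - pad)
    rng = np.random.default_rng(seed) if rng is None else rng
    upper = _upper_from_pool(pool, subsample, repeats, rng)
    if two_sided == "reciprocal":
        lower = 1.0 / _upper_from_pool(1.0 / pool, subsample, repeats, rng)
    elif two_sided == "mirror_log":
        lower = 1.0 / upper
    else:
        lower = 0.0
    return upper, lower


def classify(residuals, upper: float, lower: float, center: str = "none"):
    """Classify teeth and summarize the dentition.

    A tooth is a functional heterodont iff its residual is above *upper*
    or below *lower*. Returns ``(classes, avg_squared_residual,
    proportion_heterodont)``; *center* selects mean(r²) (``"none"``, the
    literal definition) or mean((r−1)²) (``"one"``).
    """
    r = np.asarray(residuals, dtype=float)
    if center not in ("none", "one"):
        raise ValidationError(f"unknown center mode {center!r}")
    het = (r > upper) | (r < lower)
    classes = np.where(het, "heterodont", "homodont")
    avg_sq = float(np.mean(r ** 2) if center == "none" else np.mean((r - 1.0) ** 2))
    return classes, avg_sq, float(het.sum() / len(r))


def _group_seed(master_seed: int, key) -> np.random.SeedSequence:
    """Deterministic per-jaw substream: adding a jaw never perturbs others."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(str(key).encode())])


def run_homodonty(traits, reps: int = DEFAULT_BOOTSTRAP_REPS,
                  subsample: int = DEFAULT_SUBSAMPLE,
                  repeats: int = DEFAULT_KMEDOIDS_REPEATS,
                  seed: int = 0, two_sided: str = "mirror_log",
                  center: str = "none") -> dict:
    """Full functional-homodonty pipeline, per jaw side.

    *traits* is a DataFrame with a positive ``stress`` column (a list of
    :class:`~odontomech.biomechanics.ToothTraits` is accepted and
    flattened). Rows are grouped by any of ``jaw_id``/``side`` columns
    present; each group is analyzed independently with its own
    deterministic random substream. Groups with fewer than 4 teeth are
    skipped with a warning (the bootstrap is degenerate there).

    Returns a dict mapping group key -> :class:`HomodontyResult`.
    """
    if not isinstance(traits, pd.DataFrame):
        from .biomechanics import traits_to_frame

        traits = traits_to_frame(traits)
    if "stress" not in traits.columns:
        raise ValidationError("traits table lacks a 'stress' column")
    df = traits
    if "ok" in df.columns:
        df = df[df["ok"].astype(bool)]
    group_cols = [c for c in ("jaw_id", "side") if c in df.columns]
    groups = df.groupby(group_cols, sort=True) if group_cols else [("all", df)]

    params = dict(reps=reps, subsample=subsample, repeats=repeats,
                  two_sided=two_sided, center=center)
    results = {}
    for key, sub in groups:
        if isinstance(key, tuple) and len(key) == 1:
            key = key[0]
        stresses = sub["stress"].to_numpy(dtype=float)
        if len(stresses) < 4:
            warnings.warn(f"jaw group {key!r} has {len(stresses)} teeth (< 4); skipped")
            log.warning("jaw group %r skipped: %d teeth", key, len(stresses))
            continue
        if not np.all(stresses > 0):
            raise ValidationError(f"jaw group {key!r}: stresses must be positive")
        rng = np.random.default_rng(_group_seed(seed, key))
        residuals = residual_stress(stresses)
        pool = bootstrap_null(stresses, reps=reps, rng=rng)
        upper, lower = kmedoids_threshold(pool, subsample=subsample,
                                          repeats=repeats, rng=rng,
                                          two_sided=two_sided)
        classes, avg_sq, prop = classify(residuals, upper, lower, center=center)
        names = (sub["tooth"].tolist() if "tooth" in sub.columns
                 else list(range(len(stresses))))
        results[key] = HomodontyResult(
            group=key, tooth_names=names, residuals=residuals,
            upper_threshold=upper, lower_threshold=lower, classes=classes,
            avg_squared_residual=avg_sq, proportion_heterodont=prop,
            pool=pool, seed=seed, params=params,
            degenerate=bool(np.ptp(pool) <= DEGENERATE_RTOL * np.abs(pool).max()),
        )
    return results


def results_to_frames(results: dict):
    """Flatten run_homodonty output into (per-tooth, per-jaw-summary) frames."""
    tooth_rows, summary_rows = [], []
    for key, r in results.items():
        for name, res, cls in zip(r.tooth_names, r.residuals, r.classes):
            tooth_rows.append({"group": str(key), "tooth": name,
                               "residual_stress": res, "class": cls})
        summary_rows.append({
            "group": str(key), "n_teeth": len(r.residuals),
            "upper_threshold": r.upper_threshold,
            "lower_threshold": r.lower_threshold,
            "avg_squared_residual": r.avg_squared_residual,
            "proportion_heterodont": r.proportion_heterodont,
            "degenerate": r.degenerate, "seed": r.seed, **r.params,
        })
    return pd.DataFrame(tooth_rows), pd.DataFrame(summary_rows)
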