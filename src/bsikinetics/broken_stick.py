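"""Broken-stick regression: continuous two-segment linear fit with an
estimated change-point.

The mean trajectory is modelled as two straight lines joined at an unknown
day ``c``: concentration ``= level_at_c + slope_pre * (t - c)`` for days
``t <= c`` and ``level_at_c + slope_post * (t - c)`` for ``t > c``. The
model is linear in ``(level_at_c, slope_pre, slope_post)`` once ``c`` is
fixed, so ``c`` is estimated by profiling: the three linear parameters are
solved in closed form on a grid of candidate change-points and the global
least-squares minimiser is returned, optionally refined between the two
neighbouring grid points. Continuity at ``c`` is structural (built into
the design matrix), never a penalty.

Confidence intervals come from a patient-level percentile bootstrap:
patients are resampled with replacement, the daily-mean series is rebuilt
and the model refitted per replicate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from collections.abc import Sequence

import numpy as np
from scipy import optimize

from .datatypes import WINDOW, Biomarker, DailySeries, PatientRecord
from .preprocess import daily_means, patient_day_matrices

__all__ = [
    "BrokenStickFit",
    "FitError",
    "InferenceError",
    "predict",
    "fit_broken_stick",
    "breakpoint_cis",
]

#: Default change-point search interval (open at both ends).
DEFAULT_C_SEARCH: tuple[float, float] = (-29.0, 0.0)
DEFAULT_GRID_STEP: float = 0.1
MIN_POINTS_PER_SIDE = 2


class FitError(RuntimeError):
    """Broken-stick estimation failed (too few points or singular design)."""


class InferenceError(RuntimeError):
    """Bootstrap inference failed (chronic replicate fit failures)."""


@dataclass(frozen=True)
class BrokenStickFit:
    """A fitted two-segment model.

    ``c`` is the estimated change-point (the day the concentration course
    changes), ``slope_pre`` / ``slope_post`` the segment slopes in
    units/day, ``level_at_c`` the concentration where the segments meet.
    ``sse`` is the residual sum of squares over the ``n_days`` fitted
    daily-mean points. The 95% confidence intervals are ``None`` until
    filled by :func:`breakpoint_cis`.
    """

    c: float
    level_at_c: float
    slope_pre: float
    slope_post: float
    sse: float
    n_days: int
    day_min: float
    day_max: float
    ci_c: tuple[float, float] | None = None
    ci_slope_pre: tuple[float, float] | None = None
    ci_slope_post: tuple[float, float] | None = None
    n_boot: int = 0
    n_failed: int = 0


def predict(fit: BrokenStickFit, t) -> float | np.ndarray:
    """Fitted mean concentration at day(s) ``t``.

    Days outside the fitted range trigger an extrapolation warning but the
    linear extension is still returned. Exactly at ``t == c`` both
    segments agree and ``level_at_c`` is returned.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < fit.day_min) or np.any(t_arr > fit.day_max):
        warnings.warn(
            f"predicting outside the fitted day range "
            f"[{fit.day_min}, {fit.day_max}]",
            stacklevel=2,
        )
    dt = t_arr - fit.c
    out = fit.level_at_c + np.where(dt <= 0, fit.slope_pre * dt,
                                    fit.slope_post * dt)
    return out if out.ndim else float(out)


def _solve_candidates(
    days: np.ndarray,
    values: np.ndarray,
    candidates: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form least squares at every candidate change-point at once.

    Returns ``(betas, sse)`` with ``betas[k] = (level, slope_pre,
    slope_post)`` for candidate ``k``; candidates with fewer than
    MIN_POINTS_PER_SIDE days strictly on either side get ``sse = inf``.
    """
    t = days[None, :] - candidates[:, None]  # (C, n)
    X = np.stack(
        [np.ones_like(t), np.minimum(t, 0.0), np.maximum(t, 0.0)], axis=2
    )  # (C, n, 3)
    w = np.ones_like(values) if weights is None else np.asarray(weights, float)
    Xw = X * w[None, :, None]
    XtX = np.einsum("cni,cnj->cij", Xw, X)
    Xty = np.einsum("cni,n->ci", Xw, values)
    ok = (np.sum(t <= 0, axis=1) >= MIN_POINTS_PER_SIDE) & (
        np.sum(t > 0, axis=1) >= MIN_POINTS_PER_SIDE
    )
    betas = np.full((len(candidates), 3), np.nan)
    sse = np.full(len(candidates), np.inf)
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return betas, sse
    try:
        b = np.linalg.solve(XtX[idx], Xty[idx][..., None])[..., 0]
    except np.linalg.LinAlgError:
        # rare singular candidate: fall back to one-by-one with exclusion
        b = np.full((len(idx), 3), np.nan)
        for j, k in enumerate(idx):
            try:
                b[j] = np.linalg.solve(XtX[k], Xty[k][:, None])[:, 0]
            except np.linalg.LinAlgError:
                continue
    pred = np.einsum("cni,ci->cn", X[idx], b)
    resid = values[None, :] - pred
    sse_ok = np.einsum("n,cn->c", w, resid * resid)
    solved = ~np.isnan(b[:, 0])
    betas[idx[solved]] = b[solved]
    sse[idx[solved]] = sse_ok[solved]
    return betas, sse


def _sse_at(days, values, c, weights=None) -> tuple[np.ndarray, float]:
    betas, sse = _solve_candidates(days, values, np.array([c]), weights)
    return betas[0], float(sse[0])


def fit_broken_stick(
    series: DailySeries,
    c_search: tuple[float, float] = DEFAULT_C_SEARCH,
    grid_step: float = DEFAULT_GRID_STEP,
    refine: bool = True,
    weight_by_count: bool = False,
) -> BrokenStickFit:
    """Fit the broken stick to a daily-mean series by profiling ``c``.

    Candidate change-points run over ``c_search`` (open interval) in steps
    of ``grid_step`` (default 0.1 day); each candidate's linear parameters
    are solved in closed form and the candidate with smallest residual sum
    of squares wins. Ties are broken toward the ``c`` closest to day 0
    (the latest change). With ``refine=True`` the minimiser is polished by
    a bounded scalar search between the two neighbouring grid points and
    kept only if it strictly lowers the SSE. Deterministic for fixed
    inputs.

    By default each day's mean counts once, matching a fit to the observed
    mean points; ``weight_by_count=True`` weights each day by its specimen
    count instead.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    days = np.asarray(series.days, dtype=float)
    values = np.asarray(series.means, dtype=float)
    if len(days) < 4:
        raise FitError(
            f"need at least 4 daily points to fit a broken stick, got {len(days)}"
        )
    lo, hi = c_search
    if not (days.min() <= lo and hi <= days.max() + 1e-9):
        lo = max(lo, float(days.min()))
        hi = min(hi, float(days.max()))
    candidates = np.arange(lo + grid_step, hi - grid_step / 2, grid_step)
    candidates = np.round(candidates, 10)
    if len(candidates) == 0:
        raise FitError("empty change-point search grid")
    weights = series.counts.astype(float) if weight_by_count else None

    betas, sse = _solve_candidates(days, values, candidates, weights)
    if not np.any(np.isfinite(sse)):
        raise FitError(
            "no admissible change-point candidate: every candidate leaves "
            f"fewer than {MIN_POINTS_PER_SIDE} days on one side or is singular"
        )
    sse_min = np.min(sse)
    tol = 1e-12 * max(1.0, sse_min)
    tied = np.flatnonzero(sse <= sse_min + tol)
    best = tied[np.argmin(np.abs(candidates[tied]))]
    c_hat, beta_hat, sse_hat = float(candidates[best]), betas[best], float(sse[best])

    if refine:
        lo_b = float(candidates[best - 1]) if best > 0 else c_hat - grid_step
        hi_b = float(candidates[best + 1]) if best < len(candidates) - 1 \
            else c_hat + grid_step
        res = optimize.minimize_scalar(
            lambda c: _sse_at(days, values, c, weights)[1],
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if np.isfinite(res.fun) and res.fun < sse_hat - tol:
            beta_r, sse_r = _sse_at(days, values, float(res.x), weights)
            c_hat, beta_hat, sse_hat = float(res.x), beta_r, sse_r

    return BrokenStickFit(
        c=c_hat,
        level_at_c=float(beta_hat[0]),
        slope_pre=float(beta_hat[1]),
        slope_post=float(beta_hat[2]),
        sse=max(sse_hat, 0.0),
        n_days=len(days),
        day_min=float(days.min()),
        day_max=float(days.max()),
    )


def _fit_from_matrices(
    days: np.ndarray,
    sums: np.ndarray,
    counts: np.ndarray,
    idx: np.ndarray,
    biomarker: Biomarker,
    **fit_kwargs,
) -> BrokenStickFit:
    """Refit after resampling patient rows ``idx`` with replacement."""
    s = sums[idx].sum(axis=0)
    n = counts[idx].sum(axis=0)
    present = n > 0
    series = DailySeries(
        biomarker, days[present], s[present] / n[present], n[present]
    )
    return fit_broken_stick(series, **fit_kwargs)


def breakpoint_cis(
    patients: Sequence[PatientRecord],
    biomarker: Biomarker,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    window: tuple[int, int] = WINDOW,
    **fit_kwargs,
) -> BrokenStickFit:
    """Percentile-bootstrap 95% CIs for the change-point and segment slopes.

    Patients are resampled with replacement ``n_reps`` times (default 1000
    replications); each replicate rebuilds the pooled daily means and
    refits the broken stick. The intervals are the 2.5th/97.5th
    percentiles of the replicate distributions. Replicates whose fit fails
    are excluded and counted in ``n_failed``; more than 50% failures
    aborts with :class:`InferenceError`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    full_fit = fit_broken_stick(daily_means(patients, biomarker), **fit_kwargs)
    days, sums, counts = patient_day_matrices(patients, biomarker, window)
    n_pat = len(patients)
    reps = np.full((n_reps, 3), np.nan)  # c, slope_pre, slope_post
    n_failed = 0
    for r in range(n_reps):
        idx = rng.integers(0, n_pat, size=n_pat)
        try:
            f = _fit_from_matrices(days, sums, counts, idx, biomarker, **fit_kwargs)
        except (FitError, ValueError):
            n_failed += 1
            continue
        reps[r] = (f.c, f.slope_pre, f.slope_post)
    ok = ~np.isnan(reps[:, 0])
    if ok.sum() < n_reps / 2:
        raise InferenceError(
            f"bootstrap failed: {n_failed}/{n_reps} replicate fits "
            f"unusable for {biomarker.value}"
        )
    lo, hi = np.percentile(reps[ok], [2.5, 97.5], axis=0)
    return replace(
        full_fit,
        ci_c=(float(lo[0]), float(hi[0])),
        ci_slope_pre=(float(lo[1]), float(hi[1])),
        ci_slope_post=(float(lo[2]), float(hi[2])),
        n_boot=int(ok.sum()),
        n_failed=n_failed,
    )
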