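"""Growth-curve quantification.

The sigmoidal model is the modified Gompertz form

    od(t) = y0 + A * exp(-exp((mu_max * e / A) * (lag - t) + 1))

parameterized directly by the quantities of interest: baseline OD ``y0``,
asymptotic OD rise ``A``, maximum growth rate ``mu_max`` (OD/h, the slope
at the inflection point), and lag time ``lag`` (h).  Quality control
follows the plate-run standards used for high-throughput anaerobe
phenotyping: wells whose OD rises no earlier than a sterile control on the
same plate/condition are discarded as contaminated, and of four technical
replicates the three most mutually similar are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import medfilt

__all__ = [
    "GompertzFit",
    "GrowthMetrics",
    "gompertz_model",
    "fit_gompertz",
    "detect_onset",
    "flag_contamination",
    "select_replicates",
    "compute_metrics",
    "normalize_metrics",
    "compute_dilution",
    "analyze_run",
]

_MIN_GROWTH_A = 0.05  # OD rise below this is treated as no growth


def gompertz_model(t, y0: float, A: float, mu_max: float, lag: float):
    """Evaluate the modified Gompertz curve; A = 0 degenerates to y0."""
    t = np.asarray(t, dtype=float)
    if A == 0:
        return np.full_like(t, float(y0))
    inner = (mu_max * np.e / A) * (lag - t) + 1.0
    # exp overflow for t far below lag is harmless: exp(-inf-ish) -> 0
    with np.errstate(over="ignore"):
        return y0 + A * np.exp(-np.exp(inner))


@dataclass(frozen=True)
class GompertzFit:
    """Fitted Gompertz parameters plus diagnostics for one OD curve.

    ``grew=False`` means the curve is judged a non-grower (rise < 0.05 OD
    or no improvement over a flat fit); its reported mu_max is 0.
    """

    y0: float
    A: float
    mu_max: float
    lag: float
    sse: float
    converged: bool
    grew: bool


def _initial_guess(times: np.ndarray, od: np.ndarray) -> tuple[float, float, float, float]:
    smooth = medfilt(od, kernel_size=min(5, len(od) - (1 - len(od) % 2)))
    lo, hi = float(np.min(od)), float(np.max(od))
    a0 = max(hi - lo, 1e-6)
    slopes = np.diff(smooth) / np.diff(times)
    mu0 = max(float(np.max(slopes)) if slopes.size else 0.0, 1e-3)
    above = np.nonzero(od > lo + 0.1 * a0)[0]
    lag0 = float(times[above[0]]) if above.size else float(times[0])
    return lo, a0, mu0, lag0


def fit_gompertz(times, od) -> GompertzFit:
    """Bounded nonlinear least squares of the Gompertz model on raw OD.

    Initialization: A0 = curve range, mu0 = steepest finite-difference
    slope of a 5-point median-filtered curve, lag0 = first time the curve
    exceeds min + 0.1*range; up to five starts jitter (mu0, lag0) by
    factors of 0.5 and 2 before declaring non-convergence.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if times.ndim != 1 or times.shape != od.shape:
        raise ValueError("times and od must be 1-D arrays of equal length")
    if len(times) < 10:
        raise ValueError("need at least 10 timepoints to fit")
    if not np.all(np.isfinite(od)):
        raise ValueError("OD series contains non-finite values")

    flat_sse = float(np.sum((od - od.mean()) ** 2))
    y0_0, a0, mu0, lag0 = _initial_guess(times, od)
    starts = [
        (y0_0, a0, mu0, lag0),
        (y0_0, a0, 0.5 * mu0, lag0),
        (y0_0, a0, 2.0 * mu0, lag0),
        (y0_0, a0, mu0, 0.5 * lag0),
        (y0_0, a0, mu0, 2.0 * lag0),
    ]
    lower = np.array([0.0, 1e-8, 1e-8, 0.0])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])

    def residuals(p):
        return gompertz_model(times, *p) - od

    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
        try:
            res = least_squares(
                residuals, x0, bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[1]:
            best = (res, sse)
        # a near-perfect or clearly adequate fit needs no further starts
        if sse <= max(1e-12, 1e-4 * flat_sse):
            break

    if best is None:
        return GompertzFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, False)
    res, sse = best
    y0_f, a_f, mu_f, lag_f = (float(v) for v in res.x)
    converged = bool(res.status > 0)
    grew = converged and a_f >= _MIN_GROWTH_A and sse < flat_sse
    if not grew:
        mu_f = 0.0
    return GompertzFit(y0_f, a_f, mu_f, lag_f, sse, converged, grew)


def detect_onset(
    times,
    od,
    baseline_hours: float = 1.0,
    min_rise: float = 0.05,
    sd_mult: float = 5.0,
) -> float | None:
    """First time OD exceeds baseline mean + max(min_rise, sd_mult*SD).

    The baseline is the window of the first ``baseline_hours`` hours; it
    must be shorter than the series.  Returns None if the threshold is
    never exceeded.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    window = times <= times[0] + baseline_hours
    if window.all():
        raise ValueError("baseline window spans the entire series")
    base = od[window]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValueError("baseline window has no finite readings")
    threshold = base.mean() + max(min_rise, sd_mult * base.std())
    above = np.nonzero(od > threshold)[0]
    if above.size == 0:
        return None
    return float(times[above[0]])


def flag_contamination(
    strain_curves: Sequence[np.ndarray],
    control_curves: Sequence[np.ndarray],
    times,
    **onset_kwargs,
) -> bool:
    """Discard rule: strain OD rise at the same time as or after a control.

    True (discard) iff some sterile control shows an onset and the strain
    either never rises or rises no earlier than the earliest control
    onset.  When all controls stay flat the strain is always kept.
    """
    if len(control_curves) == 0:
        raise ValueError("need at least one control well")
    control_onsets = [
        t for c in control_curves
        if (t := detect_onset(times, c, **onset_kwargs)) is not None
    ]
    if not control_onsets:
        return False
    earliest_control = min(control_onsets)
    strain_onsets = [
        t for c in strain_curves
        if (t := detect_onset(times, c, **onset_kwargs)) is not None
    ]
    if not strain_onsets:
        return True
    return min(strain_onsets) >= earliest_control


def select_replicates(curves: Sequence[np.ndarray], k: int = 3) -> tuple[int, ...]:
    """Indices of the k mutually most similar replicate curves.

    Exhaustively scores every size-k subset by the sum of pairwise
    Euclidean distances between OD vectors; ties resolve to the
    lexicographically smallest index set.
    """
    n = len(curves)
    if n < k:
        raise ValueError(f"need at least {k} replicate curves, got {n}")
    mat = np.asarray([np.asarray(c, dtype=float) for c in curves])
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    best_subset, best_total = None, np.inf
    for subset in combinations(range(n), k):
        total = sum(dist[i, j] for i, j in combinations(subset, 2))
        if total < best_total:
            best_subset, best_total = subset, total
    return best_subset


@dataclass(frozen=True)
class GrowthMetrics:
    """Per strain/condition summary over the selected replicates."""

    strain: str
    condition_type: str
    condition_value: float
    max_growth_rate: float
    max_od: float
    n_replicates_used: int


def compute_metrics(
    fits: Sequence[GompertzFit],
    curves: Sequence[np.ndarray],
    strain: str,
    condition_type: str,
    condition_value: float,
    blank: float = 0.0,
) -> GrowthMetrics:
    """Average the selected replicates into one strain/condition record.

    max_growth_rate is the mean fitted mu_max (0 for non-growers);
    max_od is the mean over replicates of the maximum of the 5-point
    median-filtered, blank-corrected OD curve, floored at 0.
    """
    # a non-converged fit is still usable if the curve is plainly flat
    usable = [
        (f, c)
        for f, c in zip(fits, curves)
        if f.converged or np.ptp(np.asarray(c, dtype=float)) < _MIN_GROWTH_A
    ]
    if not usable:
        raise ValueError(
            f"{strain} @ {condition_type}={condition_value}: no replicate "
            "with a converged fit; metrics withheld"
        )
    mus = [f.mu_max if f.grew else 0.0 for f, _ in usable]
    peaks = []
    for _, c in usable:
        c = np.asarray(c, dtype=float)
        kernel = min(5, len(c) - (1 - len(c) % 2))
        peaks.append(max(float(np.max(medfilt(c, kernel))) - blank, 0.0))
    return GrowthMetrics(
        strain=strain,
        condition_type=condition_type,
        condition_value=condition_value,
        max_growth_rate=float(np.mean(mus)),
        max_od=float(np.mean(peaks)),
        n_replicates_used=len(usable),
    )


def normalize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Scale each strain's rate and max-OD by its own across-condition maximum.

    Input columns: strain, condition_type, condition_value,
    max_growth_rate, max_od.  The maxima pool every condition measured for
    the strain, so the best condition scores 1.0 in each metric; a strain
    with no growth anywhere gets zeros and ``no_growth=True``.
    """
    if (metrics[["max_growth_rate", "max_od"]] < 0).any().any():
        raise ValueError("negative growth metrics")
    out = metrics.copy()
    out["norm_rate"] = 0.0
    out["norm_od"] = 0.0
    out["no_growth"] = False
    for strain, idx in out.groupby("strain").groups.items():
        sub = out.loc[idx]
        for raw, norm in (("max_growth_rate", "norm_rate"), ("max_od", "norm_od")):
            top = sub[raw].max()
            if top > 0:
                out.loc[idx, norm] = sub[raw] / top
        if sub["max_growth_rate"].max() == 0 and sub["max_od"].max() == 0:
            out.loc[idx, "no_growth"] = True
    return out


def compute_dilution(
    predilution_fold: float, transfer_volume_ul: float, receiving_volume_ul: float
) -> float:
    """Total dilution fold of the plate-loading scheme.

    One step dilutes by (transfer + receiving)/transfer; the total is the
    predilution fold times the step fold.  Loading 5 uL into 75 uL is a
    16-fold step; after a fivefold predilution the total is 80-fold.
    """
    if transfer_volume_ul <= 0 or receiving_volume_ul < 0:
        raise ValueError("volumes must be positive (receiving may be 0)")
    step = (transfer_volume_ul + receiving_volume_ul) / transfer_volume_ul
    return predilution_fold * step


def analyze_run(
    run,
    blank: float | None = None,
    n_keep: int = 3,
    **onset_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full growth QC + quantification for one parsed plate run.

    For every (strain, condition): check contamination against the sterile
    controls of the same condition (falling back to all controls on the
    plate), keep the ``n_keep`` most similar replicates, fit each, and
    average into metrics.  Returns ``(metrics, qc)`` DataFrames; ``qc``
    lists discarded or withheld groups with reasons.  ``blank=None``
    estimates the blank as the mean sterile-control OD (0 if no controls).
    """
    times = run.times
    controls_by_cond: dict[tuple[str, float], list[np.ndarray]] = {}
    all_controls: list[np.ndarray] = []
    for w in run.wells_where(sterile=True):
        curve = run.series(w.well)
        controls_by_cond.setdefault(
            (w.condition_type, w.condition_value), []
        ).append(curve)
        all_controls.append(curve)
    if blank is None:
        blank = (
            float(np.nanmean([np.nanmean(c) for c in all_controls]))
            if all_controls
            else 0.0
        )

    metrics_rows, qc_rows = [], []
    groups: dict[tuple[str, str, float], list] = {}
    for w in run.wells:
        if w.sterile:
            continue
        groups.setdefault(
            (w.strain, w.condition_type, w.condition_value), []
        ).append(w)
    for (strain, ctype, cval), members in sorted(groups.items()):
        members = sorted(members, key=lambda w: w.replicate)
        curves = [run.series(w.well) for w in members]
        controls = controls_by_cond.get((ctype, cval), all_controls)
        if controls:
            if flag_contamination(curves, controls, times, **onset_kwargs):
                qc_rows.append((strain, ctype, cval, "discarded",
                                "OD rise not earlier than sterile control"))
                continue
        if len(curves) >= n_keep:
            keep = select_replicates(curves, k=n_keep)
        else:
            keep = tuple(range(len(curves)))
        fits = [fit_gompertz(times, curves[i]) for i in keep]
        try:
            m = compute_metrics(
                fits, [curves[i] for i in keep], strain, ctype, cval, blank=blank
            )
        except ValueError as err:
            qc_rows.append((strain, ctype, cval, "withheld", str(err)))
            continue
        metrics_rows.append(m)
    metrics = pd.DataFrame(
        [
            (m.strain, m.condition_type, m.condition_value,
             m.max_growth_rate, m.max_od, m.n_replicates_used)
            for m in metrics_rows
        ],
        columns=["strain", "condition_type", "condition_value",
                 "max_growth_rate", "max_od", "n_replicates_used"],
    )
    qc = pd.DataFrame(
        qc_rows,
        columns=["strain", "condition_type", "condition_value", "action", "reason"],
    )
    return metrics, qc
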