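"""Dose-response curves and paradoxical-activation observables.

PA is quantified two ways, following the contour and fold-change analyses:

* **PA fold change** — peak active RAF across doses divided by the drug-free
  baseline (≥ 1 by construction when dose 0 is on the grid);
* **PA range / crossover dose** — the drug concentration above the peak at
  which activity returns to the drug-free baseline, i.e. where the inhibitor
  stops being an activator. The PA interval starts at 0⁺ whenever PA occurs
  (the initial slope is positive), so the scalar upper crossover suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from . import analytic, oracle
from .parameters import ModelVariant, Parameters, ValidationError, apply_alpha

#: relative excess over baseline required to count as PA (guards the
#: tangency of the curve at dose -> 0 against floating-point equality)
PA_DETECTION_RTOL = 1e-9

#: default dose grid of the descriptive figures: 121 log-spaced points
DEFAULT_DOSE_GRID = np.logspace(-4.0, 2.0, 121)

MODES = ("total_drug", "free_drug")
ENGINES = ("analytic", "oracle")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Paired drug doses and active-RAF fractions with provenance."""

    doses: np.ndarray
    active: np.ndarray
    baseline: float
    mode: str
    engine: str
    variant: ModelVariant
    params: Parameters
    s_free: float | None
    _evaluate: Callable[[float], float] = field(repr=False, compare=False)

    def evaluate(self, dose: float) -> float:
        """Active fraction at an arbitrary dose, off-grid."""
        return self._evaluate(float(dose))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame with fraction, percent-of-total and relative columns."""
        rel = self.active / self.baseline if self.baseline > 0 else np.full_like(self.active, np.nan)
        return pd.DataFrame(
            {
                "variant": self.variant.value,
                "engine": self.engine,
                "mode": self.mode,
                "dose_uM": self.doses,
                "active_fraction": self.active,
                "active_pct_total": 100.0 * self.active,
                "active_rel_baseline": rel,
            }
        )


def _make_evaluator(
    variant: ModelVariant,
    params: Parameters,
    mode: str,
    engine: str,
    s_free: float | None,
) -> Callable[[float], float]:
    if engine == "analytic":
        if mode != "free_drug":
            raise ValidationError(
                "the analytic engine evaluates closed forms in free drug; "
                "use mode='free_drug' (or the oracle engine for total drug)"
            )
        s = analytic.effective_s_free(params, s_free)
        return lambda d: analytic.active_fraction(variant, params, d, s)
    if engine != "oracle":
        raise ValidationError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    if mode == "free_drug":
        s = analytic.effective_s_free(params, s_free)
        return lambda d: oracle.active_raf(
            oracle.solve_free_clamped(variant, params, d, s)
        )
    if mode != "total_drug":
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    if s_free is not None:
        raise ValidationError(
            "s_free cannot be clamped in total_drug mode; 14-3-3 is conserved"
        )
    return lambda d: oracle.active_raf(
        oracle.solve_totals(variant, params.replace(D_total=d))
    )


def dose_response(
    variant: ModelVariant,
    params: Parameters,
    doses: Sequence[float] | None = None,
    mode: str = "total_drug",
    engine: str = "oracle",
    s_free: float | None = None,
) -> DoseResponseCurve:
    """Active-RAF dose-response curve over a drug grid.

    Parameters
    ----------
    doses
        Strictly increasing non-negative doses (µM); dose 0 is prepended if
        absent. Defaults to 121 log-spaced points over 1e-4…1e2 µM.
    mode
        ``total_drug`` (conservation-solved, the figure convention) or
        ``free_drug`` (drug and 14-3-3 clamped at their free values).
    engine
        ``oracle`` (mass-action solver) or ``analytic`` (closed forms;
        free-drug mode only).
    s_free
        Clamped free 14-3-3 for free-drug mode; defaults to S_total (the
        excess assumption). Must be omitted in total-drug mode.
    """
    ev = _make_evaluator(variant, params, mode, engine, s_free)
    grid = DEFAULT_DOSE_GRID if doses is None else np.asarray(doses, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValidationError("doses must be a non-empty 1-D sequence")
    if np.any(grid < 0):
        raise ValidationError("doses must be non-negative")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("doses must be strictly increasing")
    if grid[0] != 0.0:
        grid = np.concatenate(([0.0], grid))
    active = np.array([ev(d) for d in grid])
    return DoseResponseCurve(
        doses=grid,
        active=active,
        baseline=active[0],
        mode=mode,
        engine=engine,
        variant=variant,
        params=params,
        s_free=s_free,
        _evaluate=ev,
    )


@dataclass(frozen=True)
class PAMetrics:
    """The two PA observables of one dose-response curve."""

    fold_change: float
    crossover_dose: float | None
    pa_detected: bool
    peak_dose: float | None


def _refined_peak(curve: DoseResponseCurve) -> tuple[float, float]:
    """(peak dose, peak activity) refined off-grid by bounded search.

    Golden-section/Brent refinement in log-dose between the grid neighbours
    of the argmax makes the reported maximum grid-independent.
    """
    i = int(np.argmax(curve.active))
    if i == 0:
        return 0.0, curve.baseline
    lo = curve.doses[i - 1] if curve.doses[i - 1] > 0 else curve.doses[i] / 1e3
    if i + 1 < len(curve.doses):
        hi = curve.doses[i + 1]
    else:
        # argmax on the grid edge: the true peak may lie beyond; expand
        # upward until the curve turns over (capped to stay finite)
        hi = curve.doses[i] * 10.0
        best = curve.active[i]
        cap = curve.doses[i] * 1e12
        while hi < cap and curve.evaluate(hi) > best:
            best = curve.evaluate(hi)
            hi *= 10.0
    res = minimize_scalar(
        lambda x: -curve.evaluate(10.0**x),
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if -res.fun >= curve.active[i]:
        return 10.0**res.x, -res.fun
    return curve.doses[i], curve.active[i]


def pa_fold_change(curve: DoseResponseCurve) -> float:
    """Peak active RAF over baseline, refined to be grid-independent."""
    if curve.doses[0] != 0.0:
        raise ValidationError("curve must include dose 0")
    if curve.baseline <= 0.0:
        return 1.0
    _, peak = _refined_peak(curve)
    return max(peak / curve.baseline, 1.0)


def pa_metrics(curve: DoseResponseCurve) -> PAMetrics:
    """Fold change, PA detection flag and crossover dose for one curve."""
    fold = pa_fold_change(curve)
    detected = fold > 1.0 + PA_DETECTION_RTOL
    if not detected:
        return PAMetrics(fold_change=fold, crossover_dose=None, pa_detected=False, peak_dose=None)
    peak_dose, peak_value = _refined_peak(curve)
    crossover = _crossover_from(curve, peak_dose, peak_value)
    return PAMetrics(
        fold_change=fold, crossover_dose=crossover, pa_detected=True, peak_dose=peak_dose
    )


def _crossover_from(
    curve: DoseResponseCurve, peak_dose: float, peak_value: float
) -> float:
    """Dose above the peak where activity returns to baseline.

    Brackets between the refined peak and a dose where activity has fallen
    below baseline, then bisects in log-dose. Because the tail decays at
    least as fast as 1/dose, the crossing lies near peak_dose x fold
    change; the initial upper guess starts there and expands by x10.
    """
    base = curve.baseline
    lo = peak_dose if peak_dose > 0 else curve.doses[1]
    hi = max(lo * 10.0, curve.doses[-1], lo * (peak_value / base))
    cap = hi * 1e10
    while curve.evaluate(hi) >= base:
        hi *= 10.0
        if hi > cap:
            raise oracle.ConvergenceError(
                "failed to bracket the PA crossover after expanding the "
                "upper dose by 1e10; implementation defect"
            )
    return 10.0 ** brentq(
        lambda x: curve.evaluate(10.0**x) - base,
        np.log10(lo),
        np.log10(hi),
        xtol=1e-12,
        rtol=9e-16,
        maxiter=200,
    )


def pa_crossover_dose(
    variant: ModelVariant,
    params: Parameters,
    mode: str = "total_drug",
    engine: str = "oracle",
    s_free: float | None = None,
    doses: Sequence[float] | None = None,
) -> float | None:
    """Crossover dose (µM) of the variant's dose response, or None if no PA."""
    curve = dose_response(variant, params, doses, mode, engine, s_free)
    return pa_metrics(curve).crossover_dose


METRIC_NAMES = ("baseline_pct", "max_pct", "fold_change", "crossover_dose")


@dataclass(frozen=True)
class SweepGrid:
    """Gridded PA metric over the cross product of two parameter axes."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    metric: str
    values: np.ndarray  # shape (len(axis1), len(axis2))
    variant: ModelVariant
    mode: str
    engine: str

    def to_dataframe(self) -> pd.DataFrame:
        """Long/tidy frame: one row per grid cell."""
        a1, a2 = np.meshgrid(self.axis1_values, self.axis2_values, indexing="ij")
        return pd.DataFrame(
            {
                self.axis1_name: a1.ravel(),
                self.axis2_name: a2.ravel(),
                "metric": self.metric,
                "value": self.values.ravel(),
                "variant": self.variant.value,
                "engine": self.engine,
                "mode": self.mode,
            }
        )


def _set_axis(params: Parameters, name: str, value: float) -> Parameters:
    if name == "alpha":
        return apply_alpha(params, value)
    if name not in params.to_dict():
        raise ValidationError(f"unknown sweep axis {name!r}")
    return params.replace(**{name: value})


def sweep_grid(
    variant: ModelVariant,
    base: Parameters,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    metric: str,
    mode: str = "free_drug",
    engine: str = "analytic",
    doses: Sequence[float] | None = None,
) -> SweepGrid:
    """Evaluate a PA metric over a 2-D parameter grid.

    Axis names are Parameters fields or ``alpha`` (applied via the
    K_Sdim·α, K_Smon/α rescaling). Cells without PA hold NaN for
    ``crossover_dose``. In free-drug mode the clamped free 14-3-3 follows
    each cell's S_total (the excess assumption).
    """
    if metric not in METRIC_NAMES:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    out = np.empty((vals1.size, vals2.size))
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            p = _set_axis(_set_axis(base, name1, v1), name2, v2)
            out[i, j] = _cell_metric(variant, p, metric, mode, engine, doses)
    return SweepGrid(
        axis1_name=name1,
        axis1_values=vals1,
        axis2_name=name2,
        axis2_values=vals2,
        metric=metric,
        values=out,
        variant=variant,
        mode=mode,
        engine=engine,
    )


def _cell_metric(
    variant: ModelVariant,
    params: Parameters,
    metric: str,
    mode: str,
    engine: str,
    doses: Sequence[float] | None,
) -> float:
    curve = dose_response(variant, params, doses, mode, engine)
    if metric == "baseline_pct":
        return 100.0 * curve.baseline
    m = pa_metrics(curve)
    if metric == "fold_change":
        return m.fold_change
    if metric == "max_pct":
        return 100.0 * m.fold_change * curve.baseline
    return m.crossover_dose if m.crossover_dose is not None else np.nan
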