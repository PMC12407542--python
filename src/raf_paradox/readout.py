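"""Synthetic saturable downstream readouts and PA estimation from replicates.

Immunoblot-style quantification (e.g. densitometry of pERK/total-ERK) is a
*saturable* readout of RAF kinase activity: detecting the PA fold change
faithfully would require a linear readout, whereas detecting the PA *range*
only requires a monotone one. This module generates noisy replicate
readouts through a Hill-type monotone link and estimates the PA observables
back from them, so that compression of fold change and robustness of the
crossover can be studied at the desk scale.

Noise is multiplicative lognormal, parameterized by its coefficient of
variation — densitometry ratios are positive and right-skewed, and no
quantitative noise characterization of real blots is assumed. Defaults
mirror triplicate experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import DoseResponseCurve
from .parameters import ValidationError


@dataclass(frozen=True)
class ReadoutModel:
    """Monotone saturable link plus replicate noise model.

    readout = v_max · aʰ/(aʰ + k_halfʰ) × lognormal(CV), a = active fraction.
    """

    v_max: float = 1.0
    k_half: float = 0.01
    hill: float = 1.0
    noise_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.k_half <= 0 or self.hill <= 0:
            raise ValidationError("v_max, k_half and hill must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    def link(self, active: np.ndarray) -> np.ndarray:
        """Noise-free readout of an active-RAF fraction (strictly increasing)."""
        a = np.asarray(active, dtype=float)
        return self.v_max * a**self.hill / (a**self.hill + self.k_half**self.hill)


@dataclass(frozen=True)
class NoisyDoseResponse:
    """Replicate readouts per dose with full generating provenance."""

    doses: np.ndarray
    readouts: np.ndarray  # shape (n_doses, n_replicates)
    curve: DoseResponseCurve = field(repr=False)
    readout_model: ReadoutModel = field(repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        n_dose, n_rep = self.readouts.shape
        return pd.DataFrame(
            {
                "dose_uM": np.repeat(self.doses, n_rep),
                "replicate": np.tile(np.arange(1, n_rep + 1), n_dose),
                "readout": self.readouts.ravel(),
            }
        )


def generate_noisy(curve: DoseResponseCurve, readout: ReadoutModel) -> NoisyDoseResponse:
    """Simulate replicate readouts of a dose-response curve.

    Deterministic under a fixed seed. The lognormal factor has unit mean and
    the stated CV (σ² = ln(1+CV²), µ = −σ²/2).
    """
    rng = np.random.default_rng(readout.seed)
    mean = readout.link(curve.active)[:, None]
    shape = (curve.doses.size, readout.n_replicates)
    if readout.noise_cv == 0.0:
        values = np.broadcast_to(mean, shape).copy()
    else:
        sigma = np.sqrt(np.log1p(readout.noise_cv**2))
        values = mean * rng.lognormal(-0.5 * sigma**2, sigma, size=shape)
    return NoisyDoseResponse(
        doses=curve.doses.copy(), readouts=values, curve=curve, readout_model=readout
    )


@dataclass(frozen=True)
class PAEstimate:
    """PA observables estimated from replicate readouts.

    ``crossover_dose`` is the last dose whose replicate mean exceeds the
    dose-0 mean, log-interpolated to where the mean recrosses baseline;
    estimates censored at the top of the dose grid are reported as the top
    dose. Intervals are percentile bootstrap over replicate resampling.
    """

    baseline: float
    fold_change: float
    crossover_dose: float | None
    pa_detected: bool
    above_baseline: np.ndarray
    n_boot: int
    fold_ci: tuple[float, float] | None = None
    crossover_ci: tuple[float, float] | None = None

    def summary(self) -> str:
        lines = [
            "PA estimate from replicate readouts",
            f"  baseline readout        {self.baseline:.6g}",
            f"  fold change of means    {self.fold_change:.6g}",
            f"  PA detected             {self.pa_detected}",
        ]
        if self.crossover_dose is not None:
            lines.append(f"  crossover dose (uM)     {self.crossover_dose:.6g}")
        if self.fold_ci is not None:
            lines.append(
                f"  fold change 95% CI      [{self.fold_ci[0]:.6g}, {self.fold_ci[1]:.6g}]"
            )
        if self.crossover_ci is not None:
            lines.append(
                "  crossover 95% CI (uM)   "
                f"[{self.crossover_ci[0]:.6g}, {self.crossover_ci[1]:.6g}]"
            )
        lines.append(f"  bootstrap replicates    {self.n_boot}")
        return "\n".join(lines)


def _point_estimates(
    doses: np.ndarray, means: np.ndarray
) -> tuple[float, float, float | None, np.ndarray]:
    """(baseline, fold, crossover, above-flags) from per-dose means."""
    baseline = means[0]
    above = means[1:] > baseline
    fold = float(np.max(means) / baseline)
    if not above.any():
        return baseline, fold, None, above
    i = 1 + int(np.max(np.nonzero(above)[0]))  # last dose above baseline
    if i == len(doses) - 1:
        return baseline, fold, float(doses[-1]), above  # censored at grid top
    x0, x1 = np.log(doses[i]), np.log(doses[i + 1])
    y0, y1 = means[i] - baseline, means[i + 1] - baseline
    xc = x0 + (0.0 - y0) * (x1 - x0) / (y1 - y0)
    return baseline, fold, float(np.exp(xc)), above


def estimate_pa_from_noisy(
    data: NoisyDoseResponse, n_boot: int = 2000, seed: int = 0
) -> PAEstimate:
    """Estimate PA metrics from noisy replicates with bootstrap intervals.

    Requires at least two replicates per dose and dose 0 on the grid.
    ``n_boot = 0`` returns point estimates only.
    """
    doses, readouts = data.doses, data.readouts
    n_dose, n_rep = readouts.shape
    if n_rep < 2:
        raise ValidationError("at least 2 replicates per dose are required")
    if doses[0] != 0.0:
        raise ValidationError("dose grid must include dose 0 (baseline)")
    if np.any(np.all(readouts == 0.0, axis=1)):
        raise ValidationError("degenerate data: a dose with all-zero readouts")

    means = readouts.mean(axis=1)
    baseline, fold, crossover, above = _point_estimates(doses, means)
    est = PAEstimate(
        baseline=float(baseline),
        fold_change=fold,
        crossover_dose=crossover,
        pa_detected=bool(above.any()),
        above_baseline=above,
        n_boot=n_boot,
    )
    if n_boot <= 0:
        return est

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_rep, size=(n_boot, n_dose, n_rep))
    boot_means = np.take_along_axis(readouts[None, :, :], idx, axis=2).mean(axis=2)
    folds = np.empty(n_boot)
    cross = np.full(n_boot, np.nan)
    for b in range(n_boot):
        _, folds[b], cb, _ = _point_estimates(doses, boot_means[b])
        if cb is not None:
            cross[b] = cb
    fold_ci = (float(np.percentile(folds, 2.5)), float(np.percentile(folds, 97.5)))
    valid = np.isfinite(cross)
    crossover_ci = None
    if valid.any():
        crossover_ci = (
            float(np.percentile(cross[valid], 2.5)),
            float(np.percentile(cross[valid], 97.5)),
        )
    return PAEstimate(
        baseline=float(baseline),
        fold_change=fold,
        crossover_dose=crossover,
        pa_detected=bool(above.any()),
        above_baseline=above,
        n_boot=n_boot,
        fold_ci=fold_ci,
        crossover_ci=crossover_ci,
    )
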