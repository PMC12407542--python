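"""Figure-reproduction drivers: dose-response panels and contour sweeps.

Each driver writes tidy CSVs plus a JSON sidecar embedding the resolved run
configuration, so every artifact is reproducible from its sidecar alone.
Plotting is intentionally left to downstream consumers of the CSVs.
"""

from __future__ import annotations

import logging
import pathlib
import time

import numpy as np
import pandas as pd

from . import metrics
from .config import AxisSpec, RunConfig, write_sidecar
from .parameters import ModelVariant

log = logging.getLogger(__name__)

ALL_VARIANTS = (ModelVariant.CA, ModelVariant.CAS, ModelVariant.DS, ModelVariant.CAS_DS)
S_VARIANTS = (ModelVariant.CAS, ModelVariant.DS, ModelVariant.CAS_DS)


def _outdir(config: RunConfig) -> pathlib.Path:
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_fig2b(config: RunConfig) -> dict[str, pathlib.Path]:
    """Dose responses of all four variants, both normalizations.

    Writes one CSV per normalization (relative to drug-free baseline, and
    percent of total RAF) with all four variants' curves over the dose grid.
    """
    out = _outdir(config)
    t0 = time.perf_counter()
    doses = config.dose_grid.values()
    frames = []
    for variant in ALL_VARIANTS:
        curve = metrics.dose_response(
            variant, config.parameters, doses, mode=config.mode, engine=config.engine
        )
        frames.append(curve.to_dataframe())
    tidy = pd.concat(frames, ignore_index=True)
    paths = {}
    for norm, col in (
        ("relative", "active_rel_baseline"),
        ("percent", "active_pct_total"),
    ):
        sub = tidy[["variant", "engine", "mode", "dose_uM", col]]
        path = out / f"fig2b_{norm}.csv"
        sub.to_csv(path, index=False, float_format="%.12g")
        write_sidecar(path, config)
        paths[norm] = path
    log.info(
        "fig2b: %d variants x %d doses in %.2fs", len(ALL_VARIANTS), doses.size,
        time.perf_counter() - t0,
    )
    return paths


def _default_fig2c_axes(config: RunConfig) -> tuple[AxisSpec, AxisSpec, AxisSpec]:
    n = config.grid_n
    return (
        AxisSpec("K_A", 1e0, 1e3, n),
        AxisSpec("R_total", 1e-3, 1e1, n),
        AxisSpec("S_total", 1e-3, 1e2, n),
    )


def run_fig2c(config: RunConfig) -> dict[str, pathlib.Path]:
    """PA-range (crossover-dose) contour grids per 14-3-3 variant.

    For each variant, two grids: autoinhibition propensity K_A against total
    RAF, and K_A against total 14-3-3. Cells without PA hold NaN.
    """
    out = _outdir(config)
    ka, raf, s14 = _default_fig2c_axes(config)
    paths = {}
    for variant in S_VARIANTS:
        for other in (raf, s14):
            t0 = time.perf_counter()
            grid = metrics.sweep_grid(
                variant,
                config.parameters,
                (ka.name, ka.values()),
                (other.name, other.values()),
                metric="crossover_dose",
                mode="free_drug",
                engine="analytic",
            )
            key = f"fig2c_{variant.value}_{ka.name}_x_{other.name}"
            path = out / f"{key}.csv"
            grid.to_dataframe().to_csv(path, index=False, float_format="%.12g")
            write_sidecar(path, config)
            paths[key] = path
            log.info(
                "fig2c %s %sx%s: %dx%d cells in %.2fs", variant.value, ka.name,
                other.name, ka.n, other.n, time.perf_counter() - t0,
            )
    return paths


def run_s2_alpha(config: RunConfig) -> dict[str, pathlib.Path]:
    """CAS+DS metrics over total 14-3-3 × alpha.

    Four grids (baseline %, max %, fold change, PA range) over an S_total
    axis spanning 1e-3…1e2 µM against the alpha meta-parameter that trades
    DS strength (small alpha) against CAS strength (large alpha).
    """
    out = _outdir(config)
    s_axis = AxisSpec("S_total", 1e-3, 1e2, max(config.grid_n, 2))
    a_axis = AxisSpec("alpha", 1e-2, 1e2, max(config.grid_n, 2))
    paths = {}
    for metric in metrics.METRIC_NAMES:
        t0 = time.perf_counter()
        grid = metrics.sweep_grid(
            ModelVariant.CAS_DS,
            config.parameters,
            (s_axis.name, s_axis.values()),
            (a_axis.name, a_axis.values()),
            metric=metric,
            mode="free_drug",
            engine="analytic",
        )
        path = out / f"s2_alpha_{metric}.csv"
        grid.to_dataframe().to_csv(path, index=False, float_format="%.12g")
        write_sidecar(path, config)
        paths[metric] = path
        log.info("s2alpha %s in %.2fs", metric, time.perf_counter() - t0)
    return paths


def verify_engines(
    config: RunConfig, n_sets: int = 100
) -> pd.DataFrame:
    """Analytic-vs-oracle agreement report over random parameter draws.

    Draws parameter sets log-uniformly, evaluates the closed-form and
    mass-action active fractions under free clamping for every variant, and
    reports the relative discrepancies.
    """
    from . import analytic, oracle
    from .parameters import Parameters

    rng = np.random.default_rng(config.seed)
    rows = []
    for _ in range(n_sets):
        p = Parameters(
            K_A=10.0 ** rng.uniform(-1, 3),
            K_d=10.0 ** rng.uniform(-3, 1),
            K_dim=10.0 ** rng.uniform(-3, 1),
            K_Smon=10.0 ** rng.uniform(-3, 1),
            K_Sdim=10.0 ** rng.uniform(-3, 1),
            R_total=10.0 ** rng.uniform(-3, 1),
        )
        s_free = rng.uniform(0.0, 1e2)
        d_free = rng.uniform(0.0, 1e3) * p.K_d
        for variant in ALL_VARIANTS:
            a = analytic.active_fraction(variant, p, d_free, s_free)
            o = oracle.active_raf(oracle.solve_free_clamped(variant, p, d_free, s_free))
            rows.append(
                {
                    "variant": variant.value,
                    "d_free": d_free,
                    "s_free": s_free,
                    "analytic": a,
                    "oracle": o,
                    "rel_err": abs(a - o) / max(abs(o), 1e-300),
                }
            )
    return pd.DataFrame(rows)
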