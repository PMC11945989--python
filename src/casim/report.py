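"""Result serialisation: delimited tables, plots and a fit round-trip."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model_core import CasimFit, TimeSeriesDataset, predict
from .uncertainty import BootstrapResult, ConfidenceBounds

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"  # full double precision for round-trip fidelity


def fit_to_dict(fit: CasimFit) -> dict:
    return {
        "mu": fit.mu,
        "alpha": fit.weekly.alpha.tolist(),
        "default_day": fit.weekly.default_day,
        "xi": fit.growth.xi.tolist() if fit.growth is not None else None,
        "intervention": (
            [str(fit.growth.t_start.date()), str(fit.growth.t_end.date())]
            if fit.growth is not None
            else None
        ),
        "lags": fit.lags.tolist(),
        "covariates": fit.covariate_names,
        "monotone": list(fit.monotone),
        "theta": [w.theta.tolist() for w in fit.weights],
        "effects": [
            {
                "lag": g.transform.lag,
                "scale": g.transform.scale,
                "interior_knots": g.knots.interior.tolist(),
                "order": g.knots.order,
                "coefficients": np.asarray(g.coefficients).tolist(),
                "monotone": g.monotone,
                "centering_offset": g.centering_offset,
            }
            for g in fit.effects
        ],
        "mse": fit.mse,
        "aic": fit.aic,
        "n_used": fit.n_used,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "rss_trace": fit.rss_trace,
    }


def write_report(
    fit: CasimFit,
    bounds: ConfidenceBounds | None,
    outdir,
    dataset: TimeSeriesDataset | None = None,
    bootstrap: BootstrapResult | None = None,
    curve_grid_size: int = 100,
    plots: bool = True,
) -> dict[str, Path]:
    """Write parameter/lag/weight/curve/series tables and plots.

    All numerics are written at full double precision so re-reading a
    table reproduces the in-memory values exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    # parameter table (Estimate / Std. / bounds layout)
    names = ["mu"] + [f"xi_{k}" for k in range(1, 5)] + [f"alpha_{k}" for k in range(1, 7)]
    values = [fit.mu]
    values += list(fit.growth.xi) if fit.growth is not None else [np.nan] * 4
    values += list(fit.weekly.alpha)
    table = pd.DataFrame({"parameter": names, "estimate": values})
    if bounds is not None:
        remap = {f"xi_{k}": f"xi_{k}" for k in range(1, 5)}
        stds, los, his = [], [], []
        for name in names:
            key = remap.get(name, name)
            if key in bounds.scalars:
                lo, hi, sd, _ = bounds.scalars[key]
            else:
                lo = hi = sd = np.nan
            stds.append(sd)
            los.append(lo)
            his.append(hi)
        table["std"] = stds
        table[f"lower_{bounds.level:g}"] = los
        table[f"upper_{bounds.level:g}"] = his
    files["parameters"] = outdir / "parameters.csv"
    table.to_csv(files["parameters"], index=False, float_format=FLOAT_FMT)

    # lag table: one row per covariate
    files["lags"] = outdir / "lags.csv"
    pd.DataFrame({"covariate": fit.covariate_names, "lag": fit.lags}).to_csv(
        files["lags"], index=False
    )

    # per-lag weights with optional bands
    rows = []
    for j, (name, w) in enumerate(zip(fit.covariate_names, fit.weights)):
        for tau, th in enumerate(w.theta):
            row = {"covariate": name, "lag": tau, "weight": th}
            if bounds is not None:
                lo, hi, sd = bounds.theta_bands[j][:, tau]
                row.update(lower=lo, upper=hi, std=sd)
            rows.append(row)
    files["weights"] = outdir / "weights.csv"
    pd.DataFrame(rows).to_csv(files["weights"], index=False, float_format=FLOAT_FMT)

    # effect curves on index grids (bootstrap grids when bands exist)
    rows = []
    for j, (name, (w, g)) in enumerate(zip(fit.covariate_names, fit.blocks)):
        if bootstrap is not None:
            grid = bootstrap.curve_grids[j]
        else:
            grid = np.linspace(0.0, g.transform.scale, curve_grid_size)
        vals = g(grid)
        for i, v in enumerate(grid):
            row = {"covariate": name, "index": v, "effect": vals[i]}
            if bootstrap is not None and bounds is not None:
                lo, hi, sd = bounds.curve_bands[j][:, i]
                row.update(lower=lo, upper=hi, std=sd)
            rows.append(row)
    files["curves"] = outdir / "curves.csv"
    pd.DataFrame(rows).to_csv(files["curves"], index=False, float_format=FLOAT_FMT)

    # fitted/residual series
    if dataset is not None:
        frame = predict(fit, dataset)
        files["series"] = outdir / "series.csv"
        frame.to_csv(files["series"], index=False, float_format=FLOAT_FMT)

    files["fit"] = outdir / "fit.json"
    with open(files["fit"], "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=1)

    files["log"] = outdir / "run_log.txt"
    with open(files["log"], "w") as fh:
        fh.write(
            f"n_used={fit.n_used} converged={fit.converged} "
            f"iterations={fit.iterations}\nmse={fit.mse!r} aic={fit.aic!r}\n"
            "rss_trace=" + ",".join(repr(v) for v in fit.rss_trace) + "\n"
        )

    if plots:
        files.update(_write_plots(fit, bounds, outdir, dataset))
    logger.info("report written to %s", outdir)
    return files


def _write_plots(fit, bounds, outdir: Path, dataset) -> dict[str, Path]:
    files = {}
    p = len(fit.covariate_names)

    fig, axes = plt.subplots(1, p, figsize=(4 * p, 3), squeeze=False)
    for j, (name, w) in enumerate(zip(fit.covariate_names, fit.weights)):
        ax = axes[0][j]
        taus = np.arange(w.theta.size)
        ax.plot(taus, w.theta, "k.-")
        if bounds is not None:
            ax.plot(taus, bounds.theta_bands[j][0], "b--", lw=0.8)
            ax.plot(taus, bounds.theta_bands[j][1], "b--", lw=0.8)
        ax.set_title(f"{name} lag weights")
        ax.set_xlabel("lag (days)")
    fig.tight_layout()
    files["weights_plot"] = outdir / "weights.png"
    fig.savefig(files["weights_plot"], dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(1, p, figsize=(4 * p, 3), squeeze=False)
    for j, (name, (w, g)) in enumerate(zip(fit.covariate_names, fit.blocks)):
        ax = axes[0][j]
        grid = np.linspace(0.0, g.transform.scale, 100)
        ax.plot(grid, g(grid), "k-")
        ax.set_title(f"{name} cumulative effect")
        ax.set_xlabel("weighted average")
    fig.tight_layout()
    files["curves_plot"] = outdir / "curves.png"
    fig.savefig(files["curves_plot"], dpi=110)
    plt.close(fig)

    if dataset is not None:
        frame = predict(fit, dataset)
        fig, axes = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
        axes[0].plot(frame["date"], frame["log_observed"], "b.", ms=2, label="observed")
        axes[0].plot(frame["date"], frame["log_fitted"], "k-", lw=0.8, label="fitted")
        axes[0].set_ylabel("log scale")
        axes[0].legend(loc="best")
        axes[1].plot(frame["date"], frame["log_residual"], "k-", lw=0.5)
        axes[1].set_ylabel("residual")
        fig.tight_layout()
        files["series_plot"] = outdir / "series.png"
        fig.savefig(files["series_plot"], dpi=110)
        plt.close(fig)
    return files
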