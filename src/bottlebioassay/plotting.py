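"""Concentration-response plots with min-max uncertainty ribbons.

One panel per species-insecticide pair: a posterior-median curve per
institution on a log10 concentration axis, a shaded ribbon spanning the
per-bioassay fit curves, and the observed response proportions sized by the
number of mosquitoes.  Curves are drawn only across the observed
concentration range (no extrapolation).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import PosteriorDraws, mortality_curve
from .pipeline import ScopeResult

__all__ = ["plot_scope", "plot_campaign"]


def _median_curve(draws: PosteriorDraws, xs: np.ndarray) -> np.ndarray:
    return np.asarray(mortality_curve(draws.posterior_median_params(), xs))


def plot_scope(ax: plt.Axes, result: ScopeResult, color: str = "C0") -> None:
    """Draw one institution's fit onto an axes."""
    treated = [(x, n, y) for x, n, y in result.data if x > 0]
    xs_obs = np.array([x for x, _, _ in treated])
    obs = np.array([y / n for _, n, y in treated])
    sizes = np.array([n for _, n, _ in treated], dtype=float)
    grid = np.geomspace(xs_obs.min(), xs_obs.max(), 200)

    median = _median_curve(result.pooled, grid)
    label = result.scope.get("institution", "")
    ax.plot(grid, median, color=color, lw=2, label=label)

    rep_curves = [
        _median_curve(rep, grid) for rep in result.per_replicate.values() if rep.converged
    ]
    if len(rep_curves) >= 2:
        band = np.vstack(rep_curves)
        ax.fill_between(grid, band.min(axis=0), band.max(axis=0), color=color, alpha=0.2)
    elif len(rep_curves) <= 1:
        ax.annotate(
            "single curve (one replicate)",
            xy=(0.02, 0.95), xycoords="axes fraction", fontsize=7, color=color,
        )
    ax.scatter(xs_obs, obs, s=10 + sizes / 4, color=color, alpha=0.6, edgecolor="none")
    ax.set_xscale("log")
    ax.set_ylim(-0.02, 1.02)


def plot_campaign(
    results: Sequence[ScopeResult], out_dir: str | Path, fmt: str = "png"
) -> list[Path]:
    """One figure per species-insecticide pair; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panels: dict[tuple[str, str], list[ScopeResult]] = {}
    for r in results:
        panels.setdefault((r.scope["species"], r.scope["insecticide"]), []).append(r)
    written: list[Path] = []
    for (species, insecticide), group in sorted(panels.items()):
        fig, ax = plt.subplots(figsize=(5.5, 4))
        for i, result in enumerate(group):
            plot_scope(ax, result, color=f"C{i % 10}")
        endpoint = group[0].scope.get("endpoint_type", "mortality")
        ylabel = "Oviposition inhibition" if endpoint == "oviposition" else "Mortality"
        ax.set_xlabel("Concentration (µg/bottle)")
        ax.set_ylabel(f"{ylabel} (proportion)")
        ax.set_title(f"{species} — {insecticide}")
        ax.legend(fontsize=7, loc="lower right")
        fig.tight_layout()
        slug = f"{species}_{insecticide}".replace(" ", "_").replace(".", "")
        path = out_dir / f"curve_{slug}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
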