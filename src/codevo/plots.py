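"""Minimal plotting helpers mirroring the standard output figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_growth_curve", "plot_population_trajectory", "plot_maturity_ogive"]


def plot_growth_curve(curve: pd.DataFrame, path: str | Path | None = None):
    """Length-at-age with +/- SD band (output of summaries.growth_curve)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(curve["age"], curve["mean_length"], yerr=curve["sd_length"],
                fmt="o-", capsize=2)
    ax.set_xlabel("age (yr)")
    ax.set_ylabel("length (cm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_population_trajectory(summary: pd.DataFrame, path: str | Path | None = None):
    """Yearly abundance and biomass of one replicate."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(summary["year"], summary["n"], label="N")
    ax2 = ax.twinx()
    ax2.plot(summary["year"], summary["biomass"], color="tab:orange", label="biomass")
    ax.set_xlabel("year")
    ax.set_ylabel("individuals")
    ax2.set_ylabel("biomass (kg)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_maturity_ogive(ogive: pd.DataFrame, path: str | Path | None = None):
    """Proportion mature at age (output of summaries.proportion_mature_at_age)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(ogive["age"], ogive["prop_mature"], yerr=ogive["sd"], fmt="s-", capsize=2)
    ax.set_xlabel("age (yr)")
    ax.set_ylabel("proportion mature")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
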