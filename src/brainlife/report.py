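"""Reporting: predicted-vs-observed tables, stage-annotated figures, exports.

The report mirrors how life-history predictions are usually presented: a
small table of switching times, adult masses, encephalization quotient and
R0 (with an observed column when the user supplies measurements), plus
trajectory figures — tissue masses, growth metabolic rate, and skill against
age, with life stages shaded, and the (median-filtered) allocation schedule.

Observed ontogenetic series are deliberately *not* bundled with the package;
any CSV with columns ``age, body_mass, brain_mass`` can be overlaid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Union

import numpy as np
import pandas as pd

from .optimal_control import LifeHistorySummary, filter_control_for_report
from .physiology import encephalization_quotient

if TYPE_CHECKING:  # pragma: no cover
    from .trajectory import StateTrajectory

__all__ = ["ObservedSeries", "report", "summary_table"]

_STAGE_COLORS = {
    "ante_childhood": "#f5e6cc",
    "childhood_proper": "#f8d0d0",
    "preadolescence": "#fbe9e9",
    "adolescence": "#d4e4f7",
    "adulthood": "#e8f0e8",
}


@dataclass(frozen=True)
class ObservedSeries:
    """Observed ontogenetic masses: ages (years), body and brain mass (kg)."""

    age: np.ndarray
    body_mass: np.ndarray
    brain_mass: np.ndarray
    source: str = "user-supplied"

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=float)
        body = np.asarray(self.body_mass, dtype=float)
        brain = np.asarray(self.brain_mass, dtype=float)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "body_mass", body)
        object.__setattr__(self, "brain_mass", brain)
        if age.size == 0 or age.size != body.size or age.size != brain.size:
            raise ValueError("age, body_mass and brain_mass must have equal, nonzero length")
        if np.any(age < 0) or np.any(np.diff(age) <= 0):
            raise ValueError("ages must be non-negative and strictly increasing")
        if np.any(body <= 0) or np.any(brain <= 0):
            raise ValueError("masses must be positive")

    @classmethod
    def from_csv(cls, path: Union[str, Path], source: Optional[str] = None) -> "ObservedSeries":
        df = pd.read_csv(path, comment="#")
        missing = {"age", "body_mass", "brain_mass"} - set(df.columns)
        if missing:
            raise ValueError(f"observed CSV lacks column(s): {sorted(missing)}")
        return cls(df["age"].to_numpy(), df["body_mass"].to_numpy(),
                   df["brain_mass"].to_numpy(), source or str(path))

    @property
    def adult_body_mass(self) -> float:
        return float(self.body_mass[-1])

    @property
    def adult_brain_mass(self) -> float:
        return float(self.brain_mass[-1])


def summary_table(summary: LifeHistorySummary,
                  observed: Optional[ObservedSeries] = None) -> pd.DataFrame:
    """Predicted (and optionally observed) life-history quantities.

    The observed EQ is computed from the observed series' adult masses with
    the same allometric formula used for the prediction.
    """
    rows = {
        "maturity t_m [y]": summary.t_m,
        "adulthood t_a [y]": summary.t_a,
        "brain growth onset t_b0 [y]": summary.t_b0,
        "brain growth arrest t_b [y]": summary.t_b,
        "adult body mass [kg]": summary.adult_body_mass,
        "adult brain mass [kg]": summary.adult_brain_mass,
        "adult reproductive mass [kg]": summary.adult_reproductive_mass,
        "EQ [-]": summary.EQ,
        "asymptotic skill [skill]": summary.asymptotic_skill,
        "R0 [offspring]": summary.R0,
    }
    df = pd.DataFrame({"predicted": rows})
    if observed is not None:
        obs = {
            "adult body mass [kg]": observed.adult_body_mass,
            "adult brain mass [kg]": observed.adult_brain_mass,
            "EQ [-]": encephalization_quotient(observed.adult_brain_mass,
                                               observed.adult_body_mass),
        }
        df["observed"] = pd.Series(obs)
    return df


def _shade_stages(ax, traj: "StateTrajectory", labels) -> None:
    t = np.asarray(traj.t)
    labels = list(labels)
    start = 0
    for i in range(1, len(t) + 1):
        if i == len(t) or labels[i] != labels[start]:
            color = _STAGE_COLORS.get(labels[start])
            if color:
                ax.axvspan(t[start], t[min(i, len(t) - 1)], color=color, zorder=0)
            start = i


def report(summary: LifeHistorySummary, traj: "StateTrajectory",
           observed: Optional[ObservedSeries] = None,
           out_dir: Union[str, Path] = "report",
           make_plots: bool = True) -> dict:
    """Write the report bundle and return the paths written.

    Produces ``summary.json``, ``summary_table.txt`` / ``.csv``,
    ``trajectory.csv``, and (unless ``make_plots`` is false) three figures:
    masses vs age with stages shaded, growth metabolic rate and skill vs
    age, and the median-filtered allocation schedule.  With no observed
    series the table simply has no observed column.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    table = summary_table(summary, observed)
    paths["summary_json"] = out / "summary.json"
    paths["summary_json"].write_text(json.dumps(summary.as_dict(), indent=1))
    paths["summary_txt"] = out / "summary_table.txt"
    paths["summary_txt"].write_text(table.to_string(float_format=lambda v: f"{v:.4g}") + "\n")
    paths["summary_csv"] = out / "summary_table.csv"
    table.to_csv(paths["summary_csv"])
    paths["trajectory_csv"] = traj.to_csv(out / "trajectory.csv")

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        labels = summary.stage_labels or ["adulthood"] * len(traj.t)

        fig, ax = plt.subplots(figsize=(7, 4.5))
        _shade_stages(ax, traj, labels)
        ax.plot(traj.t, traj.body_mass, label="body $x_B$", color="tab:blue")
        ax.plot(traj.t, traj.x_s, label="soma $x_s$", color="tab:gray")
        ax.plot(traj.t, traj.x_b, label="brain $x_b$", color="tab:red")
        ax.plot(traj.t, traj.x_r, label="reproductive $x_r$", color="tab:purple")
        if observed is not None:
            ax.plot(observed.age, observed.body_mass, "o", ms=4, mfc="none",
                    color="tab:blue", label="observed body")
            ax.plot(observed.age, observed.brain_mass, "o", ms=4, mfc="none",
                    color="tab:red", label="observed brain")
        ax.set_xlabel("age [y]")
        ax.set_ylabel("mass [kg]")
        ax.legend(fontsize=8)
        fig.tight_layout()
        paths["masses_png"] = out / "masses_vs_age.png"
        fig.savefig(paths["masses_png"], dpi=120)
        plt.close(fig)

        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
        _shade_stages(ax1, traj, labels)
        ax1.plot(traj.t, traj.B_syn, color="tab:green")
        ax1.set_ylabel("growth metabolic rate [MJ/y]")
        _shade_stages(ax2, traj, labels)
        ax2.plot(traj.t, traj.x_k, color="tab:orange")
        ax2.set_ylabel("skill level [skill]")
        ax2.set_xlabel("age [y]")
        fig.tight_layout()
        paths["energy_skill_png"] = out / "growth_rate_and_skill.png"
        fig.savefig(paths["energy_skill_png"], dpi=120)
        plt.close(fig)

        smoothed = filter_control_for_report(traj.control)
        fig, ax = plt.subplots(figsize=(7, 3.5))
        mesh, vals = smoothed.mesh, smoothed.constant_values()
        for j, (name, color) in enumerate(
                [("$u_b$ brain", "tab:red"), ("$u_r$ reproductive", "tab:purple"),
                 ("$u_s$ soma", "tab:gray")]):
            ax.stairs(vals[:, j], mesh, label=name, color=color)
        ax.set_xlabel("age [y]")
        ax.set_ylabel("allocation fraction")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=8)
        fig.tight_layout()
        paths["control_png"] = out / "allocation_schedule.png"
        fig.savefig(paths["control_png"], dpi=120)
        plt.close(fig)

    return paths
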