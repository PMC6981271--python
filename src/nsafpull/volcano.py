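"""Hyperbolic volcano-plot threshold and interactor classification.

A protein is called an interactor of one bait form when its volcano point
(a, b) clears both a fold-change gate and a significance curve::

    f(x) = 1 / (x**2 - n) + m

* P-side interactor:  a >  sqrt(n)  and  b > f(a)
* NP-side interactor: a < -sqrt(n)  and  b > f(a)

with strict inequalities.  Defaults n = 1.35 and m = 5 place the vertical
asymptotes at ±sqrt(1.35) ≈ ±1.162 on the log2-ratio axis and the
horizontal asymptote at b = 5 (p ≈ 0.316 on the -10·log10 scale), so the
curve demands progressively stronger significance as the fold change
shrinks toward the gate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import DiffResult


@dataclass(frozen=True)
class ThresholdParams:
    """Curve parameters: ``n`` on the ratio axis, ``m`` on the significance axis."""

    n: float = 1.35
    m: float = 5.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.m < 0:
            raise ValueError("m must be non-negative")

    @property
    def x_gate(self) -> float:
        """The fold-change gate sqrt(n); also the curve's vertical asymptote."""
        return math.sqrt(self.n)


class CallClass(str, enum.Enum):
    P_SIGNIFICANT = "P_SIGNIFICANT"
    NP_SIGNIFICANT = "NP_SIGNIFICANT"
    NON_SIGNIFICANT = "NON_SIGNIFICANT"


@dataclass(frozen=True)
class VolcanoCall:
    accession: str
    a: float
    b: float
    class_label: CallClass


def threshold_curve(x, params: ThresholdParams = ThresholdParams()):
    """Evaluate ``f(x) = 1/(x^2 - n) + m`` where defined.

    Returns NaN wherever ``x**2 <= n`` (at or inside the vertical
    asymptotes, where no point can pass).  Accepts scalars or arrays.
    """
    x_arr = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 / (x_arr**2 - params.n) + params.m
    out = np.where(x_arr**2 > params.n, f, np.nan)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(out)
    return out


def classify_point(
    a: float, b: float, params: ThresholdParams = ThresholdParams()
) -> CallClass:
    """Classify one volcano point; inequalities are strict."""
    gate = params.x_gate
    if a > gate and b > threshold_curve(a, params):
        return CallClass.P_SIGNIFICANT
    if a < -gate and b > threshold_curve(a, params):
        return CallClass.NP_SIGNIFICANT
    return CallClass.NON_SIGNIFICANT


def classify(
    results: Iterable[DiffResult], params: ThresholdParams = ThresholdParams()
) -> list[VolcanoCall]:
    return [
        VolcanoCall(r.accession, r.a, r.b, classify_point(r.a, r.b, params))
        for r in results
    ]


def calls_to_frame(calls: Iterable[VolcanoCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": c.accession,
                "a": c.a,
                "b": c.b,
                "class": c.class_label.value,
            }
            for c in calls
        ],
        columns=["accession", "a", "b", "class"],
    )


def export_volcano(
    calls: Sequence[VolcanoCall],
    params: ThresholdParams,
    out_prefix: str | Path,
    formats: Sequence[str] = ("svg", "png"),
) -> list[Path]:
    """Write the points TSV and the rendered volcano figure.

    Produces ``<out_prefix>_points.tsv`` plus ``<out_prefix>.<fmt>`` for
    each requested format.  Both threshold-curve branches are drawn on
    |x| in (sqrt(n)+eps, x_max]; eps is chosen so the curve is clipped at
    the plot's top, which is purely cosmetic.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    points_path = out_prefix.with_name(out_prefix.name + "_points.tsv")
    calls_to_frame(calls).to_csv(points_path, sep="\t", index=False)
    written.append(points_path)

    a_vals = np.array([c.a for c in calls]) if calls else np.array([0.0])
    b_vals = np.array([c.b for c in calls]) if calls else np.array([0.0])
    x_max = max(3.5, float(np.max(np.abs(a_vals))) * 1.1 + 0.3)
    b_top = max(params.m * 4.0, float(np.max(b_vals)) * 1.1 + 1.0)
    gate = params.x_gate
    # start the branch where f(x) = b_top so the drawn curve is clipped
    # exactly at the axis top
    eps = math.sqrt(params.n + 1.0 / (b_top - params.m)) - gate
    xs = np.linspace(gate + eps, x_max, 400)

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {
        CallClass.P_SIGNIFICANT: "#c0392b",
        CallClass.NP_SIGNIFICANT: "#2980b9",
        CallClass.NON_SIGNIFICANT: "#95a5a6",
    }
    for label in CallClass:
        pts = [c for c in calls if c.class_label == label]
        if pts:
            ax.scatter(
                [c.a for c in pts],
                [c.b for c in pts],
                s=14,
                c=colors[label],
                label=f"{label.value} ({len(pts)})",
                alpha=0.8,
                linewidths=0,
            )
    curve = threshold_curve(xs, params)
    ax.plot(xs, curve, "k--", lw=1)
    ax.plot(-xs, curve, "k--", lw=1)
    ax.set_xlim(-x_max, x_max)
    ax.set_ylim(0, b_top)
    ax.set_xlabel(r"$\log_2(\mathrm{Mean}_P / \mathrm{Mean}_{NP})$")
    ax.set_ylabel(r"$-10\,\log_{10}(p)$")
    if calls:
        ax.legend(loc="upper center", fontsize=8)
    fig.tight_layout()
    for fmt in formats:
        fig_path = out_prefix.with_suffix(f".{fmt}")
        fig.savefig(fig_path)
        written.append(fig_path)
    plt.close(fig)
    return written
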