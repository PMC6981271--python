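"""Per-protein differential statistics between the P and NP conditions.

Each protein's replicate NSAF values are compared with a two-tailed
unequal-variance (Welch) t-test.  The volcano coordinates are

* ``a = log2(mean_P / mean_NP)`` — effect size, and
* ``b = -10 * log10(p)`` — significance,

with the p value clamped below at ``p_floor`` so ``b`` stays finite.
No multiple-testing correction is applied: downstream calls are gated by
the hyperbolic threshold curve rather than by an FDR adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import StudyDesign
from .nsaf import NSAFMatrix, condition_means

DEFAULT_P_FLOOR = 1e-300


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float


def welch_t_test(
    group1: Sequence[float], group2: Sequence[float]
) -> WelchResult:
    """Two-tailed Welch t-test with Welch–Satterthwaite degrees of freedom.

    ``t = (mean1 - mean2) / sqrt(s1^2/n1 + s2^2/n2)`` with the two-tailed
    p value from the t distribution.  Degenerate inputs where both sample
    variances vanish return ``(t=0, p=1)`` for equal means and
    ``(t=±inf, p=0)`` for unequal means (callers clamp p at their floor).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    m1, m2 = float(np.mean(x)), float(np.mean(y))
    # a constant group has variance exactly 0; np.var can return a few
    # ulp^2 of noise there because the mean of n equal values may round
    v1 = 0.0 if np.ptp(x) == 0 else float(np.var(x, ddof=1))
    v2 = 0.0 if np.ptp(y) == 0 else float(np.var(y, ddof=1))
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0)
        t = math.inf if m1 > m2 else -math.inf
        return WelchResult(t, float(n1 + n2 - 2), 0.0)
    se1, se2 = v1 / n1, v2 / n2
    t = (m1 - m2) / math.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t, df, min(p, 1.0))


@dataclass(frozen=True)
class DiffResult:
    """Differential summary for one protein."""

    accession: str
    mean_P: float
    mean_NP: float
    a: float  # log2(mean_P / mean_NP)
    t_stat: float
    df: float
    p_value: float  # clamped at p_floor
    b: float  # -10 * log10(p_value) by default
    p_floored: bool


def minus_ten_log(p: float, base: float = 10.0) -> float:
    """``-10 * log_base(p)``; base 10 is the volcano-plot convention."""
    if base == 10.0:
        return -10.0 * math.log10(p)
    return -10.0 * math.log(p) / math.log(base)


def differential_table(
    nsaf: NSAFMatrix,
    design: StudyDesign,
    p_floor: float = DEFAULT_P_FLOOR,
    log_base: float = 10.0,
) -> list[DiffResult]:
    """One DiffResult per protein, sorted by accession.

    The t-test is applied to the NSAF values directly (no log transform),
    comparing the P replicates against the NP replicates.  p values are
    clamped below at ``p_floor`` before computing ``b``; clamped proteins
    carry ``p_floored=True``.
    """
    if not 0.0 < p_floor < 1.0:
        raise ValueError("p_floor must lie in (0, 1)")
    df_nsaf = nsaf.to_frame()
    means = condition_means(nsaf, design)
    cols_p = design.samples_for("P")
    cols_np = design.samples_for("NP")
    results: list[DiffResult] = []
    for acc in sorted(nsaf.proteins):
        row = df_nsaf.loc[acc]
        welch = welch_t_test(row[cols_p].to_numpy(), row[cols_np].to_numpy())
        mean_p = float(means.loc[acc, "mean_P"])
        mean_np = float(means.loc[acc, "mean_NP"])
        # difference of logs rather than log of quotient: bit-exactly
        # antisymmetric under a P/NP label swap
        a = math.log2(mean_p) - math.log2(mean_np)
        floored = welch.p_value < p_floor
        p = max(welch.p_value, p_floor)
        results.append(
            DiffResult(
                accession=acc,
                mean_P=mean_p,
                mean_NP=mean_np,
                a=a,
                t_stat=welch.t_stat,
                df=welch.df,
                p_value=p,
                b=minus_ten_log(p, log_base),
                p_floored=floored,
            )
        )
    return results


def diff_to_frame(
    results: Iterable[DiffResult],
    gene_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "accession": r.accession,
                "gene": (gene_map or {}).get(r.accession, ""),
                "mean_P": r.mean_P,
                "mean_NP": r.mean_NP,
                "log2_ratio": r.a,
                "t_stat": r.t_stat,
                "df": r.df,
                "p_value": r.p_value,
                "minus10log10p": r.b,
                "p_floored_flag": int(r.p_floored),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "gene",
            "mean_P",
            "mean_NP",
            "log2_ratio",
            "t_stat",
            "df",
            "p_value",
            "minus10log10p",
            "p_floored_flag",
        ],
    )


def write_differential(
    results: Iterable[DiffResult],
    path: str | Path,
    gene_map: Mapping[str, str] | None = None,
) -> None:
    diff_to_frame(results, gene_map).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
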