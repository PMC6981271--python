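"""Synthetic pull-down spectral-count tables with known ground truth.

The generator emulates the statistical structure of a triplicate
two-condition pull-down identification list: hundreds of background
proteins sharing the same relative abundance across conditions, a small
set of spiked proteins enriched ``fold_change``-fold on one side, variable
protein lengths, per-sample sampling depth, and overdispersed counts with
frequent zeros.

Counts are negative binomial around a per-sample expectation::

    E[SpC_{k,s}] = D_s * share_{k,c(s)},   Var = mu + dispersion * mu^2

where the per-condition share of protein k is proportional to
``alpha_k * L_k**length_exponent`` (abundance times a sub-linear
length-linked peptide yield, so the NSAF 1/L correction is genuinely
exercised), multiplied by ``fold_change`` for spiked proteins in their
enriched condition, renormalized within the condition.  Sample depth
``D_s`` is log-normal with mean ``depth_mean`` and CV ``depth_cv``.
Spiked proteins draw their abundance from the upper quartile of the
background log-normal so triplicate power is non-trivial but achievable.

Because an identification list only contains proteins that were actually
identified, each protein's count vector is drawn conditioned on at least
one spectrum across the runs (exact conditional sampling); per-sample
zeros remain frequent, all-zero rows never occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ProteinRecord, SampleInfo, StudyDesign
from .volcano import CallClass, VolcanoCall

BACKGROUND = "BACKGROUND"
SPIKED_P = "SPIKED_P"
SPIKED_NP = "SPIKED_NP"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pull-down.

    Defaults mirror a typical triplicate bait-vs-control experiment:
    ~500 background proteins, 15 spikes per side at 8-fold enrichment,
    ~3000 spectra per run.
    """

    n_background: int = 500
    n_spiked_P: int = 15
    n_spiked_NP: int = 15
    fold_change: float = 8.0
    replicates_per_condition: int = 3
    depth_mean: float = 3000.0
    depth_cv: float = 0.15
    abundance_sigma: float = 1.5  # log-normal sigma of relative abundances
    length_range: tuple[int, int] = (80, 2000)  # aa, log-uniform
    length_exponent: float = 0.7  # peptide yield ~ L**exponent
    count_dispersion: float = 0.2  # NB overdispersion; 0 -> Poisson
    spike_quantile: float = 0.75  # spikes drawn above this abundance quantile
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_background < 0:
            bad.append("n_background")
        if self.n_spiked_P < 0:
            bad.append("n_spiked_P")
        if self.n_spiked_NP < 0:
            bad.append("n_spiked_NP")
        if self.fold_change <= 0:
            bad.append("fold_change")
        if self.replicates_per_condition < 2:
            bad.append("replicates_per_condition")
        if self.depth_mean <= 0:
            bad.append("depth_mean")
        if self.depth_cv < 0:
            bad.append("depth_cv")
        if self.abundance_sigma <= 0:
            bad.append("abundance_sigma")
        if not (1 <= self.length_range[0] <= self.length_range[1]):
            bad.append("length_range")
        if self.count_dispersion < 0:
            bad.append("count_dispersion")
        if not 0.0 <= self.spike_quantile < 1.0:
            bad.append("spike_quantile")
        if bad:
            raise ValueError(f"invalid SimulationConfig field(s): {bad}")

    @property
    def n_proteins(self) -> int:
        return self.n_background + self.n_spiked_P + self.n_spiked_NP


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth labels and parameters for a simulated table."""

    labels: dict[str, str]  # accession -> BACKGROUND | SPIKED_P | SPIKED_NP
    abundance: dict[str, float]  # accession -> true relative abundance
    fold_change: dict[str, float]  # accession -> true P/NP fold change

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "accession": list(self.labels),
                "label": [self.labels[a] for a in self.labels],
                "true_abundance": [self.abundance[a] for a in self.labels],
                "true_fold_change": [self.fold_change[a] for a in self.labels],
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _lognormal_depths(
    rng: np.random.Generator, n: int, mean: float, cv: float
) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma = math.sqrt(math.log1p(cv**2))
    mu = math.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=n)


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _nb_zero_prob(mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return np.exp(-mu)
    r = 1.0 / dispersion
    return (r / (r + mu)) ** r


def _nb_positive(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Draw counts from the zero-truncated negative binomial (>= 1)."""
    p0 = _nb_zero_prob(mu, dispersion)
    u = p0 + rng.uniform(size=mu.shape) * (1.0 - p0)
    u = np.minimum(u, np.nextafter(1.0, 0.0))
    if dispersion == 0:
        return sps.poisson.ppf(u, mu).astype(int)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return sps.nbinom.ppf(u, r, p).astype(int)


def _detected_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Sample a counts matrix with each row conditioned on detection.

    An identification list only contains proteins with at least one
    spectrum in at least one run, so each protein's count vector is drawn
    from the product negative-binomial distribution conditioned on not
    being all zero.  Sampling is exact (sequential conditioning on the
    suffix all-zero probability), not rejection, so it stays fast for
    proteins whose expected counts are far below one.
    """
    n, s = mu.shape
    p0 = _nb_zero_prob(mu, dispersion)
    # suffix[:, j] = P(columns j..s-1 all zero)
    suffix = np.ones((n, s + 1))
    for j in range(s - 1, -1, -1):
        suffix[:, j] = suffix[:, j + 1] * p0[:, j]
    counts = np.zeros((n, s), dtype=int)
    alive = np.ones(n, dtype=bool)  # all columns so far zero
    for j in range(s):
        mu_j = mu[:, j]
        free = ~alive
        if free.any():
            counts[free, j] = _nb_counts(rng, mu_j[free], dispersion)
        if alive.any():
            # P(X_j = 0 | remaining columns not all zero)
            with np.errstate(divide="ignore", invalid="ignore"):
                p_zero = (
                    p0[:, j] * (1.0 - suffix[:, j + 1]) / (1.0 - suffix[:, j])
                )
            u = rng.uniform(size=n)
            stays_zero = alive & (u < p_zero)
            becomes_pos = alive & ~stays_zero
            if becomes_pos.any():
                counts[becomes_pos, j] = _nb_positive(
                    rng, mu_j[becomes_pos], dispersion
                )
            alive = stays_zero
    return counts


def simulate_pulldown(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], StudyDesign, SyntheticTruth]:
    """Generate a counts table, its design, and the ground truth.

    Fully reproducible from ``config.seed``.  Peptide-evidence columns are
    filled so the default identification filters pass:
    ``total_peptides = max(2, ceil(total SpC / 3))``, ``unique_peptides >= 1``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    if n == 0:
        raise ValueError("invalid SimulationConfig field(s): ['n_background']")

    labels = (
        [BACKGROUND] * config.n_background
        + [SPIKED_P] * config.n_spiked_P
        + [SPIKED_NP] * config.n_spiked_NP
    )
    lo, hi = config.length_range
    lengths = np.exp(
        rng.uniform(math.log(lo), math.log(hi), size=n)
    ).astype(int)
    lengths = np.clip(lengths, lo, hi)

    # relative abundances: background from the full log-normal, spikes
    # from its upper tail (above spike_quantile)
    u = rng.uniform(size=n)
    is_spiked = np.array([lab != BACKGROUND for lab in labels])
    u = np.where(is_spiked, config.spike_quantile + u * (1 - config.spike_quantile), u)
    alpha = np.exp(config.abundance_sigma * sps.norm.ppf(u))

    base_weight = alpha * lengths.astype(float) ** config.length_exponent
    share = {}
    for cond in ("P", "NP"):
        w = base_weight.copy()
        for k, lab in enumerate(labels):
            if (lab == SPIKED_P and cond == "P") or (
                lab == SPIKED_NP and cond == "NP"
            ):
                w[k] *= config.fold_change
        share[cond] = w / w.sum()

    reps = config.replicates_per_condition
    samples = tuple(
        SampleInfo(f"{cond}{i}", cond, i)
        for cond in ("P", "NP")
        for i in range(1, reps + 1)
    )
    design = StudyDesign(samples)
    depths = _lognormal_depths(rng, len(samples), config.depth_mean, config.depth_cv)

    mu = np.column_stack(
        [depths[j] * share[s.condition] for j, s in enumerate(design.samples)]
    )
    # every listed protein was identified at least once: counts are drawn
    # conditioned on >= 1 spectrum across the runs
    counts = _detected_counts(rng, mu, config.count_dispersion)

    records: list[ProteinRecord] = []
    truth_labels: dict[str, str] = {}
    truth_alpha: dict[str, float] = {}
    truth_fold: dict[str, float] = {}
    for k in range(n):
        acc = f"SYN{k:04d}"
        total_spc = int(counts[k].sum())
        total_pep = max(2, math.ceil(total_spc / 3))
        records.append(
            ProteinRecord(
                accession=acc,
                gene_symbol=f"G{k:04d}",
                species_tag="SYNT",
                length_aa=int(lengths[k]),
                total_peptides=total_pep,
                unique_peptides=max(1, total_pep // 2),
                spc={s: int(c) for s, c in zip(design.sample_ids, counts[k])},
            )
        )
        truth_labels[acc] = labels[k]
        truth_alpha[acc] = float(alpha[k])
        if labels[k] == SPIKED_P:
            truth_fold[acc] = config.fold_change
        elif labels[k] == SPIKED_NP:
            truth_fold[acc] = 1.0 / config.fold_change
        else:
            truth_fold[acc] = 1.0
    truth = SyntheticTruth(truth_labels, truth_alpha, truth_fold)
    return records, design, truth


def evaluate_calls(
    calls: Iterable[VolcanoCall], truth: SyntheticTruth
) -> dict[str, float]:
    """Confusion-matrix summaries of volcano calls against ground truth.

    SPIKED_P is judged against P_SIGNIFICANT calls and SPIKED_NP against
    NP_SIGNIFICANT calls.  ``fpr_background`` is the fraction of background
    proteins called significant on either side.  Precision is NaN when a
    side has no calls.
    """
    calls = list(calls)
    call_acc = {c.accession for c in calls}
    if call_acc != set(truth.labels):
        raise ValueError("calls and truth cover different accession sets")

    def _side(call_label: CallClass, truth_label: str) -> tuple[float, float]:
        called = [c for c in calls if c.class_label == call_label]
        true_set = {a for a, lab in truth.labels.items() if lab == truth_label}
        tp = sum(1 for c in called if c.accession in true_set)
        recall = tp / len(true_set) if true_set else math.nan
        precision = tp / len(called) if called else math.nan
        return recall, precision

    recall_p, precision_p = _side(CallClass.P_SIGNIFICANT, SPIKED_P)
    recall_np, precision_np = _side(CallClass.NP_SIGNIFICANT, SPIKED_NP)
    background = {a for a, lab in truth.labels.items() if lab == BACKGROUND}
    fp_bg = sum(
        1
        for c in calls
        if c.accession in background
        and c.class_label != CallClass.NON_SIGNIFICANT
    )
    return {
        "recall_P": recall_p,
        "precision_P": precision_p,
        "recall_NP": recall_np,
        "precision_NP": precision_np,
        "fpr_background": fp_bg / len(background) if background else math.nan,
        "n_called_P": float(
            sum(1 for c in calls if c.class_label == CallClass.P_SIGNIFICANT)
        ),
        "n_called_NP": float(
            sum(1 for c in calls if c.class_label == CallClass.NP_SIGNIFICANT)
        ),
    }
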