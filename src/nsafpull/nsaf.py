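"""Pseudocounted Normalized Spectral Abundance Factor (NSAF).

For protein ``k`` with spectral count ``SpC_k`` and length ``L_k`` (amino
acids) in one sample::

    NSAF_k = ((SpC_k + 1) / L_k) / sum_i ((SpC_i + 1) / L_i)

The +1 pseudocount keeps zero-count proteins at a finite, strictly positive
abundance, so log ratios between conditions are always defined.  The
length division corrects for longer proteins yielding more peptides, and
the per-sample denominator corrects for differences in sampling depth
between runs.

By default the denominator runs over the union of all filtered proteins,
with SpC = 0 imputed where a protein was not observed in that sample
(``normalization="union"``); every sample column then sums to exactly 1.
The alternative ``"detected"`` mode restricts the denominator to proteins
with SpC > 0 in that sample, in which case columns need not sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io import ProteinRecord, StudyDesign


@dataclass(frozen=True)
class NSAFMatrix:
    """Per-sample NSAF values for a fixed protein set.

    ``values[i, j]`` is the NSAF of ``proteins[i]`` in ``samples[j]``;
    every entry is strictly positive.
    """

    proteins: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray  # shape (n_proteins, n_samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.proteins), columns=list(self.samples)
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "accession"
        df.to_csv(path, sep="\t", float_format="%.17e")


def compute_nsaf(
    records: list[ProteinRecord],
    design: StudyDesign,
    normalization: Literal["union", "detected"] = "union",
) -> NSAFMatrix:
    """Compute the pseudocounted NSAF matrix over the filtered protein set.

    Parameters
    ----------
    records
        Filtered protein records; proteins absent from a sample contribute
        SpC = 0 there.
    design
        Maps sample columns to conditions; all its samples are computed.
    normalization
        ``"union"`` (default): denominator sums over all proteins in
        ``records``.  ``"detected"``: denominator sums only over proteins
        with SpC > 0 in that sample; numerators are unchanged.
    """
    if not records:
        raise ValueError("no proteins after filtering")
    if normalization not in ("union", "detected"):
        raise ValueError(f"unknown normalization {normalization!r}")
    sample_ids = design.sample_ids
    counts = np.array(
        [[r.spc.get(s, 0) for s in sample_ids] for r in records], dtype=float
    )
    lengths = np.array([r.length_aa for r in records], dtype=float)
    saf = (counts + 1.0) / lengths[:, None]
    if normalization == "union":
        denom = saf.sum(axis=0)
    else:
        denom = np.where(counts > 0, saf, 0.0).sum(axis=0)
        if np.any(denom == 0):
            # a sample with no detected protein falls back to the union sum
            union = saf.sum(axis=0)
            denom = np.where(denom == 0, union, denom)
    values = saf / denom
    return NSAFMatrix(
        proteins=tuple(r.accession for r in records),
        samples=tuple(sample_ids),
        values=values,
    )


def condition_means(
    nsaf: NSAFMatrix, design: StudyDesign
) -> pd.DataFrame:
    """Arithmetic mean NSAF per protein within each condition.

    Returns a DataFrame indexed by accession with columns ``mean_P`` and
    ``mean_NP``; both are strictly positive thanks to the pseudocount.
    """
    df = nsaf.to_frame()
    out = {}
    for cond in ("P", "NP"):
        cols = [s for s in design.samples_for(cond) if s in df.columns]
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
        out[f"mean_{cond}"] = df[cols].mean(axis=1)
    return pd.DataFrame(out)
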