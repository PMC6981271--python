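"""Classify interactors on the volcano plot and score them against truth.

Reads the differential table (from 02_quantify.py) and the simulation
truth, applies the hyperbolic threshold curve with the default
parameters (n = 1.35, m = 5), renders the volcano figure, and tallies
recall/precision against the known spikes.
"""

from pathlib import Path

import pandas as pd

from nsafpull import (
    FilterPolicy,
    StudyDesign,
    ThresholdParams,
    apply_filters,
    classify,
    compute_nsaf,
    differential_table,
    evaluate_calls,
    export_volcano,
    read_counts_table,
)
from nsafpull.simulate import SyntheticTruth

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = StudyDesign.from_tsv(BASE / "sim" / "design.tsv")
    records = read_counts_table(BASE / "sim" / "counts.tsv", design)
    filtered = apply_filters(records, FilterPolicy())
    results = differential_table(compute_nsaf(filtered, design), design)
    params = ThresholdParams()
    calls = classify(results, params)
    export_volcano(calls, params, BASE / "volcano")

    truth_df = pd.read_csv(BASE / "sim" / "truth.tsv", sep="\t")
    truth = SyntheticTruth(
        labels=dict(zip(truth_df.accession, truth_df.label)),
        abundance=dict(zip(truth_df.accession, truth_df.true_abundance)),
        fold_change=dict(zip(truth_df.accession, truth_df.true_fold_change)),
    )
    ev = evaluate_calls(calls, truth)
    print(
        f"called {ev['n_called_P']:.0f} P-side and {ev['n_called_NP']:.0f} "
        f"NP-side interactors out of {len(calls)} proteins"
    )
    print(
        f"P-side recall {ev['recall_P']:.2f}, precision {ev['precision_P']:.2f}; "
        f"background FPR {ev['fpr_background']:.3f}"
    )
    print(f"volcano figure and points written under {BASE}")


if __name__ == "__main__":
    main()
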