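"""End-to-end analysis run: filters -> NSAF -> Welch stats -> volcano calls.

``run_analyze`` chains the stages on a counts/design table pair and writes
plain-TSV artifacts plus a machine-readable run summary, so the pipeline
is scriptable and every intermediate is inspectable.  On any stage error
the partial artifacts are removed and a stage-named exception is raised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as io_mod
from .io import FilterPolicy, StudyDesign
from .nsaf import compute_nsaf
from .stats import DEFAULT_P_FLOOR, differential_table, write_differential
from .volcano import (
    CallClass,
    ThresholdParams,
    calls_to_frame,
    classify,
    export_volcano,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage of the analysis failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    counts_path: Path
    design_path: Path
    out_dir: Path
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    p_floor: float = DEFAULT_P_FLOOR
    log_base: float = 10.0
    normalization: str = "union"  # union | detected


def run_analyze(config: RunConfig) -> dict:
    """Run the full differential-interactor analysis; returns the run summary.

    Artifacts written under ``config.out_dir``: filtered_proteins.tsv,
    nsaf_matrix.tsv, differential.tsv, volcano_calls.tsv, volcano.svg/.png
    and run_summary.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _fail(stage: str, exc: Exception):
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc

    try:
        design = StudyDesign.from_tsv(config.design_path)
    except (OSError, ValueError) as exc:
        _fail("read_design", exc)
    try:
        records = io_mod.read_counts_table(config.counts_path, design)
    except (OSError, ValueError) as exc:
        _fail("read_counts", exc)

    n_input = len(records)
    try:
        peptide_only = FilterPolicy(
            min_total_peptides=config.filter_policy.min_total_peptides,
            require_unique_peptide=config.filter_policy.require_unique_peptide,
            deduplicate_cross_species=False,
        )
        after_peptide = io_mod.apply_filters(records, peptide_only)
        filtered = io_mod.apply_filters(records, config.filter_policy)
        path = out / "filtered_proteins.tsv"
        io_mod.write_counts_table(filtered, design, path)
        written.append(path)
    except ValueError as exc:
        _fail("filter", exc)

    try:
        nsaf = compute_nsaf(filtered, design, config.normalization)
        path = out / "nsaf_matrix.tsv"
        nsaf.write_tsv(path)
        written.append(path)
    except ValueError as exc:
        _fail("nsaf", exc)

    try:
        results = differential_table(
            nsaf, design, p_floor=config.p_floor, log_base=config.log_base
        )
        gene_map = {r.accession: r.gene_symbol for r in filtered}
        path = out / "differential.tsv"
        write_differential(results, path, gene_map)
        written.append(path)
    except ValueError as exc:
        _fail("differential", exc)

    try:
        calls = classify(results, config.threshold)
        path = out / "volcano_calls.tsv"
        calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.17g")
        written.append(path)
        written.extend(export_volcano(calls, config.threshold, out / "volcano"))
    except (OSError, ValueError) as exc:
        _fail("classify", exc)

    tallies = {label.value: 0 for label in CallClass}
    for c in calls:
        tallies[c.class_label.value] += 1
    summary = {
        "parameters": {
            "counts_path": str(config.counts_path),
            "design_path": str(config.design_path),
            "min_total_peptides": config.filter_policy.min_total_peptides,
            "require_unique_peptide": config.filter_policy.require_unique_peptide,
            "deduplicate_cross_species": config.filter_policy.deduplicate_cross_species,
            "threshold_n": config.threshold.n,
            "threshold_m": config.threshold.m,
            "p_floor": config.p_floor,
            "log_base": config.log_base,
            "normalization": config.normalization,
        },
        "protein_counts": {
            "input": n_input,
            "after_peptide_filters": len(after_peptide),
            "after_dedup": len(filtered),
        },
        "class_tallies": tallies,
        "artifacts": [str(p) for p in written],
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info(
        "analysis complete: %d/%d proteins retained, %d P-side and %d NP-side calls",
        len(filtered),
        n_input,
        tallies["P_SIGNIFICANT"],
        tallies["NP_SIGNIFICANT"],
    )
    return summary
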