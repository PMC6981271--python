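"""Data model and table I/O for protein spectral-count pull-down experiments.

A pull-down experiment compares proteins captured by a modified bait
(condition ``P``) against a control bait (condition ``NP``) across
biological replicates.  The raw input is a protein identification table:
one row per protein with its peptide evidence and one spectral-count
column per LC-MS/MS run.

Identification-level filters are applied here, before any statistics:
a minimum number of matched peptides per protein, a unique-peptide
requirement, and deduplication of cross-species redundant entries that
arise when a merged two-species sequence database is searched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

#: Metadata columns every counts table must carry, in order, before the
#: per-sample count columns.
META_COLUMNS = (
    "accession",
    "gene",
    "species",
    "length_aa",
    "total_peptides",
    "unique_peptides",
)

CONDITIONS = ("P", "NP")


class CountsTableError(ValueError):
    """Malformed counts or design table (bad columns, cells, or invariants)."""


@dataclass(frozen=True)
class SampleInfo:
    """One LC-MS/MS run: its column name, condition and replicate index."""

    sample_id: str
    condition: str  # "P" (modified bait) or "NP" (control bait)
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise CountsTableError(
                f"sample {self.sample_id!r}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        if self.replicate < 1:
            raise CountsTableError(
                f"sample {self.sample_id!r}: replicate index must be >= 1"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Maps sample columns to condition and replicate.

    Requires exactly the two conditions ``P`` and ``NP`` with at least two
    replicates each, and unique sample ids.
    """

    samples: tuple[SampleInfo, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise CountsTableError("duplicate sample_id in design")
        for cond in CONDITIONS:
            if len(self.samples_for(cond)) < 2:
                raise CountsTableError(
                    f"condition {cond!r} needs >= 2 replicates"
                )
        extra = {s.condition for s in self.samples} - set(CONDITIONS)
        if extra:  # unreachable through SampleInfo, kept for direct construction
            raise CountsTableError(f"unknown conditions: {sorted(extra)}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_for(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]

    def swap_conditions(self) -> "StudyDesign":
        """Return the design with P and NP labels exchanged (for symmetry checks)."""
        flip = {"P": "NP", "NP": "P"}
        return StudyDesign(
            tuple(
                SampleInfo(s.sample_id, flip[s.condition], s.replicate)
                for s in self.samples
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StudyDesign":
        """Read a design TSV with columns sample_id, condition, replicate."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "condition", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise CountsTableError(
                f"design file {path}: missing columns {sorted(missing)}"
            )
        samples = []
        for row in df.itertuples(index=False):
            try:
                rep = int(row.replicate)
            except (TypeError, ValueError) as exc:
                raise CountsTableError(
                    f"design file {path}: non-integer replicate "
                    f"{row.replicate!r} for sample {row.sample_id!r}"
                ) from exc
            samples.append(SampleInfo(str(row.sample_id), str(row.condition), rep))
        return cls(tuple(samples))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ProteinRecord:
    """One identified protein: identity, length, peptide evidence, counts.

    ``spc`` maps sample_id to the spectral count SpC observed in that run;
    a protein absent from a run is encoded as SpC = 0, never as missing.
    """

    accession: str
    gene_symbol: str
    species_tag: str
    length_aa: int
    total_peptides: int
    unique_peptides: int
    spc: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise CountsTableError(
                f"protein {self.accession!r}: length_aa must be >= 1, "
                f"got {self.length_aa}"
            )
        if self.total_peptides < 0 or self.unique_peptides < 0:
            raise CountsTableError(
                f"protein {self.accession!r}: peptide counts must be >= 0"
            )
        if self.unique_peptides > self.total_peptides:
            raise CountsTableError(
                f"protein {self.accession!r}: unique_peptides "
                f"({self.unique_peptides}) exceeds total_peptides "
                f"({self.total_peptides})"
            )
        for sid, c in self.spc.items():
            if c < 0:
                raise CountsTableError(
                    f"protein {self.accession!r}: negative count in {sid!r}"
                )

    def total_spc(self) -> int:
        return sum(self.spc.values())


@dataclass(frozen=True)
class FilterPolicy:
    """Identification-level filters applied before quantification.

    ``min_total_peptides`` enforces the acceptance criterion of at least two
    matched peptides per protein; ``require_unique_peptide`` retains only
    proteins unequivocally assigned by at least one unique peptide;
    ``deduplicate_cross_species`` collapses redundant entries of the same
    gene identified from different species libraries.
    """

    min_total_peptides: int = 2
    require_unique_peptide: bool = True
    deduplicate_cross_species: bool = True

    def __post_init__(self) -> None:
        if self.min_total_peptides < 1:
            raise CountsTableError("min_total_peptides must be >= 1")


def read_counts_table(
    path: str | Path, design: StudyDesign
) -> list[ProteinRecord]:
    """Read a TSV protein identification table into ProteinRecords.

    The header must name all ``META_COLUMNS`` plus one integer count column
    per sample in ``design``.  Missing cells and non-integer counts are
    rejected with the offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    missing += [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise CountsTableError(
            f"counts table {path}: missing column(s) {missing}"
        )
    if df.empty:
        logger.warning("counts table %s has a header but no rows", path)
        return []

    def _to_int(value: str, column: str, row: int) -> int:
        text = value.strip()
        if not text:
            raise CountsTableError(
                f"counts table {path}, row {row}: empty cell in {column!r}"
            )
        try:
            return int(text)
        except ValueError as exc:
            raise CountsTableError(
                f"counts table {path}, row {row}: non-integer value "
                f"{value!r} in column {column!r}"
            ) from exc

    records: list[ProteinRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        spc = {
            sid: _to_int(row_d[sid], sid, i) for sid in design.sample_ids
        }
        records.append(
            ProteinRecord(
                accession=row_d["accession"],
                gene_symbol=row_d["gene"],
                species_tag=row_d["species"],
                length_aa=_to_int(row_d["length_aa"], "length_aa", i),
                total_peptides=_to_int(row_d["total_peptides"], "total_peptides", i),
                unique_peptides=_to_int(
                    row_d["unique_peptides"], "unique_peptides", i
                ),
                spc=spc,
            )
        )
    return records


def write_counts_table(
    records: Iterable[ProteinRecord], design: StudyDesign, path: str | Path
) -> None:
    """Write records in the same TSV dialect ``read_counts_table`` accepts."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "accession": r.accession,
            "gene": r.gene_symbol,
            "species": r.species_tag,
            "length_aa": r.length_aa,
            "total_peptides": r.total_peptides,
            "unique_peptides": r.unique_peptides,
        }
        for sid in design.sample_ids:
            row[sid] = r.spc.get(sid, 0)
        rows.append(row)
    columns = list(META_COLUMNS) + design.sample_ids
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def apply_filters(
    records: list[ProteinRecord], policy: FilterPolicy = FilterPolicy()
) -> list[ProteinRecord]:
    """Apply the identification-level filters; preserves input order.

    Peptide-evidence filters run first; cross-species deduplication then
    groups survivors by case-insensitive gene symbol (empty symbols are
    never grouped) and keeps, per group, the record with the highest summed
    spectral count, breaking ties by lexicographically smallest accession.
    Counts are never modified.
    """
    survivors = [
        r
        for r in records
        if r.total_peptides >= policy.min_total_peptides
        and (not policy.require_unique_peptide or r.unique_peptides >= 1)
    ]
    if not policy.deduplicate_cross_species:
        return survivors

    keep: dict[str, ProteinRecord] = {}
    for r in survivors:
        gene = r.gene_symbol.strip().lower()
        if not gene:
            continue
        best = keep.get(gene)
        if best is None:
            keep[gene] = r
        else:
            key_r = (-r.total_spc(), r.accession)
            key_best = (-best.total_spc(), best.accession)
            if key_r < key_best:
                keep[gene] = r
    kept_ids = {id(r) for r in keep.values()}
    return [
        r
        for r in survivors
        if not r.gene_symbol.strip() or id(r) in kept_ids
    ]
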