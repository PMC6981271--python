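import pytest

from nsafpull import (
    ProteinRecord,
    SampleInfo,
    StudyDesign,
)


@pytest.fixture
def design_3v3() -> StudyDesign:
    return StudyDesign(
        tuple(
            SampleInfo(f"{cond}{i}", cond, i)
            for cond in ("P", "NP")
            for i in (1, 2, 3)
        )
    )


def make_record(
    accession: str = "PROT1",
    gene: str = "GENE1",
    species: str = "BOVIN",
    length_aa: int = 200,
    total_peptides: int = 5,
    unique_peptides: int = 2,
    spc: dict[str, int] | None = None,
) -> ProteinRecord:
    return ProteinRecord(
        accession=accession,
        gene_symbol=gene,
        species_tag=species,
        length_aa=length_aa,
        total_peptides=total_peptides,
        unique_peptides=unique_peptides,
        spc=spc or {},
    )
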