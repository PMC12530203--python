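import pytest

from codonmk import CodonAlignment, GeneticCode, SequenceRecord


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode.standard()


def make_alignment(
    ingroup_a: str, ingroup_b: str, outgroup: str, gene_id: str = "gene"
) -> CodonAlignment:
    """Build a 3-sequence alignment directly from residue strings."""
    return CodonAlignment(
        gene_id=gene_id,
        records=(
            SequenceRecord("inA", "ingroup", ingroup_a),
            SequenceRecord("inB", "ingroup", ingroup_b),
            SequenceRecord("out", "outgroup", outgroup),
        ),
    )


def fasta_text(records: dict[str, str]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in records.items())
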