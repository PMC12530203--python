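"""Synthetic three-sequence codon alignments with known mutation truth.

The generator emulates the sampling design the MK test is applied to: a
random ancestral CDS, an out-group copy that accumulates candidate fixed
differences along its branch, and an in-group pair in which exactly one
lineage accumulates polymorphisms (the other retains the ancestral state —
with two in-group sequences and an unpolarized test this loses no
generality). Proposed changes are position-uniform single-nucleotide
substitutions with uniform alternative bases; a proposal creating a stop
codon is rejected, synonymous proposals are always accepted, and
non-synonymous proposals are accepted with a class-specific probability
omega, so omega_div / omega_poly tilt the simulated Dn/Ds vs Pn/Ps ratios.
The realized accepted changes are recorded per class in :class:`SimTruth`,
giving an exact bookkeeping oracle for the counting pipeline whenever the
mutation density is low enough that codons receive at most one hit.

The packaged 37-gene count table (exact rationals; six all-NA genes) is
exposed through :func:`make_table1_fixture`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .alignment_io import CodonAlignment, SequenceRecord
from .genetic_code import GeneticCode
from .mk_counting import MKCounts

BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Conditions for one simulated gene.

    ``mu_div`` / ``mu_poly`` are the expected numbers of proposed nucleotide
    changes on the out-group branch and the mutated in-group lineage;
    ``omega_div`` / ``omega_poly`` are the acceptance probabilities of
    non-synonymous proposals per branch class (synonymous proposals are
    always accepted). Defaults are the regime used throughout the test
    batteries: 500-codon genes with 15 expected hits per class and neutral
    acceptance.
    """

    n_codons: int = 500
    mu_div: float = 15.0
    mu_poly: float = 15.0
    omega_div: float = 1.0
    omega_poly: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons <= 0:
            raise ValueError("n_codons must be positive")
        for name in ("mu_div", "mu_poly", "omega_div", "omega_poly"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Realized accepted mutation counts per class for one simulated gene."""

    div_syn: int = 0
    div_nonsyn: int = 0
    poly_syn: int = 0
    poly_nonsyn: int = 0
    mutated_codons_div: list[int] = field(default_factory=list)
    mutated_codons_poly: list[int] = field(default_factory=list)

    @property
    def div_total(self) -> int:
        return self.div_syn + self.div_nonsyn

    @property
    def poly_total(self) -> int:
        return self.poly_syn + self.poly_nonsyn

    def to_json(self) -> str:
        return json.dumps(
            {
                "div_syn": self.div_syn,
                "div_nonsyn": self.div_nonsyn,
                "poly_syn": self.poly_syn,
                "poly_nonsyn": self.poly_nonsyn,
                "mutated_codons_div": self.mutated_codons_div,
                "mutated_codons_poly": self.mutated_codons_poly,
            }
        )


def _mutate_branch(
    seq: list[str],
    n_proposals: int,
    omega: float,
    code: GeneticCode,
    rng: np.random.Generator,
) -> tuple[int, int, list[int]]:
    """Apply accepted proposals to *seq* in place; return (syn, nonsyn, codons)."""
    syn = nonsyn = 0
    codons: list[int] = []
    n_nt = len(seq)
    for _ in range(n_proposals):
        pos = int(rng.integers(n_nt))
        old_base = seq[pos]
        new_base = BASES.replace(old_base, "")[int(rng.integers(3))]
        ci = pos // 3
        old_codon = "".join(seq[3 * ci : 3 * ci + 3])
        new_codon = old_codon[: pos % 3] + new_base + old_codon[pos % 3 + 1 :]
        if code.is_stop(new_codon):
            continue
        if code.is_synonymous(old_codon, new_codon):
            seq[pos] = new_base
            syn += 1
            codons.append(ci)
        elif rng.random() < omega:
            seq[pos] = new_base
            nonsyn += 1
            codons.append(ci)
    return syn, nonsyn, codons


def simulate_gene(
    params: SimParams, gene_id: str = "sim", code: Optional[GeneticCode] = None
) -> tuple[CodonAlignment, SimTruth]:
    """Simulate one gene; deterministic for a fixed seed.

    Returns the alignment (ingroup_a = ancestral copy, ingroup_b = mutated
    in-group lineage, outgroup = mutated out-group branch) and the realized
    truth bookkeeping.
    """
    code = code or GeneticCode.standard()
    rng = np.random.default_rng(params.seed)
    sense = code.sense_codons
    ancestral = list(
        "".join(sense[i] for i in rng.integers(len(sense), size=params.n_codons))
    )

    truth = SimTruth()
    out_seq = list(ancestral)
    n_div = int(rng.poisson(params.mu_div))
    truth.div_syn, truth.div_nonsyn, truth.mutated_codons_div = _mutate_branch(
        out_seq, n_div, params.omega_div, code, rng
    )
    in_b = list(ancestral)
    n_poly = int(rng.poisson(params.mu_poly))
    truth.poly_syn, truth.poly_nonsyn, truth.mutated_codons_poly = _mutate_branch(
        in_b, n_poly, params.omega_poly, code, rng
    )

    aln = CodonAlignment(
        gene_id=gene_id,
        records=(
            SequenceRecord(f"{gene_id}_ingroup_a", "ingroup", "".join(ancestral)),
            SequenceRecord(f"{gene_id}_ingroup_b", "ingroup", "".join(in_b)),
            SequenceRecord(f"{gene_id}_outgroup", "outgroup", "".join(out_seq)),
        ),
    )
    return aln, truth


def write_simulated_gene(
    aln: CodonAlignment, truth: SimTruth, out_dir: Path
) -> tuple[Path, Path, Path]:
    """Write FASTA + role manifest + truth JSON for one simulated gene."""
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{aln.gene_id}.fasta"
    with fasta.open("w") as fh:
        aln.to_fasta(fh)
    manifest = out_dir / f"{aln.gene_id}.roles.json"
    manifest.write_text(
        json.dumps(
            {
                "gene_id": aln.gene_id,
                "ingroup": [r.identifier for r in aln.ingroup],
                "outgroup": aln.outgroup.identifier,
            },
            indent=2,
        )
    )
    truth_path = out_dir / f"{aln.gene_id}.truth.json"
    truth_path.write_text(truth.to_json())
    return fasta, manifest, truth_path


@dataclass(frozen=True)
class Table1Row:
    """One gene of the packaged 37-gene MK count table."""

    gene: str
    trait: str
    counts: Optional[MKCounts]  # None for the all-NA genes
    ni_printed: str
    p_printed: Optional[float]

    @property
    def is_na(self) -> bool:
        return self.counts is None


def make_table1_fixture() -> list[Table1Row]:
    """Load the packaged machine-readable copy of the 37-gene count table.

    Counts are exact rationals (e.g. 2.333 is stored as 7/3, 0.33 as 1/3,
    halves as halves); the six genes with no differences among the three
    sequences carry ``counts=None``.
    """
    text = (
        resources.files("codonmk").joinpath("data/table1_counts.tsv").read_text()
    )
    rows: list[Table1Row] = []
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    assert header[:6] == ["trait", "gene", "Ds", "Dn", "Ps", "Pn"]
    for line in lines[1:]:
        trait, gene, ds, dn, ps, pn, ni, p = line.split("\t")
        if ds == "NA":
            rows.append(Table1Row(gene, trait, None, "NA", None))
            continue
        counts = MKCounts(
            gene_id=gene,
            Ds=Fraction(ds),
            Dn=Fraction(dn),
            Ps=Fraction(ps),
            Pn=Fraction(pn),
        )
        rows.append(Table1Row(gene, trait, counts, ni, float(p)))
    return rows
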