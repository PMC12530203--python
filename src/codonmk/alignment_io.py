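"""Reading, cleaning and frame validation of three-sequence codon alignments.

The unit of analysis is one gene: an in-frame CDS alignment of exactly two
in-group individuals and one out-group individual. Downstream counting only
tolerates unambiguous A/C/G/T codon columns, so cleaning removes any codon
column (nucleotide triplet) that carries a gap or an ambiguity code in *any*
sequence — gap handling is codon-granular to keep the reading frame shared
across the three sequences. Frame is taken to start at alignment position 1;
no ORF search is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import IO, Iterable, Literal, Union

from Bio import SeqIO

from .genetic_code import GeneticCode

logger = logging.getLogger(__name__)

ACGT = frozenset("ACGT")
GAP_CHARS = frozenset("-.")

Role = Literal["ingroup", "outgroup"]


class AlignmentError(ValueError):
    """Sequences that cannot form a codon alignment (unequal lengths)."""


class ConfigurationError(ValueError):
    """Requested record identifiers do not match the FASTA content."""


class FrameError(ValueError):
    """Alignment length is not a whole number of codons."""


class InternalStopError(ValueError):
    """An internal stop codon was observed; pathway counting through an
    observed stop is undefined, so the gene is rejected."""

    def __init__(self, sequence_id: str, codon_index: int):
        self.sequence_id = sequence_id
        self.codon_index = codon_index  # 1-based
        super().__init__(
            f"internal stop codon in '{sequence_id}' at codon {codon_index}"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned CDS with an explicitly assigned role.

    Roles are never inferred from identifier text: the caller states which
    identifiers are in-group and which is the out-group.
    """

    identifier: str
    role: Role
    residues: str

    def __post_init__(self) -> None:
        # Empty residues are tolerated here so cleaning may legally strip an
        # alignment down to nothing; read_codon_alignment rejects empty input.
        if self.role not in ("ingroup", "outgroup"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class CodonAlignment:
    """Three equal-length role-tagged sequences viewed as codon columns."""

    gene_id: str
    records: tuple[SequenceRecord, SequenceRecord, SequenceRecord]
    dropped_codons: int = 0

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"gene '{self.gene_id}': unequal sequence lengths {sorted(lengths)}"
            )
        roles = sorted(r.role for r in self.records)
        if roles != ["ingroup", "ingroup", "outgroup"]:
            raise ValueError(
                f"gene '{self.gene_id}': need 2 ingroup + 1 outgroup records, got {roles}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.records[0].residues)

    @property
    def length_codons(self) -> int:
        return self.length_nt // 3

    @property
    def ingroup(self) -> tuple[SequenceRecord, SequenceRecord]:
        a, b = (r for r in self.records if r.role == "ingroup")
        return a, b

    @property
    def outgroup(self) -> SequenceRecord:
        return next(r for r in self.records if r.role == "outgroup")

    def codon_column(self, index: int) -> tuple[str, str, str]:
        """Codon triplet (ingroup_a, ingroup_b, outgroup) at 0-based *index*."""
        a, b = self.ingroup
        o = self.outgroup
        s = slice(3 * index, 3 * index + 3)
        return a.residues[s], b.residues[s], o.residues[s]

    def to_fasta(self, handle: IO[str]) -> None:
        for rec in self.records:
            handle.write(f">{rec.identifier}\n{rec.residues}\n")


def read_codon_alignment(
    fasta_source: Union[str, IO[str]],
    ingroup_ids: Iterable[str],
    outgroup_id: str,
    gene_id: str = "",
) -> CodonAlignment:
    """Load the three named records from a FASTA alignment.

    Residues are upper-cased and U is mapped to T. Extra records in the file
    are ignored with a warning; missing or duplicated requested identifiers
    raise :class:`ConfigurationError`. The alignment length must be equal
    across records and a whole number of codons.
    """
    ingroup_ids = tuple(ingroup_ids)
    if len(ingroup_ids) != 2:
        raise ConfigurationError(f"need exactly 2 ingroup ids, got {len(ingroup_ids)}")
    wanted = (*ingroup_ids, outgroup_id)
    if len(set(wanted)) != 3:
        raise ConfigurationError(f"ingroup/outgroup ids must be distinct: {wanted}")

    found: dict[str, str] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if rec.id not in wanted:
            logger.warning("gene '%s': ignoring extra record '%s'", gene_id, rec.id)
            continue
        if rec.id in found:
            raise ConfigurationError(f"duplicate record '{rec.id}' in FASTA")
        residues = str(rec.seq).upper().replace("U", "T")
        if not residues:
            raise AlignmentError(f"record '{rec.id}' is empty")
        found[rec.id] = residues

    missing = [i for i in wanted if i not in found]
    if missing:
        raise ConfigurationError(f"gene '{gene_id}': records not found: {missing}")

    records = tuple(
        SequenceRecord(i, "ingroup" if i in ingroup_ids else "outgroup", found[i])
        for i in wanted
    )
    aln = CodonAlignment(gene_id=gene_id, records=records)  # checks equal lengths
    if aln.length_nt % 3 != 0:
        raise FrameError(
            f"gene '{gene_id}': alignment length {aln.length_nt} nt is not a multiple of 3"
        )
    return aln


def _codon_usable(aln: CodonAlignment, index: int) -> bool:
    return all(set(codon) <= ACGT for codon in aln.codon_column(index))


def strip_unusable_columns(
    aln: CodonAlignment, mode: Literal["column", "end-trim"] = "column"
) -> CodonAlignment:
    """Remove codon columns containing gaps or ambiguity codes.

    ``mode="column"`` (default) drops every unusable codon column wherever it
    sits; ``mode="end-trim"`` only trims runs of unusable columns at the two
    alignment ends and raises :class:`AlignmentError` if unusable columns
    remain internally. Removal is synchronized across all three sequences and
    idempotent; ``dropped_codons`` accumulates the number removed.
    """
    n = aln.length_codons
    usable = [_codon_usable(aln, i) for i in range(n)]
    if mode == "column":
        keep = [i for i in range(n) if usable[i]]
    elif mode == "end-trim":
        lo, hi = 0, n
        while lo < hi and not usable[lo]:
            lo += 1
        while hi > lo and not usable[hi - 1]:
            hi -= 1
        bad = [i + 1 for i in range(lo, hi) if not usable[i]]
        if bad:
            raise AlignmentError(
                f"gene '{aln.gene_id}': internal unusable codon columns {bad} "
                "cannot be removed in end-trim mode"
            )
        keep = list(range(lo, hi))
    else:
        raise ValueError(f"unknown strip mode {mode!r}")

    dropped = n - len(keep)
    if dropped == 0:
        return aln
    logger.info("gene '%s': dropped %d unusable codon column(s)", aln.gene_id, dropped)
    records = tuple(
        replace(
            rec,
            residues="".join(rec.residues[3 * i : 3 * i + 3] for i in keep),
        )
        for rec in aln.records
    )
    return CodonAlignment(aln.gene_id, records, aln.dropped_codons + dropped)


@dataclass(frozen=True)
class FrameReport:
    """Outcome of stop-codon screening for one gene."""

    gene_id: str
    terminal_stop_trimmed: bool
    internal_stops: tuple[tuple[str, int], ...]  # (sequence id, 1-based codon index)

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_id": self.gene_id,
                "terminal_stop_trimmed": self.terminal_stop_trimmed,
                "internal_stops": [
                    {"sequence": s, "codon": i} for s, i in self.internal_stops
                ],
            }
        )


def validate_frame(
    aln: CodonAlignment, code: GeneticCode
) -> tuple[CodonAlignment, FrameReport]:
    """Screen a cleaned alignment for stop codons.

    A stop in the final codon column of any sequence is treated as the
    natural CDS terminator: the final codon is trimmed from all three
    sequences (with a log line). A stop anywhere else raises
    :class:`InternalStopError` naming the sequence and 1-based codon index.
    """
    n = aln.length_codons
    internal: list[tuple[str, int]] = []
    terminal = False
    for rec in aln.records:
        for i in range(n):
            codon = rec.residues[3 * i : 3 * i + 3]
            if code.is_stop(codon):
                if i == n - 1:
                    terminal = True
                else:
                    internal.append((rec.identifier, i + 1))
    if internal:
        raise InternalStopError(*internal[0])
    if terminal:
        logger.info("gene '%s': trimmed terminal stop codon", aln.gene_id)
        records = tuple(replace(r, residues=r.residues[:-3]) for r in aln.records)
        aln = CodonAlignment(aln.gene_id, records, aln.dropped_codons)
    return aln, FrameReport(aln.gene_id, terminal, ())


def clean_alignment(
    aln: CodonAlignment,
    code: GeneticCode,
    mode: Literal["column", "end-trim"] = "column",
) -> tuple[CodonAlignment, FrameReport]:
    """Strip unusable columns then validate the frame (the standard pipeline)."""
    return validate_frame(strip_unusable_columns(aln, mode=mode), code)
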