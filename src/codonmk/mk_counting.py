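"""Pathway-averaged counting of synonymous and non-synonymous changes.

For a pair of codons differing at d positions (d <= 3) there are d!
orderings in which the single-nucleotide steps could have occurred. Each
step is classified as synonymous or non-synonymous against the genetic
code, and the per-pathway step counts are averaged with equal weights,
yielding exact rational counts (denominators divide the number of retained
pathways, at most 3! = 6). Pathways whose
*intermediate* codons are stops are normally excluded (such a history would
pass through a nonfunctional protein); if every pathway is excluded, the
exclusion is suspended rather than silently discarding the codon.

Per gene, each codon column contributes independently:

* the two in-group codons, where they differ, contribute pathway-averaged
  steps to the polymorphism counts (Ps, Pn);
* fixed differences contribute to the divergence counts (Ds, Dn) via a
  divergence origin codon — the in-group codon with out-group residues
  substituted at the polymorphic positions — compared against the out-group
  codon, so divergence steps traverse exactly the fixed positions.

A single out-group sequence cannot polarize changes onto lineages, so
"fixed difference" simply means the shared in-group state differs from the
out-group state. Counts are raw step tallies (no site-count normalisation):
this is the count-based McDonald-Kreitman test, not a rate estimate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import permutations
from typing import Iterator, Literal

from .alignment_io import ACGT, CodonAlignment
from .genetic_code import GeneticCode

StopPolicy = Literal["exclude", "include"]


class SiteClass(enum.Enum):
    """Classification of one nucleotide position across the three sequences."""

    IDENTICAL = "identical"
    POLYMORPHIC = "polymorphic"
    FIXED = "fixed"


def classify_position(ingroup_a: str, ingroup_b: str, outgroup: str) -> SiteClass:
    """Classify one aligned nucleotide position.

    Polymorphic whenever the two in-group residues disagree (a three-state
    site is polymorphic, never fixed); fixed when the in-group residues agree
    with each other but not with the out-group.
    """
    for sym in (ingroup_a, ingroup_b, outgroup):
        if sym not in ACGT:
            raise ValueError(f"non-ACGT symbol {sym!r}: alignment was not cleaned")
    if ingroup_a != ingroup_b:
        return SiteClass.POLYMORPHIC
    if ingroup_a != outgroup:
        return SiteClass.FIXED
    return SiteClass.IDENTICAL


@dataclass(frozen=True)
class PathwayStep:
    position: int  # 0-based position within the codon
    from_codon: str
    to_codon: str
    synonymous: bool


@dataclass(frozen=True)
class PathwaySet:
    """All retained mutational pathways between two codons."""

    origin: str
    target: str
    pathways: tuple[tuple[PathwayStep, ...], ...]
    excluded_pathways: int = 0

    @property
    def n_differences(self) -> int:
        return sum(a != b for a, b in zip(self.origin, self.target))


def _walk(origin: str, target: str, order: tuple[int, ...], code: GeneticCode):
    """One pathway: apply target residues position-by-position in *order*."""
    steps = []
    current = origin
    for pos in order:
        nxt = current[:pos] + target[pos] + current[pos + 1 :]
        steps.append(
            PathwayStep(pos, current, nxt, synonymous=code.is_synonymous(current, nxt))
        )
        current = nxt
    return tuple(steps)


def enumerate_pathways(
    origin: str,
    target: str,
    code: GeneticCode,
    stop_policy: StopPolicy = "exclude",
) -> PathwaySet:
    """Enumerate the d! single-nucleotide pathways from *origin* to *target*.

    Under the default ``stop_policy="exclude"``, pathways whose intermediate
    codons (after steps 1..d-1) are stops are dropped and counted in
    ``excluded_pathways``; endpoints are never tested, since a constructed
    divergence origin is permitted even where observed codons are not. If
    every pathway would be excluded, all d! are retained instead.
    """
    if origin == target:
        raise ValueError(f"origin and target are identical ({origin})")
    diff_positions = tuple(i for i in range(3) if origin[i] != target[i])
    all_paths = [_walk(origin, target, order, code) for order in permutations(diff_positions)]
    if stop_policy == "include" or len(diff_positions) == 1:
        return PathwaySet(origin, target, tuple(all_paths), 0)

    def passes(path: tuple[PathwayStep, ...]) -> bool:
        return not any(code.is_stop(step.to_codon) for step in path[:-1])

    kept = [p for p in all_paths if passes(p)]
    if not kept:  # all pathways traverse a stop: suspend the exclusion rule
        return PathwaySet(origin, target, tuple(all_paths), 0)
    return PathwaySet(origin, target, tuple(kept), len(all_paths) - len(kept))


def pathway_average(
    origin: str,
    target: str,
    code: GeneticCode,
    stop_policy: StopPolicy = "exclude",
) -> tuple[Fraction, Fraction]:
    """Mean (synonymous, non-synonymous) step counts over retained pathways.

    The two components always sum exactly to the number of differing
    positions; identical codons return (0, 0).
    """
    if origin == target:
        return Fraction(0), Fraction(0)
    ps = enumerate_pathways(origin, target, code, stop_policy)
    n = len(ps.pathways)
    syn = Fraction(sum(sum(s.synonymous for s in p) for p in ps.pathways), n)
    nonsyn = Fraction(sum(sum(not s.synonymous for s in p) for p in ps.pathways), n)
    return syn, nonsyn


@dataclass
class MKCounts:
    """Exact-rational per-gene MK counts plus cleaning bookkeeping."""

    gene_id: str
    Ds: Fraction = field(default_factory=Fraction)
    Dn: Fraction = field(default_factory=Fraction)
    Ps: Fraction = field(default_factory=Fraction)
    Pn: Fraction = field(default_factory=Fraction)
    codons_used: int = 0
    codons_dropped: int = 0

    def as_tuple(self) -> tuple[Fraction, Fraction, Fraction, Fraction]:
        return (self.Ds, self.Dn, self.Ps, self.Pn)

    def __add__(self, other: "MKCounts") -> "MKCounts":
        return MKCounts(
            self.gene_id,
            self.Ds + other.Ds,
            self.Dn + other.Dn,
            self.Ps + other.Ps,
            self.Pn + other.Pn,
            self.codons_used + other.codons_used,
            self.codons_dropped + other.codons_dropped,
        )


def divergence_origin(codon_a: str, codon_b: str, codon_out: str) -> str:
    """In-group codon with out-group residues at the polymorphic positions.

    Positions where the in-group codons disagree take the out-group state, so
    the returned codon differs from the out-group codon at exactly the fixed
    positions; it is symmetric in the two in-group codons.
    """
    return "".join(
        codon_out[i] if codon_a[i] != codon_b[i] else codon_a[i] for i in range(3)
    )


def count_gene(
    aln: CodonAlignment,
    code: GeneticCode,
    stop_policy: StopPolicy = "exclude",
) -> MKCounts:
    """Accumulate pathway-averaged Ds, Dn, Ps, Pn over all codon columns.

    The alignment must already be cleaned (A/C/G/T only, no internal stop).
    Codons identical across all three sequences contribute nothing; the
    syn + nonsyn contribution of each comparison equals its number of
    differing positions exactly.
    """
    counts = MKCounts(
        aln.gene_id, codons_used=aln.length_codons, codons_dropped=aln.dropped_codons
    )
    for i in range(aln.length_codons):
        cod_a, cod_b, cod_o = aln.codon_column(i)
        for codon in (cod_a, cod_b, cod_o):
            if not set(codon) <= ACGT:
                raise ValueError(
                    f"gene '{aln.gene_id}': unclean codon {codon!r} at codon {i + 1}"
                )
        if cod_a != cod_b:
            syn, nonsyn = pathway_average(cod_a, cod_b, code, stop_policy)
            counts.Ps += syn
            counts.Pn += nonsyn
        d_origin = divergence_origin(cod_a, cod_b, cod_o)
        if d_origin != cod_o:
            syn, nonsyn = pathway_average(d_origin, cod_o, code, stop_policy)
            counts.Ds += syn
            counts.Dn += nonsyn
    return counts


def iter_codon_comparisons(
    aln: CodonAlignment,
) -> Iterator[tuple[int, str, str, str, str]]:
    """Yield (1-based codon index, ingroup_a, ingroup_b, divergence origin,
    outgroup) for every codon column with at least one difference."""
    for i in range(aln.length_codons):
        cod_a, cod_b, cod_o = aln.codon_column(i)
        d_origin = divergence_origin(cod_a, cod_b, cod_o)
        if cod_a != cod_b or d_origin != cod_o:
            yield i + 1, cod_a, cod_b, d_origin, cod_o
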