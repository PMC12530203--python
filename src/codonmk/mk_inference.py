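"""Neutrality index, Fisher's exact test and cross-gene summaries.

The neutrality index NI = (Pn/Ps)/(Dn/Ds) is evaluated on the exact
rational counts, never on rounded ones. Its degeneracies map to explicit
statuses rather than NaNs:

* ``not_applicable`` — no differences at all among the three sequences;
* ``zero``           — Pn = 0 with Dn > 0 (the numerator Pn/Ps is zero, so
                       NI = 0 even when Ds or Ps is also zero);
* ``undefined``      — Dn = 0, or Ps = 0 with Pn > 0, or Ds = 0 with the
                       remaining terms positive (division by zero);
* ``value``          — Pn, Ps, Dn, Ds all positive.

Fisher's exact test needs an integer 2x2 table, so the pathway-averaged
counts are rounded half-to-even first; the two-sided p-value is the sum of
all hypergeometric table probabilities not exceeding the observed table's
(with a 1 + 1e-7 relative tolerance for floating-point ties), and is 1
whenever a margin is zero. NI < 1 suggests positive selection; NI > 1 an
excess of amino-acid polymorphism consistent with weak purifying selection.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Optional, Sequence

from scipy.stats import fisher_exact

from .alignment_io import CodonAlignment
from .genetic_code import GeneticCode
from .mk_counting import MKCounts, StopPolicy, count_gene

Rounding = Literal["half_even", "half_up"]


class NIKind(enum.Enum):
    VALUE = "value"
    ZERO = "zero"
    UNDEFINED = "undefined"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class NeutralityStatus:
    """NI outcome: an exact rational value or one of the degenerate statuses."""

    kind: NIKind
    value: Optional[Fraction] = None

    def render(self, decimals: int = 3) -> str:
        """Table-style rendering: a number, '0', 'Undefined' or 'NA'."""
        if self.kind is NIKind.VALUE:
            return f"{float(self.value):.{decimals}f}"
        if self.kind is NIKind.ZERO:
            return "0"
        if self.kind is NIKind.UNDEFINED:
            return "Undefined"
        return "NA"


def neutrality_index(counts: MKCounts) -> NeutralityStatus:
    """Evaluate NI = (Pn/Ps)/(Dn/Ds) with its degenerate-status conventions."""
    ds, dn, ps, pn = counts.as_tuple()
    if ds == dn == ps == pn == 0:
        return NeutralityStatus(NIKind.NOT_APPLICABLE)
    if pn == 0 and dn > 0:
        # the zero numerator takes precedence over any zero denominator
        return NeutralityStatus(NIKind.ZERO)
    if dn == 0 or (ps == 0 and pn > 0) or ds == 0:
        return NeutralityStatus(NIKind.UNDEFINED)
    return NeutralityStatus(NIKind.VALUE, (pn / ps) / (dn / ds))


def _round_count(x: Fraction, rounding: Rounding) -> int:
    if rounding == "half_even":
        return round(x)  # Fraction.__round__ is round-half-to-even
    if rounding == "half_up":
        return math.floor(x + Fraction(1, 2))
    raise ValueError(f"unknown rounding {rounding!r}")


def fisher_mk(
    counts: MKCounts, rounding: Rounding = "half_even"
) -> tuple[float, tuple[int, int, int, int]]:
    """Two-sided Fisher's exact test on the rounded 2x2 MK table.

    Returns ``(p_value, (Ds', Dn', Ps', Pn'))`` where the primed counts are
    the integer roundings (half-to-even by default) entering the table
    [[Ds', Dn'], [Ps', Pn']]. A zero margin gives p = 1.
    """
    ds, dn, ps, pn = (_round_count(x, rounding) for x in counts.as_tuple())
    if min(ds + dn, ps + pn, ds + ps, dn + pn) == 0:
        return 1.0, (ds, dn, ps, pn)
    p = float(fisher_exact([[ds, dn], [ps, pn]], alternative="two-sided").pvalue)
    return min(p, 1.0), (ds, dn, ps, pn)


@dataclass(frozen=True)
class MKResult:
    """Counts, neutrality status and Fisher p-value for one gene."""

    gene_id: str
    counts: MKCounts
    ni: NeutralityStatus
    rounded_table: tuple[int, int, int, int]
    p_value: float
    trait: str = ""

    def render_row(self) -> dict[str, str]:
        """One Table-style report row with counts and NI to 3 decimals."""
        ds, dn, ps, pn = self.counts.as_tuple()
        return {
            "trait": self.trait,
            "gene": self.gene_id,
            "Ds": f"{float(ds):.3f}",
            "Dn": f"{float(dn):.3f}",
            "Ps": f"{float(ps):.3f}",
            "Pn": f"{float(pn):.3f}",
            "NI": self.ni.render(),
            "p": f"{self.p_value:.3f}",
            "codons_used": str(self.counts.codons_used),
            "codons_dropped": str(self.counts.codons_dropped),
        }


def result_from_counts(
    counts: MKCounts, trait: str = "", rounding: Rounding = "half_even"
) -> MKResult:
    p, table = fisher_mk(counts, rounding)
    return MKResult(
        gene_id=counts.gene_id,
        counts=counts,
        ni=neutrality_index(counts),
        rounded_table=table,
        p_value=p,
        trait=trait,
    )


def run_mk(
    aln: CodonAlignment,
    code: GeneticCode,
    stop_policy: StopPolicy = "exclude",
    rounding: Rounding = "half_even",
) -> MKResult:
    """Count a cleaned alignment and derive NI and the Fisher p-value."""
    return result_from_counts(count_gene(aln, code, stop_policy), rounding=rounding)


@dataclass(frozen=True)
class MKSummary:
    """Cross-gene tallies over a batch of MK results."""

    n_genes: int
    ni_below_one: int  # 0 < NI < 1: putative positive selection
    ni_above_one: int  # NI > 1: consistent with weak purifying selection
    ni_zero: int
    ni_undefined: int
    not_applicable: int
    significant: int  # Fisher p < alpha
    alpha: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_genes": self.n_genes,
            "ni_below_one": self.ni_below_one,
            "ni_above_one": self.ni_above_one,
            "ni_zero": self.ni_zero,
            "ni_undefined": self.ni_undefined,
            "not_applicable": self.not_applicable,
            "significant": self.significant,
            "alpha": self.alpha,
        }


def summarize(results: Sequence[MKResult], alpha: float = 0.05) -> MKSummary:
    """Tally NI classes and Fisher significance across genes."""
    if not results:
        raise ValueError("no results to summarize")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    below = above = zero = undef = na = sig = 0
    for r in results:
        if r.ni.kind is NIKind.VALUE:
            if r.ni.value < 1:
                below += 1
            elif r.ni.value > 1:
                above += 1
        elif r.ni.kind is NIKind.ZERO:
            zero += 1
        elif r.ni.kind is NIKind.UNDEFINED:
            undef += 1
        else:
            na += 1
        if r.ni.kind is not NIKind.NOT_APPLICABLE and r.p_value < alpha:
            sig += 1
    return MKSummary(len(results), below, above, zero, undef, na, sig, alpha)
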