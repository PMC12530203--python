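"""Independent brute-force oracle for pathway-averaged codon step counts.

Deliberately shares no code with the package: permutations come from
itertools and translation from Biopython's Seq.translate, so agreement
with codonmk.pathway_average is a genuine dual-route check.
"""

from fractions import Fraction
from itertools import permutations

from Bio.Seq import Seq


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_force_average(
    origin: str, target: str, exclude_stop_paths: bool = True
) -> tuple[Fraction, Fraction]:
    """Mean (syn, nonsyn) step counts over all orderings of the differences.

    With ``exclude_stop_paths``, orderings whose intermediate codons
    translate to '*' are discarded; if none survive, all orderings count.
    """
    if origin == target:
        return Fraction(0), Fraction(0)
    diffs = [i for i in range(3) if origin[i] != target[i]]
    paths = []
    for order in permutations(diffs):
        current = origin
        syn = nonsyn = 0
        through_stop = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + target[pos] + current[pos + 1 :]
            if step < len(order) - 1 and _aa(nxt) == "*":
                through_stop = True
            if _aa(nxt) == _aa(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((through_stop, syn, nonsyn))
    if exclude_stop_paths:
        kept = [(s, n) for stop, s, n in paths if not stop]
        if not kept:
            kept = [(s, n) for _, s, n in paths]
    else:
        kept = [(s, n) for _, s, n in paths]
    total_syn = sum(s for s, _ in kept)
    total_nonsyn = sum(n for _, n in kept)
    return Fraction(total_syn, len(kept)), Fraction(total_nonsyn, len(kept))
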