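# Methods

## The test and its sampling design

`codonmk` implements the count-based McDonald–Kreitman test for the smallest
sampling design it is meaningful for: two in-group coding sequences and one
out-group sequence per gene. Variation segregating within the in-group pair
(polymorphism) is compared with variation fixed between in-group and
out-group (divergence), split into synonymous and non-synonymous changes:

* **polymorphic position** — the two in-group residues differ;
* **fixed position** — the in-group residues agree with each other and
  differ from the out-group residue.

A single out-group cannot polarize substitutions onto lineages, so "fixed"
means unpolarized in-group/out-group difference. With only two in-group
chromosomes, within-species variation (especially synonymous variation) is
systematically undersampled; this depresses the power of the Fisher test and
biases the neutrality index upward, which is why genes with NI < 1 remain
informative at this depth while large NI values should be read cautiously.

No site-count normalisation is applied: the outputs are raw step tallies
(the inputs to the 2×2 exact test), not dN/dS rate estimates. Codon models,
polarized MK variants, and adaptive-fraction (alpha) estimation are out of
scope.

## Alignment hygiene

Inputs are pre-aligned, in-frame CDS FASTA (frame starts at position 1; no
ORF search). Cleaning is codon-granular: any codon column containing a gap
or an IUPAC ambiguity code in *any* of the three sequences is removed from
all three, keeping the reading frame and the set of counted codons identical
across sequences. The removed-column count is carried through to the report
(`codons_dropped`). An alternative end-trim mode (`mode="end-trim"`) removes
only terminal runs of unusable columns and refuses internal ones, for users
who prefer trimming to column excision.

A stop codon in the final column is treated as the CDS terminator and
trimmed from all three sequences. A stop anywhere else is a hard error — a
frameshifted or mis-extracted gene, through which pathway counting is
undefined. Coordinates in all reports are 1-based codon indices. Cleaning an
alignment down to zero codons is legal; it simply yields all-zero counts and
an `NA` status downstream.

## Pathway counting

For codons differing at d positions (d ≤ 3), the d! orderings of
single-nucleotide steps are enumerated. Each step is labelled synonymous or
non-synonymous under the genetic code (standard table 1 embedded; other NCBI
table ids via Biopython). Pathways are **equally weighted** — no
transition/transversion or codon-frequency weighting — so the averages are
exact rationals; all arithmetic uses `fractions.Fraction` and floats appear
only at rendering and in the Fisher p-value.

Orderings whose *intermediate* codons are stops are excluded by default
(`stop_policy="exclude"`): such a history passes through a nonfunctional
protein. Two refinements matter:

* if *every* ordering is excluded, the exclusion is suspended and all d!
  orderings are retained, rather than silently discarding the codon's
  signal;
* endpoints are never screened, because the divergence-origin construction
  below can produce a codon not observed in any sequence.

Exclusion means the mean can legitimately run over 4 or 5 of the 6 orderings
of a triple difference (e.g. TTA→AAT, where the two orderings through TAA
are dropped), so count denominators divide the number of *retained*
pathways — they are not restricted to {1, 2, 3, 6} in general, although the
no-exclusion policy does keep them within divisors of d!.
`stop_policy="include"` disables exclusion entirely.

### Codons carrying both polymorphic and fixed positions

Such codons are decomposed deterministically:

* polymorphism is counted between the two in-group codons (all their
  differing positions are polymorphic by definition);
* divergence is counted between the out-group codon and a **divergence
  origin**: the in-group codon with out-group residues substituted at the
  polymorphic positions. The origin then differs from the out-group codon at
  exactly the fixed positions, and is symmetric in the two in-group codons.

This guarantees that Ps + Pn sums only within-in-group differences, Ds + Dn
only fixed differences, and that each comparison's syn + nonsyn contribution
equals its nucleotide difference count exactly. It is one defensible reading
of classic pathway-counting practice for mixed codons; since the divergence
origin is evaluated in the out-group codon's context, a step's syn/nonsyn
label can depend on that context (deliberately so — the alternative of
classifying against an arbitrary in-group context is no less conventional
and is not configurable here).

## Neutrality index and Fisher's exact test

NI = (Pn/Ps)/(Dn/Ds) is computed on the **unrounded** exact rationals (the
packaged table's 14.056 for WAPL requires Dn = 1/3 and Ds = 23/3; the
printed roundings 0.33 and 7.667 give a different third decimal). The
degenerate cases map to explicit statuses, in this precedence order:

1. `NA` — all four counts zero (no differences among the three sequences);
2. `0` — Pn = 0 with Dn > 0: the numerator of NI is zero, and this takes
   precedence over any zero in a denominator (so Ds = 0, Dn > 0, Pn = 0
   renders as 0, not Undefined);
3. `Undefined` — Dn = 0, or Ps = 0 with Pn > 0, or Ds = 0 with the
   remaining terms positive;
4. a value — Pn, Ps, Dn, Ds all positive.

The Fisher test needs integers, so the four counts are rounded
**half-to-even** (banker's rounding) before forming
[[Ds', Dn'], [Ps', Pn']]; this is the rounding under which the packaged
table's fractional-count p-values (0.026 with 3.5→4, 14.5→14; 0.076 with
0.33→0, 7.667→8) reproduce, whereas round-half-up does not
(`rounding="half_up"` is available for comparison). The two-sided p-value is
the minimum-likelihood rule — the sum of all hypergeometric table
probabilities not exceeding the observed table's, with a 1 + 1e-7 relative
tolerance for floating-point ties — as implemented by
`scipy.stats.fisher_exact`; any zero margin gives p = 1. No multiple-testing
correction is applied; the summary reports raw p < alpha (default 0.05)
tallies alongside the NI class tallies (0 < NI < 1, NI > 1, NI = 0,
Undefined, NA).

## The synthetic-data generator

`simulate_gene` emulates the three-sequence design directly rather than a
full coalescent: an ancestral CDS of `n_codons` codons drawn uniformly from
the 61 sense codons; a Poisson(`mu_div`) number of proposed single-nucleotide
changes on the out-group copy; a Poisson(`mu_poly`) number on **one**
in-group copy (the other keeps the ancestral state — with an unpolarized
test and two in-group sequences this loses no generality, every accepted
in-group change being a polymorphism). Proposals are position-uniform with
uniform alternative bases (no Ts/Tv bias — the counting method is
rate-agnostic, so a Ts/Tv knob would only complicate the truth bookkeeping);
a proposal creating a stop is rejected; synonymous proposals are always
accepted and non-synonymous ones accepted with probability `omega_div` /
`omega_poly` per class. Accepted changes are recorded per class in
`SimTruth`, classified in the codon context at the moment of mutation.

Defaults — 500 codons (a typical candidate-gene CDS), 15 expected proposals
per class (a few percent divergence), neutral acceptance (omega = 1), one
seeded generator per gene with replicate r using seed base + r — are the
regime used by the test batteries. What the generator does *not* emulate:
segregating variation shared between in-group and out-group lineages,
recombination, demography, linked selection, rate heterogeneity along the
gene, alignment error, and indels. Passing simulation tests therefore
demonstrate correctness of counting and calibration of the exact test under
the model's own assumptions, not robustness to real-data violations of them.

Three properties are exercised at fixed seeds:

* **exact recovery** — when no codon receives two accepted hits (checked
  from the truth bookkeeping), counted Ds/Dn/Ps/Pn equal the truth exactly;
  at 10 hits per 1,000 codons most replicates qualify;
* **type-I error** — with equal omegas, the Fisher rejection fraction over
  1,000 replicates at alpha = 0.05 stays ≤ 0.06 (the exact test is
  conservative; the observed fraction is ~0.03);
* **direction** — omega_div ≫ omega_poly drives the median defined NI below
  1, and conversely.

## The packaged count table

`make_table1_fixture` returns a machine-readable 37-gene table of published
MK counts from the song-sparrow candidate-gene scan, with fractional counts
stored as exact rationals (2.333 as 7/3, 0.33 as 1/3, halves as halves) and
six genes with no differences carried as `NA`. `codonmk table1-check`
recomputes NI and p for every row and reports per-cell agreement at
3-decimal precision. One caveat a user will notice: the per-gene counts
yield **eight** genes with NI > 1; published prose summaries of this table
give seven, which is inconsistent with the table's own rows, and the package
reports what the counts imply.

## Numerical and interface choices

* Exact rationals everywhere until rendering; reports show counts and NI to
  3 decimals, statuses as `0` / `Undefined` / `NA`.
* Batch runs never abort on a failed gene (frame error, internal stop,
  missing record): the gene is reported in a failures section and the exit
  code is non-zero, since partial results remain scientifically useful.
* Gene ids come from FASTA filename stems; record roles are always assigned
  explicitly by identifier, never inferred from header text.
* All commands are deterministic for fixed inputs and seeds; logs go to
  stderr, data to stdout or files.
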