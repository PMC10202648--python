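# Methods

## Junction signatures

Every analysis in the package reduces a rearrangement to a *junction
signature*: the unordered pair of reference sides flanking a recombined
loxPsym motif, each side written `(site_id, L|R)` where `L` is the
sequence immediately 5′ of that site's motif and `R` immediately 3′.
Because the motif is palindromic, a junction read and its reverse
complement describe the same molecule, and the unordered side pair is
exactly the strand-free invariant: reads are canonicalized to the
lexicographically smaller of (read, revcomp) before any other step.

The signature algebra fixes the class rules. On one chromosome, an `L/R`
join in reference order is a deletion junction; the reversed order is the
duplication/excision-circle join (one junction read cannot distinguish
the two, so they share the `complex` bucket); `L/L` or `R/R` joins are
inversion breakpoints; different chromosomes give `inter`. On a circular
chromosome "order" is modular: an `L/R` join deletes the forward arc from
the `L` endpoint to the `R` endpoint and is labelled a deletion when that
arc is the shorter of the two (ties break toward deletion). The
classifier is verified exhaustively against `enumerate_cre_products`,
which builds each single-event Cre product by direct sequence surgery
(excision + circle, inversion, reciprocal translocation), rediscovers its
junctions by motif scanning on the product sequence, and labels them by
the product that created them. For inter-chromosomal pairs the oracle
enumerates the direct reciprocal exchange (two junctions); the simulator
additionally samples the orientation-flipped exchange, whose junctions
classify as `inter` all the same.

## Recombination model

Events are drawn per cell, `k ~ Poisson(lambda_events)`, with pair choice
proportional to

    w_ij = (a_i * a_j)^alpha * C(bin_i, bin_j)^beta

where `a` is a latent per-site accessibility and `C` the binned contact
probability. This is the minimal positive, symmetric, separable law
consistent with accessibility mattering at each site independently
(Cre must reach both) and contact mattering for the pair jointly;
`alpha = beta = 0` recovers uniform choice, and both exponents are free
parameters. Intra-chromosomal outcomes split 50/50 between deletion and
inversion (the palindromic site permits both and nothing in the data
constrains the ratio); inter pairs recombine as reciprocal exchanges with
the two relative orientations equally likely.

Two simulation modes serve different purposes. `junction_pool` (default)
records each event's junctions against the fixed reference — the correct
regime for validating the caller and the landscape statistics, since
truth frequencies then equal the sampling weights. `genome_sequential`
applies events in order to an evolving genome held as motif-delimited
reference segments with orientation; inversions flip segment runs,
deletions drop them (the excised circle is assumed lost before
sequencing, so only the chromosomal junction is observable), and
translocations exchange or integrate arms, with rings fusing or
integrating as topology dictates. Centromere bookkeeping rides on the
segments, and a cell is viable only if every chromosome ends with exactly
one centromere — acentric and dicentric products are scored as death and
their cells discarded (but logged). Composite genotypes (duplications,
circularizations) arise only in this mode, as multi-event products.

## Synthetic data

The generator emulates the study's input data shapes, not its absolute
magnitudes:

* **Genomes** are pseudo-random nucleotide sequences with a synthetic
  34-bp palindrome spliced at declared positions. The real loxPsym
  sequence is not shipped and nothing depends on its literal identity —
  any palindromic 34-mer validates. Profiles: `toy` (2 chromosomes, 10
  sites), `ring` (circular + linear control with sites flanking the
  origin), `mini` (6 chromosomes, ~200 sites, ~600 kb — the working scale
  for stochastic studies), `paperlike` (6 chromosomes including one ring,
  894 sites of which 17 sit inside 5-kb telomere tracts, leaving 877
  analyzable — the design-accounting fixture).
* **Accessibility**: log-normal per-site weights (σ = 0.75) with a 20%
  "open" subset boosted 8×; the per-base track is uniform background
  noise (≤0.05) plus one Gaussian peak per site (sd 120 bp, clipped to
  the ±400 bp window) of integral ∝ weight, so window means rank-recover
  the weights (Spearman ≥ 0.95 by construction check).
* **Contacts**: 1-kb bins; intra-chromosomal `C = (1+d)^-gamma` with `d`
  the topology-aware bin distance (rings wrap, making former ends
  proximal); inter-chromosomal baseline κ = 0.01; entries whose bins are
  both pericentromeric ×4 (spindle-pole clustering), both peritelomeric
  ×4 (nuclear-envelope clustering). Defaults γ = 1, chosen as the
  canonical polymer-like decay.
* **Reads**: 150 bp spanning a junction, motif offset uniform subject to
  both flanks ≥ `min_flank` (20 bp), substitution errors only — no
  indels, no quality model, no duplicated genomic sequence. Background
  reads are uniform draws from the reference on both strands.

What passing tests on these data do **not** show: robustness to indels or
repeat-induced mapping ambiguity, to non-uniform coverage, or to the real
data's scale (hundreds of thousands of events at ~600 000× coverage);
the studies run at 10⁴–10⁵ events/reads on ~200-site genomes, sizes at
which every statistic tested is already stable.

## Caller design

`scan_motif` returns the leftmost window within the Hamming budget
(default 0; 1 in the noisy studies). Flank mapping is exact-match only:
candidate placements come from an index of `min_flank`-mers over both
strands (circular chromosomes indexed through the origin) and are
verified over the full flank; a unique occurrence maps, several are
`ambiguous`, none — `unmapped`. A mapped flank must abut a registered
motif boundary exactly (tolerance 0). Every read therefore lands in
exactly one of `no_motif`, `reference`, `novel`, `unresolvable`, and a
substitution inside a flank can only demote a read to `unresolvable`,
never create a wrong signature.

Deduplication follows the experiment's convention: byte-identical
(canonical) reads collapse to one rearrangement *event*; distinct reads
over the same junction stay separate events sharing a signature, so
tallies by event number and by read number are both available.

Recovery is measured two ways. Error-free emission is recovered read for
read (asserted at 100%). Under 0.5% substitutions, a read with any flank
error is unresolvable by design — per-read recovery is then bounded near
`0.995^116 ≈ 0.56` and is not a meaningful target — so noise tolerance
is scored per junction: a junction is recovered when at least one of its
~Poisson(10) reads is called with the correct signature, which the
studies show at ≥ 99% with zero false novel calls on background-only
input.

## Landscape and statistics conventions

Per-site frequencies count rearrangement *reads*: each junction credits
its two endpoint sites with its full read count, so total site mass is
exactly twice total read mass (an events-based landscape is a flag).
Telomeric sites are excluded before counting — their flanks are not
mappable in the real assay — and an event touching one is an error, not
a silent drop. Sites are ranked into 10% steps; hotspots and coldspots
are the top and bottom `round_half_up(0.10 N)` (877 → 88), ties broken
by site_id for determinism. `pearson` implements the product-moment
coefficient with the exact t-transform P value (n−2 df) and is tested to
1e-12 against closed form and an independent library implementation. No
multiple-testing correction is applied anywhere; all P values are raw
and two-sided.

## Chromatin integration choices

Window signal is the *mean* over the motif-centered ±400 bp window
(truncated at linear ends, wrapped on rings) so truncation does not bias
the level; normalization divides by the mean over all analyzable sites,
making the normalized values average exactly 1. Pseudocounts: 1e-6 on
contacts and +1 on read counts before log2. Group comparisons report
weighted means (equal weights unless the caller supplies others, since
the appropriate weighting is data-dependent) with a paired t-test when a
pairing exists and Welch's unequal-variance test otherwise — unequal-size
region comparisons can never be paired — and the mode is always recorded.

The joint model is ordinary least squares of
`log2(f+1) = b0 + b_a log2(a_i a_j) + b_c log2(C + 1e-6)` with constant
or collinear predictors flagged. On noise-free tables generated from the
law the fit is exact to machine precision; on simulated pools the
coefficients are attenuated (≈0.5 at generation exponents of 1) by
Poisson counting noise, the +1 pseudocount and the truncation to observed
pairs, so only their signs are asserted.

Region enrichment aggregates inter-chromosomal read counts to 1-kb bins
(both endpoints credited). The contact comparison uses all bins; the
frequency comparison uses only bins containing at least one analyzable
site, because siteless bins are structural zeros that dilute both groups
without carrying information about recombination. The compensation
panels (matched accessibility / matched contact / counter-effect) are a
quadratic search, so tables beyond 500 rows are restricted to the
best-supported pairs; the panels illustrate matched examples rather than
exhausting them.

## Determinism and numerics

Every stochastic component draws from one `numpy` PCG64 generator seeded
by the study or config seed; draw order is fixed by the code path
(weights → events → reads, with read emission on `seed + 1` so pools and
emission can be re-run independently). Same seed means byte-identical
FASTQ, tables and JSON. Coordinates are 0-based half-open internally;
bedGraph/BED outputs follow the same convention. Degenerate inputs are
rejected loudly (zero variance in a correlation, fewer than 10 sites for
deciles, fewer than 2 values per comparison group) rather than repaired.

## Known limitations

The simulator does not model Cre expression kinetics, induction dose,
fitness beyond the one-centromere rule, duplicated or repetitive
reference sequence, or read indels; the caller correspondingly has no
gapped alignment and treats ambiguity as unresolvable rather than
rescuing it. Hi-C-style matrices are generated and consumed as dense
text at desk scale — no ICE/KR balancing, compartment or TAD logic.
Copy number is never inferred from a single junction; `complex` is
deliberately one bucket.
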