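# loxscape

Simulation and analysis of Cre/loxPsym (SCRaMbLE-style) chromosome
rearrangements on synthetic yeast chromosomes.

## The problem

Synthetic yeast chromosomes carry 34-bp palindromic loxPsym sites in the
3′ UTRs of non-essential genes. Inducing Cre recombinase drives
recombination between pairs of these sites, producing deletions,
inversions, duplications/circularizations and translocations at massive
scale. Deep sequencing of such a recombined pool reveals a reproducible
*landscape*: some loxPsym sites recombine far more often than others, and
the pattern tracks two layers of chromatin organization — local
accessibility (how reachable a site is for Cre) and 3D contact
probability (how often two sites meet in the nucleus).

`loxscape` provides the full analysis chain for this kind of experiment,
plus a generative simulator so every stage can be verified against known
ground truth without any external data:

* **genome model** — chromosomes (linear and circular), the loxPsym site
  registry, topology-aware distances, pericentromeric (CEN, centromere
  ±5 kb) and peritelomeric (TEL, ≤5 kb from a telomere) region classes;
* **simulator** — recombination events whose pair choice follows
  `w_ij = (a_i·a_j)^α · C_ij^β` (accessibility `a`, binned contact
  probability `C`), with a one-centromere viability rule, junction-spanning
  150-bp reads, a matching bedGraph accessibility track and a 1-kb contact
  matrix with distance decay and CEN/TEL cluster enrichment;
* **junction caller** — motif scan (Hamming budget), exact-match flank
  mapping on both strands, reference/novel/unresolvable calls, and
  deduplication in which identical reads count as one rearrangement event;
* **classifier** — deletion / inversion / complex
  (duplication-or-circularization) / inter-chromosomal labels from junction
  geometry, circular-topology aware, checked exhaustively against a
  brute-force sequence-surgery oracle of all single-event Cre products;
* **landscape statistics** — per-site rearrangement read counts (each
  junction credits both endpoint sites), 10% frequency steps with
  hotspot/coldspot calls (top and bottom decile, round-half-up), Pearson
  correlations with exact t-transform P values;
* **chromatin integration** — site-centered ±400 bp window signal
  normalized to the all-site mean, log2 contact extraction, weighted-mean
  group comparisons (paired or Welch t-tests), the joint log-linear
  accessibility × contact fit, CEN/TEL enrichment tests and
  "compensation" pair-of-pairs panels.

## Worked example

The numbered scripts under `analysis/` run the canonical studies on a
synthetic 6-chromosome genome (~200 sites, ~600 kb) and write their tables
under `results/`. For example:

```
$ python analysis/03_landscape_recovery.py
reads analyzed:        131853
truth Spearman rho:    0.979
hotspot Jaccard:       1.000
hotspot accessibility: 4.42 vs coldspot 0.16 (p = 6.56e-10)
sites-per-chromosome r: 0.867
replicate landscape r:  0.999
```

Reading this: a pool was simulated under α = β = 1, its ~1.3 × 10⁵ reads
were called and classified, and the recovered per-site landscape ranks the
sites almost exactly as the true marginal weights do (Spearman 0.979); the
called hotspot set coincides with the truth top decile (Jaccard 1.0);
hotspots sit in ~27× more accessible chromatin than coldspots, and two
independent pools under the same weights give near-identical landscapes.

```
$ python analysis/05_ring_topology.py
ring:   1174/9962 end-joining events
linear: 119/9999
enrichment: 9.9x (one-sided binomial p = 0)
```

On a circular chromosome the two former ends are adjacent, so
recombination between the origin-flanking sites is ~10× enriched over an
otherwise identical linear control — purely a topology effect carried
through the contact model.

A full pipeline run (simulate → call → classify → landscape → integrate)
is one command over a generated fixture:

```
loxscape fixture toy --seed 1 --outdir demo/
loxscape run --config demo/toy.config.yaml
```

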