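# Methods

This note documents the models, parameter choices and numerical decisions
behind `haplocheck`: what the simulator emulates, how each processing
stage is defined, and which behaviours are design choices rather than
forced by the science.

## 1. The mock-community model

The simulator generates the kind of controlled assemblage used to
validate metabarcoding workflows against individual barcoding: colonies
of two congeneric, morphologically confusable colonial invertebrates,
collected at several marinas, preserved together in jars, and sequenced
as amplicon libraries.

### Reference geometry

Two species are represented by central haplotypes differing at exactly
`interspecies_distance` positions (default 74 — a deep, unambiguous
barcoding gap for a COI fragment). Within each species, satellite
haplotypes sit at configured Hamming steps from the central haplotype
(defaults: steps 1, 2, 2, 3, 5, 8 for the dominant species, one 1-step
satellite for the second — nine haplotypes in total, mirroring a
star-like intraspecific genealogy with mostly 1–2-nt variants plus a few
more distant ones). Satellite mutations use position sets disjoint from
each other and from the interspecies sites, so all within-species
distances (≤ 16) stay far below all between-species distances (≥ 74); the
generator rejects configurations for which the amplicon is too short to
allow this.

The amplicon is a fixed-length 412-nt insert. Length variation, indels
and quality scores are deliberately out of scope: the marker is a
protein-coding fragment in which the error processes of interest are
substitutions, crossovers and misassignment, and fixed length keeps every
downstream rule deterministic.

### Assemblages

Each of `n_locations` (default 10) locations contributes
uniform(32–36) colonies split near-evenly between two jars (A/B).
Colonies draw haplotypes i.i.d. from a per-location frequency vector.
The built-in default frequency structure is deterministic (no hidden
randomness): the dominant species everywhere, its central haplotype
commonest; two common satellites trading places along the location
gradient (this is what creates genuine between-location differentiation
for F_ST); several rare, patchy satellites; and the second species
present in a quarter of locations at a 15% share. Users studying other
regimes pass their own `haplotype_frequency_spec`.

Individual-barcoding failure is emulated separately: the true colony
table always carries every haplotype, and `mask_failed_colonies` hides
each colony's haplotype with a small probability (default 0.003 ≈ one
colony in ~350) in the *observed* table that the evaluation layer treats
as ground truth — exactly as a failed Sanger reaction would.

### Read generation

Per technical replicate (9 per sample = 3 extraction × 3 tagged-PCR;
depth D = 20,000 reads):

1. **Amplification bias.** Every colony in the jar receives an
   independent lognormal(0, σ_bias) weight (σ_bias default 0.5); a
   haplotype's expected read share is the normalised sum of its colonies'
   weights. This is the single biological noise source: it makes read
   proportions an imperfect but strongly correlated proxy of colony
   proportions, as observed in biomass-equalised mock communities.
2. **Template sampling.** D reads drawn multinomially from those shares.
3. **Chimeras.** Binomial(D, ρ_c) reads (ρ_c default 0.01) are replaced
   by two-parent crossovers: parents drawn abundance-weighted (the PCR
   mechanism — abundant templates recombine most), breakpoint uniform on
   [min_seg, L − min_seg] (min_seg 10).
4. **Substitution errors.** Every base flips independently with
   probability ε (default 2×10⁻³) to a uniform other base. The
   implementation samples the Bernoulli field exactly as a binomial total
   plus uniformly chosen distinct cells, so only reads that actually
   carry an error are materialised. Optional hotspot positions at an
   elevated rate are shared across replicates (default off).
5. **Index jumps.** Each finished read is reassigned with probability ρ_j
   (default 10⁻³) to a uniformly chosen other replicate *or control index
   combination* — the only way reads reach the 12 controls.

Twelve-month-aged preservative samples (`ebDNA12`) first apply a
two-knob degradation: per-replicate colony dropout (default 0.25) and a
depth multiplier (default 0.5). The degradation kinetics of real aged
ethanol are not quantified anywhere we know of; these defaults are
illustrative of "weaker, noisier amplification" and are exercised only
for the directional comparison (degraded < pristine correlation), never
for calibrated claims.

Every replicate has its own RNG stream seeded from (run seed, CRC32 of
the replicate id): replicates are independent and individually
reproducible, and total reads across replicates + controls always equal
the summed depths (conservation is asserted in tests).

### What the simulator does *not* emulate

Real libraries have quality-dependent and motif-dependent errors, indels,
primer and length artefacts, cycle-explicit PCR dynamics, and
tag-switching biased toward adjacent wells. Passing tests on this
simulator therefore demonstrates that the *pipeline logic* (merging
rules, thresholds, accounting, estimators) behaves as specified under a
realistic statistical structure — not that any particular wet-lab setup
will achieve the same correlations.

## 2. Processing stages

All stages operate on dereplicated unique sequences with dataset-wide
abundances, process them in descending abundance (ties broken
lexicographically), conserve read counts exactly, and are invariant to
input order.

* **Denoiser.** A centroid `c` may absorb a rarer sequence `u` when
  `d = editdist(u, c) ≤ d_max` (default 10) and
  `abundance(u)/abundance(c) ≤ β(d) = 2^−(αd+1)` (α default 2) — an
  abundance-skew law of the kind published denoisers use: the rarer and
  closer a sequence, the more plausibly it is an error. Among qualifying
  centroids `u` merges into the **closest** (ties: more abundant, then
  lexicographically smaller). Attributing by distance rather than by
  abundance matters: at ε = 2×10⁻³ over 412 nt, ~56% of reads carry at
  least one error, and attributing those by "most abundant qualifying
  centroid" would systematically funnel satellite haplotypes' error reads
  into the dominant haplotype, deflating satellite frequencies by up to
  half. Abundances are the static dereplicated totals, making the result
  independent of merge order.
* **Greedy clustering.** `u` joins the highest-identity centroid with
  `identity = 1 − editdist/max(len)` at or above the threshold (default
  0.99); ties go to the more abundant, then lexicographic. This is the
  classic abundance-sorted OTU builder and intentionally keeps its
  archetypal failure mode: at 0.99 over 412 nt it merges variants up to 4
  substitutions away, so near satellites are false negatives by design.
* **Linkage clustering.** Connected components of the graph with edges at
  edit distance ≤ d (default 1) — the multi-local-threshold archetype.
  Chains of 1-step error variants can bridge satellites into the central
  haplotype; that, too, is the documented trade-off being measured.
* **Chimera removal.** A feature `x` is flagged when two distinct other
  features, each ≥ `skew` (default 2.0) times as abundant, explain it as
  prefix + suffix with ≤ `max_mismatch` (default 0: the canonical
  crossover is exact) mismatches at a breakpoint ≥ `min_seg` from both
  ends; the smallest valid breakpoint is reported. Removed reads are
  accounted in the log, so counts remain auditable.

### Performance mechanics (no effect on small inputs)

Centroid search uses an exact-position piece index: split every
centroid into `d+1` contiguous pieces; by pigeonhole, any sequence within
Hamming distance d of a query shares at least one piece at the same
offsets, and one sharing fewer than `d+1 − t` pieces cannot lie within
distance t. Candidates are probed best-supported-first so the current
best distance shrinks immediately, and survivors are verified with
banded Levenshtein (edlib). The filter is exact for substitution-type
differences — the regime of fixed-length amplicons; for safety the
stages fall back to exhaustive scans whenever the centroid list is small
or lengths vary. Linkage at d = 1 on equal-length input is solved
exactly by column-masked hashing (edit distance 1 between equal-length
strings is necessarily a single substitution), with every candidate pair
verified by direct comparison.

## 3. Post filters

* **Index-jump filter.** M = the maximum, over control combinations, of
  the total reads landing in that combination; features whose summed
  count in a sample is ≤ 2M are zeroed there (features failing everywhere
  are dropped). M as a per-combination *total* matches reporting a single
  per-run control maximum; a per-feature-per-combination variant is
  available. Per-sample scope is the default because rare true
  haplotypes occur at a handful of reads per sample; a dataset-wide
  "global" mode is kept for sensitivity analyses. Control columns are
  consumed by this filter and dropped from the output (controls are not
  samples); every removed read is accounted.
* **Replicate-consensus filter.** A feature is kept in a sample only if
  present (≥ 1 read by default) in ≥ `min_replicates` (default 5) of the
  sample's 9 technical replicates. True haplotypes amplify in every
  replicate; specific error sequences rarely recur in five.

Both filters are idempotent and monotone (raising a threshold never
retains more reads) — both properties are tested. Filter order defaults
to index-jump then replicate and is configurable.

## 4. Assignment

Alignment is global and end-gap-free (match +1, mismatch −1, gap −2, end
gaps free) — appropriate for near-full-length amplicons against a curated
reference panel, and fully deterministic, which a heuristic database
search is not. Identity is computed over the aligned columns between the
first and last aligned pair (internal gaps count, terminal overhangs do
not); subject coverage is the subject span of that region. Alignments
covering < 99% of the subject are discarded; the best identity wins the
species call; a tie between references of different species voids it. A
haplotype is called only for an exact full-length sequence match to a
single reference — any distinct-reference tie (even within one species)
voids the haplotype call, the stricter reading consistent with requiring
exact identity. Exact ties are decided on integer match/column counts,
never on floating-point identity.

## 5. Population genetics

Gene diversity uses the unbiased form `H = n/(n−1)(1 − Σ p_a²)`, equal to
the fraction of ordered pairs of distinct individuals that differ (the
enumeration is the test oracle). Pairwise F_ST is the Weir–Cockerham
variance-component estimator in haploid form (see README for the
formula); it equals, and is tested to 10⁻¹² against, a two-population
AMOVA with 0/1 haplotype distances. Negative estimates are reported as
computed (they are the estimator's behaviour near θ = 0); zero-truncation
is a display option. Undefined pairs (both populations fixed for the
same haplotype) are NaN with a warning.

Two conventions deserve explicit statement:

* **Sample sizes.** Read-based populations use the read total as n (so
  the n/(n−1) correction is negligible — the plug-in behaviour of
  frequency-fed software); colony-based populations use colony counts.
  Both are recorded in the tables so the choice is auditable.
* **Allele level.** Read-based frequencies default to one allele per
  *feature* assigned to the focal species — this is how ASV/OTU
  frequency tables actually feed population-genetic software, and it is
  what keeps frequency-based indices usable even for pipelines that
  merge or split haplotypes. The stricter variant (only exact-identity
  haplotype calls, pooled by haplotype) is available as
  `allele_level="haplotype"`.

## 6. Evaluation layer

Haplotype accounting compares feature sequences with the haplotypes
actually carried by ≥ 1 colony: recovered + missing partition the
expected set; features matching no expected haplotype are unexpected and
their read share is reported. Proportion correlations pool
(read share, colony share) points over haplotypes × jars. Friedman uses
the standard tie-corrected statistic (χ² p with df = k−1; exact
enumeration over within-block orderings for small instances); the paired
Wilcoxon drops zero differences and enumerates the exact null by an
integer subset-sum over doubled (possibly tied) ranks for n ≤ 25, else a
tie-corrected normal approximation; pairwise p-values are Holm-adjusted
by default (Benjamini–Hochberg available). The Mantel test permutes the
second matrix's rows and columns jointly, `p = (1 + #{r* ≥ r})/(1 + n_perm)`
with 999 seeded permutations by default, full enumeration for ≤ 7 labels.
Species-proportion comparisons use a two-sided Fisher exact test after
downscaling read counts to a colony-equivalent sample (the location's
colony total split by read proportions) — raw read counts would make any
difference trivially significant, so the test is calibrated to the
information an individual-barcoding survey of the same size carries.

UPGMA is average-linkage agglomeration (scipy) with negative distances
floored at zero for clustering only; the newick carries ultrametric
branch lengths (cluster height = merge distance / 2). Haplotype networks
are Kruskal minimum spanning trees over Hamming distances with
deterministic tie-breaking by node label; a rejected edge is an
*alternative link* exactly when its weight equals the maximum weight on
the tree path between its endpoints — equivalently, when it belongs to
some other minimum spanning tree (the brute-force family over all
spanning trees is the test oracle). Node display size is the fourth root
of abundance.

## 7. Problem sizes used in the checks

The end-to-end suite runs the full study design (10 locations × 2 jars,
9 × 20,000-read replicates + 12 controls ≈ 3.6 M reads, ~680 k unique
sequences) once per session for the recovery checks; the six-arm
comparison harness and the degradation comparison use a 6-location,
2,000-read-per-replicate configuration — large enough for every
qualitative contrast while keeping a full run in minutes on one CPU.

## 8. Known limitations

* The greedy and linkage arms at their default resolutions merge close
  satellite haplotypes by construction; their read-based gene-diversity
  correlation with the truth is accordingly weak. This is the
  false-negative half of the trade-off the harness exists to expose, not
  a target the package tries to engineer away.
* Chimera detection assumes two parents and equal lengths; multi-parent
  chimeras and indel-bearing artefacts are out of scope.
* The piece-index candidate filter is exact for substitution-type
  differences only; pathological inputs where alignment shifts produce
  small edit distances between very different strings could be clustered
  differently than an exhaustive scan would (never on the small inputs
  the exhaustive fallback covers).
* F_ST significance testing (permutation p-values per pair) is not
  implemented: the package reports estimator values and compares whole
  matrices via Mantel tests.
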