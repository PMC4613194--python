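# Methods

This note documents the models, parameters and design choices behind
`chimeraseg`, and what its tests do and do not establish.

## 1. Reference-community model

The simulated system is an aphid-style endosymbiont community: one
primary symbiont lineage ("BA") that co-diversifies with its hosts, plus
facultative secondary symbionts that are phylogenetically distant genera.

**Sequence architecture.** The 16S gene is modelled as an alignment of
`total_length` columns (default 1500) carrying `n_conserved` equal-length
conserved regions (default 10 × 50 bp), evenly spaced with the first and
last regions abutting the sequence ends — universal 16S primers bind in
conserved sequence, so the molecule's termini are conserved by
construction.  Coordinates are 0-based, half-open everywhere.

**Substitution model.** Sites evolve independently under Jukes–Cantor
(JC69) with two rate classes: variable columns at relative rate 1,
conserved columns at `conserved_rate` (default 0.02).  JC69 was chosen
because it admits a closed-form expected difference,
`π(t) = ¾(1 − e^(−4t/3))`, making divergence calibration an exact
one-dimensional root-finding problem rather than a simulation search.  No
indels: the alignment is implicit and exact.  No GTR/Gamma — divergence
*levels*, not substitution-process realism, are what the downstream
questions depend on.

**Calibration.** With variable-column fraction `f_v`, the expected
whole-sequence p-distance across a path of length `t` is
`E[p](t) = f_v·π(t) + (1−f_v)·π(0.02·t)`.  Branch lengths are solved by
Brent root-finding on this function:

- the host tree (pure-birth, 12 leaves by default, seeded) is rescaled so
  its deepest leaf pair has `E[p] = 0.128`, the top of the observed
  within-primary divergence range;
- each secondary sits on an independent branch off the primary's
  ancestral (root) sequence, solved to its target p-distance — defaults
  0.142 (Serratia-like), 0.124 (Sodalis-like), 0.150 (Arsenophonus-like),
  0.260 (Wolbachia-like).  Whether the published values are single-pair
  values or means is not stated in the source material; they are treated
  as point calibration targets for the root-to-secondary distance.

The *realized* maximum within-primary p-distance, averaged over seeds,
comes out near 13.7% rather than 12.8%: the maximum over all 66 leaf
pairs of binomially noisy distances exceeds the expectation at the single
deepest pair (an order-statistic effect of about +1 percentage point, well
inside the ±1.5 pp calibration band).  Secondary distances to the root
sequence centre on their targets with binomial noise only (SE ≈ 0.9 pp at
1500 columns).

## 2. Clone libraries and chimera formation

Each sample is a template mixture: the host's primary symbiont plus 0–2
secondaries with positive abundances summing to 1.  Each of `n_clones`
(default 20) clones is, with probability `chimera_rate`, a chimera;
otherwise an exact copy of one template drawn by abundance.  Clones are
error-free: sequencing error is irrelevant to every question asked here
and would only blur the divergence signals.

**Chimeras** use exactly two distinct parents (multi-parent chimeras
exist behind `allow_multiparent` but are off by default — observed
chimeras in this system involve the primary plus one partner).
Breakpoint count is uniform on `{1..max_breakpoints}` (default 2);
parents alternate, so two breakpoints give the sandwich structure A|B|A.
Breakpoint positions are uniform within distinct *internal* conserved
regions.  The terminal, primer-flanking regions are excluded by default
(`include_terminal_regions=False`): a crossover there yields a
(near-)full-length single-parent amplicon — chemically a re-annealing
event, but not an observable hybrid molecule.  The breakpoint is defined
as the first column contributed by the next parent.  Every simulated
clone carries its true provenance (an exact tiling of the alignment by
parent segments), which is the ground truth for detector scoring.

**Direct sequencing** is reduced to a dominance rule: the chromatogram of
the uncloned product is usable iff the most abundant template reaches
`dominance_threshold` (default 0.9).  The pipeline's sample generator
makes a sample primary-only with probability 1/6, reproducing the
observed ~2-in-12 rate of usable direct sequences; the mechanism behind
that observed rate is not known, so the threshold and the mixing
probabilities are exposed in `PipelineConfig` rather than hard-coded.

## 3. Segment-and-assign detection

The detector operationalises the remedy of splitting a query at conserved
regions and matching the portions separately against confirmed pure
references.

1. **Anchoring.**  A conserved region anchors if the query matches the
   panel's majority consensus with ≤ `anchor_mismatch_limit` mismatches
   (default 3 per 50-bp region; non-ACGT query symbols count as
   mismatches).  Fewer than two anchors → the call is returned as
   *undetermined*, never an exception mid-pipeline.
2. **Segmentation.**  Cut points at anchor midpoints; segments tile the
   alignment; a leading/trailing piece with no variable column (it lies
   wholly inside a terminal anchor) is merged into its neighbour.  The
   default architecture yields 9 informative segments from 10 anchors.
3. **Assignment.**  Per segment, fractional identity (matches / compared
   columns, pairwise deletion) against every panel taxon; best taxon by
   arg-max with lexicographic tie-breaking (ties marked non-confident).
   An assignment is *confident* iff identity ≥ `identity_min` (0.80) and
   margin ≥ `margin_min` (0.02).
4. **Calling.**  Consecutive confident segments with the same taxon group
   merge into blocks (non-confident segments are uninformative and do not
   split a block); ≥2 blocks → chimera.  Breakpoints are reported at the
   midpoint of the separating conserved region — the true crossover is
   unidentifiable within near-identical sequence, so a conserved region
   is the finest honest resolution.  Block patterns are typed as
   `BA+oe`, `oe+BA`, `BA+oe+BA`, or `other`.

**Group-level margins.**  When the panel contains many near-identical
primary references (12 host-specific BA sequences, some 0.2% apart), the
gap between the best and second-best *taxon* is ~0 for every
primary-derived segment even though the assignment to the primary *group*
is unambiguous.  Margins are therefore computed against the best taxon of
a *different group* (all primaries collapse to group `BA`; each secondary
genus is its own group), which is exactly the question the detector must
answer — "which symbiont did this portion come from".  With no group map
supplied, every taxon is its own group and the margin reduces to the
plain runner-up gap.

**Thresholds.**  `identity_min = 0.80` tolerates the full within-primary
divergence (≤ ~13%) so a novel host's Buchnera still matches the BA
group; `margin_min = 0.02` is far below the ~12–26% primary/secondary
gaps that a true chimeric junction exposes, yet above the noise of a
same-group comparison.  Both are configuration, not constants.  Identity
is exact column-wise comparison on shared coordinates — at 16S-scale
divergences with an aligned panel, heuristic local alignment search would
add dependencies without adding information.

Scored against provenance on simulated libraries (secondary divergence
≥ 0.124), the detector reaches sensitivity ≥ 0.9 at false-positive rate
≤ 0.05, and ≥ 95% of detected breakpoints fall in the true breakpoint's
conserved region; these are design targets asserted in the test suite,
not field measurements.

## 4. Statistics

Uncorrected p-distance with pairwise deletion is the "genetic distance"
everywhere outside tree building (symmetry, identity and the triangle
inequality hold on gap-free input and are property-tested).  The OTU
criterion is strict: distinct iff divergence > 3%.  Clone-library
summaries report the chimera occurrence frequency as a percentage rounded
to 2 decimals; direct-sequencing effectiveness to 1 decimal — matching
the reporting precision of the survey tables shipped as fixtures (the
fixture files state per-category counts for 185 clones and 2/12
effective direct sequences; record names for subsets that are not
identifiable from the published summary are synthetic placeholders and
marked as such in the files).

## 5. The dataset I vs II contrast

Dataset I: the primary references (plus, in the packaged survey
inventory, 45 database records) and a Serratia-like outgroup.  Dataset
II: identical, except that chimeric clones replace the normal sequences
of a subset of species — in the pipeline, the *authentic* chimeras
detected in that run's clone libraries (so a chimera-free run yields an
exact null: identical datasets, RF 0, SH p = 1); in the standalone
experiment, freshly formed chimeras for `n_substituted` (default 6)
species with secondary partners assigned round-robin.

**Tree inference** is neighbor joining on JC69-corrected distances
(`d = −¾·ln(1 − 4p/3)`).  NJ is implemented in-package: ~60 lines,
deterministic tie-breaking (smallest index pair), and negative
branch-length estimates clamped to zero with the deficit moved to the
sibling branch so each join preserves the pair's summed length; the
test-suite cross-checks topologies against scikit-bio's NJ on additive
matrices.  A full ML search is deliberately out of scope — this is a
desk-scale, deterministic substitute, not an ML re-implementation; the
substitution-driven topology shift it measures is the phenomenon of
interest, not the precise ML tree.

**Likelihoods** come from Felsenstein pruning under JC69 with uniform
base frequencies, gaps treated as missing data, computed per unique site
pattern (verified to 1e-9 against explicit summation over internal-node
states on ≤5 taxa).  Branch lengths are floored at 1e-6 in the transition
probabilities: distance-based estimates clamp to exactly zero, which
would assign zero likelihood to any conflicting site.

**SH test.**  Both topologies are evaluated on the chimera-containing
alignment with their NJ branch lengths (not re-optimised — a fixed,
documented protocol).  `delta_lnL = lnL(best) − lnL(alt)`; RELL
replicates resample sites with replacement, each topology's replicate
score is centred on its own replicate mean, and
`p = #{centred difference ≥ delta_lnL} / n_rell` (default 1000
replicates).  Self-comparison gives p = 1.

**Known limitation.**  Without per-topology ML branch-length
optimisation, the SH test is *not* conservative for comparing two trees
neither of which was fitted to the evaluation alignment: their expected
log-likelihoods genuinely differ, and the test detects that (verified
empirically; the rejection rate for trees built from independent
resamples of signal-free data is far above 5%, with NJ branch lengths and
with OLS-refitted ones alike).  In this package's protocol the "best"
tree is always the one inferred from the evaluation alignment itself, and
the no-effect null (no chimeras substituted) gives identical datasets and
never rejects — the guarantee is protocol-level, and the property tests
assert exactly that.

**Topology distance** is the Robinson–Foulds symmetric difference of
non-trivial bipartitions on unrooted trees (dendropy backend, brute-force
bipartition oracle in tests).  Rooting on the outgroup is for display
only; all statistics are computed on unrooted trees.

## 6. Reproducibility and scale

All randomness flows from integer seeds through
`numpy.random.default_rng`; the pipeline fans one global seed into fixed
per-stage child seeds so stages can be re-run in isolation.  Deterministic
stages (detection, NJ, RF) are bit-reproducible given (config, seed);
stochastic ones are distribution-stable.

Problem sizes are chosen for a desk-scale analysis: 12 primary taxa +
4 secondaries on 1500 columns, 20-replicate batteries for calibration and
the SH contrast, 1000 RELL replicates.  The full test suite runs in well
under a minute; the acceptance script in a few seconds.

**What the synthetic data do not show.**  The generator reproduces the
divergence geometry, the conserved-region architecture and the
chimera-formation mechanism, but not: sequencing error, chimera-rate
dependence on PCR conditions, intragenomic 16S heterogeneity, indel
variation, or non-uniform base composition.  Passing tests therefore
demonstrate that the detector and the phylogenetic contrast behave
correctly *given* the divergence structure of this system — not that the
default thresholds are optimal for arbitrary real amplicon data.
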