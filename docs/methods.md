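# Methods

This note documents the models, parameter choices and numerical
conventions behind `pskit`, and what the synthetic-data experiments do
and do not demonstrate.

## Synthetic species-complex generator (`pskit.synthio`)

The generator emulates the statistical structure that genome-based
taxonomy rests on, in three layers.

**Tree.** A rooted binary tree with one ultrametric clade per genomovar.
Within-clade node heights are random below `within_divergence`
(substitutions/site; default 0.01), with each clade root pinned exactly
at it, so the maximum within-clade leaf path is `2·within_divergence`.
Clade roots are joined by a random backbone whose nodes sit at heights
in `[between_divergence, 1.2·between_divergence]` (default 0.06), so
every between-clade path is at least `2·between_divergence`. The
defaults translate, through the substitution model, into within-clade
ANI ≈ 98% and between-clade ANI ≈ 86–89% — the qualitative gradient a
species complex shows at genomovar scale. Neither level is meant to
reproduce any particular real dataset.

**Gene content.** The family universe is `root_families` (present at
the root; default 180) plus `accessory_pool` (absent at the root;
default 120). Along every branch each family runs an exact two-state
continuous-time jump process with rates `gain_rate` (0→1; default 1.2
events per unit branch length) and `loss_rate` (1→0; default 0.25),
simulated by explicit exponential waiting times so recorded per-branch
event counts equal realised transitions — the ground truth for event
inference. Defaults give a gain-dominated history (gain:loss roughly
2–3:1) and a cloud/shell/core frequency spectrum. Families never seen
in any leaf are dropped as unobservable, mirroring real data. A first
gain of a pool family plays the role of "new family arises on a
branch": its sequence is a fresh random draw, unrelated to any other
family, which keeps the clustering truth unambiguous.

**Sequences.** One CDS per family (default 900 nt): ATG start, interior
codons drawn from a fixed *biased* codon distribution shared by every
genome, TAA stop. The shared bias is deliberate: real genera carry an
oligonucleotide signature, and without it the TETRA statistic has
nothing to measure. Substitutions follow Jukes–Cantor along each branch
(per-site change probability `¾(1−e^(−4t/3))`); the final stop codon is
frozen and an interior codon mutated into a stop is repaired by setting
its third base to C, so proteins stay full-length (the repair perturbs
< 0.5% of third positions at the divergences used here and is accounted
for in test tolerances). Genomes are assembled with per-genome random
gene order and strand, 60-nt random spacers, single contig by default
(`n_contigs` fragments drafts). The optional five-gene marker cluster
(an `ectABCD-ask` analogue) is inserted as one contiguous, ordered,
co-oriented block; `drop_cluster_gene_in` deletes its first gene in
chosen genomes to emulate gene-loss microevolution.

What passing tests on this generator show: the pipeline's decision
rules, estimators and oracles are correct on data satisfying their
assumptions (no indels, no rearranged paralogs, no HGT between
families, clean annotations). What they do not show: robustness to
assembly error, contamination, pseudogenes, indel-rich alignment, or
homology detection at deep divergence.

## Distances (`pskit.distances`)

Fragment ANI cuts the query into `fragment_length` pieces (default
1,020 nt — the classical fragment convention), seeds each on the
subject with exact `seed_kmer`-mers (default 15, probed every 51 nt) on
both strands, and extends ungapped along the seeded diagonal with X-drop
20 (+1/−1 scoring). Retained fragments need identity ≥ 0.30 over
coverage ≥ 0.70 of the fragment; ANI is the mean retained identity,
averaged over both directions. Ungapped extension is exact for the
simulator (which introduces no indels) and the X-drop terminates
alignments at synteny breakpoints, which a forced global alignment over
the whole fragment would instead average in. Self-comparisons give
exactly 100; a pair with no surviving fragment yields an explicit
no-alignment marker, never 0.

The intergenomic distance pools matches and columns over all HSPs from
both directions: `d = 1 − Σmatches/Σcolumns`, a per-column identity
deficit that does not depend on how much of either genome aligns. The
dDDH mapping is a two-parameter logistic `100/(1+e^{A+Bd})` with
coefficients solved in closed form from the anchors `d=0 → 99.9` and
`d=0.05 → 60`; it is strictly decreasing and user-overridable. The
anchor choice encodes the empirical genomovar-scale correspondence
between ANI ≈ 95% and dDDH ≈ 60% rather than any published coefficient
set; dDDH values far from the anchors should be read as ordinal, and
the optional confidence-interval field is informational only (no CI
model is computed).

TETRA counts tetranucleotides on both strands, skipping windows with
ambiguous bases, against the order-2 Markov expectation; degenerate
genomes (fewer than 16 distinct observed words, e.g. a homopolymer)
return an undefined marker. Finite-size note: the z-score correlation
between related genomes rises with genome length; at the simulator's
~200-kb default the shared signature yields r ≈ 0.93–0.95 for
conspecific pairs, and the r > 0.99 regime seen in Mb-scale genomes is
reproduced by Mb-scale simulations (tested at 1.2 Mb).

## Homolog families and pan-genome (`pskit.orthopan`)

All-vs-all protein comparison with a shared 4-mer prefilter (≥ 3 shared
words, sparse matrix product) followed by global alignment; an edge
requires identity ≥ `min_identity` (default 0.5) and coverage ≥
`min_coverage` (default 0.5, shorter/longer length ratio). Identity is
computed as `1 − edit_distance/longer_length`, a conservative bound
appropriate for equal-length synthetic orthologs. Families are
connected components with ids named after the lexicographically
smallest member, making clustering invariant to input order. Connected
components (not MCL) suffice because simulated families are separated
by design; the thresholds are package defaults, not literature values.

Categories use occupancy k of N genomes: cloud k ≤ `cloud_max` (2),
strict core k = N, softcore k > `softcore_frac`·N (0.95; strict core is
its k = N subset), shell otherwise. Reported totals follow the
convention that the softcore subsumes the strict core, so
pan = cloud + shell + softcore. Note that the fraction rule at N = 123
admits k ≥ 117, one genome fewer than the 118–123 window sometimes
quoted for that cohort size; this package implements the fraction rule
as stated. The homolog-sharing fraction is
`|shared families| / mean(per-genome family counts) × 100` on the
presence view (paralogs collapsed), exactly 100 on self-pairs.

## Rarefaction and curve fits (`pskit.rarefit`)

For each x the sampler draws `min(n_samples, C(N,x))` distinct subsets
(exhaustive below the budget; default budget 20,000), recording union
and intersection sizes. Fits target the medians at each x (an
`fit_all_points` mode fits every sampled point instead); medians resist
the long upper tail of union sizes. Power (`a·xᵞ+b`) and exponential
(`a·e^{−kx}+b`) models are fitted by bounded least squares with
parameter scales tied to the data (a ∈ [0, 10·max y]); the bound
matters because on short curves the unbounded power model drifts into
its degenerate logarithmic limit (γ → 0, a → ∞) where the exponent is
meaningless. If the optimizer still fails, the nonlinear parameter is
profiled on a grid with the linear pair solved exactly. Parameter
uncertainty is the linearised (Jacobian) 95% half-width; openness is
declared when the fitted γ > 0. Expected new genes per added genome is
the exact increment `a((x+1)ᵞ − xᵞ)`, zero for closed fits.

## Trees and taxonomy (`pskit.treekit`)

Neighbour joining (scikit-bio) on zero-diagonal matrices, labels sorted
first so ties break by label order, negative branch lengths clamped to
zero. The concatenated-core distance is the pooled p-distance over
single-copy core families (column-wise on equal lengths, edit distance
otherwise) — the whole-genome generalisation of multi-locus sequence
comparison.

The Kendall–Colijn vector holds, for every leaf pair, the edge count
from the root to their most recent common ancestor; at λ = 0 only
topology matters and the distance is the Euclidean norm of the vector
difference. The null test compares the observed query–reference
distance with distances from the query to random rooted topologies
(uniform sequential pair joining) via a one-sided z-test; fewer than
100 random trees is rejected as unstable. The default background size
is 100,000; pipeline runs use a configurable smaller background (1,000
by default) since the z-statistic stabilises far earlier at the tested
tree sizes.

Genomovar delineation links pairs passing ANI ≥ `ani_t` and dDDH ≥
`ddh_t` and takes connected components (single-linkage; near-threshold
pairs are corroborated by clade membership rather than broken).
Defaults 94.5/59.5 sit just below the canonical ≈95/≈60 cutoffs so that
observed borderline conspecific pairs (ANI 94.89, dDDH 59.9) remain
grouped; both are flags. Membership screening retains candidates with
best ANI ≥ 80% against the references and then requires them to fall
inside the smallest clade containing all references in *both* the
100−ANI NJ tree and the concatenated-core NJ tree (midpoint-rooted);
the two signals are reported, never silently overridden.

## Gain/loss inference (`pskit.gainloss`)

Per family, presence evolves as a two-state Markov process with global
gain/loss rates and a Bernoulli root prior. The likelihood is computed
by Felsenstein pruning with the closed-form 2×2 transition matrix and
conditioned on observability (divided by one minus the probability of
an all-absent profile), which removes the bias from unobservable
families. Rates are fitted by coordinate-wise bounded scalar
minimisation (rates on a log₁₀ scale in [1e−6, 60], prior in
(1e−4, 1−1e−4)), up to 100 rounds with early stopping; a rate driven to
the lower boundary (frozen content) is reported with a warning, not an
error. Branch posteriors `P(parent=0, child=1 | data)` (gain) and
`P(parent=1, child=0 | data)` (loss) come from the standard up-down
recursion; counts of families with posterior > 0.5 per branch are the
"likely events", with expected (summed-posterior) counts reported
alongside since the two conventions differ. Duplication is out of
scope: family sizes collapse to presence/absence, and a fixed
gain:loss ratio across lineages is assumed.

Wagner parsimony (Sankoff DP, gain cost 2, loss cost 1, ties preferring
absence at the root and otherwise the parent state) provides an
independent combinatorial reconstruction used as a cross-check.

Recovery-experiment design: rate recovery is validated on 20-leaf,
300-family simulations at within/between divergences 0.2/0.8 — roughly
one to two expected events per family lineage, the informative regime
for this estimator. A 10-replicate pilot showed unbiased estimates with
maximum relative errors ≈ 18% (gain) and 9% (loss); shallower trees
leave the gain rate under-identified (spread ≈ 23%).

## Cluster screening (`pskit.clusterscan`)

The protein search aligns the query globally against every subject and
scores S = matches − (mismatches + gaps). Significance uses the
Karlin–Altschul extreme-value form `E = K·m·n·e^{−λS}` with λ = ln 19
(the exact solution for +1/−1 scoring over a uniform 20-letter
alphabet) and K = 0.1, with n the proteome residue count. At these
parameters the E ≤ 1e−5 cutoff turns over near 50% identity for
~300-residue proteins, so the three acceptance thresholds (E ≤ 1e−5,
identity ≥ 50%, coverage ≥ 70%) behave like their database-search
counterparts; shuffled decoy proteomes produce zero hits. Identity is
computed over the aligned region (global alignment columns), not over
an HSP.

Cluster calls: every query searched, hits mapped to gene positions;
"complete" requires all queries hit genes on one contig with at most
`max_gap` (default 2) intervening non-query genes between consecutive
members — order and strand are recorded (`order_conserved`) but not
required, since presence, not synteny, defines the call; "partial"
means at least one but not all queries found (or all found but
scattered); "absent" means none. Calls are invariant to
reverse-complementing contigs. Neighborhood extraction returns up to
`flank` genes (default 20) per side in genomic order with contig-end
truncation flags.

## Pipeline (`pskit.pipeline`, CLI `pskit`)

Stages run in dependency order (distances → delineation → pan-genome →
rarefaction → trees → gain/loss → cluster screen) with one global seed
deriving per-module seeds by hashing, content-hash stage caching
(unchanged inputs + config reload previous artifacts byte-for-byte),
and hard conservation assertions at report build (categories sum to the
pan size; shares sum to 100%). Percent shares are emitted raw and at
both printed precisions (two decimals and one decimal). Long-format
matrix exports contain all N² ordered pairs including self-pairs, so
123 genomes yield 15,129 rows.

Default problem sizes (12–24 genomes, 150–400 families, 900-nt genes)
keep a full run in minutes on one CPU; all sizes are configuration, not
constants.

## Known limitations

- No indel or rearrangement modelling in either simulator or aligners;
  real draft genomes with indel-rich divergence will read slightly low
  in ANI through the unit-cost identity bound.
- The dDDH map is a calibrated surrogate, not a reimplementation of any
  published regression; only its anchors and monotonicity are
  guaranteed.
- Homolog clustering is single-linkage on a similarity graph; at deep
  divergence or with promiscuous domains it can chain families that
  graph-aware orthology tools would split.
- The gain/loss model ignores copy number, rate variation across
  families and branch-specific rates; all families share one gain and
  one loss rate.
- The Kendall–Colijn null uses one particular random-topology
  generator (sequential pair joins); other nulls would shift absolute
  p-values, though not the contrast between concordant and discordant
  trees.
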