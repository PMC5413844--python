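# Methods

## The generative model

The central object is a level-1 species network: a rooted species tree
with at most one hybrid node, whose two parent edges carry inheritance
probabilities `1−γ` and `γ`. Removing one hybrid parent edge yields a
*displayed tree*. Each locus of the hybrid lineage is assumed to trace a
single parental path — the second displayed tree with probability γ —
which matches how a consensus sequence per locus behaves in practice for
an allopolyploid whose homoeologous copies are not separated during
assembly. Homoeolog-aware simulation is explicitly out of scope.

Branch lengths are in coalescent units: within a branch of length `t`,
`k` lineages coalesce at rate `k(k−1)/2` per unit (2N-generation units).
Gene trees are simulated by choosing the parental path per gene
(Bernoulli(γ)) and then running the standard multispecies coalescent on
the resulting displayed tree, with all sampled individuals per lineage as
starting lineages and full coalescence at the root.

The default six-lineage candidate network mirrors the *Roucela* system:
backbone `(rhodensis,((drabifolia,erinus4x),(simulans,creutzburgii)))`
with the octoploid `erinus8x` attached as a hybrid tip onto the terminal
edges of `erinus4x` (weight `1−γ`) and `creutzburgii` (weight `γ`). γ is
therefore the *creutzburgii-side* inheritance probability throughout; the
published estimate for this system is γ = 0.534 on that side, which is
the package default. All internal edges default to `scale` (1.0)
coalescent units and the two hybrid attachment points sit symmetrically
`scale/2` below the parental tips' parent nodes, so at γ = 0.5 the two
conflicting quartet resolutions involving the hybrid are exactly
equiprobable. No branch lengths or effective sizes were published for the
empirical system, so `scale` is a free parameter, not an estimate;
`scale = 1` produces the pervasive gene-tree discordance the analysis is
designed for (major-quartet probability 0.755 per displayed tree).

## Expected and observed concordance factors

For a quartet of lineages whose internal path on a displayed tree has
total length `t`, the displayed resolution has probability
`1 − (2/3)e^{−t}` and each alternative `(1/3)e^{−t}`. Quartets whose
paths avoid the hybrid use this tree formula directly; quartets involving
the hybrid take the γ-weighted mixture of the two displayed-tree triples.
Internal paths are computed symbolically (per network edge), so the same
machinery serves both closed-form evaluation and fitting. Edges that
never appear on any quartet's internal path (e.g. the root edge, which is
part of a pendant path once the root is suppressed) are unidentifiable
from quartet CFs and are excluded from the free parameters.

Observed CFs are raw gene-tree frequencies, not Bayesian concordance
factors: for each gene and 4-lineage set, all one-sample-per-lineage
quartets (subsampled to at most 500, seeded, when combinatorially larger)
vote for their resolution; the per-gene majority is that gene's vote and
ties or fully unresolved genes abstain. `cf_k = votes_k / voting genes`,
with `n_eff` the number of voting genes. This differs by construction
from Bayesian CF machinery with a discordance prior, so agreement with
published Bayesian CFs is expected to be approximate.

Quartet resolutions are read off (possibly multifurcating) trees via
pairwise MRCA depths: pairs sharing a leaf have MRCAs on that leaf's root
path, so the pair with the strictly deepest MRCA forms the cherry;
polytomies fail the strict inequality and count as unresolved. The rule
is invariant to the root position and is cross-checked in the tests
against an independent four-point-condition oracle on leaf-to-leaf
distances.

## Pseudolikelihood fitting

γ and the internal branch lengths of a fixed candidate topology maximise

    Σ_quartets n_eff · Σ_k cf_obs,k · log max(cf_exp,k, 1e−12)

treating quartets as independent (no correction for shared genes across
quartets). Optimisation is bounded L-BFGS-B over γ ∈ [0, 1] and
t ∈ [0, 20], from 10 seeded restarts (one central start at γ = 0.5,
t = 1, the rest uniform); the best restart is reported together with
convergence flags. The ε-floor inside the log keeps the objective finite
when an expected CF underflows. Fixing γ = 0 reduces the model to the
no-hybrid displayed tree, so the tree fit is obtained by the same routine
with `fix_gamma=0` and is exactly nested in the free fit. Model
comparison reports Δ pseudolikelihood (h1 − tree) plus a γ profile at the
h1 optimum; a profile range below 0.5 log-units is flagged as flat
(γ unidentifiable, tree-like data). Network topology *search* is not
implemented: the analysis consumes user-supplied candidates, which is all
the downstream inference requires.

Absolute pseudolikelihood values depend on the CF estimator and scale
with `n_eff`, so they are not comparable to values from other
implementations; only differences within one analysis are interpreted.

## Locus QC

A taxon with two or more contigs each covering at least `min_fraction`
(default 0.75) of the bait length at a locus is flagged as a potential
paralog there. "All copies removed" is interpreted per taxon: the flagged
taxon loses that locus, and the dataset-wide consequence (locus dropped
entirely) then arises through the completeness filter, which keeps only
loci present for every required taxon. This two-stage reading reproduces
the reduction of a target set to a complete matrix. Fractions may exceed
1 because contigs extend into flanking intronic sequence; the threshold
is one-sided. Tree-based (manual) paralog screening is not automated; the
binning audit trail is the intended aid for such inspection.

## Binning rules

Strict: restrict to samples of H ∪ P1 ∪ P2 ∪ O, root on the outgroup
clade (if the outgroup samples are not a clade under the read rooting,
root on the edge above the ingroup's common ancestor; the audit trail
flags non-monophyletic outgroups), then call T1 iff H's and P1's samples
are each monophyletic and sister to each other, T2 likewise with P2.
Sisterhood (not mere reciprocal monophyly) is required, consistent with
the species-tree topologies the T1 class represents; the relaxed rule
covers the weaker reading.

Relaxed: collapse branches with support below the threshold (default 80),
then let every (h, p1, p2, o) quartet vote; strictly more votes for
`h,p1|p2,o` than `h,p2|p1,o` gives T1, strictly fewer T2, ties and
all-unresolved trees stay UNASSIGNED. The published assignment this
operationalises was manual; the quartet-majority rule is a reproducible
surrogate, with the threshold and the 500-quartet subsample cap
configurable. Ties are never broken arbitrarily, preserving mutual
exclusivity of the bins.

## Morphometrics

Tooth length is corrected by dividing by bract length; the dimensionless
ratio removes plant- and bract-age effects and is scale invariant. The
report gives per-lineage n/mean/sd of the ratio, per-lineage least-squares
regressions of raw tooth on bract length (undefined-slope inputs are
flagged), and two contrasts — tetraploid vs octoploid, and *creutzburgii*
vs pooled *erinus* — each with Cohen's d (pooled SD) and a two-sided
rank-sum test. No particular test was prescribed for this comparison, so
the distribution-free rank-sum statistic is reported as descriptive
support only.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
ILS controlled by internal branch lengths, a γ-mixture of parental paths
for the hybrid, multiple individuals per lineage, noisy supports
(an internal edge of length `l` draws support from
`Binomial(B, 1 − e^{−l/λ})`, rescaled to [0, 100]; defaults λ = 0.2,
B = 100, so short ILS-prone edges get low, noisy support), optional
Jukes–Cantor alignments (coalescent-to-substitution scale 0.01/unit,
500 sites), assembly summaries (one near-full-length contig per taxon,
3% second-long-contig rate, 2% missing rate — chosen so that ~53% of
loci survive to the complete matrix, matching the 246-designed →
130-complete reduction of the motivating dataset), and bract tables
(both cytotypes share ratio 0.12 ± 0.03; *creutzburgii* 0.36 ± 0.07;
sample sizes 22/123/129 as in the herbarium survey).

It does not emulate: homoeolog sequence structure, recombination,
substitution models beyond JC, rate variation, alignment or
tree-estimation error (supports are attached directly to true simulated
trees), or rogue taxa. Passing tests therefore validate the inference
machinery under its own model assumptions, not robustness to estimation
error in empirical gene trees; empirical strict-bin proportions in
particular depend on branch lengths that were never published, so only
the relaxed bins and γ are expected to be comparable across conditions.

## Numerical and design choices

* All randomness flows from explicit integer seeds; the pipeline splits
  one root seed per stage via a seed sequence, and reruns are
  byte-identical (newick written with a fixed `%.10g` format, JSON with
  sorted keys).
* Collapsed children keep their own edge lengths; only topology is used
  downstream of collapsing.
* Unresolved quartets and CF ties abstain rather than being split
  fractionally; `n_eff` records the effective sample per quartet, and a
  quartet with no voting genes reports uninformative CFs (1/3 each) with
  `n_eff = 0`, contributing nothing to the pseudolikelihood.
* The problem sizes used by the validation runs (50,000 genes for the
  coalescent calibration, 10,000 for γ recovery, 2,000 for binning
  symmetry, 246 loci for the study-scale reanalysis) were chosen to make
  Monte Carlo error small relative to the tolerances being checked while
  keeping a full run in the order of a minute.

## Known limitations

* One hybrid node only (level-1, single reticulation); `hmax ≥ 2`
  scenarios require fitting alternative single-hybrid candidates
  separately.
* Pseudolikelihood treats quartets as independent, so Δ values are
  descriptive, not calibrated test statistics.
* Clade CFs use the trees' given rooting.
* The strict binning of deep-coalescing loci is sensitive to the unknown
  empirical branch lengths; the relaxed bins and the fitted γ are the
  robust quantities.
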