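# Methods

`coalboot` tests rival species-tree hypotheses for the North American
*Limenitis arthemis* complex by parametric bootstrap: explicit demographic
models are simulated under the structured coalescent, each simulated
multi-locus replicate is scored by gene-tree/species-tree discordance, and
the observed discordance is located within the simulated distributions.
This note records the model, its parameters, the numerical choices, and
the limits of what the simulations can show.

## The biological question and the two hypotheses

*L. arthemis* comprises three lineages: the Batesian mimics *L. a.
astyanax* and *L. a. arizonensis*, and the non-mimetic, white-banded
*L. a. arthemis*. Two arrangements of these lineages have been proposed:

- **Reversion (R)**: *astyanax* sister to *arthemis* — mimicry arose once
  in the ancestor of the complex and was later lost in *arthemis*.
- **Monophyletic mimic (MM)**: *astyanax* sister to *arizonensis* — the
  two mimetic lineages form a clade and mimicry was never lost.

Because gene trees at individual loci need not match the species tree
(incomplete lineage sorting, introgression), a best-scoring point
estimate of the phylogeny cannot by itself exclude the rival history.
The parametric bootstrap asks instead: under an explicit demographic
model of each hypothesis, how discordant would eight nuclear gene trees
typically be, and is the observed discordance typical of that model?

## Statistics

For a gene tree *G* and species tree *S*, `dc(G, S)` is the minimum
number of deep coalescences (Maddison's "extra lineages"): for the
species cluster *C* below each edge of *S*, count the maximal clades of
*G* whose tips map entirely into *C*, subtract one (floor zero), and sum
over edges, tip edges included so multiple alleles of one species
contribute. The statistic is purely topological; branch lengths are
ignored. The implementation is linear-time per edge via subtree species
bitmasks, and is verified exhaustively against an independent
brute-force minimization over all embeddings of the gene tree into the
species tree (every distinct instance with ≤ 6 tips over 2–3 species,
plus random 7–8-tip instances).

Summing over the eight loci gives, per dataset,

    δ = Σ dc(G_i, tree_R) − Σ dc(G_i, tree_MM)

so negative δ favors the reversion topology. The observed consensus gene
trees give 93 extra lineages on `tree_R`, 108 on `tree_MM`, δ = −15. The
absolute-fit statistic for a model is the summed count on the model's own
topology (`tree_MM` for MM models, `tree_R` for R models).

Polytomies in input (consensus) gene trees are treated as hard: the
cluster formula applies unchanged and no resolution search is performed.
A softer treatment would require a minimization the method does not
define; the choice is isolated in `count_deep_coalescences`.

## Demographic models

Fifteen models share a fixed outgroup scaffold
`(archippus,(weidemeyerii,(lorquini, ingroup)))` and differ in the
ingroup arrangement and times:

- MM models: T1 = *astyanax*/*arizonensis* split, T2 = *arthemis*
  divergence; six (T1, T2) pairs × two migration tiers = MM1–MM12.
- R models: T1 = *arthemis*/*astyanax* split, T2 = *arizonensis*
  divergence; R1–R3 vary T1 (235, 655, 1,075 kyr) with T2 = 1,095 kyr.

Shared parameters: every contemporary lineage has diploid effective size
N = 2.5 × 10⁶ and two generations per year; the ancestral stem of the
*arthemis* complex (above T2, until the *lorquini* join) has N = 350,000;
secondary contact between *arthemis* and *astyanax* begins 12,000 years
ago (recession of the Laurentide ice sheet) and runs to the present.
"Moderate" migration uses the published maximum-likelihood rates (3.2
*astyanax*→*arthemis*, 0.14 reverse); "high" uses the upper 90%
posterior bounds (17.71 and 15.53).

Two parameter groups are not printed in the source tables and are
exposed as configuration:

- **Outgroup divergence times.** Defaults 1.5, 2.5, 3.5 Myr for the
  *lorquini*, *weidemeyerii*, *archippus* joins — older than every
  ingroup time, so they do not interact with the hypothesis contrast.
  Every report records the values used. The absolute deep-coalescence
  level is sensitive to them (see *Known limitations*); δ is not.
- **Migration-rate units.** Published migration estimates are stored
  with an explicit `rate_unit`. The default interpretation is `"4Nm"`:
  the printed numbers are population migration rates in the MS
  simulator's convention (its `-m` parameter equals 4N·m), so the
  effective number of migrant individuals per generation is the printed
  value divided by four. Under this reading the simulated δ means
  reproduce the published per-model values for both migration tiers
  (e.g. MM11 ≈ 6.9, MM8 ≈ −2.5, R1 ≈ −29.7); under the literal
  `"Nm"` reading the high-migration models drift far from them (MM11
  near −10). Set `rate_unit="Nm"` to treat the numbers as literal
  migrant counts.

## Coalescent scaling and simulation

`to_coalescent_scale` converts a model to simulator units: time t years
→ t·g / (4 N_ref) with g generations/year; deme size N → N / N_ref;
forward flow of M migrants/generation into a deme of size N_dest → a
backward per-lineage rate 4 N_ref M / N_dest per scaled unit for
lineages in the destination deme. The reference size is 2.5 × 10⁶, so
one scaled unit is 10⁷ generations = 5 Myr.

The simulator is an event-driven exponential race in continuous time
(matching MS, not a discrete-generation model): within a deme of
relative size x holding k lineages, coalescences occur at rate
k(k−1)/x; active migration phases contribute per-lineage jump rates;
population splits move all lineages of the derived deme into the
ancestral deme. Rates are piecewise constant between demographic events;
at tied event times splits are processed before migration-phase
toggles. A proposed waiting time that crosses the next demographic event
is discarded and the state advanced to the event, which is the correct
competing-exponentials treatment for piecewise-constant rates.

Calibration: the mean pairwise coalescence time in a single deme is 0.5
scaled units and the mean TMRCA of ten samples 0.9 (both closed forms,
checked at 10⁵ replicates to 2%); means under structured models with
splits and migration phases agree with msprime on matching demographies.

Randomness uses numpy's PCG64. A replicate seed (an integer or a tuple
such as `(suite_seed, model_index, replicate)`) spawns one independent
substream per locus keyed by locus index, so any replicate, model run,
or report is bitwise reproducible from its seed and loci are
independent.

## Sampling design

Each simulated replicate contains eight gene trees with the allele
counts of the observed loci per lineage (e.g. EF1a: 22, 12, 14, 16, 17,
15 across *archippus*, *arizonensis*, *arthemis*, *astyanax*,
*lorquini*, *weidemeyerii*; 96 tips). Lineages with zero alleles at a
locus are simply absent from that tree (Anon15 lacks *lorquini*, Anon17
lacks *archippus*). All loci are treated as autosomal nuclear with equal
effective size.

## Decision rule

For each model, `nreps` replicates (default 2000, matching the 1/2000
granularity of the published p-values; the bundled scaled-down runs use
500) give empirical distributions of δ and of the absolute count on the
model's own topology. Tail probabilities are plain proportions, ties
counting in both tails (`p_low + p_high = 1 + ties/n`); zero counts are
reported as `<1/n`; no continuity correction.

A model is **supported** when both observed statistics lie within their
simulated distributions, where "within" is operationalized per
statistic:

- δ (relative fit, directional): within iff min(p_low, p_high) > 0.05.
- absolute count (goodness of fit): within iff min tail ≥ 0.025
  (central 95% interval).

The δ threshold is pinned by the published borderline decisions (models
rejected at nearer-tail probabilities 0.025–0.032); the published table
contains no absolute-count decision between 0.025 and 0.06, so the
central-95% convention is used there. Both thresholds are fields of
`ModelTestResult` and can be changed. Under this rule the suite
reproduces the published outcome: every MM model rejected (δ always in
a ≤ 5% tail), R1 and R3 rejected, R2 alone supported by both criteria.

Reports print both tails plus the nearer tail per statistic, a superset
of the single printed tail of the source table (whose direction varies
by cell).

## Pseudo-observed data and parameter recovery

`synthetic_data.generate_pseudo_observed` writes one simulated replicate
in exactly the observed-input format (per-locus newick with
`deme|allele` tips, a tip→lineage TSV map, and a JSON manifest with the
generating model, seed and parameter hash), so the entire pipeline runs
with no external data. The generator reuses the structured-coalescent
simulator deliberately — the statistical structure the analysis assumes
*is* the structured coalescent; independent validation comes from the
brute-force reconciliation oracle, the closed forms, and msprime, not
from a second tree generator. `degrade_to_consensus` additionally
collapses a chosen fraction of the shortest internal branches to mimic
the partial resolution of consensus trees.

In the recovery experiment, datasets generated under R2 and evaluated
against R2 (20 seeds, 500 replicates each) are supported in ≈ 90% of
trials — consistent with the rule's nominal miss rate of roughly 10–15%
across two correlated statistics and four tails, so near-90% is the
calibrated expectation for a true model, not a shortfall.

What the synthetic data do not emulate: mutational noise and gene-tree
estimation error (tips of a real consensus tree are inferred from finite
sequence, and poorly resolved nodes appear as polytomies unless
`degrade_to_consensus` is applied), intralocus recombination, linkage
between loci, and any geographic structure within lineages. Passing
tests therefore demonstrate correctness of the simulation–reconciliation–
decision machinery under the model's own assumptions, not robustness of
the biological conclusion to violations of those assumptions.

## Scaled-down reproduction and problem sizes

The bundled acceptance runs use 500 replicates per model (Monte-Carlo
s.e. of a mean δ ≈ 0.4) and reproduce the published per-model mean δ to
within ±2 across all fifteen models, the rejection of every MM model on
δ, and R2 as the only supported model. Absolute deep-coalescence means
land 2–10 below the published ones, with the deficit growing with T2
(≈ −3 for MM1/MM2, ≈ −10 for R2): exactly the sensitivity expected from
the unpublished outgroup parameters, since a shorter *arthemis*-complex
stem leaves more uncoalesced lineages alive into the outgroup epochs.
δ cancels this contribution across the two topologies and is stable.
The dc-based decisions used by the support rule are unaffected in the
bundled runs, except that the oldest-T2 models (MM5/MM6) can fail the
absolute-fit interval that the published table narrowly passes; they are
rejected on δ in either case.

## Known limitations

- Gene-tree uncertainty is not propagated: observed consensus trees
  enter as point estimates.
- The outgroup divergence times and non-stem ancestral sizes are
  package defaults, not published estimates; absolute deep-coalescence
  levels (not δ, not the support decisions on δ) depend on them.
- The migration-rate unit is an interpretation (documented above and
  configurable), not a printed fact.
- No recombination within loci; loci are unlinked and exchangeable.
- The brute-force oracle is exponential and restricted to ≤ 8 gene
  tips; correctness beyond that range rests on the exhaustive and random
  agreement within it.
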