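# Methods

`discordia` analyzes why different genomic regions support different
phylogenies: it separates incomplete lineage sorting (ILS) from
introgression in windowed whole-genome alignment data, and ships its own
generative model so every stage can be validated end-to-end on data with a
known truth.

## The generative model

**Multispecies coalescent with pulse introgression.** The species tree is a
rooted, binary, ultrametric tree whose branch lengths are in coalescent
units (one unit = the expected time for a pair of lineages in a population
to coalesce at rate 1). Each branch is a panmictic population; the branch
above the root extends to infinity. Going backward in time, every pair of
lineages within a branch coalesces independently at rate 1; at a speciation
node the daughter populations merge; at an introgression event
(donor, recipient, time t, proportion γ) each lineage currently in the
recipient population jumps to the donor population independently with
probability γ. This forward-time reading is a γ-fraction admixture pulse
from donor into recipient. Event times must fall inside the co-existence
interval of both branches; γ ∈ [0, 1].

Population sizes are constant and equal (time is measured in coalescent
units, so size changes are out of scope), one haploid genome is sampled per
species by default — mirroring one assembly per species — and gene
duplication/loss and indels are not modeled.

**Windows.** A simulated "chromosome" is a sequence of non-overlapping,
adjacent windows (0-based, half-open coordinates). Each window draws its
own independent gene tree: free recombination between windows, none within.
This matches treating fixed-size windows as independent samples of the
local genealogy and sidesteps a sequential coalescent; the cost is that
within-window linkage is total, which matters for site-based tests (below).

**Sequences.** Sites evolve independently under Jukes-Cantor (equal base
frequencies and exchange rates): on a branch of length b the expected
number of substitutions per site is b·μ, where μ (`mutation_scale`) is the
expected substitutions per site per coalescent unit. The root state is
uniform on {A,C,G,T}. JC69 is deliberately the same model inverted by the
distance estimator, so the simulator/estimator pair is internally
consistent. Missing data are injected i.i.d. per site per taxon as `N`;
a configurable fraction of windows carries a repeat flag. Defaults follow
the emulated study design: 10 kb windows, one haploid sample per taxon,
μ = 0.01. Fixing the seed makes a dataset byte-identical across runs.

**Validation.** The sampler is checked against closed forms (mean pairwise
TMRCA = 1; discordance (2/3)e^(−T) around a focal internal branch of length
T) and cross-validated against msprime on the same demography, with and
without an introgression pulse, at 10,000 replicates within 3 Monte-Carlo
SE. msprime is used only as an independent oracle, never in the pipeline.

## Windowing and filters

- Windows are exact `window_size` slices; a trailing remainder is dropped.
- A window is excluded if its repeat flag/masked fraction exceeds
  `max_repeat_fraction` (default 0: any repeat overlap excludes) or if its
  ungapped, non-missing length is below 150 bp (length exactly 150 is
  kept). "Length" is the minimum over taxa by default; because the rule's
  reading is ambiguous, a policy flag switches to total alignment span.
- SNP extraction keeps sites that are bi-allelic among non-missing calls
  (monomorphic and 3+-allelic sites dropped) with missing fraction ≤ 0.2,
  and can thin sites to a minimum bp distance (greedy, left to right).
  Gaps count as missing. Filters only ever remove; they never edit
  residues.

## Gene trees

Per-window trees come from JC69 distances (pairwise deletion of
gap/missing sites) and neighbor-joining. This stand-in is deliberate: the
discordance analyses consume topologies, not the inference engine, and
externally inferred newick trees can be imported to bypass the stage. A
mismatch fraction ≥ 0.75 saturates the JC transform; any saturated or
undefined pair rejects the whole window with a logged reason rather than
imputing. NJ uses the standard Q criterion with deterministic tie-breaking
(lowest index pair) and clamps negative branch lengths to zero, so runs are
exactly reproducible; NJ provably recovers the generating topology on
tree-additive matrices, which the suite verifies on random additive
matrices up to 8 taxa. Bootstrap support resamples alignment columns and
reports the percentage of replicates containing each bipartition.
Topologies are compared through canonical identifiers: the tree (optionally
restricted to a taxon subset) is anchored at its lexicographically smallest
leaf and children are sorted recursively, so any rotation/rooting of the
same topology maps to one string; subsets with fewer than three taxa
collapse to a degenerate identifier and are excluded from frequency
denominators.

## Concordance and regional stratification

Around each internal species-tree branch the four neighbouring subtrees
define quartets (one leaf per group). For each gene tree all such quartets
are tallied and per-tree proportions are averaged before averaging over
trees, so large clades do not dominate; unresolved quartets split 1/3 each.
Under the MSC the species-tree resolution has probability 1 − (2/3)e^(−T)
and each alternative (1/3)e^(−T) for a focal branch of length T — the
module's analytic baseline, with (1/3, 1/3, 1/3) at T = 0. Note this form
applies when a single branch governs discordance (e.g. an asymmetric
species tree whose other internal branches are long); with several short
internal branches the discordance compounds.

The species-tree estimator enumerates all unrooted topologies (≤ 8 taxa)
and maximizes the total number of induced quartet topologies shared with
the gene trees — an exhaustive, deterministic substitute for summary-method
heuristics, with ties broken by canonical-id order and reported.

For positional structure, each chromosome is folded in half (metacentric
assumption: both telomeres map together, the middle maps to itself) and
partitioned into five bins of 20% folded length; bin 5 is
telomere-proximal, bin 1 the chromosome middle, a window is binned by its
midpoint, and positions exactly on a boundary go to the more
telomere-proximal bin (integer arithmetic makes mirrored positions land in
identical bins exactly). Chromosomes contributing fewer than 20 window
trees are excluded. Homogeneity of topology frequencies across bins is
tested by a chi-square contingency test (bins × topologies, expected counts
from pooled frequencies, empty bins excluded); the choice of chi-square is
this package's operationalization, declared rather than inherited.
Centromere positions are not modeled — folding is exact only for
metacentric chromosomes, a documented limitation.

## D statistics (four taxa)

Alleles are haploid and polarized against the outgroup call; for
(P1, P2, P3, O), sites with any missing call or more than two alleles in
the quartet are skipped and D = (nABBA − nBABA)/(nABBA + nBABA), which is
0 in expectation under ILS alone. Significance uses a weighted delete-one
block jackknife over 20 contiguous equal-count SNP blocks (configurable):
Z = D/SE with a two-sided normal p-value. Blocks over SNP ranks absorb
linkage provided each block aggregates many independent loci; the
calibration study uses ~65 windows per block for that reason, and a
residual type-I rate of ≈0.065 at nominal 0.05 is inherent to reading a
20-block jackknife against the normal tail. The trio scan considers every
unordered ingroup trio, arranges it so the BBAA count is largest (the
majority pair becomes (P1, P2)) and D ≥ 0 by swapping P1/P2, making P3 the
candidate introgressor; under very strong gene flow the majority pair can
legitimately differ from the true sister pair. Untestable trios are
reported with a reason; a best-per-(P2, P3) table summarizes the scan.

## D_FOIL (five taxa)

On the symmetric topology (((P1,P2),(P3,P4)),O) with the (P1,P2) ancestor
younger — a chronology precondition the caller declares, and which is
checked and enforced when divergence times are supplied — four D-like
statistics are computed from left/right sums over the 16 polarized site
patterns (see the module docstring for the exact pattern sets). Each
component gets a chi-square goodness-of-fit test of L vs R; its sign is 0
unless p < α (default 0.01). The joint sign vector is looked up in the
direction table: a recipient in the younger pair zeroes the other young
taxon's statistic while D_FI/D_OL deviate jointly; a recipient in the older
pair moves D_FO and D_IL jointly while exactly one of D_FI/D_OL — naming
the donor — deviates; (±,±,0,0) patterns indicate ancestral/undirected
exchange and vectors outside the table are reported as `complex`. The
nominally zero components are zero only to leading order, so enormous
correlated site counts can push them over threshold.

Because the component test assumes independent sites, D_FOIL input should
be thinned to at most one site per window (the windows are the
recombinationally independent units); the simulation studies do exactly
that. The D statistic needs no thinning since the block jackknife absorbs
linkage.

## Simulation studies (`discordia.studies`)

The studies fix their own problem sizes, chosen as a balance between
statistical resolution and desk-scale runtimes:

- Quartet oracle: 10,000 gene trees per T ∈ {0, 0.5, 1, 2}, agreement with
  the closed form within 3 Monte-Carlo SE.
- Type-I calibration: 100 ILS-only datasets of ~2,000 SNPs (1,300 × 25 bp
  loci), trio-D rejection rate vs the nominal 5%.
- Power/direction: γ = 0.3 pulses; D significant and positive in ≥ 95% of
  20 replicates (5,000 windows); D_FOIL modal classification over 15
  replicates per donor/recipient configuration names the planted event in
  all four configurations (per-replicate accuracy for the hardest,
  older-pair recipient configurations is ~75%, so the modal call is the
  reported statistic).
- Oracle equivalence: the vectorized pattern counters equal per-site
  enumeration on 1,000 random ≤ 50-site matrices; NJ recovers 500/500
  random additive matrices.
- Regional signal: γ = 0.5 gene flow planted only in the telomere-proximal
  bins of 1,000 windows is detected by the homogeneity test at α = 0.01.

What passing these studies shows — and what it does not: the synthetic data
realize the assumed model exactly (independent windows, JC sequences, no
rate variation, no selection, uniform recombination between and none within
windows). Real alignments violate these in known ways (intra-window
recombination, alignment error, base-composition and rate heterogeneity),
so passing here validates the statistical machinery, not the biology of any
particular dataset.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere.
- Degenerate cases are explicit: zero ABBA+BABA denominators flag the trio
  untestable; zero-variance jackknives report infinite Z with a warning
  flag; all-zero D_FOIL counts are `untestable`; sub-3-taxon topology
  restrictions yield degenerate ids.
- All randomness flows through one seeded NumPy generator per run; seeds
  are recorded in dataset truth files and provenance records, and identical
  config + seed reproduces summaries byte-for-byte.
- The pipeline treats stages as pure functions of inputs + config; stage
  failures abort with the stage named and partial outputs retained, and a
  run with zero surviving gene trees writes a clean empty report and exits
  nonzero.
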