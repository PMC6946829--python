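# Methods

This note documents the models, the defaults and why they are what they are,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Bulk clonal analysis

The cancer cell fraction is computed exactly as

    CCF = VAF × (1/p) × (p·CNt + CNn·(1 − p)),

with purity `p` supplied per sample (purity estimation from clonal drivers is
out of scope), and adjusted VAF = CCF/2. CCF values above 1 are **retained
and not clipped**: they are the diagnostic signature of a wrong copy-number
context — most prominently, copy-neutral LOH at the driver locus, which makes
VAF-only tracking of driver burden misleading in bulk DNA.

Clustering input follows the depth/indel exclusions (≥ 25× at both time
points; indels < 3 bp only). Mutations seen at one time point only are kept
when they pass wherever observed, and flagged — the unmatched side is treated
as VAF 0 rather than missing.

`cluster_vafs` fits a 1-D binomial mixture by EM on (alt reads, depth)
pairs, with the component count chosen by BIC over 1..`max_clusters` (default
6). A binomial rather than Gaussian mixture keeps the per-mutation variance
tied to sequencing depth. Initialisation is quantile-anchored with seeded
jitter (4 restarts per component count); labels are canonicalised by
decreasing component mean so they are invariant to input order. No installed
library provides this primitive, so the EM is implemented here; it is a
deliberately simplified stand-in for full clonal-deconvolution tooling.

Longitudinal tracking uses identity key (chrom, pos, ref, alt), 1-based
closed coordinates, and a detection floor `detect_vaf` (default 0.05, the
whole-exome selection threshold; ultra-deep targeted data supports 0.001).

## Plate simulation (what the generator emulates)

The generator produces rooted clone trees over 2–12 assays. The first assay
is the disease-defining driver; the root clone carries it heterozygously
(`root="wt"` gives a wild-type root instead, as seen in patients whose driver
arrives as a secondary event). Every other clone is its parent plus exactly
one event: each remaining assay is gained once (0→1) on a uniformly chosen
clone, then `n_loh` LOH events (1→2 or 1→0, equiprobable) are added. LOH
defaults to the disease-defining assay because copy-neutral LOH at the driver
locus is the recurrent event in this disease; `loh_assay="random"` places it
on any heterozygous assay instead. Placing LOH on the driver also makes
planted topologies identifiable by parsimony (see "Identifiability" below).
Per-time-point prevalences are Dirichlet over clones with a per-clone floor
`min(0.05, 0.8/n_clones)`, leaving a wild-type remainder uniform on [0, 5%].

Plates emulate the measured sorting error structure: 9% empty wells and 3.5%
doublets by default. A doublet is the signal union (per WT/MUT channel) of
two independently drawn cells, with control-probe CTs shifted one cycle
earlier — one template doubling. Positive reactions draw CT ~
Normal(probe mean, `ct_sd`); negatives carry no CT. Per-assay false-positive
mutant signals are injected at `fpr_per_assay` (default 0.5%: on the
wild-type control line most assays show essentially zero false positives
while a small minority reach ~5%, which scenario configs set explicitly).
An optional false-negative (allelic dropout) rate exists and defaults to 0 —
the assay design provides no positive controls from which to measure one, so
none is invented.

Defaults chosen by error-budget analysis rather than convention:

* `ct_sd = 0.2` cycles. Replicate CT precision of plate qPCR is realistically
  0.1–0.25 cycles. This value also determines whether the one-cycle doublet
  shift is detectable at all: with the conjunctive rule "both control CTs ≤
  reference − δ", detection probability is Φ((1 − δ)/σ)², which at σ = 0.5
  would be ~48% — calibration plates could then never recover the true
  doublet rate. At σ = 0.2, δ = 0.5 it is ~99%.
* `doublet_delta_ct = 0.5` cycles — the symmetric decision midpoint of the
  one-cycle shift. Misclassification of singlets as doublets at this
  boundary is Φ(−0.5/0.2)² ≈ 0.004², i.e. negligible.

What the generator does **not** emulate: fluorescence-curve shapes and
threshold setting (amplification is a flag), preamplification chemistry,
read-level sequence data, assay cross-hybridisation, and plate-position
effects. Passing recovery tests therefore demonstrate the statistical
pipeline under the modelled error structure, not robustness to curve-calling
artefacts or spatial biases in real instruments.

## Plate QC

Well classification: empty if neither control probe amplified; ambiguous
(excluded, but counted as attempted) if exactly one amplified; doublet if
both CTs ≤ reference − δ, where the reference is the per-probe median CT over
wells with both controls amplified (doublets are rare enough not to move the
median); otherwise singlet.

The CT quartile filter is implemented as per-probe Tukey fences
[Q1 − k·IQR, Q3 + k·IQR] over amplified cells, applied to every probe a cell
amplified (controls and assay channels). The literal phrase "within the
upper and lower quartiles" is ambiguous — read literally (k = 0) it discards
half the cells per probe, which is inconsistent with ~79% of cells surviving
the whole cascade — so k is an exposed parameter: the default k = 1.5 is the
standard outlier fence, k = 0 reproduces the literal reading. Probes with
fewer than 4 amplified cells carry no estimable quartiles and are skipped.
A boundary tolerance of 1e-9·|Q3| keeps borderline CTs from being lost to
float rounding. Degenerate IQR = 0 retains exactly the cells equal to the
quartile value.

False-positive rates are estimated per assay on the wild-type control plate
as mutant-positive / evaluable QC-passed singlets, with no pooling and no
pseudocount — assays with zero observed false positives get 0, matching how
the rates are subsequently applied as per-assay thresholds.

## Subclone calling

Genotype grouping is exact; ordering is descending cell count with
lexicographic tie-break, so tables are permutation-invariant. Filtering
applies the hard FDR cut-off first (⌈fdr·n⌉ cells, floor 1), then the
per-assay error rule, processing candidates in ascending count against the
currently retained set; when several retained single-event neighbours exist
the largest is used (ties toward the larger genotype). The order (a)-then-(b)
is a choice — the source procedure does not state one — and is logged in
each genotype's failure reason, which also serves as the machine-readable
audit trail replacing manual review. Proportions keep all genotyped cells in
the denominator (no renormalisation after filtering) so that reported
subclone fractions refer to the assayed population; `renormalize=True` is
available.

## Finite-sites phylogeny

Event alphabet {0→1, 1→2, 1→0}: a homozygous-mutant state cannot revert in
one step and 0→2 requires mutation then LOH (cost of two events on one
edge). Nodes are genotypes (observed subclones can be ancestors, as the data
show); the root is constrained to wild type or driver-only. If neither is
observed, both candidates are synthesised and the better-scoring one kept.

Because QC discards incomplete cells and cells are assigned to the genotype
they match, the cell-emission term of the likelihood is
topology-independent and the search reduces to weighted minimum-event
reconstruction. The emission model (per assay: P(1|0) = α, P(0|0) = 1 − α,
P(0|1) = P(1|2) = β, zero elsewhere) still matters for reporting: it scores
how well retained cells are explained and raises an error for cells no node
can emit.

**Event prior weights.** Mutation gains cost 1.0; LOH events (1→2 and 1→0)
cost 0.9 by default. The asymmetry resolves a genuine non-identifiability:
a clone whose driver reverted to wild type is otherwise exactly tied with an
independent gain from the wild-type genotype, and a recurrent LOH is tied
with re-deriving a mutation. Copy-neutral LOH at an already-mutated locus
recurs readily (it is the hallmark convergent event at the driver locus in
this disease), whereas the identical point mutation arising twice
independently is far less likely; the prior encodes exactly that, and both
weights are exposed on `ErrorModel`.

Search: `exhaustive_ml` enumerates parent assignments over the canonical
genotype order (≤ 6 genotypes; ties broken by fewer total events, then the
lexicographically smallest parent vector — which, among equal-cost trees,
prefers attaching subclones directly to larger/earlier genotypes).
`heuristic_ml_search` hill-climbs with subtree prune-regraft and local
edge-reversal (re-rooting) moves, steepest-ascent with deterministic
tie-breaks, from 20 restarts: star, count-ordered chain, then random legal
trees from a seeded generator. Equal-cost sideways moves that reduce the
tie-break tuple are taken, so the climb terminates at the same tie-broken
optimum the enumerator reports on small instances.

**Identifiability.** With one event per clone, distinct genotypes, each
non-driver assay gained once, and LOH on the driver assay, the planted tree
is the unique weighted-parsimony optimum. Known residual ambiguity: a chain
passing through the wild-type state can sometimes be traversed in either
direction at identical weighted cost (swapping a driver gain plus passenger
reversion for a passenger gain plus driver reversion); such ties are broken
deterministically but carry no signal, and account for the few percent of
simulated replicates where the recovered topology differs from the planted
one. Resolving them needs longitudinal or copy-number evidence outside the
single-time-point genotype matrix.

## Power and concordance

Detection power is the exact binomial tail P(X ≥ min_cells) with
X ~ Binomial(round(n·(1 − loss)), f) — no normal approximation, since the
expected count at the design point (400 sorted, 10% loss, 2% frequency) is
only ~7 cells. Concordance is squared Pearson correlation of bulk VAF vs
single-cell allele burden (n₁ + 2n₂)/(2n), pooled across assays and samples;
a per-patient breakdown is available by slicing the inputs.

## Problem sizes and determinism

Simulation-based checks use 400–480-well plates, 6-assay panels, bulk depth
10 000×, 100 replicates for recovery rates and 10 000 wells for rate
recovery — sizes at which binomial standard errors make the assertions
sharp. All randomness flows from `numpy.random.default_rng` seeded once per
stream; identical seeds give byte-identical outputs, and every pipeline
artifact is stamped with the configuration hash and seed (input/output paths
are excluded from the hash).

## Known limitations

* False negatives default to 0; with appreciable allelic dropout the
  homozygous-vs-failed distinction would bias cell discard, and no stage
  corrects for that.
* The per-assay error rule compares against the single nearest retained
  genotype; compound error paths (two simultaneous false positives) are
  handled only by the hard FDR cut-off.
* The binomial VAF mixture ignores copy-number uncertainty within a cluster;
  it is a simplified stand-in for full clonal-deconvolution machinery.
* Tree search scores are parsimony-like; no continuous-time rates or
  per-site heterogeneity are estimated, and branch lengths are event counts.
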