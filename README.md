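# mfclone

Clonal-evolution analysis for myelofibrosis (MF) and related myeloproliferative
neoplasms: bulk-DNA clonal tracking across treatment time points, single-cell
qPCR genotyping quality control with explicit error-rate thresholds, subclone
calling under a false-discovery-rate cut-off, and maximum-likelihood phylogeny
reconstruction under a finite-sites model in which mutation and copy-neutral
loss of heterozygosity (LOH) can recur.

It is written for cancer-genomics analysts who track a handful of patient-
specific somatic mutations (a *JAK2* V617F or *CALR* driver plus co-mutations)
through bulk sequencing and plate-based single-cell genotyping of sorted
CD34+ progenitors, and who want the whole analysis testable end to end: a
first-class synthetic-data generator reproduces the error structure of the
real experiments (empty wells, cell doublets, per-assay false positives), so
every stage ships with truth-labelled recovery tests.

## The models

**Bulk clonal tracking.** The cancer cell fraction of a mutation with variant
allele frequency VAF in a sample of tumor purity *p*, local tumor copy number
CN<sub>t</sub> and local normal copy number CN<sub>n</sub> is

    CCF = VAF × (1/p) × (p·CNt + CNn·(1 − p))

and the copy-number-adjusted VAF (the clustering input) is CCF/2. Adjusted
VAFs are clustered with a 1-D binomial mixture selected by BIC; mutations are
excluded from clustering when depth < 25× at either time point or when an
indel is ≥ 3 bp. Longitudinal gain/loss accounting counts mutations retained,
lost and gained between baseline and follow-up at a detection floor
(VAF ≥ 5% by default).

**Single-cell QC and genotyping.** Each well carries paired allele-specific
(WT/MUT) reactions per assay plus two copy-number control probes in diploid
regions. Wells with no control amplification are empty; wells whose control
CTs sit a template-doubling earlier than the singlet reference are doublets;
singlet cells must keep every amplified CT inside per-probe quartile (Tukey)
fences. Per-assay false-positive rates are measured on a wild-type control
cell line. Genotypes are ternary: 0 wild type, 1 heterozygous, 2 homozygous
mutant via LOH; a failed reaction (both probes negative) discards the cell.

**Subclone calling.** Cells with identical ternary vectors form a genotype.
A genotype is kept only if (a) it has at least ⌈FDR × n⌉ cells (2% FDR: 4 of
192 profiled, 8 of 384, 10 of 480) and (b) when it sits one legal event from
a retained genotype, its proportion exceeds that assay's false-positive rate.

**Phylogeny.** Trees are rooted, node-labelled by subclone genotypes, with
edge events from the alphabet {0→1 mutation gain, 1→2 LOH, 1→0 LOH reversion}
under finite sites — the same locus may change repeatedly, so convergent LOH
(homoplasy) and reversion to wild type are representable. The score is the
cell-level error-model likelihood minus a weighted event-count prior;
`exhaustive_ml` enumerates all trees on ≤ 6 genotypes and serves as oracle
for the multi-restart hill-climbing `heuristic_ml_search`.

Detection-power design arithmetic (exact binomial) and bulk-vs-single-cell
allele-burden concordance (r²) round out the toolkit.

## Worked example

```python
import mfclone as m

tree = m.simulate_clone_tree(n_assays=5, n_loh=1, seed=11)       # planted truth
plate = m.simulate_plate(tree, "t1", m.SimulationConfig(n_wells=480, seed=11))
control = m.simulate_control_plate({a.name: 0.005 for a in tree.assays}, 480, seed=12)

result = m.run_pipeline(m.RunConfig(plate=plate, control_plate=control, seed=11))
print(result.subclone_table[["genotype", "n_cells", "proportion", "passed"]].head(8))
print(result.newick)
print(result.events)
```

prints

```
          genotype  n_cells  proportion  passed
0  (1, 0, 0, 0, 0)      193    0.511936    True
1  (1, 0, 1, 1, 0)       51    0.135279    True
2  (2, 1, 0, 0, 1)       39    0.103448    True
3  (1, 0, 0, 0, 1)       31    0.082228    True
4  (1, 1, 0, 0, 1)       31    0.082228    True
5  (1, 0, 1, 0, 0)       28    0.074271    True
6  (0, 0, 0, 0, 0)        2    0.005305   False
7  (1, 1, 0, 1, 1)        1    0.002653   False
(((G2:1)G4:1)G3:1,(G1:1)G5:1)root;
       n_gain  n_loh_homozygous  n_loh_reversion  n_events  homoplasy
JAK2        0                 1                0         1      False
TET2        1                 0                0         1      False
ASXL1       1                 0                0         1      False
SF3B1       1                 0                0         1      False
SRSF2       1                 0                0         1      False
```

The six planted clones (at 5.9–53.8% prevalence) are exactly the six passing
genotypes; the two singleton/doubleton genotypes fall below the 2% FDR
minimum (8 cells for the 376 profiled here) and are flagged, not silently
dropped. The fitted tree roots at the *JAK2*-only clone and carries one
1→2 LOH of *JAK2* — the planted LOH event.

A command-line surface mirrors the stages:

```sh
mfclone simulate --n-assays 5 --n-wells 480 --seed 11 --out-dir sim/
mfclone run-all --plate sim/plate.csv --control-plate sim/control_plate.csv --out-dir out/ --seed 11
mfclone power --n-sorted 400 --loss-rate 0.1 --subclone-freq 0.02 --min-cells 4
```

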