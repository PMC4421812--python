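# kelpscan

Population-genomic and comparative-genomic analyses for kelp (*Saccharina*-type)
genome projects, packaged as a tested pipeline with a coalescent synthetic-data
generator so every stage can be validated without access to sequencing data.

Kelp cultivars descend from a narrow germplasm base: years of selfing and
yield-directed selection are expected to leave (i) genome-wide loss of
diversity relative to wild populations and (ii) local signatures of
artificial selection. `kelpscan` implements the statistics used to detect
both, plus the comparative-genomics machinery that accompanies a draft
genome: gene-family gain/loss, family expansion, tandem-duplication
detection, repeat dating and assembly decontamination.

## What it computes

**Sweep scanning** (`kelpscan.popgen_scan`). In sliding windows over a
biallelic SNV table: segregating sites *S*, nucleotide diversity
θ<sub>π</sub> (mean pairwise differences), Watterson's
θ<sub>W</sub> = *S*/*a*<sub>1</sub> with *a*<sub>1</sub> = Σ<sub>i&lt;n</sub> 1/*i*,
and Tajima's

&nbsp;&nbsp;&nbsp;&nbsp;*D* = (θ<sub>π</sub> − θ<sub>W</sub>) / √(*e*<sub>1</sub>*S* + *e*<sub>2</sub>*S*(*S*−1)),

with the standard variance constants. Windows beyond the empirical 5% tails
of each population's *D* distribution are merged into candidate regions
labelled CN/CP (cultivated negative/positive) or WN/WP (wild), and
intersected with the gene annotation.

**Phylogenetics** (`kelpscan.phylo_dollo`). p-distances over sites where
both samples are homozygous; Saitou–Nei neighbour joining with
column-resampling bootstrap; Dollo parsimony reconstruction of gene-family
gain/loss (single gain at the MRCA branch of the possessing taxa, minimal
losses at the roots of maximal absent subtrees).

**Molecular evolution** (`kelpscan.mol_evolution`). Jukes–Cantor correction
*d* = −(3/4) ln(1 − (4/3)*p*) for repeat-copy insertion ages; Nei–Gojobori
(1986) Ka/Ks with pathway averaging and stop-codon exclusion; percent
identity for tandem-cluster calling.

**Family dynamics** (`kelpscan.family_dynamics`). Exact two-sided Fisher
tests of per-family gene counts between two genomes (integer arithmetic,
min-likelihood rule) with Benjamini–Hochberg correction, and
tandem-duplication clusters as connected components of near-adjacent
high-identity gene pairs.

**Assembly QC** (`kelpscan.seq_qc`). GC content, unioned six-frame ORF
density, and the contamination rule: candidate-bacterial contigs are removed
when ORF density ≥ 60% or GC is outside (40%, 60%).

**Synthetic data** (`kelpscan.synthetic_data`). Seeded generators with
recorded ground truth: a Kingman coalescent with piecewise-constant
demography and infinite-sites mutation (E[*S*] = θ·*a*<sub>1</sub> exactly),
a two-population wild/cultivated split with a bottleneck, repeat decay at
known JC ages, Dollo-compatible family evolution, host/bacterial contig
mixtures, and codon pairs with known Ka/Ks.

## Worked example

```sh
cd analysis
python 01_simulate_populations.py --seed 1
python 02_sweep_scan.py
```

prints (abridged):

```
simulated 5970 biallelic SNVs for 10 diploids -> results/data/variants.vcf
wild: mean pi 9.21, mean D -0.089, D tails [-1.376, 1.143], 28 candidate regions covering 126 genes
cultivated: mean pi 1.88, mean D +0.130, D tails [-1.733, 2.105], 16 candidate regions covering 95 genes
diversity contrast: wild pi / cultivated pi = 4.9x; cultivated mean D shifted +0.22 relative to wild
```

The simulation used θ = 10 per 10-kb window, so the wild mean π ≈ 9.2 sits
at its neutral expectation while the bottlenecked cultivated population
(5% of the wild effective size since the split) retains a fifth of the
diversity — the wild &gt; cultivated ordering that motivates germplasm
conservation — and its Tajima's *D* distribution is shifted positive, as
expected after rare variants are lost in a contraction. The remaining
drivers (`03`–`07`) produce the NJ tree with bootstrap (the
wild/cultivated split at 100% support), the per-branch Dollo gain/loss
table, the bimodal repeat-age histogram, the Fisher expansion table (the
105-vs-28 MC5E alginate-epimerase family at p ≈ 1.4 × 10⁻⁹) and the
contamination-filter report (100% of bacteria-like, 0% of host-like contigs
removed).

The same stages run end-to-end from one command with one seed:

```sh
kelpscan run --seed 1 --out-dir runs/demo
```

Reruns with the same seed are byte-identical.

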