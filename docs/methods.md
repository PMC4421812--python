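# Methods

This note documents the models, estimators and numerical conventions
implemented in `kelpscan`, the assumptions behind the synthetic-data
generators, and the design choices made where the underlying procedures are
conventionally underspecified.

## Window statistics and Tajima's D

All window statistics operate on a haplotype matrix over {0, 1, missing}
derived deterministically from diploid genotypes (hom-ref → 0,0; het → 0,1;
hom-alt → 1,1; missing → missing,missing). Heterozygote phase is arbitrary,
which leaves per-site allele counts — and therefore every statistic
computed here — unchanged.

Per window of physical coordinates (0-based half-open, tiled from 0 with a
configurable step; defaults 10 kb / 5 kb):

- **S** counts sites segregating among called alleles.
- **θπ** is the window-total nucleotide diversity in its frequency form,
  Σ<sub>sites</sub> 2p(1−p)·n<sub>s</sub>/(n<sub>s</sub>−1), with
  n<sub>s</sub> the called alleles at the site. This equals the mean
  pairwise difference count over haplotype pairs when no data are missing
  (property-tested to 1e−10); with missing data the frequency form is the
  canonical choice because it weights each site by its own sample size.
- **θW** = S/a₁(n).
- **D** = (θπ − θW)/√(e₁S + e₂S(S−1)) with Tajima's variance constants
  (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ as functions of n only). D is undefined
  (NaN) when S = 0, n < 3, or the variance term is non-positive; undefined
  windows are excluded from quantiles and can never become candidates.

Missing-data policy: the n used for the variance constants is the number of
haplotypes with ≤ 20% missing calls in the window; π uses per-site
n<sub>s</sub>; S counts segregation among whatever alleles are called. This
is the least-discarding rule that keeps all three quantities internally
consistent. Trailing windows shorter than the nominal size are kept and
flagged (`full=False`): S and π are window totals and D's constants depend
on n, not on window length, so partial windows are statistically valid,
merely noisier.

Empirical thresholds are quantiles of the finite per-population D values by
linear interpolation between order statistics (the numpy default), at a
configurable tail fraction (default 0.05). Thresholds are computed per
population, not pooled — the four region labels CN/CP/WN/WP presuppose
per-population tails; a pooled variant would conflate the two D
distributions, whose means differ under the bottleneck. Candidate windows
of the same sign are merged when consecutive or overlapping; a gene is
reported for a region on ≥ 1 bp overlap in half-open coordinates, and genes
spanning several regions count once in the unique total.

## Coalescent generator

The simulator is a standard Kingman coalescent per window: with k lineages
and relative population size σ(t), coalescence times are exponential at
rate k(k−1)/(2σ), integrated across piecewise-constant epochs; mutations
are Poisson with mean (θ/2) × total branch length and fall on branches
proportionally to length; infinite-sites placement draws distinct integer
positions uniformly in the window (an error is raised in the astronomically
unlikely case that S exceeds the window length). There is no recombination
within windows and windows are independent — a deliberate simplification
that leaves all expectations used for testing exact: E[S] = θ·a₁,
E[θπ] = θ, E[D] ≈ 0 at equilibrium. Haplotypes are paired at random into
diploids.

The two-population scenario is a structured coalescent: cultivated lineages
coalesce among themselves at relative size `bottleneck_severity` (default
0.05) until `split_time` (default 0.1) coalescent units ago, when survivors
join the wild pool (size 1). Severity 1.0 makes the demes exchangeable
(tested as the null case). The defaults encode a recent, severe
domestication bottleneck: diversity in the cultivated sample collapses
toward θ × severity plus the deep-coalescence residual, and its Tajima's D
shifts positive as rare variants are lost. No values for the cultivar
demography exist to calibrate against, so severity and split time are free
scenario parameters, chosen once to produce an unambiguous ordering at
desk-scale sample sizes (5 + 5 diploids), and are not estimates.

What the generator does **not** emulate: linkage within windows,
recombination, gene flow after the split, sequencing/genotyping error and
missingness patterns of real resequencing data. Passing tests therefore
demonstrate correctness of the estimators and calling logic under the
neutral model, not robustness to real-data artefacts.

## Repeat dating

Copies are derived from a random consensus by i.i.d. per-site substitution
with probability p(d) = (3/4)(1 − e^(−4d/3)) — the inverse of the
Jukes–Cantor correction d = −(3/4)ln(1 − (4/3)p) — to a uniformly chosen
different base, optionally truncated to a contiguous fragment with the
remainder gapped. p is computed excluding gap/ambiguity columns; p ≥ 0.75
is reported as saturated and lands in an overflow histogram bin rather than
producing an infinite age silently. Default histogram bin width is 0.01
substitutions/site. At a 10-kb consensus the JC estimator recovers true
ages within ±0.01 (tested at d = 0.02 and 0.20); `log1p` is used so that
ages of nearly identical copies do not underflow to −0.

## Ka/Ks (Nei–Gojobori 1986)

Synonymous site counts per codon are the fraction of the three possible
changes per position that preserve the amino acid, with changes to stop
codons counted as nonsynonymous (so S + N = 3 × codons always, a tested
invariant); counts are averaged between the two sequences. Codon
differences at multiple positions are averaged over all substitution
orderings that avoid stop codons; if every ordering passes through a stop
(rare), the changes are counted as nonsynonymous. Ks = JC(ps),
Ka = JC(pn); a proportion at or beyond 3/4 raises a saturation error per
component — note this makes Ks undefined for very short alignments with a
synonymous difference (e.g. a single codon pair), where ps necessarily
exceeds saturation. The implementation agrees with Biopython's NG86 routine
to machine precision on simulated pairs (cross-checked in the tests).

The paralog-pair generator applies round(p·sites) single-base changes of
each class, preferring untouched codons so that pathway averaging stays
exact; with only synonymous changes requested, the NG86 Ka is exactly 0.

## Neighbour joining and bootstrap

Distances between accessions are p-distances over sites where both samples
are homozygous (heterozygous or missing calls exclude the site for that
pair); a pair with no comparable site is an error naming the pair.
NJ is the classical Saitou–Nei algorithm (join the minimal-Q pair, branch
lengths by the three-point formulas, ending in a basal trifurcation). Two
conventions are fixed for determinism: equal-Q ties join the
lexicographically smallest pair of cluster representatives (the smallest
leaf label under each cluster), making output invariant to input order; and
negative branch lengths are clamped to zero with the deficit moved to the
sister branch, preserving path lengths through the joined pair. On additive
matrices NJ provably recovers the generating tree; this is tested exactly
(path distances to 1e−9) on random trees of 4–12 leaves.

Bootstrap support resamples SNP columns with replacement, recomputes
distances and the NJ tree, and reports per-bipartition frequencies (0–100)
as internal node labels on the full-data tree. Replicates in which some
pair loses all comparable sites are skipped and logged.

## Dollo parsimony

Gene families are 0/1 presence characters on a rooted species tree. Under
Dollo's single-origin assumption the minimal reconstruction is closed-form:
the gain sits on the branch above the MRCA of the possessing taxa, and the
losses are the roots of the maximal subtrees below the gain containing no
possessing leaf. Both the reconstruction and an exhaustive search over all
candidate gain branches are implemented; they agree on all random fixtures
(tested on 200 trees of ≤ 8 leaves). Branches are identified by their clade
leaf-set, which is stable across topologically equal trees. Families absent
everywhere are skipped with a warning; absences are treated as true losses
(annotation gaps are not modelled). The family-evolution generator draws
the gain branch uniformly (root included), then Poisson losses at
`loss_rate` per unit branch length below the gain, recording the minimal
loss set; at the default loss rate 0.02 the reconstruction recovers ≥ 99%
of gain branches, with the residual being families whose losses prune
enough of the clade edge to move the MRCA down.

## Fisher expansion test and correction

The two-sided Fisher p-value sums hypergeometric probabilities of all
tables (conditional on margins) no more likely than the observed one. It is
computed in exact integer arithmetic (`math.comb`, `Fraction`), so
probability ties — which the common floating-point implementations handle
with a relative slop — are resolved exactly; results agree with
`scipy.stats.fisher_exact` to 1e−9 across all tables with total ≤ 30
(tested exhaustively) and a large sample of margins ≤ 30. Families are
pre-filtered to a combined size ≥ 10 across both genomes (summed, the
natural reading of "large families") before testing and correction.
Correction is Benjamini–Hochberg by default — "corrected p" in
comparative-genomics usage is most often FDR — with Bonferroni available;
the choice is surfaced as a parameter, not hidden.

Tandem clusters are connected components (size ≥ 2) of a graph joining
same-scaffold gene pairs with identity ≥ 0.85 and at most `max_intervening`
(default 5) annotated genes between them. The intervening-gene bound
encodes "tandem order" while tolerating small insertions; identity values
are consumed from a matrix (computed upstream by `percent_identity` when
sequences are available).

## Contamination filter

ORFs are ATG-to-stop spans (stop included) of ≥ 300 nt in all six frames,
unioned on the contig coordinate line before summing, so density cannot
exceed 1 (a multiply-counted "density" could). A stop-to-stop mode is
available by flag. The boundary semantics follow the rule as stated:
ORF density ≥ 0.60 inclusive; GC biased when strictly > 0.60 or < 0.40.
The rule applies only to contigs hinted as candidate-bacterial by upstream
homology assignment (consumed as a hint table; homology search itself is
out of scope); authentic/unknown contigs are never removed. The contig
generator separates the classes by construction (host GC 0.50 with sparse
incidental ORFs vs bacterial GC 0.65 at 80% stop-free coding density), and
the filter removes ≥ 90% of bacteria-like and ≤ 5% of host-like contigs at
the defaults — in practice 100% and 0% at these parameter separations.

## Problem sizes and determinism

Default analysis scales — 2,000 windows for calibration checks, 40 × 200
windows for the diversity contrast, 3,000 families for Dollo recovery,
10-kb consensus for repeat dating, 50 pairs × 2,000 codons for Ks
recovery — were chosen so that Monte-Carlo standard errors are far inside
the assertion bounds while a full run stays interactive on a single CPU.
Every stochastic component takes an explicit seed (numpy `default_rng`);
the pipeline derives per-stage seeds from one top-level seed by fixed
offsets, and reruns with the same configuration are byte-identical.

## Known limitations

- No recombination or linkage modelling; windows are exchangeable draws.
- The NG86 implementation is the classical counting method; codon-model
  (GY94-style) rate estimation is out of scope, so absolute Ks values are
  not comparable to likelihood-based tools on saturated data.
- Dollo treats annotation absence as biological loss.
- The contamination filter's discriminative power is only as good as the
  GC/coding-density separation of the input classes; the defaults mirror a
  strong host/bacteria contrast.
- The CLI's minimal VCF dialect carries GT only; rich INFO/FORMAT fields
  are dropped on read.
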