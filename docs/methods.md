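# Methods

`popsel` estimates the strength of positive and negative selection across
coding and noncoding site classes of a diploid, outcrossing plant genome
from three ingredients: an all-sites population genotype table, a
three-way alignment to two outgroups, and a per-gene expression table.
This note records the models, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices made where the design was genuinely open.

## Site classification

Coding positions are classed by codon degeneracy on the coding strand
under the standard nuclear code: 0-fold positions (every change is
nonsynonymous) are the selected coding class, 4-fold positions the
putatively neutral reference. 2- and 3-fold positions are excluded from
analysis so the selected/neutral contrast is not diluted by mixed
mutational effects; sites whose degeneracy conflicts between overlapping
gene models are excluded likewise (precedence: CDS > UTR > intron >
intergenic). Intron sites within 30 bp of a splice boundary form their own
junction class (splice-proximal selection is known to be much stronger
than in intron interiors). Conserved noncoding sequence (CNS) intervals,
supplied as BED with a category column (intergenic, intronic, 5'/3' UTR,
small-noncoding-RNA), flag sites orthogonally to the primary class; a
CNS-flagged site is analyzed as CNS, not as its host class.

## Genotype filters, region mask, IBD

Site-level filters follow a GATK-style all-sites callset: (1) site QUAL
< 90 excluded; (2) any spanning-deletion reads ('Dels' > 0) excluded; (3)
any individual's depth outside [20, 60] excluded; at polymorphic sites
additionally (4) any individual whose best genotype PL is not 0, or (5)
whose second-best PL is below 40, excludes the site. Sites with more than
two segregating bases are excluded. Whole 20 kb windows in which fewer
than 30% of sites pass everything else are dropped outright — this is what
removes repetitive, pericentromere-like regions wholesale. All filters are
pure per-site predicates, so their application order cannot change the
kept set; INFO-level logging records per-filter drop counts.

Identity-by-descent from biparental inbreeding is flagged per sample in
200 kb windows by the inbreeding coefficient `F_IS = 1 - H_obs/H_exp`,
with `H_exp` the mean of `2p(1-p)` over usable polymorphic sites (p the
full-sample alternate-allele frequency). Windows with `F_IS > 0.5` are
IBD; adjacent flagged windows merge into tracts. The per-sample form is
used because IBD is a per-sample phenomenon; the threshold and window are
configuration values.

## Spectra

Unfolded spectra are built per class at a fixed 23 chromosomes: each of
the 13 individuals contributes two chromosomes, or one inside its own IBD
tract (allele drawn once from the genotype), and the contributed pool is
downsampled to 23 by a hypergeometric draw (a deterministic
expected-value option exists; stochastic with a fixed seed is the
default). 23 is the largest target that no site with up to three
overlapping IBD tracts falls below. Polarization takes the
outgroup-agreement base as ancestral; sites where the outgroups disagree,
or where the ancestral base matches neither sampled allele, are excluded
from unfolded spectra. Diversity statistics (Watterson's theta_w, pi,
Tajima's D) use folded information only and are computed from
polarization-free spectra so unpolarizable sites still count.

## Divergence

Lineage-specific substitutions are called by two-outgroup parsimony: a
site is diverged where both outgroups share a base that differs from the
focal reference. A missing base in any of the three rows masks the site
and 5 bp to either side (the strictest reading — any row — guarding
against alignment slippage around indels); only assessed sites enter
numerators or denominators. For the sweep scan, substitutions are further
restricted to sites fixed in the population sample (monomorphic reference
with at least 20 non-missing chromosomes, filter-passing). Per-gene dN/dS
is the count ratio (0-fold substitutions per assessed 0-fold site over the
same at 4-fold sites); dS = 0 genes are flagged NaN, never zero.

## DFE, alpha, omega_a

Under the Poisson random field at constant size, derived alleles at
independent sites have density
`f(x; S) = theta (1 - e^{-S(1-x)}) / ((1 - e^{-S}) x(1-x))` with
`S = 4 Ne s` (signed); binomial sampling gives expected class counts. The
deleterious DFE is a gamma over |S| (shape beta, mean E[S]). A two-epoch
size change (ratio N2/N1 at scaled time t2) is fitted on the neutral
spectrum as a nuisance by Poisson composite likelihood and held fixed; its
expectations come from a discretized Wright-Fisher transition matrix
(matrix size N = 100, eigendecomposition-accelerated evolution), corrected
by the closed-form/matrix ratio at constant size so the flat limit is
exact. The search is bounded to ratios in [1/5, 5] and t2 <= 2 — outside
that range the nuisance starts absorbing polarization noise (genuinely
high-frequency back-mutation variants) rather than demography.

The gamma DFE is fitted to the selected spectrum by Poisson composite
likelihood with Nelder-Mead from a 5-point deterministic start lattice.
By default the selected-class theta is tied to the neutral per-site
estimate (`share_theta=True`): selected and neutral sites share the
mutation rate, and the absolute polymorphism deficit at selected sites is
precisely the information that identifies the strongly selected mass,
which contributes almost no polymorphism of its own shape. With a free
selected theta the strong mass is identified only by spectrum shape and a
spike-near-S=10 mode can genuinely beat the truth in likelihood; the free
option remains available. Bin masses over |S| in (0,1], (1,10], (10,100],
(100,inf) come analytically from the gamma CDF.

Divergence enters through Kimura's fixation-rate ratio
`r(S) = S/(1 - e^{-S})`: the expected nonadaptive substitution rate at
selected sites relative to neutral is `omega_na = E[r(-|S|)]` under the
fitted gamma, and with per-site divergences d_n (selected) and d_s
(neutral), `alpha = (d_n - d_s omega_na)/d_n` and
`omega_a = alpha d_n/d_s`. Alpha is computed from pooled counts, not per
gene. Confidence intervals come from resampling 10 kb blocks with
replacement (200 replicates by default), rebuilding spectra and divergence
and refitting (replicates warm-started from the point estimate). The
randomization test between two classes doubles the smaller one-sided
proportion of replicate pairs, capped at 1; a reported 0 means "below the
2/reps resolution".

Quadrature: the gamma mixture is integrated with 64 Gauss-Legendre nodes
in the quantile domain (`S_k = F^{-1}(u_k)`), which adapts automatically
to wherever the gamma concentrates its mass. Generalized Gauss-Laguerre
on the |S| axis — the textbook choice — is badly wrong exactly in the
regime this analysis lives in (beta ~ 0.3, E[S] ~ 300: omega_na off by a
factor of 15), because its nodes are sparse at small |S| where both the
polymorphism and the fixation integrands concentrate; the quantile scheme
agrees with adaptive quadrature to ~1e-5. The binomial sampling integral
over x uses 512 Gauss-Legendre points on (0,1), exact for the neutral
polynomial case and verified to ~1e-9 against adaptive quadrature at
|S| = 500.

## Sweep scan

Around a focal set of substitutions (or CNS intervals, measuring from the
nearest edge), non-overlapping windows of 500/1000/2000 bp out to ±40 kb
pool kept 4-fold sites across anchors per offset; diversity is the
proportion segregating, divergence the proportion lineage-diverged, and
their ratio controls for locally elevated mutation rates (which inflate
both). Sites inside a focal interval are excluded from that anchor's own
pools. The comparison set is bootstrapped by substitution (1000
replicates); per offset, dropping the top and bottom 25 replicates bounds
the 95% CI, and the one-tailed p is `(i+1)/(n+2)` with i the number of
replicates at or below the observed focal value. Three standard contrasts
run: replacement vs silent substitutions, CNS vs non-conserved noncoding
substitutions, and CNS intervals with vs without a fixed substitution.

A caveat established while validating the test on known-truth data: the
one-tailed bootstrap p-value is intrinsically anticonservative, by a
factor of roughly 1.3-1.4 on the z scale at these problem sizes, because
the null distribution is built from the comparison set alone and never
represents the focal set's own sampling noise. The effect is structural:
it appears even when the focal "set" is an exchangeable random half of
the comparison set, and it is insensitive to substitution density,
gene clustering, window size and genome size. Gene-clustered adaptation
makes it worse (focal and comparison windows then stop sharing sites).
Consequences for use: p-values near 0.05 from this scan should not be
taken at face value — the trough signal is trusted when it is
overwhelming (the package's power checks detect the injected troughs at
the formula's floor, p = 1/1002), and the suite's null-calibration check
documents the residual miscalibration rather than hiding it.

## Expression stratification

Genes with mean FPKM >= 1 are sorted and split into four near-equal
quartile bins (ties broken by stable sort on gene id, so even all-tied
input yields four bins differing by at most one gene). Each bin gets its
own 0-fold and 4-fold spectra and divergence — the bin's own 4-fold data
is its neutral reference — a DFE fit, alpha/omega_a, and the proportion of
invariant replacement sites. CIs resample genes with replacement (1000
default); bin differences use the randomization p. The
dN/dS-vs-expression relationship is summarized by Spearman rank
correlation with a permutation p (rank correlation is robust to the
heavy-tailed FPKM scale); Pearson on log FPKM is reported alongside.

## The synthetic-data generator

The generator is the package's test bed: it emulates every input with
known truth. Default study conditions: 13 diploid individuals (26
chromosomes, downsampling target 23); neutral theta = 0.022 per site;
lineage-specific neutral divergence d_s = 0.14; class DFEs gamma(0.3, m)
with m chosen so the per-class selection structure matches a large-Ne
outcrossing crucifer — replacement sites ~14% effectively neutral (m =
302), UTRs ~45% (m = 5.9), CNSs ~28% (m = 29.7), intron junctions ~68%
(m = 1.3), intron interiors and intergenic neutral; adaptive proportion
0.417 at replacement sites, 0.35 at UTRs and CNSs. Per-gene expression is
log-normal (30% of genes below the 1-FPKM filter), and the mean |S| of a
gene's replacement sites scales as `exp(3.8 (rank - 1/2))` of its
expression rank, so the extreme expression quartiles bracket neutral
masses of roughly 0.21 and 0.09. The adaptive substitution rate per
replacement site is anchored to the class-level DFE, not the gene's, so
positive selection is expression-independent: gene-level alpha then rises
with expression while omega_a stays flat, as observed in real data.

Genomes have multi-exon genes (introns 120 bp, so the 30 bp
junction/internal split is exercised) on alternating strands with
irregular intergenic spacing (uniform 0.5-1.5x the mean — a regular gene
lattice would alias distance-anchored profiles), CNS intervals in
intergenic, intronic and UTR sequence plus an sncRNA category, QUAL/
Dels/DP/PL noise calibrated to exercise every filter branch (depth Poisson
around 34), IBD tracts of 300 kb implemented by copying one haplotype over
the other, and a smooth log-normal regional diversity field (sd 0.4 on the
log scale, 30 kb correlation length, mean exactly 1) standing in for
linked selection and local Ne variation. Genotypes are site-independent
(no linkage) except for injected troughs and IBD: no statistic computed
here needs LD, and independence keeps every expectation analytic.

Substitutions are placed per site at `d_s` for neutral classes and
`d_s (omega_na + omega_na(base) alpha/(1-alpha))` for selected ones, each
labelled adaptive with the implied probability; outgroups carry the
shared ancestral base. Polymorphism may coexist with substitution (such
sites are honestly "not fixed" and dropped by the fixed-substitution
restriction; when the new allele matches the ancestral base the site
polarizes as a genuinely high-frequency derived variant — a real
phenomenon that the demography nuisance partially absorbs, hence the
bounded demographic search). Sweep troughs thin polymorphic 4-fold sites
around trough-bearing ("recent") adaptive fixations with probability
`depth e^{-dist/decay}` per fixation (multiplicative survival under
overlap). In the whole-genome scenario only ~0.05% of adaptive fixations
are recent — scaled so the total trough footprint covers ~10% of the
genome as in the emulated system. The sweep-scan scenario instead models
adaptation clustered in a 20% subset of adaptive-prone genes (alpha 0.75
there, 0 elsewhere; overall alpha ~0.4) with 15% of adaptive fixations
trough-bearing, genes every ~14 kb, on 2 x 1.5 Mb — sized so the
replacement-vs-silent contrast at the substitution is ~30% with a
well-counted divergence denominator.

What the generator does not emulate: linkage disequilibrium and
haplotype structure (so nothing here validates LD-based inference),
sequencing reads and mapping artifacts (quality fields are drawn, not
derived), population structure (Tajima's D is ~0 at default conditions,
not negative as in a structured range-wide sample), codon usage or
GC-biased gene conversion, and indels beyond alignment gaps. Passing
tests therefore demonstrate estimator correctness under the stated
sampling models, not robustness to those real-data complications.

The Wright-Fisher forward simulator (genic selection, genotype fitnesses
1, 1+s, 1+2s, N <= 1000) is the independent oracle: its fixation
probabilities match Kimura's `(1-e^{-S/2N})/(1-e^{-S})` and its
time-averaged sample spectra match the discrete-matrix expectations
exactly (the diffusion closed form to O(1/N), ~4% on the singleton class
at N = 100 — which is why oracle tests compare against the matrix at the
simulated N and check the matrix against the closed form separately).

## Problem sizes

Default test/validation sizes are chosen for desk-scale runs: whole-genome
scenario 2 x 400 kb (~266 genes, every site class >= 500 sites), sweep
scenario 2 x 1.5 Mb, DFE recovery at 1e5 + 1e5 sites over 20 seeds, alpha
CI coverage over 20 replicates of 50 x 2 kb blocks with 150 bootstrap
replicates, expression null over 10 seeds of a 2 x 150 kb genome. The
acceptance script reruns the whole pipeline at the default conditions
with 200-replicate expression bootstraps and a 1000-replicate sweep scan.

## Known limitations

- The gamma-DFE fit to a gene-heterogeneous mixture (the expression
  coupling makes the pooled replacement DFE a gamma mixture) recovers bin
  masses well but overestimates omega_na somewhat, biasing pooled alpha
  low by ~0.05 at default conditions; per-bin estimates are much less
  affected.
- The demographic nuisance absorbs polarization artifacts; with bounded
  search this is benign, but reported size ratios should not be read as
  demographic estimates when polarization error is present.
- The sweep test's p-values are anticonservative under strongly
  gene-clustered adaptation (see above); effects there are detected at
  overwhelming significance or not trusted.
- `region_pass_filter` and the IBD windows quantize boundaries to their
  window sizes; tract edges are accurate to one window only.
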