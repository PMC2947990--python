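# Methods

## Generative model of whole-testis expression

Whole testis is modelled as a mixture over four spermatogenic
compartments $c \in \{$somatic, mitotic, meiotic, postmeiotic$\}$.  The
tissue-level linear signal of gene $g$ in sample $s$ of genotype $t$ is

$$S_{gs} \;=\; \Big(\sum_c f_c(t)\, a_{gc}\Big)\;
  2^{\,\delta_g\, s(t)}\; 2^{\,\beta\,[t=\mathrm{MxD}\ \wedge\ g\ \mathrm{on\ X}]}\;
  2^{\,\varepsilon_{gs}},\qquad \varepsilon_{gs}\sim N(0,\sigma^2).$$

- $f_c(t)$: tissue cell-type fractions of genotype $t$.  Fertile
  genotypes default to $(0.02, 0.08, 0.05, 0.85)$ — postmeiotic cells
  dominate normal adult testis at roughly 85% — and the sterile MxD
  genotype to $(0.06, 0.24, 0.15, 0.55)$: the postmeiotic compartment
  collapses to 55% and the remaining mass rescales proportionally.  No
  quantitative sterile fractions are established biology; the default
  follows the standard 85% → 55% worked example and is configuration,
  not assertion.
- $a_{gc}$: per-cell activity.  A gene's own cell class carries full
  activity, every other class a leakage of 0.05 (class labels mean
  "greatest induction", not exclusivity); unlabelled genes are spread
  evenly over the four compartments and are therefore
  composition-neutral.  Activities are normalised per gene so the
  *fertile-tissue* mixture equals $2^{b_g}$ with
  $b_g \sim N(7.0, 1.5^2)$ (log2 units): base abundance is defined at
  the tissue level, where the detected-gene universe lives.  Fold
  changes between genotypes depend only on activity ratios, so this
  normalisation leaves every composition effect untouched while keeping
  detectability independent of cell class.
- $\delta_g$: species-divergence effect.  Carried with probability 0.10
  (×3.0 for meiotic genes, where between-species expression divergence
  concentrates), magnitude 0.5 log2 with random sign.  $s(t)$ is the
  *M. musculus* genome dose: $-\tfrac12$ (DxD), $+\tfrac12$ (MxM), $0$
  (either F1), so the full MxM−DxD difference is $\delta_g$ and hybrids
  sit midway (additive cis-regulation).
- $\beta$: X over-expression restricted to the sterile genotype;
  default $\log_2 1.17 \approx 0.2265$, the magnitude scale of the
  chromosome-wide X effect the analysis is designed to detect.
- $\sigma$: residual replicate noise, default 0.15 log2 — the middle of
  the 0.10–0.20 band typical for between-male replicates of inbred/F1
  genotypes on expression arrays.

Probe level: each gene carries `n_probes_per_gene` (default 17) probe
pairs with fixed log-normal affinities ($\mathrm{sd} = 0.5$ log2);
$\mathrm{PM} = S\,\phi + b$, $\mathrm{MM} = 0.35\, S\,\phi + b'$ with
independent log-normal backgrounds (median 50, sd 0.5 log2).  The MM
cross-fraction and background scale were chosen so that detection calls
are informative (clearly expressed genes pass, background-level genes
fail) — only their effect on the signed-rank detection test matters.

Annotations: chromosomes 1–19, X, Y with the X at 3.03% of genes (the
share of the detected universe implied by the published chromosome-wise
expectations) and autosomes weighted by physical length; positions
uniform per chromosome; 33% of genes carry no cell-class label; on the
X (and Y) the meiotic class has weight exactly zero — MSCI eliminates
meiotic X expression — and the mitotic class is inflated, matching the
published X class mix.  X-linked genes also receive one of the five
X-expression timing classes A–E.

One root seed feeds named sub-streams (annotations, base levels,
divergence, noise, affinities, backgrounds, dN/dS) so that changing one
stage's scale does not perturb another's draws.  `null_mode` sets
$\delta = \beta = 0$ and equalises all cell fractions, making the twelve
samples exchangeable.

## Preprocessing

**Detection.**  A gene is expressed in a sample when the one-sided
Wilcoxon signed-rank test of paired (PM, MM) intensities gives
$p < 0.01$; a gene is retained only if expressed in *all* samples.
Zero differences are dropped; with fewer than 20 nonzero untied
differences the exact null distribution of $W^+$ is enumerated by the
subset-sum recursion, otherwise a tie-corrected normal approximation
with continuity correction is used.  Genes with fewer than 5 probes are
excluded outright (the exact test cannot reach $p < 0.01$).  One-sided
is the coherent direction — detection asks whether PM exceeds MM.

**Summarisation.**  The probe-level signal is
$\max(\mathrm{PM}-\mathrm{MM}, 1)$; Tukey median polish on its log2
(default) fits probe + sample effects robustly — a single wildly
aberrant probe among 17 moves the summary by under 5% where a plain
mean moves several-fold.  A trimmed mean (10% per tail) is the
pluggable alternative.  The proprietary model-based probe-weighting
estimator used on the original chips is unpublished in detail and is
deliberately not reimplemented; the summariser sits behind a single
interface.

**Normalisation.**  Quantile normalisation maps every column onto the
across-column mean of sorted values; tied observations receive the mean
of the reference quantiles their ranks span.  Values are floored at 1
before log2.  The operation is idempotent and rank-preserving within
columns.

## Contrasts and FDR

Equal-variance Student t-tests per gene (Welch available behind a
flag), two-sided, $\mathrm{df} = n_a + n_b - 2$; genes with zero
variance in both groups are excluded and listed.  The permutation FDR
enumerates *all* distinct relabelings (10 for 3 vs 3, with the observed
labeling included and its count the denominator), hence is fully
deterministic.  The median of the relabeling counts includes the
observed labeling's count; this changes the median only in pathological
cases.  The Benjamini–Hochberg step-up cutoff translates a target FDR
into a p-value threshold where a density-based local-fdr estimate would
otherwise be used; with 10 permutations the empirical ratio is the
primary quantity and BH the secondary convenience.

## Sterility-correlated genes

Three nested definitions at per-contrast $\alpha$ (default 0.05, with
0.01 as the stringent mirror): significant between the reciprocal
hybrids *and* versus at least one parent; significant in all three
sterile-vs-fertile contrasts; additionally not significant in any
fertile-vs-fertile contrast.  False discovery is managed by
intersection, not per-gene adjustment.  Direction bins compare the MxD
mean against all three fertile genotype means; exact ties fall in
`intermediate` (conservative, measure-zero for continuous data).

## Enrichment conventions

- Chromosome-wise: two-sided hypergeometric as the doubled smaller
  tail, capped at 1, Bonferroni-multiplied by the number of chromosomes
  with universe genes.  The universe is the detected-expressed gene set
  (switchable to any caller-supplied universe).
- Cell-type panels: exact binomial per class against the stratum's
  expressed-universe class proportions, computed independently for
  autosomes and X.  The default tail is the two-sided
  minimum-likelihood ("minlike", R `binom.test`) convention multiplied
  by the number of classes tested within the stratum (4 autosomal, 3
  X-linked).  This convention was *inferred by calibration* against the
  published panel tables — it reproduces their corrected p-values to
  printed precision (e.g. 0.0222, 0.0369, 0.8445, 0.7937) where
  one-sided and larger-family variants do not — and is not stated
  anywhere as a protocol; a one-sided tail is available as an option.
- X-expression-class bias: per class A, B, C, E (class D, "variable",
  is excluded as a negligible and uninterpretable subset) and pooled,
  the count of genes with higher MxD than MxM mean is tested against
  1/2 with a two-sided exact binomial; an autosomal reference row is
  reported alongside.

## Composition model and profiles

The confound model constrains only two compartments: mitotic genes
should *appear* higher and postmeiotic genes lower in sterile tissue;
somatic and meiotic classes are unconstrained (sterile males retain
those populations, and the model makes no prediction for them).  The
robust-gene filter keeps exactly the contradictions — postmeiotic ∧
higher, mitotic ∧ lower.  The mixture arithmetic
$(1-f_s)/(1-f_f)$ gives the fold increase in relative non-postmeiotic
abundance (85% → 55% postmeiotic ⇒ 15% → 45%, three-fold).

Deviation profiles anchor each gene at its median log2 value across all
12 males; a genotype's chromosome deviation is the gene-mean of
(genotype mean − anchor), reported as $100(2^{\bar d}-1)$ percent.  The
back-transformed mean-log2 form (rather than the mean linear ratio) is
used because the profile is defined on the log2 scale.  **Known
attenuation:** with 3 of 12 samples carrying a shift $\beta$, the
sample median is the average of the 6th/7th order statistics of the 9
unshifted samples, whose expectation lies $\approx 0.42\sigma$ above
the gene mean; the profile therefore estimates roughly
$\beta - 0.42\sigma$ for well-separated shifts, an attenuation of a few
percentage points at realistic replicate noise.  This is a property of
the statistic itself (the published form of it included), not of the
implementation.  The X-vs-autosome distribution shift per contrast uses
the two-sample Kolmogorov–Smirnov test on per-gene mean differences,
flagged unreliable below 5 X-linked genes.

## dN/dS comparison

The X-vs-autosome comparison of per-gene dN/dS is between two disjoint
gene sets, so it is run as an unpaired Mann–Whitney rank-sum test (the
only coherent reading; the rates themselves derive from pairwise
species alignments, which is where a "paired" label would originate).
Rate estimation from alignments is out of scope; the generator can emit
a matching log-normal table (default medians 0.160 on X vs 0.112 on
autosomes at stratum sizes 152 / 5611).

## What the generator does and does not emulate

It reproduces: the 4 × 3 study layout; a heterogeneous tissue whose
signal is a cell-type mixture with a depleted postmeiotic compartment
in the sterile genotype; meiosis-enriched species effects with additive
hybrid inheritance; a sterile-restricted X shift; probe-level PM/MM
structure adequate for detection calls; and an exchangeable null.  It
does not emulate: probe-sequence effects or cross-hybridisation between
species genomes (the generator's affinities are genotype-independent);
correlated noise between genes; count-based RNA-seq error; or any
within-chromosome spatial structure.  Passing tests therefore
demonstrate the statistical machinery and its calibration, not the
biology of any particular dataset.

## Problem sizes and numerical choices

Test and demonstration runs use 300–2000 genes with 9–11 probes per
gene — enough for every statistic to be in its asymptotic regime while
keeping the full suite inside a few minutes; the generator's study-scale
default is 7000 genes × 17 probes.  Calibration checks fix seeds and
use bands derived from enumeration or binomial standard errors (type-I
rate within 3 s.e. of $\alpha$; null permutation FDR within the spread
of the 10-relabeling ratio).  Intensities are floored at 1 before any
log2; corrected p-values are capped at 1; the exact signed-rank path is
used below 20 nonzero differences; ties anywhere fall to the
conservative side (mean reference quantiles, `intermediate` direction,
tie-corrected variance).
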