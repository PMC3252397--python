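# Methods

## Scope and data model

The package reimplements, as a tested library, the computational
workflow used to characterize the three small heat-shock-protein (sHSP)
genes of *Acidithiobacillus ferrooxidans* ATCC 23270: promoter
discovery for the heat-shock sigma factor σ³², relative quantification
of the genes' heat-shock response by qRT-PCR, a GC-composition screen
for horizontal acquisition, and protein physicochemical parameters.
Coordinates in all interfaces are 1-based inclusive (GenBank
convention). The public NC_011761 genome is not redistributed; analyses
that need it read user-supplied FASTA from `data/reference/`, and all
other functionality runs on the synthetic generators described below.

## Two-block σ³² promoter model

σ³² promoters are modeled as a 6-nt −35 element and an 8-nt −10
element separated by a spacer of variable length. One position weight
matrix per block is estimated from an aligned training set of
(site35, spacer, site10) records with Laplace smoothing

    p_l(b) = (n_l(b) + c) / (n + 4c),     c = 0.5 by default.

The pseudocount default of half a count per base avoids infinite
log-odds for bases unseen in a training set of realistic size (the
emulated sets have 18 sites); c is exposed everywhere.

*Scoring.* A candidate placement is scored as the sum of the two
blocks' log-odds in bits, Σ_l log₂(p_l(b_l)/q(b_l)). The background q
is equiprobable by default; a GC-parameterized background
(q(G)=q(C)=gc/2) is available because the *A. ferrooxidans* genome is
GC-skewed. Changing the background rescales scores but, being a
per-base constant shift, does not reorder placements. Individual
information R_i is always reported against the equiprobable background
(the standard "bits" display for binding sites), so with the default
background R_i and the log-odds score coincide. Model information
content is R_sequence = Σ_l Σ_b p log₂(p/q), with 0·log 0 = 0.

*Scanning.* Every (−35 start, spacer) pair whose spacer lies in the
training set's observed [min, max] range and whose blocks fit in the
window is enumerated and scored; there is no spacer-length penalty,
since only the admissible range is justified by the data. Windows are
the 200 nt upstream of the start codon in coding orientation
(reverse-complemented for minus-strand genes), truncated and flagged at
replicon edges, and deliberately not clipped at neighboring gene
boundaries. Hits are ranked by total score; scores equal to 6 decimals
are treated as exact ties (stabilizing the ranking against floating-
point summation order) and broken toward the site nearer the start
codon, then leftmost — promoters proximal to the gene are biologically
preferred, and the ordering must be deterministic. `N` bases score as
the background-expected log-odds, i.e. they neither reward nor
disqualify a site.

## ΔΔCt relative quantification

Per replicate, ΔCt = Ct_target − Ct_reference pairs the target with
the endogenous control (*alaS*) by replicate index;
ΔΔCt = mean ΔCt(treatment) − mean ΔCt(control) and fold = 2^(−ΔΔCt),
assuming perfect amplification efficiency (the Livak model; efficiency
correction is out of scope). Replicates are the unit of error; a
helper collapses technical into biological replicates by averaging Ct
when both levels are present. The p-value is a two-sided two-sample
Student's t-test on the replicate ΔCt sets (equal-variance by default,
Welch by flag). A gene is called up-regulated when p < 0.05 **and**
fold ≥ 2.0; the threshold is strict (<, not ≤) and documented because
both conventions appear in common usage. With fewer than two
replicates per condition the p-value is undefined (NaN) and the gene
is never called significant.

## GC composition / HGT screen

GC content is computed on the annotated CDS from start through stop
codon inclusive, excluding `N` from numerator and denominator. The
screen is a one-proportion Pearson χ² with 1 df of the observed
[GC, AT] counts against the genome-average coding GC (default 0.59 for
*A. ferrooxidans*; recomputable from a genome-wide CDS FASTA), with
the p-value from the χ²(1) tail and a warning when an expected class
count falls below 1. Genes with p < 0.01 are flagged as candidate
horizontal acquisitions. Only the significance pattern — not any
particular χ² statistic value — is treated as the reproducible outcome
of the published analysis, because the exact statistic formulation
behind the published values is not recoverable from the printed
summary data; the standard Pearson test on the printed GC percentages
and CDS lengths reproduces the published pattern (two AT-rich genes
significant at α = 0.01, the third not).

## Protein parameters

Molecular weight is the sum of average (not monoisotopic) residue
masses plus one water (18.0153 Da); average masses are the convention
under which ~16 kDa sHSPs are reported, and the residue table is fixed
in code. Theoretical pI follows the ProtParam convention: net charge
from Henderson–Hasselbalch terms for the N- and C-termini (terminal
pKa depending on the terminal residue) and the D/E/C/Y/H/K/R side
chains with the Bjellqvist pKa set, solved by bisection on pH ∈ [0, 14]
to 1e-4 (the charge is strictly decreasing in pH, so the root is
unique). Identity and similarity come from a global pairwise alignment
with BLOSUM62, gap open 10 and gap extend 0.5: identity is the
fraction of identical alignment columns, similarity the fraction of
columns with a positive substitution score, both over all columns and
rounded to integer percent. Because co-optimal alignments depend on
argument order, the pair is aligned in a canonical order so results
are symmetric. Alignment parameters for the published values are
unknown, so agreement with them is asserted only within ±5 percentage
points.

## In-silico PCR

Primer matching is exact (the published primers were designed for
perfect identity to the genome): the forward primer is located on each
strand and the reverse complement of the reverse primer downstream of
it; amplicon length includes both primer footprints. Zero products
returns none; more than one raises an error listing all sites, since
multiple products signal non-specific primers.

## Synthetic generators (study conditions)

The generators emulate the study design so every stage has inputs with
known ground truth; all draw from named, independent PRNG streams
under one integer seed (`SeedSequence(seed, spawn_key=(stream,))`), so
outputs are bit-reproducible and adding a generator never perturbs
existing streams.

- **Training sets:** 18 sites; each block is the consensus with i.i.d.
  per-position mutations at rate 0.1; spacers uniform on 11–15 nt.
  The demonstration consensus (CTTGAA / CCCCATTT) is configurable and
  is not a claim about any particular genome.
- **Upstream windows:** 200 nt i.i.d. at 59% GC with consensus boxes
  planted at recorded positions and spacers.
- **Genes:** i.i.d. bases at a target GC fraction (the three gene
  targets default to the published per-gene GC percentages); optional
  CDS-like mode (ATG start, TAA stop, internal stops resampled, which
  perturbs realized GC slightly).
- **Ct tables:** Ct = base − log₂(true fold) + N(0, sd), triplicates,
  sd 0.2 cycles by default (a typical qPCR replicate SD); the reference
  gene is fixed at fold 1. The default true folds encode the reported
  60-min outcome — the weakest responder (Afe_2172) anchored at the
  2.0 fold floor, giving Afe_1437 = 40 and Afe_1009 = 40/11.5 from the
  reported 20× and 11.5× between-gene ratios; the unreported 15- and
  30-min folds ramp log-linearly toward the 60-min value.

What the generators do **not** emulate: amplification-efficiency
differences between assays, plate/batch effects beyond what the
ΔCt normalization cancels by construction, codon structure or
compositional heterogeneity along genes, and correlated training-site
evolution. Tests passing on these data therefore validate the
estimators and their calibration under the stated error model, not
robustness to those real-data complications.

## Numerical choices and problem sizes

Validation and calibration runs use: 100 random model/window pairs
(windows ≤ 60 nt) for exact scanner-vs-enumeration agreement; 200
planted 200-nt windows for recovery (an 18-site, mutation-rate-0.1
model carries ~16 bits, well above the ~10 bits where single-site
recovery is reliable); 500 simulated experiments for fold-change
recovery and type-I calibration; and 10,000 genes of 450 nt (a typical
sHSP CDS length) for the GC screen's null calibration, whose exact
binomial analysis at n = 450, p = 0.59 gives a true test size of
≈0.0096 at nominal 0.01 — the residual discreteness of the binomial
count. Tolerances: PWM columns sum to 1 within 1e-9; pI bisection to
1e-4 pH; zero-noise fold recovery is exact to floating-point rounding.

## Known limitations

- The scanner models only the 6+8 bipartite core; extended promoter
  elements and transcription-start-site prediction are out of scope,
  as are phylogenetics and structural modeling of the proteins.
- Exact-match PCR ignores mismatch tolerance, ambiguity codes, and
  thermodynamics.
- The ΔΔCt model assumes 100% amplification efficiency and an ideal
  reference gene.
- Exact reproduction of the published per-gene values requires the
  public genome sequences, supplied by the user; the package validates
  everything else against independent oracles and printed summary
  statistics.
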