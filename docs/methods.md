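# Methods

This note documents the models, conventions and numerical decisions behind
`ciceratlas`, what the synthetic atlas generator does and does not emulate,
and the known limitations.

## Coordinates and formats

All genomic coordinates are internally 0-based half-open. GFF3/GTF (1-based
inclusive) and the VCF-like variant table (1-based POS) are converted on
read and back on write; BED passes through unchanged. One convention across
every module removes off-by-one drift between stages. Motif files use the
MEME-minimal dialect; the probability block is read directly (rather than
through a motif library that silently renormalizes) so that rows deviating
from sum 1 by more than 1e-3 can be rejected, as the format contract
requires. Biotype (`PCG` / `lncRNA`) and TF family are annotation
attributes, read from configurable keys (defaults `biotype`, `tf_family`);
they are inputs, not predictions.

## Tissue specificity

Tau is the canonical max-normalized index,
`tau = sum_i (1 - x_i/max_j x_j) / (N-1)`, computed on the **linear** tissue
mean-FPKM profile because the 0.5-FPKM eligibility floor is defined on that
scale; a log-scale variant can be obtained by transforming the profile
before calling `compute_tau`. Tau is scale-invariant, lies in [0, 1], and is
undefined (NaN, flagged) for all-zero profiles. Replicate QC correlations
and row Z-scores use log2(FPKM + 1); the pseudocount 1 is the package's
convention. Peak-tissue ties are broken by tissue column order and flagged
rather than raised. Thresholds: eligibility peak mean FPKM >= 0.5,
specificity tau >= 0.9, both inclusive.

## lncRNA genomic context

Positional classes are assigned with a fixed precedence — exonic
(same-strand exon–exon overlap) > natural-antisense (opposite-strand
exon–exon overlap) > intronic (span fully inside one intron, either strand)
> intergenic — because a lncRNA can satisfy several of these at once and the
class must be unique. The supporting PCG is the one with the largest overlap
(ties by id). Cis targets use the most literal reading of a 10-kb window:
the gap between transcript *spans* (not TSSs), inclusive at exactly 10 kb,
strand-agnostic, with overlap counting as gap 0. Trans targets are Pearson
correlations of log2(mean FPKM + 1) across the N tissue means (not the
individual samples), |r| >= 0.97, with cis partners excluded and constant
profiles skipped. GO transfer is the union over targets with per-term
provenance (cis / trans / both).

For alternative-splicing typing, donor = intron 5' end and acceptor =
intron 3' end in transcription orientation (swapped genomic sides on the
minus strand). IR: an intron of one isoform inside an exon of the other;
ES: an internal exon inside the other's intron; AA/AD: overlapping introns
whose acceptor/donor sites differ, unless the shift is explained by a fully
skipped internal exon lying between the two alternative sites (that case is
ES, not an alternate site). Typing is symmetric in the pair.

## Coexpression modules

Prefilter: tissue mean FPKM >= 0.1 somewhere, log2(FPKM+1), row variance
(ddof = 1) >= 1.5 inclusive. The network is unsigned, `a_ij = |r_ij|^beta`
with zero diagonal. The scale-free index bins connectivity into 10
equal-width bins, regresses log10(frequency) on log10(mean k), and reports
R² when the slope is negative, 0 otherwise; the selected beta is the
smallest one reaching 0.8, falling back (with a warning) to the argmax.
Topological overlap is
`TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)` with unit
diagonal; dissimilarity 1 − TOM is clustered by average linkage.

The dendrogram cut is the simplified "tree" variant: cut at a fixed fraction
of the maximal merge height mapped from deepSplit (0–4 →
0.95/0.97/0.99/0.995/0.999; default deepSplit 2 → 0.99), then drop clusters
below minClusterSize 30 to the unassigned module M0. The published
dynamic-hybrid branch-splitting algorithm is deliberately not reproduced;
recovery is assessed by adjusted Rand index against planted truth instead.
This is the package's main approximation: because inter-module merge heights
sit close to the maximum on topological-overlap dissimilarities, the fixed
0.99 fraction can occasionally fuse two planted modules or absorb background
on some random realizations, even though recovery at the default study
conditions (seed 1) is exact. Module eigengenes are the first right singular
vectors of the row-standardized module submatrix (unit norm over tissues,
sign oriented to correlate non-negatively with the module mean profile);
merging iteratively fuses module pairs with eigengene dissimilarity
1 − r < 0.2, recomputing after each fusion. Final labels M1..Mk are by
descending size (ties by smallest member id), which makes them invariant to
input row order. Module–tissue relations use Pearson r between each
eigengene and a per-tissue indicator over the N = 32 tissue columns, with a
two-sided P from `t = r sqrt((N-2)/(1-r^2))` on N − 2 df; this transform
reproduces the published M1 value (r = 0.71 → P ≈ 5e−06), and the
32-column basis is the one consistent with that value.

## Promoters, motifs, enrichment, TRN

Promoters are 2 kb upstream of the TSS in transcription orientation
(minus-strand promoters reverse-complemented), clipped and flagged at
chromosome ends. PWMs are scored as log2 odds against a uniform 0.25
background (probabilities clipped at 1e-6; unknown bases score 0), both
orientations, every offset; a hit needs >= 80% of the motif's maximal
score, and overlapping hits are all reported. Enrichment is the
hypergeometric upper tail of foreground carriers (a transcript carries a
motif iff it has >= 1 hit) against a caller-chosen background universe,
Benjamini–Hochberg corrected across items, enriched at q <= 0.05; the same
machinery serves GO terms. Running the motif test separately on the PCG and
lncRNA members of a module yields the "PCG-only" vs "both" scope flag used
when reporting regulatory modules. The TRN edge list connects TF families to
their enriched motifs and each motif to the enriched GO terms carried by its
hit-bearing module members; motifs without a TF mapping are kept as flagged
orphans. The enrichment backend (hypergeometric against all analyzed
promoters) is the package's choice where upstream motif-discovery tooling
was out of scope.

## QTL screening

"Located within" a QTL means full span containment; boundary-straddling
transcripts are recorded with a `partial` flag but never promoted.
Differential expression is log2((mean_A+1)/(mean_B+1)) on FPKM with a
two-sided Welch t-test on log2(FPKM+1) replicates; degenerate variance is
resolved as p = 0 for unequal constant groups and p = 1 for identical
constants, single-replicate groups get undefined p and are never
significant, and no multiple-testing correction is applied to the per-
contrast P <= 0.05 rule (the rule is a fixed threshold convention, not an
FDR procedure). Variant membership in bodies and promoters is by point
position; variant–motif overlap uses the reference-allele span with
any-base intersection against the hit's half-open genomic interval. The
tissue-specific screen keeps QTL-contained, Tau-specific transcripts; the
stress screen keeps QTL-contained transcripts significant in >= 1 contrast
that also carry >= 1 body/promoter variant. Reports are deterministically
sorted by chromosome and position.

## The synthetic atlas

The generator defines the study conditions: 32 named tissues, three
biological replicates except two seed stages (20DAP, 30DAP) with two — 94
samples; ~2,000 transcripts (1,950 PCGs, 50 lncRNAs in the four positional
classes) on four 4-Mb chromosomes; five planted modules of 40–80 members
with log-scale eigen-profiles (sd 2.0), loadings 0.8–1.2 and gene noise sd
0.5; ~200 high-variance background transcripts (sd 1.5, enough to pass the
variance prefilter); five planted tissue-specific transcripts per tissue
(peak FPKM 10–100, off-tissue FPKM 0.02); eight planted lncRNA–PCG trans
pairs sharing a profile (noise sd 0.05); log-normal replicate noise sd 0.25
(log2 scale). FPKM is simulated as 2^(log-level + noise), matching the
pipeline's log2(FPKM+1) analysis transform. Motifs are eight width-10
matrices (0.85 consensus / 0.05 off); at the 80% score threshold only exact
consensus occurrences score as hits, which makes planted-instance recovery
deterministic. Module motifs are planted in 70% of their module's
promoters; QTL candidates get one planted motif with a SNP inside it, a
promoter SNP >= 50 bp from any motif, and a body variant; decoy variants
and decoy QTLs live in reserved per-chromosome gene deserts. The stress
experiment plants a +2 log2 effect in designated candidates over a flat
baseline (replicate sd 0.15) per contrast.

Design choices that keep the planted truth recoverable exactly at default
settings: tissue-specific transcripts and module members are PCGs only
(a tissue-specific or module lncRNA would share its profile with same-peak
PCGs and create accidental |r| >= 0.97 trans pairs, making "exact" trans
truth ill-defined); planted QTLs are placed so they never fully contain a
transcript from the high-variance roles (module, background, shared-profile
pairs), whose incidental tau can cross 0.9; cis-target truth is recorded by
a brute-force quadratic span scan, independent of the interval index the
analysis uses. Effect sizes default to comfortably recoverable values;
stressing them (lower loadings, higher noise) is for power exploration, not
for the shipped checks.

What the generator does **not** emulate: read-level sequencing (no FASTQ,
no mapping noise), compositional FPKM coupling between transcripts,
correlated replicate structure, tissue-specific lncRNAs, lncRNAs inside
coexpression modules, hierarchical tissue similarity (tissue profiles are
exchangeable draws, so module–tissue correlations are weaker than in a real
atlas where related tissues co-activate), motif positional preferences, and
linkage between variants. Passing tests therefore show the algorithms are
implemented to contract and recover planted structure under realistic noise
magnitudes — not that the pipeline is robust to every artifact of real
sequencing data.

## Problem sizes and determinism

The default generator (~2,000 transcripts × 94 samples, 16 Mb genome) runs
in well under 30 s on one CPU, and the full pipeline on it in a few
seconds more; these sizes were chosen so the whole recovery suite runs
comfortably on a laptop while keeping every count (modules, classes,
candidates) large enough to be meaningful. Every generator output is a pure
function of the spec (including its seed), with independent sub-streams per
stage, so the same spec reproduces byte-identical files and the analysis
pipeline is deterministic end-to-end (labels are stable under input row
permutation; all tie-breaks are explicit).

## Known limitations

- The simplified tree cut (above) can under-split modules on some random
  realizations; the dynamic-hybrid algorithm would be needed for parity
  with the reference clustering on hard cases.
- The scale-free beta selection frequently falls back to the argmax on
  small planted networks (the synthetic correlation structure is blockier
  than a real atlas); the fallback is deterministic and warned about.
- Hit scoring treats every promoter base as background 0.25; no GC
  correction or higher-order background model is provided.
- The DE test assumes log-scale normality within condition groups and does
  not borrow variance across transcripts.
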