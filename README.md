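# ciceratlas

Integrated analysis of a multi-tissue transcriptome expression atlas, of the
kind built for crop functional genomics (the conventions follow a chickpea
atlas of protein-coding genes and lncRNAs across 32 tissues/organs in 94
RNA-seq libraries). The package takes a transcript-level FPKM matrix with a
tissue/replicate design, a genome annotation with biotypes, a genome FASTA,
motif matrices, variants and trait QTL intervals, and carries them through
five analysis stages:

1. **Tissue specificity.** For each transcript the tissue-mean profile
   `x_1..x_N` (N = 32) is scored with the tissue-specificity index

   `tau = sum_i (1 - x_i / max_j x_j) / (N - 1)`,

   0 for uniform and 1 for single-tissue expression. Transcripts with peak
   mean FPKM >= 0.5 are eligible; `tau >= 0.9` calls a transcript
   tissue-specific, with the argmax tissue as its peak.
2. **lncRNA genomic context.** Each lncRNA is classified against the
   protein-coding gene models as exonic (same-strand exon overlap),
   natural-antisense (opposite-strand exon overlap), intronic (span inside
   one intron) or intergenic; PCGs within 10 kb are its *cis* targets, PCGs
   with `|r| >= 0.97` across the log-scale tissue means its *trans* targets,
   and GO terms transfer from targets to the lncRNA. Pairwise isoform
   comparison types alternative-splicing events (IR / ES / AA / AD).
3. **Coexpression modules.** A weighted network is built from the prefiltered
   (FPKM >= 0.1, log2 variance >= 1.5) profiles: unsigned adjacency
   `a = |r|^beta` with `beta` chosen by scale-free fit, topological overlap
   `TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)`,
   average-linkage clustering with minClusterSize 30 and eigengene merging at
   cutHeight 0.2. Module eigengenes (first principal components) are
   correlated with per-tissue indicators; P-values use
   `t = r sqrt((N-2)/(1-r^2))` on N-2 degrees of freedom.
4. **Regulatory networks.** 2-kb strand-aware promoters are scanned with
   position weight matrices (log-odds vs uniform background, hits at >= 80%
   of the maximal score); per-module motif and GO enrichment is
   hypergeometric with Benjamini-Hochberg correction (q <= 0.05), and
   enriched TF -> motif -> GO edges form the transcriptional regulatory
   network.
5. **QTL candidate screening.** Transcripts fully contained in trait QTL
   intervals are filtered by tissue specificity, or by differential
   expression between stress and control genotypes (`|log2FC| >= 1`,
   `P <= 0.05`, Welch t on log2(FPKM+1)), intersected with variants in their
   bodies, promoters and promoter motif hits, and reported with the full
   evidence chain.

A first-class synthetic atlas generator (`ciceratlas.synthetic`) emulates the
whole study design — genome, annotation, planted modules, planted
tissue-specific transcripts, planted motif instances, variants and QTLs —
with machine-readable ground truth, so every stage is testable end-to-end
without any download.

## Worked example

```bash
python examples/02_tissue_specificity.py
```

```
eligible transcripts (peak FPKM >= 0.5): 2000
tissue-specific (Tau >= 0.9):            361
...
recall of the 160 planted tissue-specific transcripts: 1.00
```

All 2,000 synthetic transcripts pass the FPKM floor; 361 reach `tau >= 0.9`,
and all 160 transcripts the generator planted as tissue-specific are
recovered with the correct peak tissue (the additional calls come from
high-variance module and background transcripts whose profiles legitimately
concentrate in one tissue — the planted *broad* transcripts contribute
none). `examples/04_coexpression_modules.py` then
recovers the five planted modules exactly (M1–M5, 40–80 members, unassigned
transcripts in M0), and `examples/06_qtl_screen.py` prints the candidate
reports in which every planted QTL candidate appears with its trait, its
Tau or log2 fold-change, and the promoter variants that fall inside planted
cis-regulatory motifs.

The other examples (`01` simulation and file export, `03` lncRNA context,
`05` promoter scanning/enrichment/TRN) each print the quantity they compute
and a line on how to read it.

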