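"""Promoter extraction, motif scanning, enrichment tests and TRN assembly.

Promoters are the 2 kb immediately upstream of the transcription start, in
transcription orientation (minus-strand promoters are reverse-complemented),
clipped at chromosome ends. Position weight matrices are scored as log-odds
against a uniform 0.25 background on both orientations; a hit is any window
scoring at least ``score_fraction`` of the motif's maximum achievable score.

Enrichment (motifs or GO terms) is a hypergeometric upper-tail test of
foreground hits against a background universe, corrected across items with
Benjamini-Hochberg; an item is enriched at q <= 0.05. A transcriptional
regulatory network is then assembled as TF -> motif -> GO-term edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import (
    GenomeAnnotation,
    Motif,
    MotifHit,
    Promoter,
    ValidationError,
)

__all__ = [
    "extract_promoters",
    "scan_motifs",
    "motif_enrichment",
    "go_enrichment",
    "hypergeom_upper_tail",
    "build_trn",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_promoters(
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    length: int = 2000,
    transcripts: list[str] | None = None,
) -> list[Promoter]:
    """Promoter of every (or the selected) transcript.

    Plus strand: ``[max(0, TSS - length), TSS)``; minus strand:
    ``[end, end + length)`` reverse-complemented. Clipping at chromosome
    ends sets the ``clipped`` flag.
    """
    ids = transcripts if transcripts is not None else [t.id for t in annotation.transcripts]
    out = []
    for tid in ids:
        t = annotation[tid]
        if t.chromosome not in genome:
            raise ValidationError(f"chromosome {t.chromosome!r} missing from FASTA")
        chrom_seq = genome[t.chromosome]
        clen = len(chrom_seq)
        if t.strand == "+":
            start, end = max(0, t.start - length), t.start
            seq = chrom_seq[start:end]
        else:
            start, end = t.end, min(clen, t.end + length)
            seq = reverse_complement(chrom_seq[start:end])
        out.append(
            Promoter(
                transcript_id=tid,
                chromosome=t.chromosome,
                start=start,
                end=end,
                strand=t.strand,
                sequence=seq.upper(),
                clipped=(end - start) < length,
            )
        )
    return out


def _log_odds(motif: Motif) -> np.ndarray:
    p = np.clip(motif.matrix, 1e-6, None)
    return np.log2(p / 0.25)


def _encode(seq: str) -> np.ndarray:
    # unknown bases get index 4 -> scored 0 (background-neutral)
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def _window_scores(encoded: np.ndarray, lods: np.ndarray) -> np.ndarray:
    w = lods.shape[0]
    if encoded.size < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    padded = np.hstack([lods, np.zeros((w, 1))])  # column 4: neutral unknown base
    return padded[np.arange(w), windows].sum(axis=1)


def scan_motifs(
    promoters: list[Promoter],
    motifs: list[Motif],
    score_fraction: float = 0.8,
) -> list[MotifHit]:
    """All motif occurrences in the promoters, both orientations.

    A window is a hit when its log-odds score (vs uniform background) is at
    least ``score_fraction`` of the motif's maximal achievable score.
    Overlapping hits are all reported. Promoters shorter than the motif give
    no hits.
    """
    hits: list[MotifHit] = []
    for motif in motifs:
        lods = _log_odds(motif)
        threshold = score_fraction * lods.max(axis=1).sum()
        w = motif.width
        for prom in promoters:
            fwd = _encode(prom.sequence)
            rev = _encode(reverse_complement(prom.sequence))
            for orientation, enc in (("+", fwd), ("-", rev)):
                scores = _window_scores(enc, lods)
                for pos in np.flatnonzero(scores >= threshold):
                    offset = (
                        int(pos) if orientation == "+" else len(prom.sequence) - int(pos) - w
                    )
                    # promoter-relative offset (transcription orientation) ->
                    # genomic interval
                    if prom.strand == "+":
                        gstart = prom.start + offset
                    else:
                        gstart = prom.end - offset - w
                    hits.append(
                        MotifHit(
                            motif=motif.name,
                            transcript_id=prom.transcript_id,
                            offset=offset,
                            orientation=orientation,
                            score=float(scores[pos]),
                            chromosome=prom.chromosome,
                            start=gstart,
                            end=gstart + w,
                        )
                    )
    hits.sort(key=lambda h: (h.motif, h.transcript_id, h.offset, h.orientation))
    return hits


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValidationError("impossible contingency table")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _enrich(
    items_by_transcript: dict[str, set[str]],
    foreground: list[str],
    background: list[str],
    fdr: float,
) -> pd.DataFrame:
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValidationError("empty foreground")
    if not fg <= bg:
        raise ValidationError("foreground is not a subset of the background")
    items = sorted({i for t in bg for i in items_by_transcript.get(t, set())})
    rows = []
    for item in items:
        carriers = {t for t in bg if item in items_by_transcript.get(t, set())}
        k, K = len(carriers & fg), len(carriers)
        rows.append(
            {
                "item": item,
                "k": k,
                "n": len(fg),
                "K": K,
                "N": len(bg),
                "p": hypergeom_upper_tail(k, len(fg), K, len(bg)),
            }
        )
    df = pd.DataFrame(rows, columns=["item", "k", "n", "K", "N", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["enriched"] = df["q"] <= fdr
    else:
        df["q"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df


def motif_enrichment(
    foreground: list[str],
    background: list[str],
    hits: list[MotifHit],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of foreground promoters.

    A transcript "has" a motif iff it carries >= 1 hit. Returns columns
    item (motif), k, n, K, N, p, q, enriched.
    """
    carriers: dict[str, set[str]] = {}
    for h in hits:
        carriers.setdefault(h.transcript_id, set()).add(h.motif)
    return _enrich(carriers, foreground, background, fdr)


def motif_enrichment_by_biotype(
    annotation: GenomeAnnotation,
    foreground: list[str],
    background: list[str],
    hits: list[MotifHit],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Run the motif test separately for PCG and lncRNA foregrounds and flag
    each enriched motif as "PCG_only" or "both" (mirroring how regulatory
    modules are reported)."""
    def split(ids: list[str], biotype: str) -> list[str]:
        return [i for i in ids if annotation[i].biotype == biotype]

    fg_pcg, fg_lnc = split(foreground, "PCG"), split(foreground, "lncRNA")
    res_pcg = motif_enrichment(fg_pcg, background, hits, fdr) if fg_pcg else pd.DataFrame()
    res_lnc = motif_enrichment(fg_lnc, background, hits, fdr) if fg_lnc else pd.DataFrame()
    enriched_pcg = set(res_pcg.loc[res_pcg["enriched"], "item"]) if len(res_pcg) else set()
    enriched_lnc = set(res_lnc.loc[res_lnc["enriched"], "item"]) if len(res_lnc) else set()
    if len(res_pcg):
        res_pcg = res_pcg.copy()
        res_pcg["scope"] = [
            ("both" if m in enriched_lnc else "PCG_only") if m in enriched_pcg else ""
            for m in res_pcg["item"]
        ]
    return res_pcg


def go_enrichment(
    genes: list[str],
    background: list[str],
    go_map: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment with Benjamini-Hochberg correction.

    Terms absent from the background annotation are skipped (they cannot be
    tested); enrichment is q <= ``fdr``.
    """
    return _enrich(go_map, genes, background, fdr)


def build_trn(
    module_id: str,
    enriched_motifs: pd.DataFrame,
    motif_tf_map: dict[str, str],
    enriched_go: pd.DataFrame,
    hits: list[MotifHit],
    module_transcripts: list[str],
    go_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Assemble the TF -> cis-motif -> GO-term edge list of one module.

    Edges: TF->motif from the motif/TF-family map; motif->GO when some module
    transcript carrying the motif in its promoter also carries the enriched
    term. Motifs with no TF mapping are kept as orphan nodes (edge rows with
    an empty TF). Rows are sorted deterministically.
    """
    module_set = set(module_transcripts)
    motif_names = (
        list(enriched_motifs.loc[enriched_motifs["enriched"], "item"])
        if len(enriched_motifs)
        else []
    )
    go_terms = (
        list(enriched_go.loc[enriched_go["enriched"], "item"]) if len(enriched_go) else []
    )
    carriers: dict[str, set[str]] = {m: set() for m in motif_names}
    for h in hits:
        if h.motif in carriers and h.transcript_id in module_set:
            carriers[h.motif].add(h.transcript_id)
    rows = []
    for motif in motif_names:
        tf = motif_tf_map.get(motif, "")
        rows.append(
            {
                "module": module_id,
                "source": tf,
                "source_type": "TF" if tf else "",
                "target": motif,
                "target_type": "motif",
                "edge": "TF-motif" if tf else "orphan-motif",
            }
        )
        for term in go_terms:
            if any(term in go_map.get(t, set()) for t in carriers[motif]):
                rows.append(
                    {
                        "module": module_id,
                        "source": motif,
                        "source_type": "motif",
                        "target": term,
                        "target_type": "GO",
                        "edge": "motif-GO",
                    }
                )
    df = pd.DataFrame(
        rows, columns=["module", "source", "source_type", "target", "target_type", "edge"]
    )
    return df.sort_values(["edge", "source", "target"], kind="stable").reset_index(
        drop=True
    )


def trn_to_sif(edges: pd.DataFrame, path: str) -> None:
    """Write a TRN edge list as a SIF file (source, interaction, target)."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            if row["source"]:
                fh.write(f"{row['source']}\t{row['edge']}\t{row['target']}\n")
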