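"""QTL / variant / motif candidate-gene screening.

Joins transcripts to trait-associated QTL intervals (full containment;
partial overlaps flagged separately), applies a tissue-specificity or
differential-expression filter, intersects variants with transcript bodies
and promoters, overlaps variants with promoter motif hits, and emits a
deterministic candidate report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    ExpressionAtlas,
    GenomeAnnotation,
    MotifHit,
    Promoter,
    QTLInterval,
    ValidationError,
    Variant,
)

__all__ = [
    "transcripts_in_qtls",
    "differential_expression",
    "variants_in_features",
    "variant_motif_overlap",
    "candidate_report",
]


def transcripts_in_qtls(
    annotation: GenomeAnnotation, qtls: list[QTLInterval]
) -> pd.DataFrame:
    """Map QTL intervals to the transcripts they contain.

    A transcript belongs to a QTL iff its genomic span is fully contained in
    the interval; partial overlaps are recorded with relation="partial".
    Returns columns qtl, trait, chromosome, transcript, relation.
    """
    rows = []
    for q in qtls:
        for t in annotation.overlapping(q.chromosome, q.start, q.end):
            contained = q.start <= t.start and t.end <= q.end
            rows.append(
                {
                    "qtl": q.name,
                    "trait": q.trait,
                    "chromosome": q.chromosome,
                    "transcript": t.id,
                    "relation": "contained" if contained else "partial",
                }
            )
    return pd.DataFrame(
        rows, columns=["qtl", "trait", "chromosome", "transcript", "relation"]
    )


def differential_expression(
    atlas_a: ExpressionAtlas,
    atlas_b: ExpressionAtlas,
    contrast: str = "A/B",
    log2fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript differential expression between two condition atlases.

    log2FC = log2((mean_A + 1) / (mean_B + 1)) on FPKM; P from a two-sided
    Welch t-test on log2(FPKM+1) replicate values. Degenerate cases: both
    groups zero-variance with unequal means -> p = 0; equal constants ->
    p = 1; a single replicate in either group -> p undefined (NaN), never
    significant. A transcript is significant iff |log2FC| >=
    ``log2fc_threshold`` and p <= ``p_threshold``.
    """
    common = [t for t in atlas_a.transcript_ids if t in set(atlas_b.transcript_ids)]
    if not common:
        raise ValidationError("no shared transcripts between conditions")
    a = atlas_a.matrix.loc[common].to_numpy(dtype=float)
    b = atlas_b.matrix.loc[common].to_numpy(dtype=float)
    log2fc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    p = np.full(len(common), np.nan)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        va, vb = la.var(axis=1, ddof=1), lb.var(axis=1, ddof=1)
        degenerate = (va == 0) & (vb == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
        p = np.where(
            degenerate, np.where(la.mean(axis=1) != lb.mean(axis=1), 0.0, 1.0), p
        )
    significant = (
        (np.abs(log2fc) >= log2fc_threshold) & np.nan_to_num(p <= p_threshold, nan=False)
    )
    significant &= ~np.isnan(p)
    return pd.DataFrame(
        {
            "contrast": contrast,
            "log2fc": log2fc,
            "p": p,
            "significant": significant,
        },
        index=pd.Index(common, name="transcript"),
    )


def variants_in_features(
    variants: list[Variant],
    annotation: GenomeAnnotation,
    promoters: list[Promoter],
) -> pd.DataFrame:
    """Point membership of each variant position in transcript bodies and
    promoter intervals. One row per (variant, transcript, feature); a variant
    may annotate several transcripts.
    """
    rows = []
    for vi, v in enumerate(variants):
        for t in annotation.overlapping(v.chromosome, v.position, v.position + 1):
            rows.append(
                {
                    "variant": vi,
                    "chromosome": v.chromosome,
                    "position": v.position,
                    "kind": v.kind,
                    "transcript": t.id,
                    "feature": "body",
                }
            )
        for prom in promoters:
            if (
                prom.chromosome == v.chromosome
                and prom.start <= v.position < prom.end
            ):
                rows.append(
                    {
                        "variant": vi,
                        "chromosome": v.chromosome,
                        "position": v.position,
                        "kind": v.kind,
                        "transcript": prom.transcript_id,
                        "feature": "promoter",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["variant", "chromosome", "position", "kind", "transcript", "feature"],
    )


def variant_motif_overlap(
    variants: list[Variant], motif_hits: list[MotifHit]
) -> pd.DataFrame:
    """Variants whose reference-allele span intersects a motif hit interval.

    Any-base intersection: an InDel overlaps when any base of its ref span
    falls inside the hit's half-open genomic interval.
    """
    rows = []
    for vi, v in enumerate(variants):
        vs, ve = v.ref_span
        for h in motif_hits:
            if h.chromosome == v.chromosome and vs < h.end and h.start < ve:
                rows.append(
                    {
                        "variant": vi,
                        "chromosome": v.chromosome,
                        "position": v.position,
                        "kind": v.kind,
                        "motif": h.motif,
                        "transcript": h.transcript_id,
                        "hit_start": h.start,
                        "hit_end": h.end,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "variant",
            "chromosome",
            "position",
            "kind",
            "motif",
            "transcript",
            "hit_start",
            "hit_end",
        ],
    )


def candidate_report(
    qtl_map: pd.DataFrame,
    annotation: GenomeAnnotation,
    mode: str,
    specificity: pd.DataFrame | None = None,
    de_results: pd.DataFrame | None = None,
    variant_features: pd.DataFrame | None = None,
    variant_motifs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Joined candidate-gene report.

    mode="tissue-specific": QTL-contained transcripts with is_specific.
    mode="stress": QTL-contained transcripts significant in >= 1 contrast AND
    harboring >= 1 variant in the body or promoter.

    Evidence columns (peak tissue/tau, contrasts/log2FC/p, variant counts,
    variant-in-motif records) are attached; rows are sorted by chromosome
    then position.
    """
    if mode not in ("tissue-specific", "stress"):
        raise ValidationError(f"unknown mode {mode!r}")
    contained = qtl_map[qtl_map["relation"] == "contained"]
    vf = variant_features if variant_features is not None else pd.DataFrame()
    vm = variant_motifs if variant_motifs is not None else pd.DataFrame()

    rows = []
    for tid, group in contained.groupby("transcript", sort=False):
        t = annotation[tid]
        if mode == "tissue-specific":
            if specificity is None or tid not in specificity.index:
                raise ValidationError(f"no specificity result for {tid!r}")
            spec = specificity.loc[tid]
            if not bool(spec["is_specific"]):
                continue
            evidence = {
                "peak_tissue": spec["peak_tissue"],
                "tau": float(spec["tau"]),
                "contrasts": "",
                "max_abs_log2fc": np.nan,
                "min_p": np.nan,
            }
        else:
            if de_results is None:
                raise ValidationError("stress mode needs DE results")
            de = de_results[
                (de_results.index == tid) & de_results["significant"]
            ]
            if de.empty:
                continue
            n_var = 0
            if len(vf):
                n_var = int((vf["transcript"] == tid).sum())
            if n_var == 0:
                continue
            evidence = {
                "peak_tissue": "",
                "tau": np.nan,
                "contrasts": ";".join(sorted(de["contrast"])),
                "max_abs_log2fc": float(de["log2fc"].abs().max()),
                "min_p": float(de["p"].min()),
            }
        body = promoter = 0
        motif_records = ""
        if len(vf):
            mine = vf[vf["transcript"] == tid]
            body = int((mine["feature"] == "body").sum())
            promoter = int((mine["feature"] == "promoter").sum())
        if len(vm):
            mine = vm[vm["transcript"] == tid]
            motif_records = ";".join(
                f"{r.chromosome}:{r.position}:{r.motif}" for r in mine.itertuples()
            )
        rows.append(
            {
                "transcript": tid,
                "chromosome": t.chromosome,
                "start": t.start,
                "end": t.end,
                "traits": ";".join(sorted(set(group["trait"]))),
                "qtls": ";".join(sorted(set(group["qtl"]))),
                **evidence,
                "variants_in_body": body,
                "variants_in_promoter": promoter,
                "variants_in_motifs": motif_records,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "transcript",
            "chromosome",
            "start",
            "end",
            "traits",
            "qtls",
            "peak_tissue",
            "tau",
            "contrasts",
            "max_abs_log2fc",
            "min_p",
            "variants_in_body",
            "variants_in_promoter",
            "variants_in_motifs",
        ],
    )
    return report.sort_values(["chromosome", "start", "transcript"], kind="stable").reset_index(drop=True)
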