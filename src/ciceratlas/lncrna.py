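"""Genomic-context analysis of lncRNAs and isoform splicing differences.

A lncRNA is positionally classified against the protein-coding gene (PCG)
models around it, with a fixed precedence:

1. ``exlncRNA``  - same-strand exon-exon overlap with a PCG;
2. ``natlncRNA`` - opposite-strand overlap with a PCG exon (natural antisense);
3. ``intlncRNA`` - span fully inside a single intron of a PCG (either strand);
4. ``lincRNA``   - none of the above (intergenic).

Target inference follows the atlas conventions: a PCG within 10 kb of the
lncRNA span (inclusive, strand-agnostic) is a *cis* target; a non-cis PCG
whose log2(mean FPKM + 1) tissue profile has absolute Pearson correlation
>= 0.97 with the lncRNA is a *trans* target.

Pairwise alternative-splicing typing distinguishes intron retention (IR),
exon skipping (ES), alternate acceptor (AA) and alternate donor (AD); donor
and acceptor are the intron 5' and 3' ends in transcription orientation, so
on the minus strand they map to the opposite genomic sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import GenomeAnnotation, TranscriptModel, ValidationError

__all__ = [
    "LncClass",
    "TargetPair",
    "classify_lncrna_position",
    "classify_all_lncrnas",
    "find_cis_targets",
    "find_trans_targets",
    "transfer_go_terms",
    "classify_as_events",
]

CLASS_ORDER = ["lincRNA", "natlncRNA", "exlncRNA", "intlncRNA"]


@dataclass
class LncClass:
    lncrna_id: str
    label: str  # one of CLASS_ORDER
    supporting_pcg: str | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValidationError(f"unknown lncRNA class {self.label!r}")
        if (self.label != "lincRNA") != (self.supporting_pcg is not None):
            raise ValidationError(
                "supporting PCG must be present iff the class is not lincRNA"
            )


@dataclass
class TargetPair:
    lncrna_id: str
    pcg_id: str
    mode: str  # "cis" or "trans"
    evidence: float  # genomic gap in bp (cis) or Pearson r (trans)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_lncrna_position(
    lnc: TranscriptModel, annotation: GenomeAnnotation
) -> LncClass:
    """Positional class of one lncRNA with respect to the annotated PCGs."""
    if lnc.biotype != "lncRNA":
        raise ValidationError(f"{lnc.id!r} is not a lncRNA")
    candidates = [
        t
        for t in annotation.overlapping(lnc.chromosome, lnc.start, lnc.end)
        if t.biotype == "PCG"
    ]

    def best(pcgs_overlaps: list[tuple[TranscriptModel, int]]) -> str:
        pcgs_overlaps.sort(key=lambda p: (-p[1], p[0].id))
        return pcgs_overlaps[0][0].id

    ex_hits, nat_hits, int_hits = [], [], []
    for pcg in candidates:
        exon_ov = sum(
            _overlap(le, pe) for le in lnc.exons for pe in pcg.exons
        )
        if exon_ov > 0:
            (ex_hits if pcg.strand == lnc.strand else nat_hits).append((pcg, exon_ov))
            continue
        for intron in pcg.introns:
            if intron[0] <= lnc.start and lnc.end <= intron[1]:
                int_hits.append((pcg, _overlap(lnc.span, intron)))
                break
    if ex_hits:
        return LncClass(lnc.id, "exlncRNA", best(ex_hits))
    if nat_hits:
        return LncClass(lnc.id, "natlncRNA", best(nat_hits))
    if int_hits:
        return LncClass(lnc.id, "intlncRNA", best(int_hits))
    return LncClass(lnc.id, "lincRNA", None)


def classify_all_lncrnas(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Class of every annotated lncRNA, plus class counts in the canonical
    lincRNA / natlncRNA / exlncRNA / intlncRNA reporting order."""
    rows = []
    for lnc in annotation.lncrnas:
        c = classify_lncrna_position(lnc, annotation)
        rows.append(
            {"lncrna_id": c.lncrna_id, "label": c.label, "supporting_pcg": c.supporting_pcg}
        )
    df = pd.DataFrame(rows, columns=["lncrna_id", "label", "supporting_pcg"])
    df.attrs["class_counts"] = {c: int((df["label"] == c).sum()) for c in CLASS_ORDER}
    return df


def span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two half-open intervals (0 when they overlap)."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def find_cis_targets(
    lnc: TranscriptModel, annotation: GenomeAnnotation, window: int = 10_000
) -> list[TargetPair]:
    """PCGs whose span lies within ``window`` bp of the lncRNA span.

    Inclusive boundary, strand-agnostic; overlap counts as gap 0.
    """
    out = []
    for pcg in annotation.nearby(lnc.chromosome, lnc.start, lnc.end, window):
        if pcg.biotype != "PCG":
            continue
        gap = span_gap(lnc.span, pcg.span)
        if gap <= window:
            out.append(TargetPair(lnc.id, pcg.id, "cis", float(gap)))
    out.sort(key=lambda p: (p.evidence, p.pcg_id))
    return out


def find_trans_targets(
    lnc_profile: pd.Series,
    pcg_profiles: pd.DataFrame,
    r_threshold: float = 0.97,
    exclude: set[str] | None = None,
) -> list[TargetPair]:
    """PCGs whose tissue profile correlates with the lncRNA at |r| >= threshold.

    Correlation is Pearson on log2(mean FPKM + 1) across tissue means.
    ``exclude`` removes cis partners from the trans list. Constant profiles
    have undefined r and are skipped.
    """
    exclude = exclude or set()
    x = np.log2(np.asarray(lnc_profile, dtype=float) + 1.0)
    if x.std() == 0:
        return []
    mat = np.log2(pcg_profiles.to_numpy(dtype=float) + 1.0)
    sds = mat.std(axis=1)
    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ xc) / (np.sqrt((mc**2).sum(axis=1)) * np.sqrt((xc**2).sum()))
    out = []
    lnc_id = lnc_profile.name if lnc_profile.name is not None else "lncRNA"
    for pcg_id, ri, sd in zip(pcg_profiles.index, r, sds):
        if pcg_id in exclude or sd == 0 or not np.isfinite(ri):
            continue
        if abs(ri) >= r_threshold:
            out.append(TargetPair(str(lnc_id), str(pcg_id), "trans", float(ri)))
    out.sort(key=lambda p: (-abs(p.evidence), p.pcg_id))
    return out


def transfer_go_terms(
    targets: list[TargetPair], go_map: dict[str, set[str]]
) -> dict[str, str]:
    """GO terms inherited by a lncRNA from its cis/trans PCG targets.

    Returns term -> provenance ("cis", "trans" or "both").
    """
    out: dict[str, str] = {}
    for pair in targets:
        for term in sorted(go_map.get(pair.pcg_id, set())):
            prev = out.get(term)
            if prev is None:
                out[term] = pair.mode
            elif prev != pair.mode and prev != "both":
                out[term] = "both"
    return out


def _intron_sites(intron: tuple[int, int], strand: str) -> tuple[int, int]:
    """(donor, acceptor) genomic coordinates of an intron, strand-aware.

    Donor = intron 5' end, acceptor = intron 3' end in transcription
    orientation.
    """
    if strand == "+":
        return intron[0], intron[1]
    return intron[1], intron[0]


def classify_as_events(a: TranscriptModel, b: TranscriptModel) -> set[str]:
    """Alternative-splicing event types distinguishing two isoforms.

    Returns a subset of {"IR", "ES", "AA", "AD"}; symmetric in its pair.
    """
    if a.chromosome != b.chromosome or a.strand != b.strand:
        raise ValidationError("AS typing needs same-chromosome, same-strand isoforms")
    events: set[str] = set()
    for first, second in ((a, b), (b, a)):
        # IR: an intron of one isoform fully inside an exon of the other
        for intron in first.introns:
            for exon in second.exons:
                if exon[0] <= intron[0] and intron[1] <= exon[1]:
                    events.add("IR")
        # ES: an internal exon of one falls fully within an intron of the other
        for exon in first.exons[1:-1]:
            for intron in second.introns:
                if intron[0] <= exon[0] and exon[1] <= intron[1]:
                    events.add("ES")
        # AA/AD: overlapping introns with a shifted splice site. A boundary
        # shift explained by a fully skipped internal exon lying between the
        # two alternative sites is exon skipping, not an alternate site.
        internal_exons = [e for t in (first, second) for e in t.exons[1:-1]]

        def explained_by_skip(site_x: int, site_y: int) -> bool:
            lo, hi = sorted((site_x, site_y))
            return any(lo <= e[0] and e[1] <= hi for e in internal_exons)

        for ia in first.introns:
            for ib in second.introns:
                if _overlap(ia, ib) == 0 or ia == ib:
                    continue
                donor_a, acceptor_a = _intron_sites(ia, first.strand)
                donor_b, acceptor_b = _intron_sites(ib, second.strand)
                if acceptor_a != acceptor_b and not explained_by_skip(
                    acceptor_a, acceptor_b
                ):
                    events.add("AA")
                if donor_a != donor_b and not explained_by_skip(donor_a, donor_b):
                    events.add("AD")
    return events
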