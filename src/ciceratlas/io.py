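"""Readers and writers for every on-disk format the pipeline touches.

One convention everywhere: internal coordinates are 0-based half-open.
GFF3/GTF (1-based inclusive) and the VCF-like variant table (1-based POS)
are converted on read and back on write; BED passes through unchanged.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .models import (
    ExpressionAtlas,
    GenomeAnnotation,
    Motif,
    QTLInterval,
    TranscriptModel,
    ValidationError,
    Variant,
)

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_expression",
    "write_expression",
    "read_variants",
    "write_variants",
    "read_qtls",
    "write_qtls",
    "read_motifs",
    "write_motifs",
    "read_genome",
    "write_genome",
    "read_go_map",
    "write_go_map",
]


# ---------------------------------------------------------------------------
# annotation


def read_annotation(
    path: str | Path,
    chrom_lengths: dict[str, int] | str | Path,
    biotype_key: str = "biotype",
    tf_family_key: str = "tf_family",
) -> GenomeAnnotation:
    """Read a GFF3/GTF file into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    path
        GFF3 or GTF file with ``transcript`` and ``exon`` features.
    chrom_lengths
        Either a mapping chromosome -> length, or the path to a FASTA index
        (``.fai``) / two-column TSV.
    biotype_key, tf_family_key
        Attribute keys carrying the transcript biotype (PCG / lncRNA) and the
        optional TF-family tag. The keys are configurable because annotation
        dialects differ.
    """
    if not isinstance(chrom_lengths, dict):
        tbl = pd.read_csv(chrom_lengths, sep="\t", header=None)
        chrom_lengths = dict(zip(tbl[0].astype(str), tbl[1].astype(int)))

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    transcripts: list[TranscriptModel] = []
    for feat in db.features_of_type(("transcript", "mRNA")):
        if feat.strand not in ("+", "-"):
            raise ValidationError(
                f"unstranded transcript at {feat.seqid}:{feat.start}-{feat.end}"
                f" (strand {feat.strand!r})"
            )
        exons = []
        for ex in db.children(feat, featuretype="exon"):
            # GFF 1-based inclusive -> 0-based half-open
            exons.append((ex.start - 1, ex.end))
        if not exons:
            exons = [(feat.start - 1, feat.end)]
        biotype = feat.attributes.get(biotype_key, ["PCG"])[0]
        tf_family = feat.attributes.get(tf_family_key, [None])[0]
        go_raw = feat.attributes.get("go_terms", [])
        go_terms = set(",".join(go_raw).split(",")) - {""}
        transcripts.append(
            TranscriptModel(
                id=feat.id,
                chromosome=feat.seqid,
                strand=feat.strand,
                exons=exons,
                biotype=biotype,
                tf_family=tf_family,
                go_terms=go_terms,
            )
        )
    transcripts.sort(key=lambda t: (t.chromosome, t.start, t.end, t.id))
    return GenomeAnnotation(transcripts, chrom_lengths)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write a GFF3 file (1-based inclusive) that :func:`read_annotation` round-trips."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(
            annotation.transcripts, key=lambda t: (t.chromosome, t.start, t.end, t.id)
        ):
            attrs = [f"ID={t.id}", f"biotype={t.biotype}"]
            if t.tf_family:
                attrs.append(f"tf_family={t.tf_family}")
            if t.go_terms:
                attrs.append("go_terms=" + ",".join(sorted(t.go_terms)))
            fh.write(
                "\t".join(
                    [
                        t.chromosome,
                        "ciceratlas",
                        "transcript",
                        str(t.start + 1),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(t.exons, 1):
                fh.write(
                    "\t".join(
                        [
                            t.chromosome,
                            "ciceratlas",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            t.strand,
                            ".",
                            f"ID={t.id}.exon{i};Parent={t.id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# expression


def read_expression(matrix_path: str | Path, sample_sheet_path: str | Path) -> ExpressionAtlas:
    """Read a transcripts x samples FPKM TSV plus a sample sheet.

    The sample sheet maps sample name -> (tissue, replicate index); every
    column of the matrix header must appear in it.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    if "tissue" not in sheet.columns or "replicate" not in sheet.columns:
        raise ValidationError("sample sheet needs 'tissue' and 'replicate' columns")
    return ExpressionAtlas(matrix, sheet)


def write_expression(atlas: ExpressionAtlas, matrix_path: str | Path, sample_sheet_path: str | Path) -> None:
    atlas.matrix.to_csv(matrix_path, sep="\t", index_label="transcript_id")
    atlas.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# variants


def read_variants(path: str | Path) -> list[Variant]:
    """Read a VCF-like TSV (CHROM, POS 1-based, REF, ALT, optional INFO)."""
    tbl = pd.read_csv(path, sep="\t", header=0, dtype=str)
    cols = {c.lstrip("#"): c for c in tbl.columns}
    for needed in ("CHROM", "POS", "REF", "ALT"):
        if needed not in cols:
            raise ValidationError(f"variant table missing column {needed!r}")
    out = []
    for _, row in tbl.iterrows():
        contrast = ""
        if "INFO" in cols and isinstance(row[cols["INFO"]], str):
            for kv in row[cols["INFO"]].split(";"):
                if kv.startswith("contrast="):
                    contrast = kv.split("=", 1)[1]
        out.append(
            Variant(
                chromosome=row[cols["CHROM"]],
                position=int(row[cols["POS"]]) - 1,  # 1-based POS -> 0-based
                ref=row[cols["REF"]],
                alt=row[cols["ALT"]],
                contrast=contrast,
            )
        )
    return out


def write_variants(variants: list[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chromosome, v.position, v.ref, v.alt)):
            info = f"contrast={v.contrast}" if v.contrast else "."
            fh.write(f"{v.chromosome}\t{v.position + 1}\t{v.ref}\t{v.alt}\t{info}\n")


# ---------------------------------------------------------------------------
# QTLs


def read_qtls(path: str | Path) -> list[QTLInterval]:
    """Read a BED4 file (0-based half-open; trait label in column 4)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"line {lineno}: missing trait column")
            chrom, start, end, trait = fields[:4]
            source = fields[4] if len(fields) > 4 else ""
            out.append(
                QTLInterval(
                    trait=trait,
                    chromosome=chrom,
                    start=int(start),
                    end=int(end),
                    source=source,
                )
            )
    return out


def write_qtls(qtls: list[QTLInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in sorted(qtls, key=lambda q: (q.chromosome, q.start, q.end, q.trait)):
            fh.write(f"{q.chromosome}\t{q.start}\t{q.end}\t{q.trait}\t{q.source}\n")


# ---------------------------------------------------------------------------
# motifs (MEME-minimal)
#
# Bio.motifs also reads this dialect but silently renormalizes probability
# rows, which would hide rows that violate the sum-to-one invariant; the
# matrix block is therefore read directly so raw values can be validated.


def read_motifs(path: str | Path, tf_map_path: str | Path | None = None) -> list[Motif]:
    """Read a MEME-minimal motif file, optionally attaching TF families.

    Rows must sum to 1 within 1e-3 (they are renormalized); larger deviations
    and widths below 4 are rejected.
    """
    tf_map: dict[str, str] = {}
    if tf_map_path is not None:
        tbl = pd.read_csv(tf_map_path, sep="\t", header=None, names=["motif", "family"])
        tf_map = dict(zip(tbl["motif"], tbl["family"]))

    motifs: list[Motif] = []
    name: str | None = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush() -> None:
        nonlocal name, rows, in_matrix
        if name is not None:
            motifs.append(
                Motif(name=name, matrix=np.array(rows), tf_family=tf_map.get(name))
            )
        name, rows, in_matrix = None, [], False

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line and (line[0].isdigit() or line[0] == "."):
                rows.append([float(x) for x in line.split()])
            elif in_matrix and not line:
                in_matrix = False
    flush()
    return motifs


def write_motifs(motifs: list[Motif], path: str | Path, tf_map_path: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
    if tf_map_path is not None:
        with open(tf_map_path, "w") as fh:
            for m in motifs:
                if m.tf_family:
                    fh.write(f"{m.name}\t{m.tf_family}\n")


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an in-memory chromosome -> sequence mapping."""
    fa = Fasta(str(path), sequence_always_upper=True, build_index=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def write_genome(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    # refresh any stale pyfaidx index from a previous write
    fai = str(path) + ".fai"
    if os.path.exists(fai):
        os.remove(fai)


# ---------------------------------------------------------------------------
# GO map


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (transcript_id, comma-separated GO terms)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, terms = line.split("\t")[:2]
            out[tid] = set(terms.split(",")) - {""}
    return out


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(go_map):
            fh.write(f"{tid}\t{','.join(sorted(go_map[tid]))}\n")
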