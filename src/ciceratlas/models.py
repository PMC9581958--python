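"""Core domain types shared by every stage of the atlas pipeline.

All genomic coordinates are internally 0-based, half-open ``[start, end)``.
File formats that use other conventions (GFF3/GTF, the VCF-like variant
table) are converted on read by :mod:`ciceratlas.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "TranscriptModel",
    "GenomeAnnotation",
    "ExpressionAtlas",
    "Variant",
    "QTLInterval",
    "Motif",
    "Promoter",
    "MotifHit",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violated one of the documented invariants."""


@dataclass
class TranscriptModel:
    """A stranded exon-chain gene model.

    Parameters
    ----------
    id : str
        Unique transcript identifier.
    chromosome : str
    strand : {"+", "-"}
    exons : list of (int, int)
        Sorted, non-overlapping half-open intervals.
    biotype : {"PCG", "lncRNA"}
    tf_family : str, optional
        Transcription-factor family tag for TF-encoding PCGs.
    go_terms : set of str
        GO identifiers attached to the transcript.
    """

    id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "PCG"
    tf_family: str | None = None
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"unstranded transcript {self.id!r}: strand {self.strand!r}"
            )
        if self.biotype not in ("PCG", "lncRNA"):
            raise ValidationError(f"unknown biotype {self.biotype!r} for {self.id!r}")
        if not self.exons:
            raise ValidationError(f"transcript {self.id!r} has no exons")
        exons = sorted(tuple(e) for e in self.exons)
        for s, e in exons:
            if not s < e:
                raise ValidationError(f"empty exon [{s},{e}) in {self.id!r}")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValidationError(f"overlapping exons in {self.id!r}")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (first exon start, last exon end)."""
        return self.start, self.end

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, half-open."""
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        ]

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end


class GenomeAnnotation:
    """A set of transcript models with a per-chromosome interval index."""

    def __init__(
        self,
        transcripts: list[TranscriptModel],
        chrom_lengths: dict[str, int],
    ) -> None:
        self.chrom_lengths = dict(chrom_lengths)
        self.transcripts = list(transcripts)
        self._by_id: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_lengths}
        for t in self.transcripts:
            if t.id in self._by_id:
                raise ValidationError(f"duplicated transcript id {t.id!r}")
            if t.chromosome not in self.chrom_lengths:
                raise ValidationError(
                    f"transcript {t.id!r} on unknown chromosome {t.chromosome!r}"
                )
            clen = self.chrom_lengths[t.chromosome]
            if t.start < 0 or t.end > clen:
                raise ValidationError(
                    f"transcript {t.id!r} exon outside chromosome bounds "
                    f"[0,{clen}): span [{t.start},{t.end})"
                )
            self._by_id[t.id] = t
            self._trees[t.chromosome][t.start : t.end] = t.id

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    def overlapping(self, chromosome: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose span intersects ``[start, end)``."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        out = [self._by_id[iv.data] for iv in hits]
        out.sort(key=lambda t: (t.start, t.end, t.id))
        return out

    def nearby(self, chromosome: str, start: int, end: int, window: int) -> list[TranscriptModel]:
        """Transcripts whose span lies within ``window`` bp of ``[start, end)``.

        The query is widened by one base on each side so that features whose
        gap to the query equals ``window`` exactly (touching the half-open
        search bounds) are still returned.
        """
        return self.overlapping(chromosome, max(0, start - window - 1), end + window + 1)

    @property
    def pcgs(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == "PCG"]

    @property
    def lncrnas(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == "lncRNA"]


class ExpressionAtlas:
    """Transcript x sample FPKM matrix together with the tissue/replicate design.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Transcripts (rows) x samples (columns), non-negative finite FPKM.
    samples : pandas.DataFrame
        Indexed by sample name, with columns ``tissue`` and ``replicate``.
    """

    def __init__(self, matrix: pd.DataFrame, samples: pd.DataFrame) -> None:
        if matrix.index.duplicated().any():
            dup = matrix.index[matrix.index.duplicated()][0]
            raise ValidationError(f"duplicated transcript id {dup!r}")
        values = matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid FPKM {values[i, j]!r} at "
                f"(row {matrix.index[i]!r}, col {matrix.columns[j]!r})"
            )
        missing = [c for c in matrix.columns if c not in samples.index]
        if missing:
            raise ValidationError(f"samples missing from sample sheet: {missing}")
        self.matrix = matrix.astype(float)
        self.samples = samples.loc[list(matrix.columns)]
        if self.samples["tissue"].isna().any():
            raise ValidationError("sample sheet contains empty tissue labels")

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in sample-sheet (first appearance) order."""
        seen: dict[str, None] = {}
        for t in self.samples["tissue"]:
            seen.setdefault(t, None)
        return list(seen)

    def samples_for(self, tissue: str) -> list[str]:
        return list(self.samples.index[self.samples["tissue"] == tissue])

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class Variant:
    """A SNP or InDel, 0-based, distinguishing a genotype contrast."""

    chromosome: str
    position: int
    ref: str
    alt: str
    contrast: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValidationError("empty allele in variant")
        if self.ref == self.alt:
            raise ValidationError(
                f"variant at {self.chromosome}:{self.position} has REF == ALT"
            )

    @property
    def kind(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "InDel"

    @property
    def ref_span(self) -> tuple[int, int]:
        """Half-open genomic footprint of the reference allele."""
        return self.position, self.position + len(self.ref)


@dataclass
class QTLInterval:
    """A trait-associated genomic interval (0-based half-open)."""

    trait: str
    chromosome: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trait:
            raise ValidationError("QTL with empty trait label")
        if not self.start < self.end:
            raise ValidationError(
                f"QTL {self.trait!r} has start >= end ({self.start} >= {self.end})"
            )

    @property
    def name(self) -> str:
        return f"{self.trait}:{self.chromosome}:{self.start}-{self.end}"


_ALPHABET = "ACGT"


@dataclass
class Motif:
    """A position probability matrix over A, C, G, T."""

    name: str
    matrix: np.ndarray  # width x 4
    tf_family: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValidationError(f"motif {self.name!r}: matrix must be width x 4")
        if m.shape[0] < 4:
            raise ValidationError(f"motif {self.name!r}: width {m.shape[0]} < 4")
        sums = m.sum(axis=1)
        off = np.abs(sums - 1.0)
        if (off > 1e-3).any():
            row = int(np.argmax(off))
            raise ValidationError(
                f"motif {self.name!r}: row {row} sums to {sums[row]:.4f}"
            )
        self.matrix = m / sums[:, None]  # renormalize within tolerance

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class Promoter:
    """A promoter region: up to 2 kb upstream of a TSS, transcription-oriented."""

    transcript_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    sequence: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValidationError(
                f"promoter of {self.transcript_id!r}: sequence/interval length mismatch"
            )


@dataclass
class MotifHit:
    """One motif occurrence inside a promoter."""

    motif: str
    transcript_id: str
    offset: int  # promoter-relative, transcription orientation
    orientation: str  # "+" forward on the promoter, "-" reverse complement
    score: float
    chromosome: str
    start: int  # genomic, half-open
    end: int
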