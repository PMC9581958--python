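"""Synthetic chickpea-like atlas generator with machine-readable ground truth.

Everything downstream of the sequencers is emulated: a random-base genome
with planted protein-coding gene models and positionally classified lncRNAs,
a 32-tissue FPKM atlas with planted coexpression modules and tissue-specific
transcripts, promoters carrying planted motif instances, variant sets inside
and outside those motifs, trait QTL intervals containing chosen candidates,
and a two-condition stress experiment with planted differential expression.

Every output is a pure function of the :class:`AtlasSpec` (including its
seed): the same spec generates byte-identical files. The planted effect
sizes default to comfortably recoverable values so that each analysis stage,
run at its default settings, recovers the planted truth; the generator is a
study-conditions definition, not a tuning surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as ca_io
from .models import (
    ExpressionAtlas,
    GenomeAnnotation,
    Motif,
    Promoter,
    QTLInterval,
    TranscriptModel,
    ValidationError,
    Variant,
)
from .regnet import extract_promoters, reverse_complement

__all__ = [
    "AtlasSpec",
    "GroundTruth",
    "SyntheticAtlas",
    "generate_genome_annotation",
    "generate_expression",
    "plant_regulatory_elements",
    "generate_qtls",
    "generate_stress_experiment",
    "generate_atlas",
    "write_atlas",
]

#: The 32 tissues/organs of the atlas design (vegetative, flower, seed).
TISSUES_32 = (
    "GS", "S", "ML", "YL", "Brac", "R", "Rtip", "RH", "Nod", "SAM",
    "FB1", "FB2", "FB3", "FB4", "FL1", "FL2", "FL3", "FL4", "FL5",
    "Cal", "Cor", "And", "Gyn", "Pedi", "Emb", "Endo", "SdCt", "PodSh",
    "5DAP", "10DAP", "20DAP", "30DAP",
)

_TF_FAMILIES = ("MYB", "WRKY", "bZIP", "NAC", "AP2-EREBP", "bHLH", "HB", "C2H2")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class AtlasSpec:
    """Full parameterization of the synthetic atlas.

    The defaults define the study conditions: 32 tissues in 3 replicates
    (2 for 20DAP and 30DAP, 94 samples), ~2000 transcripts, five planted
    coexpression modules of 40-80 members over ~200 high-variance background
    transcripts, 5 tissue-specific transcripts per tissue, four lncRNA
    positional classes, and planted motif/variant/QTL evidence.
    """

    seed: int = 1
    chromosomes: tuple[str, ...] = ("Ca1", "Ca2", "Ca3", "Ca4")
    chrom_length: int = 4_000_000
    tissues: tuple[str, ...] = TISSUES_32
    replicates: int = 3
    two_replicate_tissues: tuple[str, ...] = ("20DAP", "30DAP")
    # annotation plan
    n_pcg: int = 1950
    n_lnc: dict[str, int] = field(
        default_factory=lambda: {"linc": 20, "nat": 10, "ex": 10, "int": 10}
    )
    n_cis_lincs: int = 6  # lincRNAs planted 0.2-1 kb from a PCG (cis pairs)
    n_trans_pairs: int = 8  # desert lincRNAs with a correlated distant PCG
    gene_gap: tuple[int, int] = (2_500, 6_000)
    desert_zone: int = 200_000  # per-chromosome tail reserved for deserts
    tf_fraction: float = 0.08
    # expression plan
    module_sizes: tuple[int, ...] = (40, 50, 60, 70, 80)
    n_background: int = 200
    n_specific_per_tissue: int = 5
    eigen_profile_sd: float = 2.0
    loading_range: tuple[float, float] = (0.8, 1.2)
    module_base_range: tuple[float, float] = (2.0, 6.0)
    gene_noise_sd: float = 0.5
    background_sd: float = 1.5
    broad_sd: float = 0.5
    replicate_sd: float = 0.25
    specific_peak_fpkm: tuple[float, float] = (10.0, 100.0)
    specific_off_fpkm: float = 0.02
    trans_profile_sd: float = 1.5
    trans_noise_sd: float = 0.05
    # regulatory plan
    n_motifs: int = 8
    n_module_motifs: int = 5  # motifs 1..k planted in modules 1..k
    motif_width: int = 10
    motif_plant_fraction: float = 0.7
    promoter_length: int = 2_000
    # QTL / variant / stress plan
    n_qtl_specific: int = 6
    n_qtl_stress: int = 5
    n_decoy_qtls: int = 4
    n_control_qtls: int = 2  # contain only non-specific transcripts
    qtl_margin: tuple[int, int] = (5_000, 20_000)
    n_decoy_variants: int = 6
    stress_replicates: int = 3
    stress_log2_effect: float = 2.0
    stress_base_log2: float = 3.0
    stress_replicate_sd: float = 0.15
    # GO plan
    n_go_terms: int = 30
    go_terms_per_gene: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        reserved = (
            sum(self.module_sizes)
            + self.n_background
            + self.n_specific_per_tissue * len(self.tissues)
            + self.n_trans_pairs
        )
        if reserved > self.n_pcg:
            raise ValidationError(
                f"module/background/specific plan needs {reserved} PCGs, "
                f"only {self.n_pcg} requested"
            )
        if any(v < 0 for v in self.n_lnc.values()):
            raise ValidationError("negative lncRNA counts")
        if self.n_cis_lincs + self.n_trans_pairs > self.n_lnc.get("linc", 0):
            raise ValidationError("more cis/trans lincRNAs than lincRNAs")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one sub-stream of the spec's seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Machine-readable planted truth; every table refers to generator ids."""

    transcripts: pd.DataFrame = field(default_factory=pd.DataFrame)
    module_profiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    cis_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    trans_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    promoter_motifs: pd.DataFrame = field(default_factory=pd.DataFrame)
    variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    qtl_contained: pd.DataFrame = field(default_factory=pd.DataFrame)
    de_planted: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SyntheticAtlas:
    """Everything one spec generates, in memory."""

    spec: AtlasSpec
    genome: dict[str, str]
    annotation: GenomeAnnotation
    atlas: ExpressionAtlas
    motifs: list[Motif]
    variants: list[Variant]
    qtls: list[QTLInterval]
    go_map: dict[str, set[str]]
    stress: dict[str, tuple[ExpressionAtlas, ExpressionAtlas]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# genome + annotation


def _random_genome(spec: AtlasSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        c: _BASES[rng.integers(0, 4, size=spec.chrom_length)]
        for c in spec.chromosomes
    }


def _pcg_structure(
    rng: np.random.Generator, cursor: int, force_big_intron: bool
) -> list[tuple[int, int]]:
    n_ex = int(rng.integers(1, 9))
    if force_big_intron:
        n_ex = max(n_ex, 2)
    exon_lens = rng.integers(100, 301, size=n_ex)
    intron_lens = rng.integers(150, 501, size=max(n_ex - 1, 0))
    if force_big_intron and n_ex > 1:
        intron_lens[0] = int(rng.integers(1_200, 1_601))
    exons, pos = [], cursor
    for i in range(n_ex):
        exons.append((pos, pos + int(exon_lens[i])))
        pos = exons[-1][1] + (int(intron_lens[i]) if i < n_ex - 1 else 0)
    return exons


def generate_genome_annotation(
    spec: AtlasSpec,
) -> tuple[dict[str, str], GenomeAnnotation, GroundTruth]:
    """Random-base chromosomes with planted PCG and lncRNA gene models.

    lncRNAs are planted so that their positional class (as recovered by the
    classifier at default settings) equals the truth label; intergenic
    lincRNAs sit in per-chromosome deserts > 10 kb from any PCG unless they
    are designated cis pairs. Expression roles (module membership, planted
    tissue specificity, trans partners) are assigned here so downstream
    generators agree on them.
    """
    rng = spec.rng(1)
    genome = _random_genome(spec, rng)
    n_chrom = len(spec.chromosomes)
    per_chrom = [
        spec.n_pcg // n_chrom + (1 if i < spec.n_pcg % n_chrom else 0)
        for i in range(n_chrom)
    ]
    # distribute hosted lncRNA classes round-robin over chromosomes
    hosts_needed = {cls: spec.n_lnc.get(cls, 0) for cls in ("ex", "nat", "int")}
    host_plan: list[tuple[str, int]] = []  # (class, chromosome index)
    for cls in ("ex", "nat", "int"):
        for j in range(hosts_needed[cls]):
            host_plan.append((cls, j % n_chrom))

    transcripts: list[TranscriptModel] = []
    pcg_by_chrom: dict[int, list[TranscriptModel]] = {i: [] for i in range(n_chrom)}
    pcg_i = 0
    for ci, chrom in enumerate(spec.chromosomes):
        n_here = per_chrom[ci]
        host_classes = [cls for cls, cj in host_plan if cj == ci]
        host_ordinals = rng.choice(
            np.arange(1, max(n_here - 1, 2)), size=len(host_classes), replace=False
        )
        host_at = dict(zip(host_ordinals.tolist(), host_classes))
        cursor = 5_000
        limit = spec.chrom_length - spec.desert_zone - 50_000
        for k in range(n_here):
            cls = host_at.get(k)
            exons = _pcg_structure(rng, cursor, force_big_intron=(cls == "int"))
            if exons[-1][1] >= limit:
                raise ValidationError(
                    f"chromosome {chrom!r} too short for {n_here} gene models"
                )
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            t = TranscriptModel(
                id=f"TC{pcg_i:05d}",
                chromosome=chrom,
                strand=strand,
                exons=exons,
                biotype="PCG",
            )
            t._host_class = cls  # type: ignore[attr-defined]
            transcripts.append(t)
            pcg_by_chrom[ci].append(t)
            pcg_i += 1
            cursor = exons[-1][1] + int(rng.integers(*spec.gene_gap))

    # hosted lncRNAs (ex / nat / int)
    lnc_rows = []
    lnc_i = 0

    def add_lnc(chrom: str, strand: str, exons: list[tuple[int, int]], cls: str) -> str:
        nonlocal lnc_i
        lid = f"LNC{lnc_i:04d}"
        transcripts.append(
            TranscriptModel(
                id=lid, chromosome=chrom, strand=strand, exons=exons, biotype="lncRNA"
            )
        )
        lnc_rows.append({"id": lid, "lnc_class": cls})
        lnc_i += 1
        return lid

    for ci in range(n_chrom):
        for host in pcg_by_chrom[ci]:
            cls = getattr(host, "_host_class", None)
            if cls is None:
                continue
            e0 = host.exons[0]
            if cls == "ex":
                add_lnc(
                    host.chromosome,
                    host.strand,
                    [(e0[0] + 20, e0[1] + 180)],
                    "exlncRNA",
                )
            elif cls == "nat":
                add_lnc(
                    host.chromosome,
                    "-" if host.strand == "+" else "+",
                    [(e0[0] + 30, e0[1] + 150)],
                    "natlncRNA",
                )
            elif cls == "int":
                intron = host.introns[0]
                length = int(rng.integers(200, 401))
                start = intron[0] + 100
                if start + length > intron[1]:
                    raise ValidationError("intron too short for intronic lncRNA")
                add_lnc(
                    host.chromosome,
                    "+" if rng.integers(0, 2) == 0 else "-",
                    [(start, start + length)],
                    "intlncRNA",
                )

    # cis-paired lincRNAs: 0.2-1.0 kb downstream of a host PCG
    n_linc = spec.n_lnc.get("linc", 0)
    cis_hosts = []
    for j in range(spec.n_cis_lincs):
        ci = j % n_chrom
        candidates = pcg_by_chrom[ci][:-1]
        host = candidates[int(rng.integers(0, len(candidates)))]
        cis_hosts.append(host)
        off = int(rng.integers(200, 1_000))
        length = int(rng.integers(300, 601))
        add_lnc(host.chromosome, "+", [(host.end + off, host.end + off + length)], "lincRNA")

    # desert lincRNAs: > 10 kb from every PCG (trans pairs + plain)
    n_desert = n_linc - spec.n_cis_lincs
    desert_linc_ids = []
    for j in range(n_desert):
        ci = j % n_chrom
        chrom = spec.chromosomes[ci]
        slot = j // n_chrom
        start = spec.chrom_length - spec.desert_zone + 2_000 + slot * 12_000
        if start + 12_000 > spec.chrom_length - spec.desert_zone // 2:
            raise ValidationError("desert zone too small for requested lincRNAs")
        desert_linc_ids.append(
            add_lnc(chrom, "+", [(start, start + 400)], "lincRNA")
        )

    annotation = GenomeAnnotation(
        sorted(transcripts, key=lambda t: (t.chromosome, t.start, t.id)),
        {c: spec.chrom_length for c in spec.chromosomes},
    )

    # ---- expression roles over PCGs -------------------------------------
    pcg_ids = [t.id for t in annotation.pcgs]
    order = rng.permutation(len(pcg_ids))
    shuffled = [pcg_ids[i] for i in order]
    roles = {tid: "broad" for tid in pcg_ids}
    module_of = {tid: 0 for tid in [t.id for t in annotation.transcripts]}
    specific_tissue = {tid: "" for tid in module_of}
    pos = 0
    for m, size in enumerate(spec.module_sizes, 1):
        for tid in shuffled[pos : pos + size]:
            roles[tid] = "module"
            module_of[tid] = m
        pos += size
    for tid in shuffled[pos : pos + spec.n_background]:
        roles[tid] = "background"
    pos += spec.n_background
    for ti, tissue in enumerate(spec.tissues):
        for tid in shuffled[pos : pos + spec.n_specific_per_tissue]:
            roles[tid] = "specific"
            specific_tissue[tid] = tissue
        pos += spec.n_specific_per_tissue
    # trans partners: broad PCGs on a different chromosome than their lincRNA
    trans_lincs = desert_linc_ids[: spec.n_trans_pairs]
    trans_rows = []
    remaining = [tid for tid in shuffled[pos:] if roles[tid] == "broad"]
    for lid in trans_lincs:
        lchrom = annotation[lid].chromosome
        partner = next(
            tid for tid in remaining if annotation[tid].chromosome != lchrom
        )
        remaining.remove(partner)
        roles[partner] = "trans_partner"
        trans_rows.append({"lncrna_id": lid, "pcg_id": partner})

    # TF-family tags on a slice of the broad PCGs
    n_tf = int(round(spec.tf_fraction * len(pcg_ids)))
    tf_pool = [tid for tid in shuffled if roles[tid] in ("broad", "module")][:n_tf]
    for i, tid in enumerate(tf_pool):
        annotation[tid].tf_family = _TF_FAMILIES[i % len(_TF_FAMILIES)]

    rows = []
    for t in annotation.transcripts:
        if t.biotype == "PCG":
            role = roles[t.id]
            lnc_class = ""
        else:
            lnc_class = next(r["lnc_class"] for r in lnc_rows if r["id"] == t.id)
            role = "trans_linc" if t.id in trans_lincs else "lnc_broad"
        rows.append(
            {
                "id": t.id,
                "biotype": t.biotype,
                "role": role,
                "module": module_of[t.id],
                "specific_tissue": specific_tissue[t.id],
                "lnc_class": lnc_class,
            }
        )
    truth = GroundTruth(
        transcripts=pd.DataFrame(rows).set_index("id"),
        trans_pairs=pd.DataFrame(trans_rows, columns=["lncrna_id", "pcg_id"]),
    )

    # cis truth: brute-force span-gap scan (independent of the interval index)
    cis_rows = []
    pcgs = annotation.pcgs
    for lnc in annotation.lncrnas:
        for pcg in pcgs:
            if pcg.chromosome != lnc.chromosome:
                continue
            gap = max(0, max(lnc.start, pcg.start) - min(lnc.end, pcg.end))
            if gap <= 10_000:
                cis_rows.append(
                    {"lncrna_id": lnc.id, "pcg_id": pcg.id, "gap": gap}
                )
    truth.cis_pairs = pd.DataFrame(cis_rows, columns=["lncrna_id", "pcg_id", "gap"])

    genome_str = {c: genome[c].tobytes().decode() for c in genome}
    return genome_str, annotation, truth


# ---------------------------------------------------------------------------
# expression


def _sample_sheet(spec: AtlasSpec) -> pd.DataFrame:
    rows = []
    for tissue in spec.tissues:
        n = 2 if tissue in spec.two_replicate_tissues else spec.replicates
        for r in range(1, n + 1):
            rows.append({"sample": f"{tissue}_r{r}", "tissue": tissue, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def generate_expression(
    spec: AtlasSpec, annotation: GenomeAnnotation, truth: GroundTruth
) -> ExpressionAtlas:
    """FPKM atlas realizing the planted expression roles.

    Tissue-level log2 profiles are built per role (module members follow
    loading x eigen-profile + noise; tissue-specific transcripts are >= 5
    FPKM in their tissue and <= 0.1 elsewhere; background transcripts get
    uncorrelated noise), then exponentiated with log-normal replicate noise.
    """
    rng = spec.rng(2)
    tissues = list(spec.tissues)
    n_t = len(tissues)
    ids = [t.id for t in annotation.transcripts]
    info = truth.transcripts

    profiles = pd.DataFrame(
        rng.normal(0.0, spec.eigen_profile_sd, size=(len(spec.module_sizes), n_t)),
        index=np.arange(1, len(spec.module_sizes) + 1),
        columns=tissues,
    )
    truth.module_profiles = profiles

    shared: dict[str, np.ndarray] = {}
    for _, pair in truth.trans_pairs.iterrows():
        profile = 3.0 + rng.normal(0.0, spec.trans_profile_sd, size=n_t)
        shared[pair["lncrna_id"]] = profile
        shared[pair["pcg_id"]] = profile

    log_levels = np.zeros((len(ids), n_t))
    for i, tid in enumerate(ids):
        role = info.at[tid, "role"]
        if role == "module":
            m = int(info.at[tid, "module"])
            base = rng.uniform(*spec.module_base_range)
            loading = rng.uniform(*spec.loading_range)
            log_levels[i] = (
                base
                + loading * profiles.loc[m].to_numpy()
                + rng.normal(0.0, spec.gene_noise_sd, size=n_t)
            )
        elif role == "background":
            base = rng.uniform(1.0, 5.0)
            log_levels[i] = rng.normal(base, spec.background_sd, size=n_t)
        elif role == "specific":
            tissue = info.at[tid, "specific_tissue"]
            peak = rng.uniform(*spec.specific_peak_fpkm)
            row = np.full(n_t, np.log2(spec.specific_off_fpkm))
            row[tissues.index(tissue)] = np.log2(peak)
            log_levels[i] = row
        elif role in ("trans_partner", "trans_linc"):
            log_levels[i] = shared[tid] + rng.normal(
                0.0, spec.trans_noise_sd, size=n_t
            )
        else:  # broad PCGs and non-trans lncRNAs
            base = rng.uniform(1.0, 3.0)
            log_levels[i] = base + rng.normal(0.0, spec.broad_sd, size=n_t)

    sheet = _sample_sheet(spec)
    cols = {}
    for sample, row in sheet.iterrows():
        ti = tissues.index(row["tissue"])
        noise = rng.normal(0.0, spec.replicate_sd, size=len(ids))
        cols[sample] = np.exp2(log_levels[:, ti] + noise)
    matrix = pd.DataFrame(cols, index=ids)
    return ExpressionAtlas(matrix, sheet)


# ---------------------------------------------------------------------------
# motifs, planted promoter instances and variants


def _random_motifs(spec: AtlasSpec, rng: np.random.Generator) -> list[Motif]:
    motifs = []
    for j in range(1, spec.n_motifs + 1):
        consensus = rng.integers(0, 4, size=spec.motif_width)
        matrix = np.full((spec.motif_width, 4), 0.05)
        matrix[np.arange(spec.motif_width), consensus] = 0.85
        motifs.append(
            Motif(
                name=f"MOT{j}",
                matrix=matrix,
                tf_family=_TF_FAMILIES[(j - 1) % len(_TF_FAMILIES)],
            )
        )
    return motifs


def plant_motif(
    genome: dict[str, np.ndarray],
    promoter: Promoter,
    motif: Motif,
    offset: int,
    orientation: str,
    used: dict[str, list[tuple[int, int]]],
) -> tuple[int, int]:
    """Write a motif consensus into a promoter at a transcription-oriented
    offset; returns the genomic hit interval. Overlapping plants in the same
    promoter raise."""
    w = motif.width
    if offset < 0 or offset + w > promoter.end - promoter.start:
        raise ValidationError("motif does not fit in the promoter")
    intervals = used.setdefault(promoter.transcript_id, [])
    for s, e in intervals:
        if offset < e and s < offset + w:
            raise ValidationError(
                f"overlapping motif plants in promoter of {promoter.transcript_id!r}"
            )
    intervals.append((offset, offset + w))
    oriented = motif.consensus if orientation == "+" else reverse_complement(
        motif.consensus
    )
    if promoter.strand == "+":
        gstart = promoter.start + offset
        genomic = oriented
    else:
        gstart = promoter.end - offset - w
        genomic = reverse_complement(oriented)
    genome[promoter.chromosome][gstart : gstart + w] = np.frombuffer(
        genomic.encode(), dtype=np.uint8
    )
    return gstart, gstart + w


def _promoter_to_genomic(prom: Promoter, offset: int) -> int:
    """Genomic coordinate of one transcription-oriented promoter position."""
    if prom.strand == "+":
        return prom.start + offset
    return prom.end - 1 - offset


def plant_regulatory_elements(
    spec: AtlasSpec,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
) -> tuple[dict[str, str], list[Motif], list[Variant]]:
    """Plant motif instances into promoters and emit a variant set.

    Module-associated motifs MOT1..MOTk go into a fraction of the promoters
    of modules 1..k. Each QTL candidate additionally receives one planted
    motif with a SNP inside it, a promoter SNP away from every motif, and a
    body variant; decoy variants land in gene deserts. Returns the edited
    genome, the motif library, and the variants; planted instances and
    inside-motif flags are recorded in the truth tables.
    """
    rng = spec.rng(3)
    motifs = _random_motifs(spec, rng)
    arrays = {c: np.frombuffer(genome[c].encode(), dtype=np.uint8).copy() for c in genome}
    promoters = {
        p.transcript_id: p
        for p in extract_promoters(annotation, genome, spec.promoter_length)
    }
    used: dict[str, list[tuple[int, int]]] = {}
    planted_rows: list[dict] = []
    variant_rows: list[dict] = []
    variants: list[Variant] = []

    def plant(tid: str, motif: Motif) -> tuple[Promoter, int, str, tuple[int, int]]:
        prom = promoters[tid]
        for _ in range(50):
            offset = int(rng.integers(0, spec.promoter_length - motif.width))
            orientation = "+" if rng.integers(0, 2) == 0 else "-"
            try:
                interval = plant_motif(arrays, prom, motif, offset, orientation, used)
            except ValidationError:
                continue
            planted_rows.append(
                {
                    "transcript": tid,
                    "motif": motif.name,
                    "offset": offset,
                    "orientation": orientation,
                    "genome_start": interval[0],
                    "genome_end": interval[1],
                }
            )
            return prom, offset, orientation, interval
        raise ValidationError(f"could not place motif in promoter of {tid!r}")

    def add_variant(
        chrom: str,
        position: int,
        contrast: str,
        target: str,
        placement: str,
        inside_motif: bool,
        indel: bool = False,
    ) -> None:
        seq = arrays[chrom]
        if indel:
            ref = seq[position : position + 3].tobytes().decode()
            alt = ref[0]
        else:
            ref = chr(seq[position])
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        variants.append(Variant(chrom, position, ref, alt, contrast))
        variant_rows.append(
            {
                "chromosome": chrom,
                "position": position,
                "contrast": contrast,
                "target_transcript": target,
                "placement": placement,
                "inside_motif": inside_motif,
            }
        )

    info = truth.transcripts
    # module-motif associations
    for m in range(1, min(spec.n_module_motifs, len(spec.module_sizes)) + 1):
        members = list(info.index[(info["module"] == m)])
        n_plant = int(round(spec.motif_plant_fraction * len(members)))
        chosen = rng.choice(members, size=n_plant, replace=False)
        for tid in sorted(chosen):
            plant(tid, motifs[m - 1])

    # QTL candidates: tissue-specific (seed-size contrast) then stress
    specific_ids = list(info.index[info["role"] == "specific"])
    tissue_candidates = specific_ids[: spec.n_qtl_specific]
    broad_ids = list(info.index[info["role"] == "broad"])
    stress_candidates = broad_ids[: spec.n_qtl_stress]
    truth.transcripts["qtl_candidate"] = ""
    for i, tid in enumerate(tissue_candidates):
        truth.transcripts.loc[tid, "qtl_candidate"] = "tissue-specific"
        motif = motifs[(i % spec.n_module_motifs)]
        prom, offset, orientation, interval = plant(tid, motif)
        inside = int(rng.integers(2, motif.width - 2))
        add_variant(
            prom.chromosome,
            _promoter_to_genomic(prom, offset + inside),
            "seed-size",
            tid,
            "promoter_motif",
            True,
        )
        # promoter SNP well away from every planted motif
        for _ in range(100):
            off = int(rng.integers(0, spec.promoter_length))
            if all(
                off < s - 50 or off > e + 50 for s, e in used.get(tid, [])
            ):
                break
        add_variant(
            prom.chromosome,
            _promoter_to_genomic(prom, off),
            "seed-size",
            tid,
            "promoter",
            False,
        )
        t = annotation[tid]
        add_variant(
            t.chromosome, (t.start + t.end) // 2, "seed-size", tid, "body", False
        )

    stress_contrasts = ["drought", "drought", "drought", "salinity", "salinity"]
    for i, tid in enumerate(stress_candidates):
        truth.transcripts.loc[tid, "qtl_candidate"] = "stress"
        contrast = stress_contrasts[i % len(stress_contrasts)]
        motif = motifs[spec.n_module_motifs + (i % (spec.n_motifs - spec.n_module_motifs))]
        prom, offset, orientation, interval = plant(tid, motif)
        inside = int(rng.integers(2, motif.width - 2))
        add_variant(
            prom.chromosome,
            _promoter_to_genomic(prom, offset + inside),
            contrast,
            tid,
            "promoter_motif",
            True,
        )
        t = annotation[tid]
        add_variant(
            t.chromosome, (t.start + t.end) // 2, contrast, tid, "body", False, indel=True
        )

    # decoy variants in the desert tail (no features, no motifs)
    for j in range(spec.n_decoy_variants):
        chrom = spec.chromosomes[j % len(spec.chromosomes)]
        position = spec.chrom_length - spec.desert_zone // 4 + j * 1_000
        add_variant(chrom, position, "seed-size", "", "decoy", False)

    truth.promoter_motifs = pd.DataFrame(
        planted_rows,
        columns=["transcript", "motif", "offset", "orientation", "genome_start", "genome_end"],
    )
    truth.variants = pd.DataFrame(
        variant_rows,
        columns=[
            "chromosome",
            "position",
            "contrast",
            "target_transcript",
            "placement",
            "inside_motif",
        ],
    )
    edited = {c: arrays[c].tobytes().decode() for c in arrays}
    return edited, motifs, variants


# ---------------------------------------------------------------------------
# QTLs


def generate_qtls(
    spec: AtlasSpec, annotation: GenomeAnnotation, truth: GroundTruth
) -> list[QTLInterval]:
    """Trait QTL intervals fully containing their designated candidates,
    plus control QTLs around non-specific transcripts and decoy QTLs in gene
    deserts. Containment truth is recorded by a brute-force scan."""
    rng = spec.rng(4)
    info = truth.transcripts
    qtls: list[QTLInterval] = []
    # High-variance roles (clustered or shared-profile transcripts) can show
    # incidental high tissue specificity; planted QTLs are placed so they
    # never fully contain one, keeping the candidate truth unambiguous.
    avoid_roles = {"background", "module", "trans_partner", "trans_linc"}
    avoid_by_chrom: dict[str, list] = {c: [] for c in spec.chromosomes}
    for t in annotation.transcripts:
        if info.at[t.id, "role"] in avoid_roles:
            avoid_by_chrom[t.chromosome].append(t)

    def around(tid: str, trait: str) -> None:
        t = annotation[tid]
        lo = max(0, t.start - int(rng.integers(*spec.qtl_margin)))
        hi = min(spec.chrom_length, t.end + int(rng.integers(*spec.qtl_margin)))
        for other in avoid_by_chrom[t.chromosome]:
            if lo <= other.start < t.start:
                lo = other.start + 1
            if t.end < other.end <= hi:
                hi = min(hi, other.end - 1)
        if hi - lo < t.end - t.start:
            raise ValidationError(f"candidate {tid!r} longer than its QTL")
        qtls.append(QTLInterval(trait, t.chromosome, lo, hi, source="planted"))

    tissue_candidates = list(info.index[info["qtl_candidate"] == "tissue-specific"])
    for tid in tissue_candidates:
        around(tid, "100SDW")
    stress_candidates = list(info.index[info["qtl_candidate"] == "stress"])
    for tid in stress_candidates:
        contrast = truth.variants.loc[
            truth.variants["target_transcript"] == tid, "contrast"
        ].iloc[0]
        around(tid, contrast)
    # control QTLs: contain transcripts but no candidates
    controls = [
        tid
        for tid in info.index[(info["role"] == "broad") & (info["qtl_candidate"] == "")]
    ][: spec.n_control_qtls]
    for tid in controls:
        around(tid, "100SDW")
    # decoy QTLs in the feature-free desert tail
    for j in range(spec.n_decoy_qtls):
        chrom = spec.chromosomes[j % len(spec.chromosomes)]
        start = spec.chrom_length - spec.desert_zone // 2 + j * 10_000
        qtls.append(QTLInterval("100SDW", chrom, start, start + 8_000, source="decoy"))

    # brute-force containment truth
    rows = []
    for q in qtls:
        for t in annotation.transcripts:
            if (
                t.chromosome == q.chromosome
                and q.start <= t.start
                and t.end <= q.end
            ):
                rows.append({"qtl": q.name, "trait": q.trait, "transcript": t.id})
    truth.qtl_contained = pd.DataFrame(rows, columns=["qtl", "trait", "transcript"])
    return qtls


# ---------------------------------------------------------------------------
# stress experiment


def generate_stress_experiment(
    spec: AtlasSpec, annotation: GenomeAnnotation, truth: GroundTruth
) -> dict[str, tuple[ExpressionAtlas, ExpressionAtlas]]:
    """Two-condition (stress vs control) expression per stress contrast.

    Planted candidates gain ``stress_log2_effect`` under stress; everything
    else is flat. Returns contrast -> (stress atlas, control atlas).
    """
    rng = spec.rng(5)
    ids = [t.id for t in annotation.transcripts]
    info = truth.transcripts
    out = {}
    de_rows = []
    for contrast in ("drought", "salinity"):
        planted = [
            tid
            for tid in info.index[info["qtl_candidate"] == "stress"]
            if (truth.variants["target_transcript"] == tid).any()
            and truth.variants.loc[
                truth.variants["target_transcript"] == tid, "contrast"
            ].iloc[0]
            == contrast
        ]
        base = rng.normal(spec.stress_base_log2, 0.7, size=len(ids))
        effect = np.array([spec.stress_log2_effect if t in planted else 0.0 for t in ids])
        atlases = []
        for condition, shift in (("stress", effect), ("control", 0.0)):
            cols = {}
            for r in range(1, spec.stress_replicates + 1):
                noise = rng.normal(0.0, spec.stress_replicate_sd, size=len(ids))
                cols[f"{contrast}_{condition}_r{r}"] = np.exp2(base + shift + noise)
            sheet = pd.DataFrame(
                {
                    "tissue": [condition] * spec.stress_replicates,
                    "replicate": list(range(1, spec.stress_replicates + 1)),
                },
                index=list(cols),
            )
            atlases.append(ExpressionAtlas(pd.DataFrame(cols, index=ids), sheet))
        out[contrast] = (atlases[0], atlases[1])
        de_rows += [{"transcript": t, "contrast": contrast} for t in planted]
    truth.de_planted = pd.DataFrame(de_rows, columns=["transcript", "contrast"])
    return out


# ---------------------------------------------------------------------------
# orchestration


def generate_atlas(spec: AtlasSpec | None = None) -> SyntheticAtlas:
    """Run every generator stage and return the full in-memory bundle."""
    spec = spec or AtlasSpec()
    genome, annotation, truth = generate_genome_annotation(spec)
    atlas = generate_expression(spec, annotation, truth)
    genome, motifs, variants = plant_regulatory_elements(spec, genome, annotation, truth)
    qtls = generate_qtls(spec, annotation, truth)
    stress = generate_stress_experiment(spec, annotation, truth)
    go_map = _generate_go_map(spec, truth)
    return SyntheticAtlas(
        spec, genome, annotation, atlas, motifs, variants, qtls, go_map, stress, truth
    )


def _generate_go_map(spec: AtlasSpec, truth: GroundTruth) -> dict[str, set[str]]:
    """Random GO terms per PCG plus one module-characteristic term per module."""
    rng = spec.rng(6)
    pool = [f"GO:{i:07d}" for i in range(1, spec.n_go_terms + 1)]
    module_terms = {
        m: f"GO:{1_000_000 + m:07d}" for m in range(1, len(spec.module_sizes) + 1)
    }
    info = truth.transcripts
    out: dict[str, set[str]] = {}
    for tid in info.index:
        if info.at[tid, "biotype"] != "PCG":
            continue
        n = int(rng.integers(spec.go_terms_per_gene[0], spec.go_terms_per_gene[1] + 1))
        terms = set(rng.choice(pool, size=n, replace=False).tolist())
        m = int(info.at[tid, "module"])
        if m > 0 and rng.random() < 0.8:
            terms.add(module_terms[m])
        out[tid] = terms
    return out


def write_atlas(bundle: SyntheticAtlas, outdir: str) -> dict[str, str]:
    """Write the bundle in the exact formats the readers consume.

    Returns a name -> path map (genome FASTA, GFF3, expression TSV + sample
    sheet, MEME-minimal motifs + TF map, variants, QTL BED, GO map, truth
    tables, stress matrices).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "matrix": os.path.join(outdir, "expression.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "motifs": os.path.join(outdir, "motifs.meme"),
        "tf_map": os.path.join(outdir, "motif_tf_map.tsv"),
        "variants": os.path.join(outdir, "variants.tsv"),
        "qtls": os.path.join(outdir, "qtls.bed"),
        "go_map": os.path.join(outdir, "go_map.tsv"),
        "chrom_lengths": os.path.join(outdir, "chrom_lengths.tsv"),
    }
    ca_io.write_genome(bundle.genome, paths["genome"])
    ca_io.write_annotation(bundle.annotation, paths["annotation"])
    ca_io.write_expression(bundle.atlas, paths["matrix"], paths["samples"])
    ca_io.write_motifs(bundle.motifs, paths["motifs"], paths["tf_map"])
    ca_io.write_variants(bundle.variants, paths["variants"])
    ca_io.write_qtls(bundle.qtls, paths["qtls"])
    ca_io.write_go_map(bundle.go_map, paths["go_map"])
    with open(paths["chrom_lengths"], "w") as fh:
        for c, ln in bundle.annotation.chrom_lengths.items():
            fh.write(f"{c}\t{ln}\n")
    for name, table in (
        ("truth_transcripts", bundle.truth.transcripts.reset_index()),
        ("truth_cis_pairs", bundle.truth.cis_pairs),
        ("truth_trans_pairs", bundle.truth.trans_pairs),
        ("truth_promoter_motifs", bundle.truth.promoter_motifs),
        ("truth_variants", bundle.truth.variants),
        ("truth_qtl_contained", bundle.truth.qtl_contained),
        ("truth_de_planted", bundle.truth.de_planted),
    ):
        p = os.path.join(outdir, f"{name}.tsv")
        table.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
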