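import numpy as np
import pandas as pd
import pytest

from ciceratlas import lncrna
from ciceratlas.models import ValidationError
from conftest import make_annotation, make_transcript, random_small_annotation


def classify_oracle(lnc, annotation):
    """All-pairs interval logic written independently of the indexed
    implementation: exonic (same strand) > antisense (opposite strand) >
    intronic (span inside one intron) > intergenic."""

    def overlap(a, b):
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    ex_best, nat_best, int_best = None, None, None
    for pcg in annotation.transcripts:
        if pcg.biotype != "PCG" or pcg.chromosome != lnc.chromosome:
            continue
        ov = sum(overlap(le, pe) for le in lnc.exons for pe in pcg.exons)
        if ov > 0:
            bucket = "ex" if pcg.strand == lnc.strand else "nat"
            current = ex_best if bucket == "ex" else nat_best
            if current is None or (-ov, pcg.id) < current[0]:
                entry = ((-ov, pcg.id), pcg.id)
                if bucket == "ex":
                    ex_best = entry
                else:
                    nat_best = entry
        else:
            for intron in pcg.introns:
                if intron[0] <= lnc.start and lnc.end <= intron[1]:
                    ov_i = overlap(lnc.span, intron)
                    if int_best is None or (-ov_i, pcg.id) < int_best[0]:
                        int_best = ((-ov_i, pcg.id), pcg.id)
    if ex_best:
        return "exlncRNA", ex_best[1]
    if nat_best:
        return "natlncRNA", nat_best[1]
    if int_best:
        return "intlncRNA", int_best[1]
    return "lincRNA", None


def cis_oracle(lnc, annotation, window=10_000):
    out = set()
    for pcg in annotation.transcripts:
        if pcg.biotype != "PCG" or pcg.chromosome != lnc.chromosome:
            continue
        gap = max(0, max(lnc.start, pcg.start) - min(lnc.end, pcg.end))
        if gap <= window:
            out.add(pcg.id)
    return out


class TestPositionalClassification:
    def test_same_strand_exon_overlap_is_exonic(self):
        pcg = make_transcript("P", [(1000, 2000)], "+")
        lnc = make_transcript("L", [(1500, 2500)], "+", biotype="lncRNA")
        ann = make_annotation([pcg, lnc])
        c = lncrna.classify_lncrna_position(lnc, ann)
        assert (c.label, c.supporting_pcg) == ("exlncRNA", "P")

    def test_opposite_strand_exon_overlap_is_antisense(self):
        pcg = make_transcript("P", [(1000, 2000)], "+")
        lnc = make_transcript("L", [(1500, 2500)], "-", biotype="lncRNA")
        ann = make_annotation([pcg, lnc])
        assert lncrna.classify_lncrna_position(lnc, ann).label == "natlncRNA"

    def test_span_inside_intron_is_intronic(self):
        pcg = make_transcript("P", [(1000, 2000), (5000, 6000)], "+")
        lnc = make_transcript("L", [(3000, 3500)], "-", biotype="lncRNA")
        ann = make_annotation([pcg, lnc])
        assert lncrna.classify_lncrna_position(lnc, ann).label == "intlncRNA"

    def test_distant_lncrna_is_intergenic(self):
        pcg = make_transcript("P", [(1000, 2000)], "+")
        lnc = make_transcript("L", [(52_000, 53_000)], "+", biotype="lncRNA")
        ann = make_annotation([pcg, lnc])
        c = lncrna.classify_lncrna_position(lnc, ann)
        assert (c.label, c.supporting_pcg) == ("lincRNA", None)

    def test_non_lncrna_rejected(self):
        pcg = make_transcript("P", [(1000, 2000)], "+")
        ann = make_annotation([pcg])
        with pytest.raises(ValidationError):
            lncrna.classify_lncrna_position(pcg, ann)

    def test_matches_bruteforce_oracle_on_random_annotations(self):
        rng = np.random.default_rng(11)
        for _ in range(120):
            ann = random_small_annotation(rng)
            for lnc in ann.lncrnas:
                got = lncrna.classify_lncrna_position(lnc, ann)
                label, pcg = classify_oracle(lnc, ann)
                assert (got.label, got.supporting_pcg) == (label, pcg)

    def test_every_lncrna_gets_one_class_and_counts_reported(self, bundle):
        df = lncrna.classify_all_lncrnas(bundle.annotation)
        assert len(df) == len(bundle.annotation.lncrnas)
        counts = df.attrs["class_counts"]
        assert list(counts) == ["lincRNA", "natlncRNA", "exlncRNA", "intlncRNA"]
        assert sum(counts.values()) == len(df)


class TestCisTargets:
    @pytest.mark.parametrize(
        "pcg_start,expected_gap,is_target",
        [
            (58_000, 7_000, True),
            (61_000, 10_000, True),  # boundary inclusive: "within 10 kb"
            (61_001, 10_001, False),
            (50_500, 0, True),  # overlap => gap 0
        ],
    )
    def test_window_boundary(self, pcg_start, expected_gap, is_target):
        lnc = make_transcript("L", [(50_000, 51_000)], "+", biotype="lncRNA")
        pcg = make_transcript("P", [(pcg_start, pcg_start + 2_000)], "-")
        ann = make_annotation([lnc, pcg])
        targets = lncrna.find_cis_targets(lnc, ann)
        if is_target:
            assert [(t.pcg_id, t.evidence) for t in targets] == [("P", expected_gap)]
        else:
            assert targets == []

    def test_matches_oracle_on_random_annotations(self):
        rng = np.random.default_rng(12)
        for _ in range(120):
            ann = random_small_annotation(rng)
            for lnc in ann.lncrnas:
                got = {t.pcg_id for t in lncrna.find_cis_targets(lnc, ann)}
                assert got == cis_oracle(lnc, ann)


class TestTransTargets:
    def test_perfect_and_anti_correlation(self):
        lnc = pd.Series([1.0, 2, 3, 4], name="L")
        # anti is built so its log2(FPKM+1) profile is exactly K - log2(lnc+1),
        # i.e. Pearson r = -1 on the analysis scale
        anti = 2.0 ** (4.0 - np.log2(np.array([1.0, 2, 3, 4]) + 1)) - 1
        pcgs = pd.DataFrame(
            {
                "same": [1.0, 2, 3, 4],
                "anti": anti,
                "flat": [2.0, 2, 2, 2],
            }
        ).T
        got = {t.pcg_id: t.evidence for t in lncrna.find_trans_targets(lnc, pcgs)}
        assert got["same"] == pytest.approx(1.0)
        assert "anti" in got and got["anti"] < 0  # |r| >= threshold counts
        assert "flat" not in got  # constant profile skipped

    def test_threshold_uses_log_scale_r(self):
        lnc = pd.Series([1.0, 2, 3, 4], name="L")
        pcgs = pd.DataFrame({"p": [1.0, 2, 3, 10]}).T
        x = np.log2(np.array([1.0, 2, 3, 4]) + 1)
        y = np.log2(np.array([1.0, 2, 3, 10]) + 1)
        r = np.corrcoef(x, y)[0, 1]
        got = lncrna.find_trans_targets(lnc, pcgs)
        assert (len(got) == 1) == (abs(r) >= 0.97)

    def test_cis_partners_excluded(self):
        lnc = pd.Series([1.0, 2, 3, 4], name="L")
        pcgs = pd.DataFrame({"p": [1.0, 2, 3, 4]}).T
        assert lncrna.find_trans_targets(lnc, pcgs, exclude={"p"}) == []

    def test_planted_pairs_recovered_exactly(self, bundle, profiles):
        truth = bundle.truth
        cis = truth.cis_pairs.groupby("lncrna_id")["pcg_id"].apply(set).to_dict()
        trans = truth.trans_pairs.groupby("lncrna_id")["pcg_id"].apply(set).to_dict()
        pcg_prof = profiles.loc[[t.id for t in bundle.annotation.pcgs]]
        for lnc in bundle.annotation.lncrnas:
            got_cis = {t.pcg_id for t in lncrna.find_cis_targets(lnc, bundle.annotation)}
            assert got_cis == cis.get(lnc.id, set())
            got_trans = {
                t.pcg_id
                for t in lncrna.find_trans_targets(
                    profiles.loc[lnc.id], pcg_prof, exclude=got_cis
                )
            }
            assert got_trans == trans.get(lnc.id, set())


class TestGoTransfer:
    def test_union_with_provenance(self):
        targets = [
            lncrna.TargetPair("L", "P1", "cis", 0.0),
            lncrna.TargetPair("L", "P2", "trans", 0.99),
            lncrna.TargetPair("L", "P3", "trans", 0.98),
        ]
        go_map = {
            "P1": {"GO:0006355", "GO:0001666"},
            "P2": {"GO:0009737", "GO:0001666"},
            "P3": set(),
        }
        got = lncrna.transfer_go_terms(targets, go_map)
        assert got == {
            "GO:0006355": "cis",
            "GO:0009737": "trans",
            "GO:0001666": "both",
        }

    def test_no_targets_empty(self):
        assert lncrna.transfer_go_terms([], {"P": {"GO:1"}}) == {}


class TestASEvents:
    A = [(0, 100), (200, 300), (400, 500)]

    def test_exon_skipping(self):
        a = make_transcript("a", self.A, "+")
        b = make_transcript("b", [(0, 100), (400, 500)], "+")
        assert lncrna.classify_as_events(a, b) == {"ES"}

    def test_intron_retention(self):
        a = make_transcript("a", self.A, "+")
        b = make_transcript("b", [(0, 300), (400, 500)], "+")
        assert lncrna.classify_as_events(a, b) == {"IR"}

    def test_alternate_acceptor_plus_strand(self):
        a = make_transcript("a", [(0, 100), (200, 300)], "+")
        b = make_transcript("b", [(0, 100), (230, 300)], "+")
        assert lncrna.classify_as_events(a, b) == {"AA"}

    def test_same_shift_is_donor_on_minus_strand(self):
        a = make_transcript("a", [(0, 100), (200, 300)], "-")
        b = make_transcript("b", [(0, 100), (230, 300)], "-")
        assert lncrna.classify_as_events(a, b) == {"AD"}

    def test_alternate_donor_plus_strand(self):
        a = make_transcript("a", [(0, 100), (200, 300)], "+")
        b = make_transcript("b", [(0, 80), (200, 300)], "+")
        assert lncrna.classify_as_events(a, b) == {"AD"}

    def test_symmetry_on_random_isoform_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            exons = []
            pos = 0
            for _ in range(int(rng.integers(2, 6))):
                pos += int(rng.integers(0, 50))
                end = pos + int(rng.integers(20, 120))
                exons.append((pos, end))
                pos = end + int(rng.integers(30, 200))
            # isoform b drops internal exons and may shift one splice site
            keep = rng.random(len(exons)) > 0.3
            keep[0] = keep[-1] = True
            b_exons = [e for e, k in zip(exons, keep) if k]
            if len(b_exons) > 1 and rng.random() < 0.5:
                i = int(rng.integers(1, len(b_exons)))
                s, e = b_exons[i]
                shift = int(rng.integers(1, 15))
                if s + shift < e:
                    b_exons[i] = (s + shift, e)
            strand = "+" if rng.integers(0, 2) else "-"
            a = make_transcript("a", exons, strand)
            b = make_transcript("b", b_exons, strand)
            assert lncrna.classify_as_events(a, b) == lncrna.classify_as_events(b, a)

    def test_different_strand_rejected(self):
        a = make_transcript("a", self.A, "+")
        b = make_transcript("b", self.A, "-")
        with pytest.raises(ValidationError):
            lncrna.classify_as_events(a, b)
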