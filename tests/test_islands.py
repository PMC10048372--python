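"""ROH islands: incidence, thresholded island calling, gene annotation and
the shared-haplotype audit."""

import numpy as np
import pandas as pd
import pytest

from rohkit import (
    MISSING,
    GenotypeMatrix,
    ROHSegment,
    annotate_islands,
    call_islands,
    haplotype_audit,
    read_gene_intervals,
    snv_incidence,
)
from rohkit.islands import IslandRegion


def _matrix(n_samples, pos, chrom="1", calls=None):
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
                          "filter": "PASS", "vtype": "SNV"})
    if calls is None:
        calls = np.zeros((n_samples, len(pos)), dtype=np.int8)
    return GenotypeMatrix([f"S{i}" for i in range(n_samples)], sites, calls)


def incidence_oracle(segments, m):
    """O(sites x segments) interval stabbing, written independently."""
    out = np.zeros(m.n_sites)
    for j in range(m.n_sites):
        chrom = m.sites.loc[j, "chrom"]
        pos = m.sites.loc[j, "pos"]
        covered = {s.sample for s in segments
                   if s.chrom == chrom and s.start <= pos <= s.end}
        out[j] = len(covered) / m.n_samples
    return out


class TestSnvIncidence:
    def test_thirty_of_thirty_three(self):
        pos = 1000 + 100 * np.arange(10)
        m = _matrix(33, pos)
        segs = [ROHSegment(f"S{i}", "1", 1000, 1400, 10) for i in range(30)]
        track = snv_incidence(segs, m)
        assert track.loc[0, "incidence"] == pytest.approx(30 / 33)
        assert track.loc[9, "incidence"] == 0.0

    def test_matches_stabbing_oracle(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(100_000, size=50, replace=False)) + 1
        m = _matrix(7, pos)
        segs = []
        for i in range(7):
            cursor = 1
            for _ in range(rng.integers(1, 5)):
                start = cursor + int(rng.integers(0, 20_000))
                end = start + int(rng.integers(1000, 30_000))
                segs.append(ROHSegment(f"S{i}", "1", start, end, 10))
                cursor = end + 2
        track = snv_incidence(segs, m)
        np.testing.assert_allclose(track["incidence"], incidence_oracle(segs, m))

    def test_equals_boolean_coverage_matrix(self, sim_default, roh_default):
        """Incidence from segments equals incidence recomputed from an
        independently constructed per-sample boolean coverage matrix."""
        m = sim_default.matrix
        track = snv_incidence(roh_default, m)
        cover = np.zeros((m.n_samples, m.n_sites), dtype=bool)
        chrom_arr = m.sites["chrom"].to_numpy()
        pos_arr = m.sites["pos"].to_numpy()
        for s in roh_default:
            si = m.sample_index(s.sample)
            hit = (chrom_arr == s.chrom) & (pos_arr >= s.start) & (pos_arr <= s.end)
            cover[si] |= hit
        np.testing.assert_allclose(track["incidence"], cover.mean(axis=0))


def _track(incidences, pos=None, chrom="1"):
    return pd.DataFrame({
        "chrom": chrom,
        "pos": pos if pos is not None else 1000 + 100 * np.arange(len(incidences)),
        "incidence": incidences})


class TestCallIslands:
    def test_uniform_track_single_island(self):
        regions = call_islands(_track([0.95] * 20))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end, regions[0].n_snvs) \
            == (1000, 2900, 20)

    def test_single_snv_island_no_minimum_size(self):
        regions = call_islands(_track([0.5, 0.91, 0.5]))
        assert len(regions) == 1
        assert regions[0].n_snvs == 1 and regions[0].start == regions[0].end

    def test_rule_triggers_at_exactly_30_of_33(self):
        track = _track([29 / 33, 30 / 33, 30 / 33, 29 / 33])
        regions = call_islands(track, threshold=0.90)
        assert len(regions) == 1
        assert regions[0].n_snvs == 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        track = _track(rng.random(500))
        previous = None
        for thr in (0.5, 0.7, 0.9, 0.95):
            total_snvs = sum(r.n_snvs for r in call_islands(track, thr))
            if previous is not None:
                assert total_snvs <= previous
            previous = total_snvs

    def test_membership_is_exact(self):
        rng = np.random.default_rng(9)
        inc = rng.random(300)
        track = _track(inc)
        regions = call_islands(track, 0.9)
        member = np.zeros(300, dtype=bool)
        pos = track["pos"].to_numpy()
        for r in regions:
            member |= (pos >= r.start) & (pos <= r.end)
        np.testing.assert_array_equal(member, inc >= 0.9)


GFF_BODY = """##gff-version 3
2\tRefSeq\tgene\t71840000\t71850000\t.\t+\t.\tID=gene1;Name=SMPDL3B
2\tRefSeq\tgene\t71852000\t71870000\t.\t-\t.\tID=gene2;Name=RPA2
2\tRefSeq\tgene\t71871000\t71880000\t.\t+\t.\tID=gene3;Name=THEMIS2
2\tRefSeq\tgene\t71881000\t71890000\t.\t+\t.\tID=gene4;Name=LOC119870383
2\tRefSeq\tgene\t71891000\t71900000\t.\t-\t.\tID=gene5;Name=PPP1R8
2\tRefSeq\tgene\t71901000\t71946000\t.\t+\t.\tID=gene6;Name=LOC119870569
2\tRefSeq\tgene\t80000000\t80010000\t.\t+\t.\tID=gene7;Name=FARAWAY
2\tRefSeq\texon\t71840000\t71841000\t.\t+\t.\tID=exon1
"""


class TestAnnotateIslands:
    @pytest.fixture()
    def gff(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GFF_BODY)
        return str(path)

    def test_six_genes_in_region(self, gff):
        ann = read_gene_intervals(gff)
        region = IslandRegion("2", 71_838_359, 71_946_097, 500, 1.0)
        annotate_islands([region], ann)
        assert region.genes == ["LOC119870383", "LOC119870569", "PPP1R8",
                                "RPA2", "SMPDL3B", "THEMIS2"]

    def test_no_overlap_and_shared_gene(self, gff):
        ann = read_gene_intervals(gff)
        empty = IslandRegion("2", 1_000, 2_000, 5, 1.0)
        # gene6 spans 71.901-71.946 Mb: overlaps both of these islands
        left = IslandRegion("2", 71_900_500, 71_910_000, 50, 0.95)
        right = IslandRegion("2", 71_940_000, 71_950_000, 50, 0.95)
        annotate_islands([empty, left, right], ann)
        assert empty.genes == []
        assert "LOC119870569" in left.genes and "LOC119870569" in right.genes

    def test_one_bp_overlap_counts(self, gff):
        ann = read_gene_intervals(gff)
        region = IslandRegion("2", 71_850_000, 71_850_000, 1, 0.92)
        annotate_islands([region], ann)
        assert region.genes == ["SMPDL3B"]

    def test_chrom_mismatch_warns(self, gff):
        ann = read_gene_intervals(gff)
        region = IslandRegion("chrUn", 100, 200, 2, 0.91)
        with pytest.warns(UserWarning, match="chrUn"):
            annotate_islands([region], ann)
        assert region.genes == []

    def test_bed_annotation(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("1\t999\t2000\tGENEA\n1\t5000\t6000\tGENEB\n")
        ann = read_gene_intervals(str(path))
        assert ann.loc[0, "start"] == 1000  # BED 0-based start converted
        region = IslandRegion("1", 1500, 1600, 3, 0.95)
        annotate_islands([region], ann)
        assert region.genes == ["GENEA"]


class TestHaplotypeAudit:
    def test_identical_shared_haplotype(self):
        pos = 1000 + 100 * np.arange(40)
        calls = np.full((33, 40), 2, dtype=np.int8)
        calls[5, 7] = MISSING  # missing never breaks identity
        m = _matrix(33, pos, calls=calls)
        region = IslandRegion("1", 1000, 4900, 40, 1.0)
        verdict, breaks = haplotype_audit(region, m)
        assert verdict == "identical" and breaks == []

    def test_two_het_stretches_in_five_samples(self):
        """Five of 33 samples heterozygous across two internal stretches:
        two het-break subregions, each affecting five samples."""
        pos = 1000 + 100 * np.arange(60)
        calls = np.full((33, 60), 2, dtype=np.int8)
        for s in range(5):
            calls[s, 10:16] = 1
            calls[s, 40:44] = 1
        m = _matrix(33, pos, calls=calls)
        region = IslandRegion("1", 1000, 6900, 60, 1.0)
        verdict, breaks = haplotype_audit(region, m)
        assert verdict == "not-identical"
        assert len(breaks) == 2
        assert [(b.start, b.end, b.n_samples) for b in breaks] == \
            [(2000, 2500, 5), (5000, 5300, 5)]

    def test_single_discordant_homozygote(self):
        pos = 1000 + 100 * np.arange(10)
        calls = np.full((4, 10), 2, dtype=np.int8)
        calls[2, 4] = 0  # hom-ref where the rest are hom-alt
        m = _matrix(4, pos, calls=calls)
        region = IslandRegion("1", 1000, 1900, 10, 1.0)
        verdict, breaks = haplotype_audit(region, m)
        assert verdict == "not-identical" and breaks == []

    def test_min_het_run_length(self):
        pos = 1000 + 100 * np.arange(10)
        calls = np.full((4, 10), 2, dtype=np.int8)
        calls[0, 3] = 1  # isolated het, below the default run length of 2
        m = _matrix(4, pos, calls=calls)
        region = IslandRegion("1", 1000, 1900, 10, 1.0)
        _, breaks = haplotype_audit(region, m, min_het_run=2)
        assert breaks == []
        _, breaks = haplotype_audit(region, m, min_het_run=1)
        assert [(b.start, b.end, b.n_samples) for b in breaks] == [(1300, 1300, 1)]
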