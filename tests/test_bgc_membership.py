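"""BGC region parsing, containment membership and cluster-type tallies."""

import pytest

from cypcensus.bgc_membership import (
    BGCRegion,
    GeneLocus,
    bgc_summary,
    p450s_in_bgcs,
    parse_bgc_table,
    parse_gene_table,
    read_genbank_regions,
    tally_cluster_types,
    write_bgc_table,
    write_gene_table,
    write_membership_tsv,
)

BGC_TSV = """\
species	region_id	cluster_type	contig	start	end	most_similar_known_cluster	similarity
Celeribacter indicus	r1	Ectoine	c1	1000	42000	Ectoine, other	100%
Bradyrhizobium sp. S23321	r2	hserlactone, t2pks	c1	90000	130000	Colabomycin	4
Agrobacterium fabrum	r3	terpene	c2	500	21000	-	-
"""


def test_parse_bgc_table(tmp_path):
    p = tmp_path / "bgcs.tsv"
    p.write_text(BGC_TSV)
    regions = parse_bgc_table(p)
    assert len(regions) == 3
    assert regions[0].similarity == 100.0
    assert regions[0].most_similar_known_cluster == "Ectoine, other"
    assert regions[1].cluster_types == ("hserlactone", "t2pks")
    assert regions[1].similarity == 4.0
    assert regions[2].similarity is None


def test_unknown_columns_warned_and_ignored(tmp_path):
    p = tmp_path / "bgcs.tsv"
    p.write_text("region_id\tcluster_type\tcontig\tstart\tend\tmystery\n"
                 "r1\tterpene\tc1\t1\t100\tx\n")
    with pytest.warns(UserWarning, match="mystery"):
        regions = parse_bgc_table(p)
    assert len(regions) == 1


def test_reversed_coordinates_rejected(tmp_path):
    p = tmp_path / "bgcs.tsv"
    p.write_text("region_id\tcluster_type\tcontig\tstart\tend\n"
                 "r1\tterpene\tc1\t500\t100\n")
    with pytest.raises(ValueError, match="start"):
        parse_bgc_table(p)


def test_bgc_table_round_trip(tmp_path):
    p = tmp_path / "in.tsv"
    p.write_text(BGC_TSV)
    regions = parse_bgc_table(p)
    q = tmp_path / "out.tsv"
    write_bgc_table(regions, q)
    assert parse_bgc_table(q) == regions


class TestMembership:
    REGION = BGCRegion(species="S", region_id="r1", cluster_types=("terpene",),
                       contig="c1", start=1, end=50_000)

    def _gene(self, start, end, contig="c1", is_p450=True, gid="g1"):
        return GeneLocus(gene_id=gid, contig=contig, start=start, end=end,
                         is_p450=is_p450, cyp_name="CYP901A1" if is_p450 else None)

    def test_contained_gene_is_member(self):
        assert len(p450s_in_bgcs([self._gene(100, 1300)], [self.REGION])) == 1

    def test_straddling_gene_is_not_member(self):
        assert p450s_in_bgcs([self._gene(49_000, 51_000)], [self.REGION]) == []

    def test_other_contig_is_not_member(self):
        assert p450s_in_bgcs([self._gene(100, 1300, contig="c2")], [self.REGION]) == []

    def test_non_p450_gene_ignored(self):
        assert p450s_in_bgcs([self._gene(100, 1300, is_p450=False)], [self.REGION]) == []

    def test_membership_monotone_in_region_extent(self):
        """Enlarging a region never removes members."""
        genes = [self._gene(100, 1300, gid="g1"),
                 self._gene(49_500, 50_600, gid="g2")]
        small = self.REGION
        large = BGCRegion(species="S", region_id="r1", cluster_types=("terpene",),
                          contig="c1", start=1, end=60_000)
        members_small = {m.gene.gene_id for m in p450s_in_bgcs(genes, [small])}
        members_large = {m.gene.gene_id for m in p450s_in_bgcs(genes, [large])}
        assert members_small <= members_large
        assert members_large == {"g1", "g2"}


def test_tally_cluster_types():
    def region(rid, types):
        return BGCRegion(species="S", region_id=rid, cluster_types=types,
                         contig="c", start=1, end=10)
    tallies = tally_cluster_types([
        region("r1", ("terpene",)), region("r2", ("terpene",)),
        region("r3", ("NRPS",)),
    ])
    assert tallies == {"terpene": 2, "NRPS": 1}
    assert tally_cluster_types([]) == {}


def test_hybrid_regions_count_once_per_label():
    """Sum of per-type counts equals the sum of label multiplicities."""
    regions = [
        BGCRegion(species="S", region_id=f"r{i}", cluster_types=types,
                  contig="c", start=1, end=10)
        for i, types in enumerate([
            ("hserlactone", "t2pks"), ("NRPS", "T1PKS"), ("terpene",),
        ])
    ]
    tallies = tally_cluster_types(regions)
    assert sum(tallies.values()) == sum(len(r.cluster_types) for r in regions)


def test_dominant_type_tally_mirrors_published_scale(tmp_path):
    """A fixture with 270 terpene rows tallies 270 (the published count)."""
    rows = ["region_id\tcluster_type\tcontig\tstart\tend"]
    rows += [f"t{i}\tterpene\tc1\t{i * 100 + 1}\t{i * 100 + 50}" for i in range(270)]
    rows += [f"h{i}\thserlactone\tc1\t{100_000 + i * 100}\t{100_000 + i * 100 + 50}"
             for i in range(180)]
    p = tmp_path / "big.tsv"
    p.write_text("\n".join(rows) + "\n")
    tallies = tally_cluster_types(parse_bgc_table(p))
    assert tallies["terpene"] == 270
    assert tallies["hserlactone"] == 180
    assert list(tallies)[0] == "terpene"  # dominant type first


class TestSummary:
    def test_published_percentage(self):
        from cypcensus.bgc_membership import Membership
        mems = [
            Membership(
                gene=GeneLocus(gene_id=f"g{i}", contig="c1", start=100, end=1300,
                               is_p450=True, cyp_name="CYP206A1"),
                region=BGCRegion(species=f"sp{i}", region_id=f"r{i}",
                                 cluster_types=("terpene",), contig="c1",
                                 start=1, end=50_000),
            )
            for i in range(21)
        ]
        s = bgc_summary(mems, n_p450s_total=874)
        assert s.n_member_p450s == 21
        assert s.percentage_of_p450s == pytest.approx(2.40, abs=0.005)

    def test_one_species_three_members(self):
        """One species contributing three member P450s is counted once."""
        from cypcensus.bgc_membership import Membership
        mems = [
            Membership(
                gene=GeneLocus(gene_id=g, contig="c1", start=s, end=s + 1200,
                               is_p450=True, cyp_name=cyp),
                region=BGCRegion(species="Sulfitobacter synthetica", region_id=r,
                                 cluster_types=(t,), contig="c1",
                                 start=s - 50, end=s + 2000),
            )
            for g, s, cyp, r, t in [
                ("g1", 100, "CYP901A1", "r1", "acyl_amino_acids"),
                ("g2", 5000, "CYP902A1", "r2", "bacteriocin"),
                ("g3", 9000, "CYP903A1", "r3", "NRPS-like"),
            ]
        ]
        s = bgc_summary(mems, n_p450s_total=10)
        assert s.n_member_p450s == 3
        assert s.n_contributing_species == 1
        assert s.per_family_counts == {"901": 1, "902": 1, "903": 1}

    def test_zero_members(self):
        s = bgc_summary([], n_p450s_total=100)
        assert s.n_member_p450s == 0
        assert s.percentage_of_p450s == 0.0


def test_membership_tsv(tmp_path):
    from cypcensus.bgc_membership import Membership
    m = Membership(
        gene=GeneLocus(gene_id="g1", contig="c1", start=100, end=1300,
                       is_p450=True, cyp_name="CYP1101A27"),
        region=BGCRegion(species="Celeribacter indicus", region_id="r1",
                         cluster_types=("Ectoine",), contig="c1", start=1,
                         end=50_000, most_similar_known_cluster="Ectoine, other",
                         similarity=100.0),
    )
    out = tmp_path / "members.tsv"
    write_membership_tsv([m], out)
    lines = out.read_text().splitlines()
    assert lines[1].split("\t") == [
        "Celeribacter indicus", "CYP1101A27", "g1", "r1", "Ectoine",
        "Ectoine, other", "100%",
    ]


def test_gene_table_round_trip(tmp_path):
    genes = [
        GeneLocus(gene_id="g1", contig="c1", start=100, end=1300, strand="+",
                  is_p450=True, cyp_name="CYP901A1"),
        GeneLocus(gene_id="g2", contig="c1", start=2000, end=2900, strand="-"),
    ]
    p = tmp_path / "genes.tsv"
    write_gene_table(genes, p)
    assert parse_gene_table(p) == genes


GENBANK_REGION = """\
LOCUS       c1                     60000 bp    DNA     linear   BCT 01-JAN-2021
FEATURES             Location/Qualifiers
     region          1000..42000
                     /product="ectoine"
     region          50000..59000
                     /product="terpene"
                     /product="NRPS"
ORIGIN
//
"""


def test_read_genbank_regions(tmp_path):
    p = tmp_path / "regions.gbk"
    p.write_text(GENBANK_REGION)
    regions = read_genbank_regions(p, species="Synthetica exempli")
    assert len(regions) == 2
    assert regions[0].start == 1000 and regions[0].end == 42000
    assert regions[0].cluster_types == ("ectoine",)
    assert regions[1].cluster_types == ("terpene", "NRPS")
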