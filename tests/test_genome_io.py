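"""Format readers/writers: coordinate conventions, round-trips, error
contracts for the FASTA/GFF3/BED bundle and both genotype-table dialects."""

import numpy as np
import pytest

from popsel.annotate import SiteClass, classify_sites
from popsel.genome import (Feature, GenomeBundle, load_genome_bundle,
                           write_genome_bundle)
from popsel.simulate import simulate_genome
from popsel.variants import (VariantTable, load_variant_table,
                             read_variant_table, write_variant_table)
from popsel.variants import write_vcf


def test_gff3_coordinates_become_half_open(tmp_path):
    """A GFF3 line with start=11, end=13 maps to internal (10, 13)."""
    (tmp_path / "g.fa").write_text(">chr1\n" + "ACGT" * 10 + "\n")
    (tmp_path / "g.gff3").write_text(
        "##gff-version 3\n"
        "chr1\tx\tgene\t11\t13\t.\t+\t.\tID=g1\n")
    bundle = load_genome_bundle(tmp_path / "g.fa", tmp_path / "g.gff3")
    f = bundle.features[0]
    assert (f.start, f.end) == (10, 13)


def test_bed_already_half_open(tmp_path):
    (tmp_path / "g.fa").write_text(">chr1\n" + "A" * 40 + "\n")
    (tmp_path / "g.gff3").write_text("##gff-version 3\n")
    (tmp_path / "c.bed").write_text("chr1\t10\t13\tintergenic_cns\n")
    bundle = load_genome_bundle(tmp_path / "g.fa", tmp_path / "g.gff3",
                                tmp_path / "c.bed")
    iv = bundle.cns_intervals[0]
    assert (iv.start, iv.end) == (10, 13)


def test_malformed_gff3_line_names_line_number(tmp_path):
    (tmp_path / "g.fa").write_text(">chr1\n" + "A" * 40 + "\n")
    (tmp_path / "g.gff3").write_text("##gff-version 3\n"
                                     "chr1\tx\tgene\t11\n")
    with pytest.raises(ValueError, match=":2"):
        load_genome_bundle(tmp_path / "g.fa", tmp_path / "g.gff3")


def test_feature_past_contig_end_rejected(tmp_path):
    (tmp_path / "g.fa").write_text(">chr1\n" + "A" * 40 + "\n")
    (tmp_path / "g.gff3").write_text(
        "##gff-version 3\nchr1\tx\tCDS\t30\t99\t.\t+\t0\tParent=g1\n")
    with pytest.raises(ValueError, match="outside contig"):
        load_genome_bundle(tmp_path / "g.fa", tmp_path / "g.gff3")


def test_two_gene_bundle_round_trip(tmp_path, two_gene_config):
    """The generator's annotation survives write + reload, and a CDS base
    queries back as coding."""
    rng = np.random.default_rng(5)
    bundle = simulate_genome(two_gene_config, rng)
    genes = bundle.gene_ids
    assert len(genes) == 2
    write_genome_bundle(bundle, tmp_path / "g.fa", tmp_path / "g.gff3",
                        tmp_path / "c.bed")
    loaded = load_genome_bundle(tmp_path / "g.fa", tmp_path / "g.gff3",
                                tmp_path / "c.bed")
    assert loaded.sequences == bundle.sequences
    assert sorted(loaded.features) == sorted(bundle.features)
    assert sorted(loaded.cns_intervals) == sorted(bundle.cns_intervals)
    assert len(loaded.features_of(genes[0], "CDS")) >= 2
    cm = classify_sites(loaded)
    cds0 = loaded.features_of(genes[0], "CDS")[0]
    cls = cm.class_of(cds0.contig, cds0.start)
    assert cls in (SiteClass.zero_fold, SiteClass.four_fold,
                   SiteClass.other_coding_excluded)


def _tiny_table() -> VariantTable:
    rng = np.random.default_rng(0)
    t = VariantTable.allocate(["s01", "s02", "s03"],
                              {"chr1": np.arange(50, dtype=np.int64)})
    d = t.arrays("chr1")
    d["qual"][:] = 120.0
    d["dp"][:] = 34
    d["ref"][:] = rng.integers(0, 4, 50)
    # one polymorphic site with full PL data, one with a missing PL
    d["gt"][7] = [1, 0, 2]
    d["alt"][7] = (d["ref"][7] + 1) % 4
    d["n_alts"][7] = 1
    d["pl_best"][7] = [0, 0, 0]
    d["pl_second"][7] = [55, 42, 61]
    d["gt"][9] = [0, 1, 0]
    d["alt"][9] = (d["ref"][9] + 2) % 4
    d["n_alts"][9] = 1
    d["pl_best"][9] = [0, 0, -1]       # missing PL for sample 3
    d["pl_second"][9] = [44, 48, -1]
    d["dels"][3] = 0.25
    return t


def test_tsv_and_vcf_dialects_parse_identically(tmp_path):
    table = _tiny_table()
    write_variant_table(table, tmp_path / "v.tsv")
    write_vcf(table, str(tmp_path / "v.vcf"))
    recs_tsv = list(load_variant_table(tmp_path / "v.tsv"))
    recs_vcf = list(load_variant_table(str(tmp_path / "v.vcf")))
    assert len(recs_tsv) == len(recs_vcf) == 50
    for a, b in zip(recs_tsv, recs_vcf):
        assert (a.contig, a.pos) == (b.contig, b.pos)
        assert a.qual == pytest.approx(b.qual, abs=0.01)
        assert a.dels == pytest.approx(b.dels, abs=0.001)
        np.testing.assert_array_equal(a.gt, b.gt)
        np.testing.assert_array_equal(a.dp, b.dp)
        np.testing.assert_array_equal(a.pl_best, b.pl_best)
        np.testing.assert_array_equal(a.pl_second, b.pl_second)


def test_record_field_passthrough_and_missing_marking(tmp_path):
    table = _tiny_table()
    write_variant_table(table, tmp_path / "v.tsv")
    recs = list(load_variant_table(tmp_path / "v.tsv"))
    r7 = recs[7]
    assert r7.qual == pytest.approx(120.0)
    assert r7.dels == 0.0
    assert list(r7.dp) == [34, 34, 34]
    r9 = recs[9]
    assert r9.pl_best[2] == -1 and r9.pl_second[2] == -1


def test_unknown_sample_id_rejected(tmp_path):
    table = _tiny_table()
    write_variant_table(table, tmp_path / "v.tsv")
    with pytest.raises(ValueError, match="absent from header"):
        read_variant_table(tmp_path / "v.tsv", ["nope"])


def test_non_monotone_positions_rejected(tmp_path):
    table = _tiny_table()
    write_variant_table(table, tmp_path / "v.tsv")
    text = (tmp_path / "v.tsv").read_text().splitlines()
    text.insert(3, text[10])   # duplicate an earlier position out of order
    (tmp_path / "v.tsv").write_text("\n".join(text) + "\n")
    with pytest.raises(ValueError, match="non-monotone"):
        read_variant_table(tmp_path / "v.tsv")


def test_streaming_site_count_matches_fixture(tmp_path):
    t = VariantTable.allocate(["s01"],
                              {"chr1": np.arange(10_000, dtype=np.int64)})
    t.arrays("chr1")["qual"][:] = 100.0
    t.arrays("chr1")["dp"][:] = 30
    write_variant_table(t, tmp_path / "v.tsv")
    assert sum(1 for _ in load_variant_table(tmp_path / "v.tsv")) == 10_000
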