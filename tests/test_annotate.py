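"""Gene-region classification, consequence typing, and annotation tallies."""

import pytest

from gynotrace import (
    AnnotateParams,
    Biotype,
    Category,
    Consequence,
    Gene,
    GeneModel,
    RegionCall,
    SVType,
    Transcript,
    classify_region,
    exonic_consequence,
    tally_annotations,
)

from conftest import make_rec


def coding_gene(gene_id, chrom, strand, start=10_000):
    """Three-exon protein-coding gene with UTR5/CDS/UTR3 annotated."""
    e1 = (start, start + 2000)
    e2 = (start + 4000, start + 6000)
    e3 = (start + 8000, start + 10_000)
    cut1 = start + 1000
    cut2 = start + 9000
    left_utr = [(e1[0], cut1 - 1)]
    right_utr = [(cut2 + 1, e3[1])]
    tx = Transcript(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=e1[0],
        end=e3[1],
        exons=[e1, e2, e3],
        cds=[(cut1, e1[1]), e2, (e3[0], cut2)],
        utr5=left_utr if strand == "+" else right_utr,
        utr3=right_utr if strand == "+" else left_utr,
    )
    return Gene(gene_id, gene_id, Biotype.PROTEIN_CODING, chrom, strand,
                e1[0], e3[1], [tx])


def lnc_gene(gene_id, chrom, start=50_000):
    tx = Transcript(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        start=start,
        end=start + 10_000,
        exons=[(start, start + 2000), (start + 8000, start + 10_000)],
    )
    return Gene(gene_id, gene_id, Biotype.LNCRNA, chrom, "+",
                start, start + 10_000, [tx])


@pytest.fixture(scope="module")
def model():
    genes = {
        "G1": coding_gene("G1", "A1", "+", start=10_000),     # 10k-20k
        "G2": lnc_gene("G2", "A1", start=50_000),             # 50k-60k
        "G3": coding_gene("G3", "A1", "-", start=100_000),    # 100k-110k, minus
        "G4": coding_gene("G4", "A1", "+", start=200_000),    # 200k-210k
        "G5": coding_gene("G5", "A1", "+", start=212_000),    # 212k-222k
    }
    return GeneModel(genes)


def classify(model, pos, end=None, svtype=SVType.INS, **kw):
    rec = make_rec(pos=pos, end=end, svtype=svtype,
                   svlen=kw.pop("svlen", 100), **kw)
    return classify_region(rec, model, AnnotateParams())


class TestClassifyRegion:
    def test_ins_in_cds_is_exonic_with_consequence(self, model):
        call = classify(model, 11_500)
        assert call.category is Category.EXONIC
        assert call.genes_hit == ["G1"]
        assert call.consequence is not None

    def test_utr5_and_utr3(self, model):
        assert classify(model, 10_500).category is Category.UTR5
        assert classify(model, 19_500).category is Category.UTR3

    def test_intronic(self, model):
        assert classify(model, 13_000).category is Category.INTRONIC

    def test_splicing_window(self, model):
        # exon1 of G1 ends at 12000: bases 12001-12002 are the donor window
        assert classify(model, 12_002).category is Category.SPLICING
        assert classify(model, 12_003).category is Category.INTRONIC

    def test_lncrna_categories(self, model):
        assert classify(model, 51_000).category is Category.NCRNA_EXONIC
        assert classify(model, 55_000).category is Category.NCRNA_INTRONIC

    def test_more_than_2kb_away_is_intergenic(self, model):
        # nearest gene boundary (G1 end 20,000) is 2,500 bp away
        assert classify(model, 22_500).category is Category.INTERGENIC

    def test_upstream_downstream_between_two_genes(self, model):
        # 1,000 bp past G4's end (downstream, + strand) and 1,500 bp before
        # G5's start (upstream): both flanks hit different genes
        call = classify(model, 210_500 + 500)
        assert call.category is Category.UPSTREAM_DOWNSTREAM
        assert call.genes_hit == ["G4", "G5"]

    def test_flank_is_strand_aware_for_minus_gene(self, model):
        # before the span of minus-strand G3 lies its 3' side
        assert classify(model, 99_000).category is Category.DOWNSTREAM
        assert classify(model, 111_000).category is Category.UPSTREAM

    def test_gene_body_beats_flank(self, model):
        # intron of G1, also within 2 kb of nothing else: intronic, not flank
        call = classify(model, 12_500)
        assert call.category in (Category.INTRONIC, Category.SPLICING)

    def test_del_spanning_exon_and_intron_is_exonic(self, model):
        call = classify(model, 11_900, end=13_000, svtype=SVType.DEL, svlen=-1101)
        assert call.category is Category.EXONIC

    def test_unknown_chromosome_is_intergenic(self, model):
        rec = make_rec(chrom="Z9", pos=1000, svtype=SVType.INS, svlen=100)
        assert classify_region(rec, model, AnnotateParams()).category is Category.INTERGENIC

    def test_empty_model_everything_intergenic(self):
        empty = GeneModel({})
        for pos in (1000, 11_500, 55_000):
            rec = make_rec(pos=pos, svtype=SVType.INS, svlen=100)
            assert classify_region(rec, empty, AnnotateParams()).category is Category.INTERGENIC

    def test_transcript_order_invariance(self, model):
        g = coding_gene("GX", "A1", "+", start=10_000)
        extra = Transcript(
            transcript_id="GX.t2", gene_id="GX", chrom="A1", strand="+",
            start=10_000, end=20_000, exons=[(10_000, 20_000)],
        )
        m1 = GeneModel({"GX": Gene("GX", "GX", Biotype.PROTEIN_CODING, "A1", "+",
                                   10_000, 20_000, [g.transcripts[0], extra])})
        m2 = GeneModel({"GX": Gene("GX", "GX", Biotype.PROTEIN_CODING, "A1", "+",
                                   10_000, 20_000, [extra, g.transcripts[0]])})
        for pos in (10_500, 11_500, 13_000):
            assert classify(m1, pos).category is classify(m2, pos).category


class TestExonicConsequence:
    @pytest.mark.parametrize(
        "svtype,svlen,expected",
        [
            (SVType.INS, 5174, Consequence.FRAMESHIFT),  # 5174 % 3 == 2
            (SVType.INS, 6, Consequence.NONFRAMESHIFT),
            (SVType.DEL, -1, Consequence.FRAMESHIFT),
            (SVType.DEL, -300, Consequence.NONFRAMESHIFT),
        ],
    )
    def test_net_length_mod_3(self, svtype, svlen, expected):
        end = 1000 if svtype is SVType.INS else 1000 + abs(svlen) - 1
        rec = make_rec(pos=1000, end=end, svtype=svtype, svlen=svlen)
        assert exonic_consequence(rec) is expected

    def test_inversion_typed_other_with_warning(self):
        rec = make_rec(pos=1000, end=2000, svtype=SVType.INV, svlen=1001)
        with pytest.warns(UserWarning):
            assert exonic_consequence(rec) is Consequence.OTHER


class TestTally:
    def test_gene_associated_fraction(self, model):
        calls = [classify(model, 22_500 + i * 10_000) for i in range(3)] + [
            classify(model, p) for p in (11_500, 13_000, 10_500, 19_500, 51_000,
                                         55_000, 12_002)
        ]
        t = tally_annotations(calls, model)
        assert t.total == 10 and t.n_intergenic == 3
        assert t.gene_associated_fraction == pytest.approx(0.70)
        # categories partition the calls
        assert sum(t.per_category.values()) == t.total
        # independent per-call recount
        from collections import Counter

        recount = Counter(c.category for c in calls)
        assert all(t.per_category[c] == recount.get(c, 0) for c in t.per_category)

    def test_biotype_distinct_gene_counts(self, model):
        calls = [classify(model, p) for p in (11_500, 13_000, 51_000)]
        t = tally_annotations(calls, model)
        assert t.genes_per_biotype == {
            Biotype.PROTEIN_CODING: 1,  # G1 hit twice, counted once
            Biotype.LNCRNA: 1,
        }

    def test_empty_input_all_zeros(self, model):
        t = tally_annotations([], model)
        assert t.total == 0 and t.gene_associated_fraction == 0.0


class TestGff3RoundTrip:
    def test_written_model_classifies_identically(self, model, tmp_path):
        from gynotrace import load_gene_model
        from gynotrace.simulate import write_gff3

        p = tmp_path / "genes.gff3"
        write_gff3(model, p)
        reloaded = load_gene_model(p)
        assert set(reloaded.genes) == set(model.genes)
        probes = [1000, 10_500, 11_500, 12_002, 13_000, 19_500, 22_500,
                  51_000, 55_000, 99_000, 111_000, 210_000 + 1000]
        for pos in probes:
            a = classify(model, pos)
            b = classify(reloaded, pos)
            assert a.category is b.category, pos
            assert a.genes_hit == b.genes_hit
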