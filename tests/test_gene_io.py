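"""Annotation loading, coordinate conventions, splicing and translation."""

import pytest

from helpers import oracle_spliced_cds, revcomp

from intronsig.errors import FormatError, InconsistencyError, ValidationError
from intronsig.io import (
    load_gene_models, load_precursor_annotations, read_fasta, spliced_cds,
    translate_cds, write_gff3, write_precursor_annotations,
)
from intronsig.models import GeneModel, GenomicInterval, PrecursorAnnotation
from intronsig.simulate import SyntheticGeneSpec, generate_gene


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGff3Loading:
    def test_one_based_inclusive_converts_to_zero_based_half_open(self, tmp_path):
        gff = _write(tmp_path, "g.gff3", "\n".join([
            "##gff-version 3",
            "chr1\tsrc\tgene\t101\t160\t.\t+\t.\tID=gene:G1",
            "chr1\tsrc\tmRNA\t101\t160\t.\t+\t.\tID=G1;Parent=gene:G1",
            "chr1\tsrc\texon\t101\t160\t.\t+\t.\tParent=G1",
            "chr1\tsrc\tCDS\t101\t160\t.\t+\t.\tParent=G1",
        ]) + "\n")
        (model,) = load_gene_models(gff)
        assert (model.exons[0].start, model.exons[0].end) == (100, 160)
        assert model.strand == "+"
        assert model.complete  # 60 nt CDS

    def test_minus_strand_exons_listed_acceptor_first(self, tmp_path):
        gff = _write(tmp_path, "g.gff3", "\n".join([
            "##gff-version 3",
            "chr1\tsrc\tmRNA\t11\t100\t.\t-\t.\tID=G1",
            "chr1\tsrc\texon\t11\t40\t.\t-\t.\tParent=G1",
            "chr1\tsrc\texon\t61\t100\t.\t-\t.\tParent=G1",
            "chr1\tsrc\tCDS\t11\t40\t.\t-\t.\tParent=G1",
            "chr1\tsrc\tCDS\t61\t100\t.\t-\t.\tParent=G1",
        ]) + "\n")
        (model,) = load_gene_models(gff)
        # transcript orientation: the downstream-coordinate exon comes first
        assert [e.start for e in model.exons] == [60, 10]

    def test_minus_strand_splice_matches_revcomp_oracle(self, tmp_path):
        spec = SyntheticGeneSpec(
            gene_id="g", strand="-", intron_specs=[(22, 1, 60), (50, 2, 80)],
            seed=5,
        )
        gene = generate_gene(spec)
        assert spliced_cds(gene.model) == oracle_spliced_cds(gene.model)

    def test_cds_without_parent_rejected(self, tmp_path):
        gff = _write(tmp_path, "bad.gff3", "\n".join([
            "##gff-version 3",
            "chr1\tsrc\tCDS\t1\t30\t.\t+\t.\tID=orphan",
        ]) + "\n")
        with pytest.raises(ValidationError, match="no Parent"):
            load_gene_models(gff)

    def test_unknown_strand_rejected(self, tmp_path):
        gff = _write(tmp_path, "bad.gff3", "\n".join([
            "##gff-version 3",
            "chr1\tsrc\tmRNA\t1\t30\t.\t?\t.\tID=G1",
            "chr1\tsrc\texon\t1\t30\t.\t?\t.\tParent=G1",
        ]) + "\n")
        with pytest.raises(ValidationError, match="strand"):
            load_gene_models(gff)

    def test_longest_cds_transcript_selected_by_default(self, tmp_path):
        lines = ["##gff-version 3", "chr1\tsrc\tgene\t1\t200\t.\t+\t.\tID=gene:G"]
        for tid, end in (("T1", 90), ("T2", 150)):
            lines += [
                f"chr1\tsrc\tmRNA\t1\t{end}\t.\t+\t.\tID={tid};Parent=gene:G",
                f"chr1\tsrc\texon\t1\t{end}\t.\t+\t.\tParent={tid}",
                f"chr1\tsrc\tCDS\t1\t{end}\t.\t+\t.\tParent={tid}",
            ]
        gff = _write(tmp_path, "multi.gff3", "\n".join(lines) + "\n")
        (model,) = load_gene_models(gff)
        assert model.gene_id == "T2"
        both = load_gene_models(gff, all_transcripts=True)
        assert {m.gene_id for m in both} == {"T1", "T2"}

    def test_bmkn1_like_two_exon_topology_loads_complete(self, tmp_path):
        # signal-peptide exon | phase-1 intron | mature+propeptide exon
        spec = SyntheticGeneSpec(
            gene_id="amp", signal_len=23, precursor_len=48,
            mature_spans=[(23, 36)], propeptide_spans=[(36, 48)],
            intron_specs=[(23, 1, 85)], seed=7,
        )
        gene = generate_gene(spec)
        from intronsig.simulate import write_cohort
        paths = write_cohort([gene], tmp_path)
        (model,) = load_gene_models(paths["gff3"], paths["fasta"])
        assert len(model.exons) == 2
        assert model.complete


class TestGff3RoundTrip:
    def test_write_then_load_reproduces_models(self, mixed_cohort, tmp_path):
        models = [g.model for g in mixed_cohort[:20]]
        out = tmp_path / "rt.gff3"
        write_gff3(models, out)
        reloaded = {m.gene_id: m for m in load_gene_models(out)}
        assert len(reloaded) == len(models)
        for m in models:
            r = reloaded[m.gene_id]
            assert r.strand == m.strand
            assert [(e.start, e.end) for e in r.exons] == \
                [(e.start, e.end) for e in m.exons]
            assert [(s.start, s.end) for s in r.cds_segments] == \
                [(s.start, s.end) for s in m.cds_segments]


class TestGenBank:
    def test_joined_cds_feature_parses_and_translates(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio.SeqFeature import SeqFeature, CompoundLocation, SimpleLocation
        from Bio import SeqIO

        exon1, intron, exon2 = "ATGGAA", "GTAAGTTTAG", "TTTTGA"
        seq = SeqRecord(Seq(exon1 + intron + exon2), id="L1", name="L1",
                        description="synthetic two-exon locus",
                        annotations={"molecule_type": "DNA"})
        loc = CompoundLocation([SimpleLocation(0, 6, 1), SimpleLocation(16, 22, 1)])
        seq.features.append(SeqFeature(loc, type="CDS", qualifiers={"gene": ["tox1"]}))
        path = tmp_path / "locus.gb"
        SeqIO.write(seq, path, "genbank")

        (model,) = load_gene_models(path)
        assert model.gene_id == "tox1"
        assert translate_cds(spliced_cds(model)) == "MEF"


class TestSplicingAndTranslation:
    def test_plus_strand_single_segment(self):
        m = GeneModel("g", "s", "+",
                      exons=[GenomicInterval("s", 0, 6, "+")],
                      cds_segments=[GenomicInterval("s", 0, 6, "+")],
                      sequence="ATGAAA")
        assert spliced_cds(m) == "ATGAAA"

    def test_minus_strand_single_segment_reverse_complements(self):
        m = GeneModel("g", "s", "-",
                      exons=[GenomicInterval("s", 0, 6, "-")],
                      cds_segments=[GenomicInterval("s", 0, 6, "-")],
                      sequence="ATGAAA")
        assert spliced_cds(m) == "TTTCAT"

    @pytest.mark.parametrize("cds,expected", [("ATGGAATAA", "ME"), ("ATGGAA", "ME")])
    def test_translate_strips_single_trailing_stop(self, cds, expected):
        assert translate_cds(cds) == expected

    def test_internal_stop_names_codon_index(self):
        with pytest.raises(ValidationError, match="codon index 1"):
            translate_cds("ATGTAAGAA")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValidationError, match="multiple of 3"):
            translate_cds("ATGGA")

    def test_every_complete_synthetic_gene_translates(self, mixed_cohort):
        for g in mixed_cohort[:25]:
            cds = spliced_cds(g.model)
            assert len(cds) % 3 == 0
            assert translate_cds(cds) == g.truth.protein

    def test_locus_and_reverse_complement_yield_same_cds(self, mixed_cohort):
        from helpers import flip_model
        for g in mixed_cohort[:15]:
            assert spliced_cds(flip_model(g.model)) == spliced_cds(g.model)


class TestPrecursorAnnotations:
    def test_missing_spans_inferred_as_single_mature_span(self, tmp_path):
        p = _write(tmp_path, "a.tsv",
                   "gene_id\tsignal_len\tprecursor_len\tpropeptide_spans\tmature_spans\n"
                   "G1\t22\t85\t\t\n")
        (a,) = load_precursor_annotations(p)
        assert a.mature_spans == [(22, 85)]
        assert a.complete

    def test_ick_like_propeptide_and_mature_spans_retained(self, tmp_path):
        p = _write(tmp_path, "a.tsv",
                   "gene_id\tsignal_len\tprecursor_len\tpropeptide_spans\tmature_spans\n"
                   "G1\t22\t85\t22-28\t28-85\n")
        (a,) = load_precursor_annotations(p)
        assert a.propeptide_spans == [(22, 28)]
        assert a.mature_spans == [(28, 85)]

    def test_mature_before_propeptide_accepted(self):
        # SP-MP-PP topology of linear antimicrobial peptide precursors
        a = PrecursorAnnotation("G1", signal_len=23, precursor_len=48,
                                mature_spans=[(23, 36)],
                                propeptide_spans=[(36, 48)])
        assert a.region_of(30) == "MATURE"
        assert a.region_of(40) == "PROPEPTIDE"

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            PrecursorAnnotation("G1", signal_len=22, precursor_len=85,
                                propeptide_spans=[(22, 30)],
                                mature_spans=[(28, 85)])

    def test_nonpositive_signal_len_rejected(self):
        with pytest.raises(ValidationError):
            PrecursorAnnotation("G1", signal_len=0, precursor_len=85)

    def test_json_and_tsv_round_trip(self, tmp_path):
        annots = [
            PrecursorAnnotation("G1", 22, 85, [(22, 28)], [(28, 85)]),
            PrecursorAnnotation("G2", 19, 60),
        ]
        tsv = tmp_path / "a.tsv"
        write_precursor_annotations(annots, tsv)
        reloaded = load_precursor_annotations(tsv)
        assert [(a.gene_id, a.signal_len, a.propeptide_spans, a.mature_spans)
                for a in reloaded] == \
            [(a.gene_id, a.signal_len, a.propeptide_spans, a.mature_spans)
             for a in annots]


class TestFastaErrors:
    def test_unparseable_fasta_rejected(self, tmp_path):
        bad = _write(tmp_path, "bad.fa", "this is not fasta\n")
        with pytest.raises(FormatError, match="FASTA"):
            read_fasta(bad)
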