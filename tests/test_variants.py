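"""Background subtraction, breakpoint filters/pairing, effect naming."""

import pytest
from Bio.Seq import Seq

from rexscan.regulon import GeneFeature
from rexscan.scan import reverse_complement
from rexscan.variants import (
    BreakpointRecord,
    VariantRecord,
    annotate_coding_effect,
    filter_breakpoints,
    pair_breakpoints,
    parse_effect_description,
    read_variants_tsv,
    read_variants_vcf,
    subtract_background,
)


def _bp(pos, side="left", reads=20, frac=0.5, seq="ACGTACGTACGTACGTACGT"):
    return BreakpointRecord("c1", pos, side, reads, frac, seq)


class TestSubtractBackground:
    S1 = VariantRecord("c1", 100, "C", "A", "SNV", 0.9)
    S2 = VariantRecord("c1", 200, "T", "C", "SNV", 0.5)

    def test_shared_variant_removed(self):
        control = [VariantRecord("c1", 100, "C", "A", "SNV", 1.0)]
        assert subtract_background([self.S1, self.S2], control) == [self.S2]

    def test_empty_control_is_identity(self):
        assert subtract_background([self.S1, self.S2], []) == [self.S1, self.S2]

    def test_same_pos_different_alt_retained(self):
        control = [VariantRecord("c1", 100, "C", "T", "SNV")]
        assert subtract_background([self.S1], control) == [self.S1]


class TestFilterBreakpoints:
    @pytest.mark.parametrize(
        "reads,frac,kept",
        [
            (9, 0.5, False),  # too few reads
            (10, 0.20, True),  # exact boundary survives
            (50, 0.19, False),  # fraction below threshold
            (10, 0.19999, False),
            (100, 1.0, True),
        ],
    )
    def test_strict_boundaries(self, reads, frac, kept):
        out = filter_breakpoints([_bp(1, reads=reads, frac=frac)])
        assert bool(out) is kept

    def test_negative_threshold_raises(self):
        with pytest.raises(ValueError):
            filter_breakpoints([], min_reads=-1)


class TestPairBreakpoints:
    def test_constructed_pair(self):
        left = _bp(100, "left", seq="ACGTACGTACGTACGTACGTAAAA")
        right = _bp(400, "right", seq="ACGTACGTACGTACGTACGTTTTT")
        calls, unpaired = pair_breakpoints([left], [right])
        assert len(calls) == 1 and not unpaired
        assert calls[0].span == 300
        assert calls[0].evidence_seq in left.unaligned_seq
        assert (
            calls[0].evidence_seq in right.unaligned_seq
            or reverse_complement(calls[0].evidence_seq) in right.unaligned_seq
        )

    def test_reverse_complement_evidence_counts(self):
        left = _bp(100, "left", seq="ACGTACGTACGTACGTACGT")
        right = _bp(300, "right", seq=reverse_complement("ACGTACGTACGTACGTACGT"))
        calls, _ = pair_breakpoints([left], [right])
        assert len(calls) == 1

    def test_no_partner_in_range(self):
        calls, unpaired = pair_breakpoints([_bp(100)], [_bp(100_000, "right")])
        assert calls == [] and len(unpaired) == 2

    def test_short_overlap_rejected(self):
        calls, _ = pair_breakpoints(
            [_bp(100, seq="ACGTACGTAA")], [_bp(200, "right", seq="ACGTACGTAA")]
        )
        assert calls == []

    def test_equidistant_tie_breaks_to_lower_coordinate(self):
        left = _bp(300, "left")
        near_hi = _bp(500, "right")
        near_lo = _bp(450, "right")
        calls, _ = pair_breakpoints([left], [near_hi, near_lo])
        assert calls[0].right.pos == 450

    def test_conservation(self):
        lefts = [_bp(p, "left") for p in (100, 200, 300)]
        rights = [_bp(p, "right") for p in (350, 360)]
        calls, unpaired = pair_breakpoints(lefts, rights)
        assert len(calls) <= min(len(lefts), len(rights))
        assert 2 * len(calls) + len(unpaired) == len(lefts) + len(rights)


def _make_cds():
    """700-codon synthetic CDS with named residues planted for effect tests."""
    codons = ["GCT"] * 700  # Ala backbone
    codons[0] = "ATG"
    codons[289] = "AAA"  # Lys290
    codons[453] = "GAA"  # Glu454
    codons[596] = "ACA"  # Thr597
    codons[699] = "TAA"  # stop
    return "".join(codons)


class TestCodingEffects:
    CDS = _make_cds()
    GENE = GeneFeature("c1", 1000, 1000 + len(CDS), "+", "synthetic_adhE")

    def _apply_and_translate(self, cds, off, ref, alt):
        """Independent oracle: apply the edit, translate, return protein."""
        ref = "" if ref == "-" else ref
        alt = "" if alt == "-" else alt
        edited = cds[:off] + alt + cds[off + len(ref):]
        return str(Seq(edited[: len(edited) - len(edited) % 3]).translate(table=11))

    def test_missense(self):
        off = 596 * 3 + 1  # second base of codon 597: ACA -> AAA
        v = VariantRecord("c1", 1001 + off, "C", "A", "SNV")
        eff = annotate_coding_effect(v, self.GENE, self.CDS)
        assert (eff.description, eff.kind) == ("Thr597Lys", "missense")
        assert self._apply_and_translate(self.CDS, off, "C", "A")[596] == "K"

    def test_nonsense(self):
        off = 453 * 3  # GAA -> TAA
        v = VariantRecord("c1", 1001 + off, "G", "T", "SNV")
        eff = annotate_coding_effect(v, self.GENE, self.CDS)
        assert (eff.description, eff.kind) == ("Glu454*", "nonsense")
        assert self._apply_and_translate(self.CDS, off, "G", "T")[453] == "*"

    def test_frameshift_deletion(self):
        off = 289 * 3  # delete first base of Lys290 codon
        v = VariantRecord("c1", 1001 + off, "A", "-", "DEL")
        eff = annotate_coding_effect(v, self.GENE, self.CDS)
        assert (eff.description, eff.kind) == ("Lys290fs", "frameshift")
        # downstream of the frameshift the translation diverges
        shifted = self._apply_and_translate(self.CDS, off, "A", "-")
        assert shifted[290:300] != str(Seq(self.CDS).translate(table=11))[290:300]

    def test_synonymous(self):
        off = 99 * 3 + 2  # GCT -> GCC, still Ala
        v = VariantRecord("c1", 1001 + off, "T", "C", "SNV")
        eff = annotate_coding_effect(v, self.GENE, self.CDS)
        assert eff.kind == "synonymous"
        assert self._apply_and_translate(self.CDS, off, "T", "C")[99] == "A"

    def test_upstream(self):
        v = VariantRecord("c1", 1000 - 184 + 1, "A", "T", "SNV")
        eff = annotate_coding_effect(v, self.GENE, self.CDS)
        assert (eff.description, eff.kind) == ("184 bp upstream", "upstream")

    def test_inframe_insertion_names_flanking_residues(self):
        off = 290 * 3  # codon boundary after Lys290
        v = VariantRecord("c1", 1001 + off, "-", "AATACT", "INS")
        eff = annotate_coding_effect(v, self.GENE, self.CDS)
        assert eff.kind == "inframe_ins"
        assert eff.description.startswith("Lys290_")
        assert "ins" in eff.description

    def test_inframe_deletion(self):
        off = 289 * 3
        v = VariantRecord("c1", 1001 + off, "AAA", "-", "DEL")
        eff = annotate_coding_effect(v, self.GENE, self.CDS)
        assert (eff.description, eff.kind) == ("Lys290del", "inframe_del")

    def test_minus_strand_gene(self):
        gene = GeneFeature("c1", 1000, 1000 + len(self.CDS), "-", "rev_gene")
        # genomic position of the second codon-597 base on a - gene
        off = 596 * 3 + 1
        genomic_pos = gene.end - off  # 1-based
        v = VariantRecord("c1", genomic_pos, "G", "T", "SNV")  # revcomp C->A
        eff = annotate_coding_effect(v, gene, self.CDS)
        assert eff.description == "Thr597Lys"

    def test_out_of_range_raises(self):
        v = VariantRecord("c1", 100, "A", "T", "SNV")  # 900 bp upstream
        with pytest.raises(ValueError, match="upstream"):
            annotate_coding_effect(v, self.GENE, self.CDS)

    def test_ref_mismatch_raises(self):
        v = VariantRecord("c1", 1001 + 596 * 3 + 1, "G", "A", "SNV")
        with pytest.raises(ValueError, match="annotation mismatch"):
            annotate_coding_effect(v, self.GENE, self.CDS)

    def test_internal_stop_raises(self):
        codons = ["ATG", "TAA"] + ["GCT"] * 10
        cds = "".join(codons)
        gene = GeneFeature("c1", 1000, 1000 + len(cds), "+", "broken")
        v = VariantRecord("c1", 1001 + 5 * 3, "G", "A", "SNV")
        with pytest.raises(ValueError, match="internal stop"):
            annotate_coding_effect(v, gene, cds)

    @pytest.mark.parametrize(
        "desc,expected",
        [
            ("Thr597Lys", {"ref_aa": "Thr", "position": 597, "alt": "Lys"}),
            ("Glu454*", {"ref_aa": "Glu", "position": 454, "alt": "*"}),
            ("Lys290fs", {"ref_aa": "Lys", "position": 290, "alt": "fs"}),
            ("184 bp upstream", {"ref_aa": None, "position": -184, "alt": "upstream"}),
        ],
    )
    def test_descriptions_parse_back(self, desc, expected):
        assert parse_effect_description(desc) == expected


class TestVariantIO:
    def test_vcf_and_tsv_agree(self, tmp_path):
        vcf = tmp_path / "s.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c1\t449017\t.\tC\tA\t.\tPASS\tAF=0.57\n"
            "c1\t2539210\t.\tAT\tA\t.\tPASS\tAF=0.99\n"
        )
        recs = read_variants_vcf(vcf)
        assert recs[0] == VariantRecord("c1", 449017, "C", "A", "SNV", 0.57)
        assert recs[1].type == "DEL"

        tsv = tmp_path / "s.tsv"
        tsv.write_text(
            "contig\tpos\tref\talt\ttype\tsupporting_fraction\n"
            "c1\t449017\tC\tA\tSNV\t0.57\n"
        )
        assert read_variants_tsv(tsv)[0] == recs[0]
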