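"""Determinism and truth-completeness of the synthetic-data generators."""

import numpy as np
import pytest

from rexscan.pattern import match_window
from rexscan.physiology import (
    ODSeries,
    fit_growth,
    fit_standard_curve,
    percent_theoretical_yield,
    quantify_and_normalize,
    theoretical_yield_coeff,
)
from rexscan.regulon import (
    annotate_sites,
    filter_sites,
    load_features_gff,
)
from rexscan.scan import scan_sequence
from rexscan.simulate import (
    GeneratorConfig,
    gen_breakpoint_table,
    gen_fermentation_table,
    gen_genome,
    gen_gff,
    gen_od_curves,
    gen_qpcr,
    sample_accepted_site,
    write_fasta,
)
from rexscan.variants import filter_breakpoints


class TestSampleAcceptedSite:
    def test_every_draw_matches(self, union_pattern):
        rng = np.random.default_rng(3)
        for _ in range(500):
            assert match_window(sample_accepted_site(union_pattern, rng),
                                union_pattern).matched

    def test_seed_determinism(self, union_pattern):
        draws = lambda: [
            sample_accepted_site(union_pattern, np.random.default_rng(5))
            for _ in range(5)
        ]
        assert draws() == draws()

    def test_mismatch_fraction_near_six_sevenths(self, union_pattern):
        rng = np.random.default_rng(12)
        n = 10_000
        mm = sum(
            match_window(sample_accepted_site(union_pattern, rng),
                         union_pattern).arm_mismatch_position != 0
            for _ in range(n)
        )
        assert mm / n == pytest.approx(6 / 7, abs=0.02)


class TestGenGenome:
    CFG = GeneratorConfig(seed=7, genome_length=20_000, n_sites=5)

    def test_scan_recovers_truth_exactly(self, union_pattern):
        seqs, truth = gen_genome(self.CFG, union_pattern)
        hits = scan_sequence(seqs[self.CFG.contig], union_pattern,
                             contig=self.CFG.contig)
        assert {h.start for h in hits} == {s[1] for s in truth.planted_sites}

    def test_pure_at_background_has_no_accidentals(self, union_pattern):
        cfg = GeneratorConfig(seed=1, genome_length=20_000, n_sites=5,
                              at_fraction=1.0)
        _, truth = gen_genome(cfg, union_pattern)
        # the only G/C bases are inside planted windows; truth is planted only
        assert len(truth.planted_sites) == 5

    def test_byte_determinism(self, union_pattern, tmp_path):
        out1, out2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        for out in (out1, out2):
            seqs, _ = gen_genome(self.CFG, union_pattern)
            write_fasta(seqs, out)
        assert out1.read_bytes() == out2.read_bytes()

    def test_infeasible_packing_raises(self, union_pattern):
        with pytest.raises(ValueError, match="packing"):
            GeneratorConfig(seed=1, genome_length=100, n_sites=10)

    def test_planted_strands_balanced(self, union_pattern):
        _, truth = gen_genome(self.CFG, union_pattern)
        planted = truth.planted_sites[: self.CFG.n_sites]
        strands = [s[2] for s in planted]
        assert strands.count("+") == 3 and strands.count("-") == 2


class TestGenGff:
    def test_round_trip_and_downstream_filtering(self, union_pattern, tmp_path):
        cfg = GeneratorConfig(seed=21, genome_length=40_000, n_sites=8,
                              annotated_fraction=1.0, deny_fraction=0.4)
        seqs, truth = gen_genome(cfg, union_pattern)
        gff = tmp_path / "genes.gff3"
        gen_gff(truth, gff)
        feats = load_features_gff(gff)
        assert feats == sorted(truth.genes, key=lambda g: (g.contig, g.start))

        hits = scan_sequence(seqs[cfg.contig], union_pattern, contig=cfg.contig)
        kept = filter_sites(annotate_sites(hits, feats), require_annotation=True)
        assert sorted((a.locus_tag, a.distance) for a in kept) == sorted(
            truth.expected_regulon
        )
        # deny-listed genes exist and none of them appear in the report
        denied = {g.locus_tag for g in truth.genes
                  if g.product == "hypothetical protein"}
        assert denied and not denied & {a.locus_tag for a in kept}

    def test_empty_gene_list(self, tmp_path):
        from rexscan.simulate import SyntheticTruth

        out = tmp_path / "empty.gff3"
        gen_gff(SyntheticTruth(), out)
        assert out.read_text() == "##gff-version 3\n"


class TestGenOdCurves:
    def test_noise_free_recovery(self):
        df, truth = gen_od_curves({"wt": 0.31, "slow": 0.06}, seed=2)
        for strain, mu in truth.items():
            grp = df[df.strain == strain]
            fit = fit_growth(ODSeries(tuple(grp.time_h), tuple(grp.od600)))
            assert fit.mu_max == pytest.approx(mu, rel=0.01)

    def test_zero_rate_is_flat(self):
        df, _ = gen_od_curves({"dead": 0.0}, od0=0.05, seed=2)
        assert df.od600.nunique() == 1
        assert df.od600.iloc[0] == pytest.approx(0.05)

    def test_seeded_reproducibility(self):
        a, _ = gen_od_curves({"x": 0.2}, noise_sd=0.05, seed=4)
        b, _ = gen_od_curves({"x": 0.2}, noise_sd=0.05, seed=4)
        assert a.equals(b)

    def test_nonpositive_k_raises(self):
        with pytest.raises(ValueError):
            gen_od_curves({"x": 0.2}, k=0.0)


class TestGenBreakpoints:
    def test_filter_recovers_labels_exactly(self):
        records, labels = gen_breakpoint_table(n=300, pass_fraction=0.4, seed=5)
        kept = filter_breakpoints(records)
        assert kept == [r for r, keep in zip(records, labels) if keep]

    def test_boundary_rows_present_and_pass(self):
        records, labels = gen_breakpoint_table(n=100, pass_fraction=0.5, seed=5)
        exact = [r for r in records
                 if r.read_count == 10 and r.frac_not_perfectly_matched == 0.20]
        assert exact and all(r in filter_breakpoints(records) for r in exact)
        near_miss = [r for r in records
                     if r.read_count == 9 and r.frac_not_perfectly_matched == 0.19]
        assert near_miss and not set(near_miss) & set(filter_breakpoints(records))

    def test_zero_pass_fraction(self):
        records, labels = gen_breakpoint_table(n=50, pass_fraction=0.0, seed=5)
        assert not any(labels)
        assert filter_breakpoints(records) == []


class TestGenFermentation:
    def test_round_trip(self):
        records, truth = gen_fermentation_table(
            {"wt": 40.0, "rex": 91.0, "adapted": 56.0}, seed=8
        )
        for rec in records:
            got = percent_theoretical_yield(rec).percent_theoretical
            assert got == pytest.approx(truth[rec.strain], rel=0.005)

    def test_extremes(self):
        records, _ = gen_fermentation_table({"none": 0.0, "full": 100.0}, seed=8)
        by = {r.strain: r for r in records}
        assert by["none"].ethanol == 0.0
        assert by["full"].ethanol == pytest.approx(
            5.0 * theoretical_yield_coeff("cellobiose")
        )

    def test_guard_against_implausible_yield(self):
        with pytest.raises(ValueError, match="implausible"):
            gen_fermentation_table({"x": 151.0}, seed=8)


class TestGenQpcr:
    def test_noise_free_ratio_recovery(self):
        samples, standards, truth = gen_qpcr({"adhE": 10.0}, noise_sd=0.0, seed=6)
        curve = fit_standard_curve(standards)
        curves = {t: curve for t in {s.target for s in samples}}
        ratios = quantify_and_normalize(samples, curves)
        assert ratios["adhE"] == pytest.approx(10.0, rel=1e-6)
        assert ratios["recA"] == 1.0

    def test_unit_ratio(self):
        samples, standards, _ = gen_qpcr({"adhA": 1.0}, noise_sd=0.0, seed=6)
        curve = fit_standard_curve(standards)
        ratios = quantify_and_normalize(
            samples, {t: curve for t in {s.target for s in samples}}
        )
        assert ratios["adhA"] == pytest.approx(1.0)

    def test_seeded_reproducibility(self):
        a = gen_qpcr({"adhE": 10.0}, noise_sd=0.1, seed=3)[0]
        b = gen_qpcr({"adhE": 10.0}, noise_sd=0.1, seed=3)[0]
        assert a == b
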