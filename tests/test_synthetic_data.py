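import filecmp

import numpy as np
import pytest

from yy2scan import enrichment_scoring as es
from yy2scan import feature_annotation as fa
from yy2scan import synthetic_data as sd
from yy2scan.io_genomics import GenomicInterval


class TestGenerateGenome:
    def test_zero_genes_empty_catalog(self):
        cfg = sd.SimulationConfig(seed=1)
        g = sd.generate_genome(cfg)
        assert len(g.catalog) == 0

    def test_determinism_byte_identical(self, tmp_path):
        cfg = sd.SimulationConfig(seed=7, n_genes=3, peaks=[sd.PeakSpec("any")])
        a = sd.generate_genome(cfg)
        b = sd.generate_genome(cfg)
        assert a.sequences == b.sequences
        assert [(f.feature_id, f.interval) for f in a.catalog] == [
            (f.feature_id, f.interval) for f in b.catalog
        ]

    def test_repeat_copy_identity(self):
        # divergence 0.02 on 500 bp: pairwise identity stays high
        for seed in range(50):
            cfg = sd.SimulationConfig(
                seed=seed, repeat_family=sd.RepeatFamilySpec(n_copies=5, copy_length=500, divergence=0.02)
            )
            g = sd.generate_genome(cfg)
            assert len(g.truth.repeat_copies) == 5
            seqs = [
                g.sequences[c.chrom][c.start : c.end] for c in g.truth.repeat_copies
            ]
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    ident = sum(a == b for a, b in zip(seqs[i], seqs[j])) / 500
                    assert ident >= 0.90  # two copies each <= ~2% diverged

    def test_infeasible_placement(self):
        cfg = sd.SimulationConfig(seed=1, chrom_lengths={"c": 1_000}, peaks=[sd.PeakSpec("TSS")])
        with pytest.raises(sd.PlacementError):
            sd.generate_genome(cfg)

    def test_invalid_divergence(self):
        with pytest.raises(ValueError):
            sd.RepeatFamilySpec(n_copies=2, divergence=1.5)


class TestPlantPeaksAndMotif:
    def test_21_peak_class_split(self):
        specs = (
            [sd.PeakSpec("TSS")] * 2 + [sd.PeakSpec("O")] * 8 + [sd.PeakSpec("DD")] * 3
            + [sd.PeakSpec("DU")] * 6 + [sd.PeakSpec("I")] * 2
        )
        cfg = sd.SimulationConfig(seed=3, peaks=specs)
        g = sd.generate_genome(cfg)
        sd.plant_peaks_and_motif(g, cfg)
        assert len(g.truth.peaks) == 21
        from collections import Counter

        assert Counter(t.location_class for t in g.truth.peaks) == {
            "TSS": 2, "O": 8, "DD": 3, "DU": 6, "I": 2,
        }

    def test_motif_written_at_center(self):
        cfg = sd.SimulationConfig(seed=4, peaks=[sd.PeakSpec("any")], motif="AAAA")
        g = sd.generate_genome(cfg)
        sd.plant_peaks_and_motif(g, cfg)
        t = g.truth.peaks[0]
        assert g.sequences[t.interval.chrom][t.motif_offset : t.motif_offset + 4] == "AAAA"
        assert t.motif_instance == "AAAA"

    def test_empty_spec_unchanged_genome(self):
        cfg = sd.SimulationConfig(seed=4)
        g = sd.generate_genome(cfg)
        before = dict(g.sequences)
        sd.plant_peaks_and_motif(g, cfg)
        assert g.sequences == before
        assert g.truth.peaks == []

    def test_iupac_instantiation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            inst = sd._instantiate_iupac("ANAGAAGTGG", rng)
            assert len(inst) == 10
            assert inst[0] == "A" and inst[2:] == "AGAAGTGG"
            assert inst[1] in "ACGT"

    def test_unsatisfiable_lnc_for_intergenic(self):
        with pytest.raises(sd.PlacementError):
            sd.PeakSpec("I", lnc="within_5kb")


class TestSimulateReads:
    def test_planted_fold_recovered_in_window_ratio(self):
        for seed in range(20):
            cfg = sd.SimulationConfig(seed=seed, peaks=[sd.PeakSpec("any", fold=8.0, width=300)],
                                      control_depth=20.0)
            g = sd.generate_genome(cfg)
            sd.plant_peaks_and_motif(g, cfg)
            ip, ctrl = sd.simulate_reads(g, g.truth, cfg)
            grid = es.make_windows(g.chrom_lengths)
            ipc = es.count_reads(grid, ip)
            ctc = es.count_reads(grid, ctrl)
            pk = g.truth.peaks[0].interval
            idx = [
                i for i in range(grid.n_windows(pk.chrom))
                if grid.window_interval(pk.chrom, i).overlaps(pk)
            ]
            ratio = ipc.counts[pk.chrom][idx].sum() / max(1, ctc.counts[pk.chrom][idx].sum())
            assert ratio > 4.0

    def test_null_distributions_similar(self):
        from scipy.stats import mannwhitneyu

        cfg = sd.SimulationConfig(seed=11, control_depth=20.0,
                                  chrom_lengths={"chr1": 50_000})
        g = sd.generate_genome(cfg)
        sd.plant_peaks_and_motif(g, cfg)
        ip, ctrl = sd.simulate_reads(g, g.truth, cfg)
        grid = es.make_windows(g.chrom_lengths)
        a = es.count_reads(grid, ip).counts["chr1"]
        b = es.count_reads(grid, ctrl).counts["chr1"]
        assert mannwhitneyu(a, b).pvalue > 0.01

    def test_degenerate_depth_parses(self, tmp_path):
        from yy2scan.io_genomics import read_alignments, write_alignments_bed

        cfg = sd.SimulationConfig(seed=2, control_depth=0.0001)
        g = sd.generate_genome(cfg)
        sd.plant_peaks_and_motif(g, cfg)
        ip, ctrl = sd.simulate_reads(g, g.truth, cfg)
        p = tmp_path / "ip.bed"
        write_alignments_bed(ip, p)
        assert read_alignments(p, "bed") is not None

    def test_repeat_label_conservation(self):
        cfg = sd.SimulationConfig(
            seed=6,
            repeat_family=sd.RepeatFamilySpec(n_copies=4, copy_length=400, divergence=0.01),
            control_depth=10.0,
        )
        g = sd.generate_genome(cfg)
        sd.plant_peaks_and_motif(g, cfg)
        ip, ctrl = sd.simulate_reads(g, g.truth, cfg)
        n_rep_ip = sum(r.mapping_class == "repeated" for r in ip)
        n_rep_ctrl = sum(r.mapping_class == "repeated" for r in ctrl)
        assert n_rep_ip == g.truth.n_repeat_origin["ip"]
        assert n_rep_ctrl == g.truth.n_repeat_origin["control"]
        assert n_rep_ctrl > 0
        # every repeated read lies within a repeat copy
        for r in ip + ctrl:
            if r.mapping_class == "repeated":
                assert any(r.interval.overlaps(c) for c in g.truth.repeat_copies)


class TestSimulateCtTable:
    def test_zero_sd_fold_one(self):
        cfg = sd.SimulationConfig(seed=1, ct_design=sd.CtDesign(true_folds={"t": 1.0}, ct_sd=0.0))
        table, _ = sd.simulate_ct_table(cfg)
        from yy2scan.qpcr_quant import relative_expression_ddct

        r = relative_expression_ddct(table, "t", "Gapdh", "knockdown", "control")
        assert r.ddct == pytest.approx(0.0)

    def test_zero_sd_exact_inversion(self):
        cfg = sd.SimulationConfig(seed=1, ct_design=sd.CtDesign(true_folds={"t": 0.2}, ct_sd=0.0))
        table, _ = sd.simulate_ct_table(cfg)
        from yy2scan.qpcr_quant import relative_expression_ddct

        r = relative_expression_ddct(table, "t", "Gapdh", "knockdown", "control")
        assert r.fold == pytest.approx(0.2)

    def test_same_seed_identical_csv(self, tmp_path):
        cfg = sd.SimulationConfig(seed=5, ct_design=sd.CtDesign(true_folds={"t": 2.0}))
        a, _ = sd.simulate_ct_table(cfg)
        b, _ = sd.simulate_ct_table(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa)
        b.to_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()


class TestGenerateDataset:
    def test_full_dataset_files(self, tmp_path):
        cfg = sd.SimulationConfig(
            seed=17, n_genes=2, n_lncrnas=1,
            peaks=[sd.PeakSpec("O", fold=8.0), sd.PeakSpec("any", fold=6.0)],
            ct_design=sd.CtDesign(true_folds={"lnc1": 0.3}),
        )
        paths = sd.generate_dataset(cfg, tmp_path / "out")
        for p in paths.values():
            assert p.exists()
        truth = sd.read_truth_tsv(paths["truth"])
        assert len(truth.peaks) == 2

    def test_byte_identical_across_reruns(self, tmp_path):
        cfg = sd.SimulationConfig(seed=17, n_genes=2, peaks=[sd.PeakSpec("any", fold=8.0)])
        pa = sd.generate_dataset(cfg, tmp_path / "a")
        pb = sd.generate_dataset(cfg, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_yaml_config_roundtrip(self, tmp_path):
        yaml_text = """
seed: 9
n_genes: 1
peaks:
  - location_class: O
    fold: 8.0
    width: 300
ct_design:
  true_folds: {geneA: 0.2}
"""
        p = tmp_path / "sim.yaml"
        p.write_text(yaml_text)
        cfg = sd.SimulationConfig.from_yaml(p)
        assert cfg.seed == 9
        assert cfg.peaks[0].location_class == "O"
        assert cfg.ct_design.true_folds == {"geneA": 0.2}


class TestEndToEndRoundTrip:
    def test_recovery_class_and_motif(self):
        """Pipeline on generated data recovers planted peaks, classes and motif."""
        from yy2scan import motif_consensus as mc
        from yy2scan.io_genomics import extract_sequence
        from tests.test_motif_consensus import consensus_matches

        n_recovered = n_planted = n_class_ok = 0
        for seed in range(5):
            specs = [sd.PeakSpec(c, fold=8.0, width=300) for c in ("TSS", "O", "DU", "DD", "I")]
            cfg = sd.SimulationConfig(seed=seed, peaks=specs, control_depth=20.0)
            g = sd.generate_genome(cfg)
            sd.plant_peaks_and_motif(g, cfg)
            ip, ctrl = sd.simulate_reads(g, g.truth, cfg)
            grid = es.make_windows(g.chrom_lengths)
            scale = es.compute_scale_factor(len(ctrl), len(ip))
            peaks = es.rank_peaks(es.call_peaks(grid, ip, ctrl, scale, 2.0))
            for t in g.truth.peaks:
                n_planted += 1
                hit = next((p for p in peaks if p.interval.overlaps(t.interval)), None)
                if hit is None:
                    continue
                n_recovered += 1
                if fa.classify_location(hit, g.catalog) == t.location_class:
                    n_class_ok += 1
        assert n_recovered / n_planted >= 0.9
        assert n_class_ok / n_recovered >= 0.8
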