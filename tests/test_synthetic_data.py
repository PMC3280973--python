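"""Generator correctness: locus geometry, determinism, event mechanics,
cohort prevalence and detection-channel behaviour."""

import dataclasses
import io as stdio

import numpy as np
import pandas as pd
import pytest

from ragdelscan import io as rio
from ragdelscan import rss_scanner as rs
from ragdelscan import synthetic_data as sd


class TestSimulateLocus:
    def test_desk_scale_geometry(self, desk_config, desk_locus):
        locus = desk_locus
        assert 5_000 < locus.locus_length < 8_000
        sizes = [locus.deletion_size(s.label) for s in locus.distal_rss_sites]
        expected = [
            round(d * desk_config.scale_factor)
            for d in sd.PAPER_DISTAL_DISTANCES_BP.values()
        ]
        assert sorted(sizes) == sorted(expected)
        assert min(sizes) == 1010 and max(sizes) == 5570

    def test_truth_bed_coordinates_read_back(self, desk_config, desk_locus):
        bed = sd.locus_deletion_bed(desk_locus)
        lengths = dict(zip(bed.name, bed.end - bed.start))
        for label, dist in sd.PAPER_DISTAL_DISTANCES_BP.items():
            assert lengths[f"DEL_{label}"] == round(dist * desk_config.scale_factor)

    def test_paper_scale_distance_endpoints(self):
        cfg = sd.SimulatorConfig(seed=3, scale_factor=1.0)
        locus = sd.simulate_locus(cfg)
        sizes = sorted(locus.deletion_size(s.label) for s in locus.distal_rss_sites)
        assert len(sizes) == 8
        assert sizes[0] == 101_000
        assert sizes[-1] == 557_000

    def test_embedded_motifs_verbatim(self, desk_locus):
        seq = desk_locus.sequence
        for site in [desk_locus.hotspot_rss, *desk_locus.distal_rss_sites]:
            window = seq[site.position : site.position + 7]
            observed = window if site.strand == "+" else rs.reverse_complement(window)
            assert observed == site.heptamer, site.label
        h = desk_locus.hotspot_rss
        assert seq[h.position + 7 + h.spacer_len : h.position + 16 + h.spacer_len] \
            == h.nonamer

    def test_nested_intervals(self, desk_locus):
        g0, g1 = desk_locus.gene_interval
        e0, e1 = desk_locus.exon2_interval
        assert 0 <= g0 < e0 < e1 <= g1 <= desk_locus.locus_length
        assert e0 <= desk_locus.hotspot_rss.position < e1

    def test_no_spurious_exact_consensus_rss(self, desk_locus):
        exact = rs.scan(desk_locus.sequence, "both", 0, 0)
        truth = {
            (s.position, s.strand)
            for s in [desk_locus.hotspot_rss, *desk_locus.distal_rss_sites]
        }
        assert all((c.heptamer_start, c.strand) in truth for c in exact)

    def test_determinism_byte_identical_fasta(self, desk_config):
        def fasta_bytes():
            locus = sd.simulate_locus(dataclasses.replace(desk_config))
            buf = stdio.StringIO()
            import Bio.SeqIO
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord
            Bio.SeqIO.write([SeqRecord(Seq(locus.sequence), id="locus",
                                       description="")], buf, "fasta")
            return buf.getvalue()

        assert fasta_bytes() == fasta_bytes()

    def test_infeasible_scale_names_minimum(self):
        cfg = sd.SimulatorConfig(seed=1, scale_factor=1e-4)
        with pytest.raises(ValueError, match="minimal feasible scale"):
            sd.simulate_locus(cfg)


class TestSimulateDeletion:
    def test_spacer_classes_follow_12_23_rule(self, desk_locus, desk_config, rng):
        for _ in range(50):
            ev = sd.simulate_deletion(desk_locus, rng, desk_config)
            assert {ev.proximal_rss.spacer_class, ev.distal_rss.spacer_class} == {23, 12}

    def test_zero_insertion_is_exact_concatenation(self, desk_locus, rng):
        cfg = sd.SimulatorConfig(
            seed=7, scale_factor=0.01, insertion_len_range=(0, 0))
        ev = sd.simulate_deletion(desk_locus, rng, cfg)
        b_p, b_d = ev.deleted_interval
        f = ev.junction_flank
        assert ev.inserted_nt == ""
        assert ev.junction_sequence == (
            desk_locus.sequence[b_p - f : b_p] + desk_locus.sequence[b_d : b_d + f])

    def test_junction_assembly_convention(self, desk_locus, desk_config, rng):
        ev = sd.simulate_deletion(desk_locus, rng, desk_config)
        b_p, b_d = ev.deleted_interval
        f = ev.junction_flank
        assert ev.junction_sequence == (
            desk_locus.sequence[b_p - f : b_p]
            + ev.inserted_nt
            + desk_locus.sequence[b_d : b_d + f]
        )
        assert ev.size == b_d - b_p
        assert 1 <= len(ev.inserted_nt) <= 10

    def test_uniform_site_choice_frequencies(self, desk_locus, rng):
        """With uniform weights each of the 8 sites is used 1/8 of the time
        (3-sigma binomial check at n = 10,000)."""
        cfg = sd.SimulatorConfig(
            seed=7, scale_factor=0.01,
            site_weights={l: 1.0 for l in sd.PAPER_DISTAL_DISTANCES_BP})
        n = 10_000
        counts = {}
        for _ in range(n):
            ev = sd.simulate_deletion(desk_locus, rng, cfg)
            counts[ev.deletion_type] = counts.get(ev.deletion_type, 0) + 1
        sigma = np.sqrt(n * (1 / 8) * (7 / 8))
        for label in sd.PAPER_DISTAL_DISTANCES_BP:
            assert abs(counts.get(label, 0) - n / 8) < 3 * sigma

    def test_proximal_breakpoints_scatter_in_region(self, desk_locus, desk_config, rng):
        h = desk_locus.hotspot_rss.cleavage_edge
        breaks = [
            sd.simulate_deletion(desk_locus, rng, desk_config).deleted_interval[0]
            for _ in range(500)
        ]
        span = max(breaks) - min(breaks) + 1
        assert span <= desk_config.breakpoint_region_bp
        in_core = sum(abs(b - h) <= 5 for b in breaks) / len(breaks)
        assert in_core >= 0.6  # ~75% drawn in the 10 bp core


class TestSimulateCohort:
    def test_expected_bulk_positive_count(self):
        """Defaults emulate the reference cohort: 722 B-lineage samples at
        ~9% overall clonal prevalence -> ~65 bulk-detected deletions."""
        cfg = sd.SimulatorConfig(seed=101, scale_factor=0.01)
        records = sd.simulate_cohort(cfg)
        bcp = [r for r in records if r.lineage == "BCP-ALL"]
        assert len(bcp) == 722
        mlpa_pos = sum(
            any(c.clonal_fraction >= cfg.mlpa_detect_fraction for c in r.clones)
            for r in bcp
        )
        sigma = np.sqrt(722 * 0.09 * 0.91)
        assert abs(mlpa_pos - 65) < 3 * sigma

    def test_tall_and_normal_carry_no_deletions(self):
        cfg = sd.SimulatorConfig(seed=5, scale_factor=0.01)
        records = sd.simulate_cohort(cfg)
        for rec in records:
            if rec.lineage in ("T-ALL", "normal"):
                assert rec.clones == []

    def test_zero_probabilities_give_event_free_cohort(self):
        cfg = sd.SimulatorConfig(
            seed=5, scale_factor=0.01,
            n_samples={"other": 30},
            deletion_prob={"other": 0.0},
            subclonal_prob=0.0, n_tall=5, n_normal=0)
        records = sd.simulate_cohort(cfg)
        frame = sd.cohort_to_frame(records, cfg)
        assert (frame.deletion_type == "none").all()
        assert set(frame.columns) >= {
            "sample_id", "lineage", "subgroup", "timepoint",
            "clone_id", "deletion_type", "clonal_fraction"}

    def test_empty_cohort_raises(self):
        cfg = sd.SimulatorConfig(
            seed=5, scale_factor=0.01, n_samples={}, n_tall=0, n_normal=0)
        with pytest.raises(ValueError):
            sd.simulate_cohort(cfg)

    def test_determinism(self):
        cfg = sd.SimulatorConfig(
            seed=17, scale_factor=0.01, n_samples={"other": 40}, n_tall=0, n_normal=0)
        f1 = sd.cohort_to_frame(sd.simulate_cohort(cfg), cfg)
        f2 = sd.cohort_to_frame(sd.simulate_cohort(dataclasses.replace(cfg)), cfg)
        pd.testing.assert_frame_equal(f1, f2)

    def test_prevalence_recovery_large_n(self):
        """Law of large numbers: estimated clonal rate converges to the
        configured rate at n = 10,000."""
        cfg = sd.SimulatorConfig(
            seed=23, scale_factor=0.01,
            n_samples={"g": 10_000}, deletion_prob={"g": 0.19},
            subclonal_prob=0.0, n_tall=0, n_normal=0)
        records = sd.simulate_cohort(cfg)
        rate = np.mean([
            any(c.clonal_fraction >= cfg.mlpa_detect_fraction for c in r.clones)
            for r in records
        ])
        sigma = np.sqrt(0.19 * 0.81 / 10_000)
        assert abs(rate - 0.19) < 3 * sigma

    def test_no_same_class_pairs_ever(self):
        cfg = sd.SimulatorConfig(
            seed=2, scale_factor=0.01, n_samples={"g": 60},
            deletion_prob={"g": 0.5}, n_tall=0, n_normal=0)
        for rec in sd.simulate_cohort(cfg):
            for clone in rec.clones:
                assert clone.proximal_rss.spacer_class != clone.distal_rss.spacer_class

    def test_clonal_fractions_sum_below_one(self):
        cfg = sd.SimulatorConfig(
            seed=2, scale_factor=0.01, n_samples={"g": 200},
            deletion_prob={"g": 0.5}, n_tall=0, n_normal=0)
        for rec in sd.simulate_cohort(cfg):
            assert sum(c.clonal_fraction for c in rec.clones) <= 1.0 + 1e-9


class TestApplyDetection:
    @pytest.mark.parametrize(
        "fraction,label",
        [(0.5, "MLPA+"), (0.05, "PCR-only"), (0.001, "undetected")],
    )
    def test_threshold_labels(self, desk_locus, desk_config, rng, fraction, label):
        ev = sd.simulate_deletion(
            desk_locus, rng, desk_config, clone_id="c0", clonal_fraction=fraction)
        rec = sd.CohortRecord("s0", "BCP-ALL", "other", [ev])
        assert sd.apply_detection(rec, desk_config) == {"c0": label}

    def test_monotone_in_fraction(self, desk_locus, desk_config, rng):
        order = {"undetected": 0, "PCR-only": 1, "MLPA+": 2}
        fractions = np.linspace(0.001, 0.95, 25)
        labels = []
        for i, f in enumerate(fractions):
            ev = sd.simulate_deletion(
                desk_locus, rng, desk_config, clone_id=f"c{i}", clonal_fraction=float(f))
            rec = sd.CohortRecord("s", "BCP-ALL", "other", [ev])
            labels.append(order[sd.apply_detection(rec, desk_config)[f"c{i}"]])
        assert labels == sorted(labels)


class TestConfigValidation:
    def test_threshold_ordering_enforced(self):
        cfg = sd.SimulatorConfig(mlpa_detect_fraction=0.005, pcr_detect_fraction=0.01)
        problems = cfg.validate()
        assert any(
            "mlpa_detect_fraction" in p and "pcr_detect_fraction" in p
            for p in problems)

    def test_bad_probability_flagged(self):
        cfg = sd.SimulatorConfig(deletion_prob={"g": 1.5})
        assert any("deletion_prob" in p for p in cfg.validate())

    def test_default_config_valid(self):
        assert sd.SimulatorConfig().validate() == []
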