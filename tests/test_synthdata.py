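"""Synthetic cohort generator: determinism, CpG validity, plants, survival."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmotif.synthdata import (
    SimulationConfig,
    reverse_complement,
    simulate_all,
    simulate_genome_and_cpgs,
    simulate_phenotypes,
    simulate_pwms_and_plant,
    simulate_tf_edges,
)


def _small_config(**kw):
    defaults = dict(
        seed=3, n_chromosomes=1, chrom_length=50_000, n_cpgs=200, n_samples=60,
        n_motifs_decoy=4, n_motifs_planted=1, n_causal_survival_cpgs=20,
        n_diffmeth_cpgs=30, n_tf_nodes=8,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenomeAndCpgs:
    def test_fixed_seed_bit_identical(self):
        cfg = _small_config()
        g1, a1 = simulate_genome_and_cpgs(cfg)
        g2, a2 = simulate_genome_and_cpgs(cfg)
        assert g1 == g2
        assert a1.equals(a2)

    def test_every_annotated_site_is_a_cg_dinucleotide(self):
        genome, ann = simulate_genome_and_cpgs(_small_config())
        for rec in ann.itertuples(index=False):
            p = rec.position  # 1-based C
            assert genome[rec.chrom][p - 1 : p + 1] == "CG"

    def test_windows_fit_inside_chromosomes(self):
        cfg = _small_config(chrom_length=300, n_cpgs=2)
        genome, ann = simulate_genome_and_cpgs(cfg)
        for rec in ann.itertuples(index=False):
            assert rec.position - 51 >= 0
            assert rec.position + 51 <= len(genome[rec.chrom])

    def test_too_many_cpgs_errors_with_shortfall(self):
        cfg = _small_config(chrom_length=500, n_cpgs=1000)
        with pytest.raises(ValueError, match="shortfall"):
            simulate_genome_and_cpgs(cfg)


class TestPlanting:
    def test_rate_one_plants_every_causal_cpg_within_window(self):
        cfg = _small_config(
            plant_rate_foreground=1.0, plant_rate_background=0.0, n_causal_survival_cpgs=50
        )
        genome, ann = simulate_genome_and_cpgs(cfg)
        pwms, genome2, truth = simulate_pwms_and_plant(genome, ann, cfg)
        assert len(truth.planted_site_coordinates) == 50
        pos = ann.set_index("cpg_id")["position"]
        widths = {p.motif_id: p.width for p in pwms}
        causal_windows = {
            cid: (pos[cid] - 51, pos[cid] + 51) for cid in truth.causal_cpg_ids
        }
        for chrom, start, strand, mid in truth.planted_site_coordinates:
            w = widths[mid]
            assert any(s <= start and start + w <= e for s, e in causal_windows.values())

    def test_overwrite_semantics_recorded_exactly(self):
        cfg = _small_config(plant_rate_foreground=1.0, plant_rate_background=0.0)
        genome, ann = simulate_genome_and_cpgs(cfg)
        pwms, genome2, truth = simulate_pwms_and_plant(genome, ann, cfg)
        sites = sorted(
            zip(truth.planted_site_coordinates, truth.planted_site_sequences),
            key=lambda x: (x[0][0], x[0][1]),
        )
        # verify sites that no later plant could have clobbered
        for i, ((chrom, start, strand, mid), seq) in enumerate(sites):
            end = start + len(seq)
            clobbered = any(
                o[0][0] == chrom and o[0][1] < end and o[0][1] + len(o[1]) > start
                for j, o in enumerate(sites) if j != i
            )
            if not clobbered:
                assert genome2[chrom][start:end] == seq

    def test_plant_count_within_binomial_bounds(self):
        cfg = _small_config(
            seed=9, n_chromosomes=2, chrom_length=400_000, n_cpgs=1000,
            n_causal_survival_cpgs=1000, plant_rate_foreground=0.6,
            plant_rate_background=0.0,
        )
        genome, ann = simulate_genome_and_cpgs(cfg)
        _, _, truth = simulate_pwms_and_plant(genome, ann, cfg)
        n = len(truth.planted_site_coordinates)
        sd = np.sqrt(1000 * 0.6 * 0.4)
        assert abs(n - 600) <= 3 * sd

    def test_minus_strand_plants_inserted_as_reverse_complement(self):
        cfg = _small_config(plant_rate_foreground=1.0)
        genome, ann = simulate_genome_and_cpgs(cfg)
        pwms, genome2, truth = simulate_pwms_and_plant(genome, ann, cfg)
        consensus = {p.motif_id: p.consensus for p in pwms}
        minus = [
            (c, s)
            for (c, s) in zip(truth.planted_site_coordinates, truth.planted_site_sequences)
            if c[2] == "-"
        ]
        assert minus, "expected some minus-strand plants"
        for (chrom, start, strand, mid), seq in minus:
            # reading the written sequence back on the minus strand recovers a
            # PWM sample: it should be close to the consensus (dominant 0.9)
            sample = reverse_complement(seq)
            matches = sum(a == b for a, b in zip(sample, consensus[mid]))
            assert matches >= len(sample) - 3

    def test_motif_width_above_region_rejected(self):
        cfg = _small_config()
        cfg.motif_width_range = (103, 110)
        genome, ann = simulate_genome_and_cpgs(_small_config())
        with pytest.raises(ValueError, match="width"):
            simulate_pwms_and_plant(genome, ann, cfg)


class TestPhenotypes:
    def test_beta_in_closed_unit_interval(self, tiny_dataset):
        vals = tiny_dataset.beta.to_numpy()
        assert np.all((vals >= 0) & (vals <= 1))

    def test_censoring_rate_near_target(self):
        cfg = _small_config(n_samples=300, censoring_rate=0.3)
        genome, ann = simulate_genome_and_cpgs(cfg)
        _, _, truth = simulate_pwms_and_plant(genome, ann, cfg)
        _, clinical = simulate_phenotypes(ann, truth, cfg)
        censored = 1 - clinical["event"].mean()
        assert abs(censored - 0.3) <= 0.1

    def test_null_effect_gives_uniform_t_test_pvalues(self):
        cfg = _small_config(diffmeth_effect=0.0, n_cpgs=400, log_hazard_coefficient=0.0)
        genome, ann = simulate_genome_and_cpgs(cfg)
        _, _, truth = simulate_pwms_and_plant(genome, ann, cfg)
        beta, clinical = simulate_phenotypes(ann, truth, cfg)
        from methmotif.diffassoc import diff_methylation

        groups = dict(zip(clinical["sample_id"], clinical["ER"]))
        res = diff_methylation(beta, groups)
        ks = stats.kstest(res["raw_p"], "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_censoring_warns(self):
        cfg = _small_config(censoring_rate=0.0)
        genome, ann = simulate_genome_and_cpgs(cfg)
        _, _, truth = simulate_pwms_and_plant(genome, ann, cfg)
        with pytest.warns(UserWarning, match="degenerate"):
            _, clinical = simulate_phenotypes(ann, truth, cfg)
        assert (clinical["event"] == 1).all()

    def test_group_sizes_follow_fractions(self, tiny_dataset):
        frac = (tiny_dataset.clinical["ER"] == "ER+").mean()
        assert frac == pytest.approx(0.77, abs=0.02)


class TestTFEdges:
    def test_zero_probability_empty_edge_list(self):
        assert simulate_tf_edges(_small_config(edge_probability=0.0)).empty

    def test_probability_one_complete_graph(self):
        cfg = _small_config(edge_probability=1.0, n_tf_nodes=4)
        edges = simulate_tf_edges(cfg, tf_names=["A", "B", "C", "D"])
        assert len(edges) == 6

    def test_fixed_seed_identical_edges(self):
        cfg = _small_config(edge_probability=0.4)
        e1 = simulate_tf_edges(cfg, tf_names=["A", "B"])
        e2 = simulate_tf_edges(cfg, tf_names=["A", "B"])
        assert e1.equals(e2)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            simulate_tf_edges(_small_config(n_tf_nodes=1))


class TestConfigValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            _small_config(plant_rate_foreground=1.5)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            _small_config(group_fractions={"a": 0.5, "b": 0.2})

    def test_chromosome_must_exceed_region(self):
        with pytest.raises(ValueError):
            _small_config(chrom_length=102)


def test_simulate_all_fixed_seed_reproducible(tiny_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d1 = simulate_all(tiny_config)
        d2 = simulate_all(tiny_config)
    assert d1.genome == d2.genome
    assert d1.beta.equals(d2.beta)
    assert d1.clinical.equals(d2.clinical)
    assert d1.tf_edges.equals(d2.tf_edges)
    assert d1.truth.causal_cpg_ids == d2.truth.causal_cpg_ids
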