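"""Generator behavior: drift model, polyploid sampling, depths, determinism."""

import hashlib

import numpy as np
import pytest
from scipy import stats

import polyorigin as po
from polyorigin.simdata import _balding_nichols

from conftest import make_freq_table, make_genotypes, make_sites


class TestSpeciesFrequencies:
    def test_zero_drift_limit_recovers_ancestral_frequencies(self):
        cfg = po.SimConfig(
            n_loci=1000,
            seed=5,
            clade_f=1e-6,
            divergence={s: 1e-6 for s in po.simdata.DEFAULT_SPECIES},
        )
        table = po.draw_species_frequencies(cfg)
        assert np.max(np.abs(table.freq - table.p0[None, :])) < 0.01

    def test_degenerate_frequencies_stay_fixed(self):
        rng = np.random.default_rng(0)
        p = np.array([0.0, 1.0, 0.5])
        out = _balding_nichols(rng, p, 0.3)
        assert out[0] == 0.0 and out[1] == 1.0 and 0 < out[2] < 1

    def test_mean_frequency_unbiased_under_drift(self):
        cfg = po.SimConfig(n_loci=10_000, seed=11, divergence={s: 0.1 for s in po.simdata.DEFAULT_SPECIES})
        table = po.draw_species_frequencies(cfg)
        for s in cfg.species_labels:
            diff = table.freq_of(s) - table.p0
            assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(len(diff))

    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError, match="divergence F"):
            po.SimConfig(divergence={s: 1.5 for s in po.simdata.DEFAULT_SPECIES})


class TestGeneFlow:
    def test_identity_full_replacement_and_midpoint(self):
        table = make_freq_table({"A": [0.8, 0.3], "B": [0.2, 0.6]})
        same = po.apply_gene_flow(table, "A", "B", 0.0)
        assert np.array_equal(same.freq, table.freq)
        full = po.apply_gene_flow(table, "A", "B", 1.0)
        assert np.array_equal(full.freq_of("B"), table.freq_of("A"))
        mid = po.apply_gene_flow(table, "A", "B", 0.5)
        assert mid.freq_of("B")[0] == pytest.approx(0.5)
        assert np.array_equal(mid.freq_of("A"), table.freq_of("A"))

    def test_errors(self):
        table = make_freq_table({"A": [0.5], "B": [0.5]})
        with pytest.raises(KeyError):
            po.apply_gene_flow(table, "A", "Z", 0.1)
        with pytest.raises(ValueError):
            po.apply_gene_flow(table, "A", "A", 0.1)


class TestGenotypeSampling:
    def test_diploid_fixed_loci_and_moments(self):
        table = make_freq_table({"A": [0.0, 1.0] + [0.3] * 100})
        g = po.sample_diploid_genotypes(table, "A", 500, seed=2)
        assert np.all(g.dosage[:, 0] == 0) and np.all(g.dosage[:, 1] == 2)
        mean = g.dosage[:, 2:].mean()
        se = np.sqrt(2 * 0.3 * 0.7 / (500 * 100))
        assert abs(mean - 0.6) < 3 * se

    def test_allotetraploid_fixed_heterozygosity_and_truth(self):
        table = make_freq_table({"A": [0.0, 1.0], "B": [1.0, 1.0]})
        g, truth = po.sample_allotetraploid(table, "A", "B", 50, seed=3)
        assert np.all(g.dosage[:, 0] == 2)  # p_A=0, p_B=1: every sample dosage 2
        assert np.all(g.dosage[:, 1] == 4)
        assert truth.inheritance_mode == "disomic"
        assert np.array_equal(truth.total_dosage(), g.dosage)

    def test_equal_parent_allotetraploid_matches_binomial(self):
        # convolution identity: Bin(2,q) + Bin(2,q) = Bin(4,q)
        q = 0.4
        table = make_freq_table({"A": [q], "B": [q]})
        g, _ = po.sample_allotetraploid(table, "A", "B", 2000, seed=9)
        obs = np.bincount(g.dosage[:, 0].astype(int), minlength=5)
        exp = 2000 * stats.binom.pmf(np.arange(5), 4, q)
        assert stats.chisquare(obs, exp).pvalue > 0.01

    def test_autotetraploid_class_frequencies(self):
        table = make_freq_table({"A": [0.5], "B": [0.0]})
        g, truth = po.sample_autotetraploid(table, "A", 5000, seed=4)
        freqs = np.bincount(g.dosage[:, 0].astype(int), minlength=5) / 5000
        exp = stats.binom.pmf(np.arange(5), 4, 0.5)
        assert truth.inheritance_mode == "tetrasomic"
        assert freqs[2] == pytest.approx(0.375, abs=3 * np.sqrt(0.375 * 0.625 / 5000))
        assert np.max(np.abs(freqs - exp)) < 0.02

    def test_allohexaploid_three_subgenomes(self):
        table = make_freq_table({"A": [1.0, 0.0, 0.5], "B": [1.0, 1.0, 0.5], "C": [1.0, 0.0, 0.5]})
        g, truth = po.sample_allohexaploid(table, "A", "B", "C", 2000, seed=5)
        assert np.all(g.dosage[:, 0] == 6)
        assert np.all(g.dosage[:, 1] == 2)
        obs = np.bincount(g.dosage[:, 2].astype(int), minlength=7)
        exp = 2000 * stats.binom.pmf(np.arange(7), 6, 0.5)
        assert stats.chisquare(obs, exp).pvalue > 0.01
        assert np.array_equal(truth.total_dosage(), g.dosage)
        with pytest.raises(ValueError):
            po.sample_allohexaploid(table, "A", "A", "B", 5, seed=1)


class TestReadDepths:
    def test_error_free_extremes(self):
        table = make_freq_table({"A": [0.0, 1.0]})
        g = po.sample_diploid_genotypes(table, "A", 100, seed=1)
        d = po.simulate_read_depths(g, mean_depth=30, error_rate=0.0, seed=2)
        assert np.all(d.alt_depth[:, 0] == 0)  # dosage 0
        assert np.all(d.alt_depth[:, 1] == d.total_depth[:, 1])  # dosage = ploidy

    def test_balanced_dosage_gives_half_ratio(self):
        table = make_freq_table({"A": [0.5] * 200, "B": [0.5] * 200})
        g, _ = po.sample_allotetraploid(table, "A", "B", 50, seed=6)
        g.dosage[:] = 2  # force balanced heterozygotes
        d = po.simulate_read_depths(g, mean_depth=60, error_rate=0.0, seed=7)
        nz = d.total_depth > 0
        ratios = d.alt_depth[nz] / d.total_depth[nz]
        se = np.sqrt(0.25 / (60 * nz.sum()))
        assert abs(ratios.mean() - 0.5) < 3 * se


class TestAlignments:
    def test_iupac_encoding_of_dosage(self):
        # dosages 0, 2, 4 of ploidy 4 at A/G sites -> 'A', 'R', 'G'
        sites = make_sites(120, ref="A", alt="G")
        dosage = np.tile([[0.0], [2.0], [4.0]], (1, 120))
        g = make_genotypes(dosage, ploidy=4, sites=sites)
        alns = po.genotypes_to_alignments(g, regions_per_chromosome=2, background_length=10, seed=0)
        col = {name: seq for name, seq in alns[0].sequences.items()}
        snp_cols = [i for i in range(len(col["s0"])) if len({col[s][i] for s in col}) > 1]
        assert all(col["s0"][i] == "A" and col["s1"][i] == "R" and col["s2"][i] == "G" for i in snp_cols)

    def test_all_homozygous_has_no_ambiguity_codes(self):
        sites = make_sites(60, ref="C", alt="T")
        g = make_genotypes(np.tile([[0.0], [2.0]], (1, 60)), ploidy=2, sites=sites)
        alns = po.genotypes_to_alignments(g, regions_per_chromosome=3, background_length=5, seed=1)
        joined = "".join(seq for a in alns for seq in a.sequences.values())
        assert set(joined) <= set("ACGT")


class TestStudyLevel:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = po.SimConfig(n_loci=200, samples_per_population=3, seed=77)
        for sub in ("a", "b"):
            po.write_study(po.simulate_study(cfg), tmp_path / sub)
        for name in ("simulated.vcf", "consensus.fasta", "popmap.tsv", "truth.json"):
            ha = hashlib.sha256((tmp_path / "a" / name).read_bytes()).hexdigest()
            hb = hashlib.sha256((tmp_path / "b" / name).read_bytes()).hexdigest()
            assert ha == hb, name

    def test_frequency_recovery(self):
        cfg = po.SimConfig(n_loci=1000, seed=21)
        table = po.draw_species_frequencies(cfg)
        g = po.sample_diploid_genotypes(table, "PAL", 500, seed=22)
        p_hat = g.dosage.mean(axis=0) / 2
        p = table.freq_of("PAL")
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / (2 * 500))
        frac_ok = np.mean(np.abs(p_hat - p) <= np.maximum(3 * se, 1e-9))
        assert frac_ok >= 0.99
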