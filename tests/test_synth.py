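"""Synthetic study generator: reference construction, trait model, bulks, pileups."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import chi2 as chi2_dist

import tetrabsa as tb
from tetrabsa.errors import PlacementError
from tetrabsa.synth import STOP_CODONS, spliced_cds

from conftest import run_contrast_stage


class TestConfig:
    def test_bulk_size_bound(self):
        with pytest.raises(ValueError):
            tb.SimConfig(n_population=30, bulk_size=18)

    def test_gc_bounds(self):
        with pytest.raises(ValueError):
            tb.SimConfig(gc_fraction=1.2)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            tb.SimConfig(broken_pair_rate=-0.1)


class TestReference:
    def test_gc_fraction_within_band(self):
        cfg = tb.SimConfig(seed=2, n_contigs=1, contig_length=50_000)
        ref = tb.generate_reference(cfg)
        seq = ref.sequences["contig1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.34 <= gc <= 0.38

    def test_both_strands_and_cds_structure(self, small_study):
        genes = small_study.reference.genes
        assert {g.strand for g in genes} == {"+", "-"}
        for g in genes:
            assert g.cds_length % 3 == 0
            assert len(g.segments) == 2  # multi-segment chains

    def test_no_internal_stop_codons(self, small_study):
        """Brute-force translation of every generated CDS."""
        for gene in small_study.reference.genes:
            coding = spliced_cds(small_study.reference, gene)
            codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
            assert not any(c in STOP_CODONS for c in codons)
            assert "*" not in str(Seq(coding).translate())

    def test_sizing_error_when_contig_too_short(self):
        with pytest.raises(Exception) as err:
            tb.generate_reference(tb.SimConfig(contig_length=2000, n_genes_per_contig=10))
        assert "stride" in str(err.value)


class TestGenotypesAndTrait:
    def test_zero_effect_gives_no_dosage_trait_correlation(self):
        cfg = tb.SimConfig(seed=4, n_contigs=1, contig_length=20_000, n_genes_per_contig=6,
                           causal_effect_size=0.0, n_neutral_sites=10)
        ref = tb.generate_reference(cfg)
        population, truth = tb.assign_genotypes_and_trait(cfg, ref)
        site = next(t for t in truth if t.is_causal)
        dosages = np.array([g.dosages[site.site_id] for g in population])
        traits = np.array([g.trait_value for g in population])
        r = np.corrcoef(dosages, traits)[0, 1]
        assert abs(r) < 0.2  # ~3 SE at n=232

    def test_single_strong_causal_site_separates_bulk_dosages(self):
        cfg = tb.SimConfig(seed=5, n_contigs=1, contig_length=20_000, n_genes_per_contig=6,
                           n_causal_sites=1, causal_effect_size=0.1, trait_noise_sd=0.01,
                           n_neutral_sites=5)
        ref = tb.generate_reference(cfg)
        population, truth = tb.assign_genotypes_and_trait(cfg, ref)
        low, high = tb.select_bulks(population, cfg.bulk_size)
        site = next(t for t in truth if t.is_causal)
        by_id = {g.individual_id: g for g in population}
        mean_low = np.mean([by_id[i].dosages[site.site_id] for i in low])
        mean_high = np.mean([by_id[i].dosages[site.site_id] for i in high])
        assert mean_high > mean_low

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_default_calibration_reproduces_bulk_trait_means(self, seed):
        """Tail means of the default population land near 1.03 / 1.48 %dmb."""
        study = tb.simulate_study(tb.SimConfig(seed=seed))
        by_id = {g.individual_id: g for g in study.population}
        low_mean = np.mean([by_id[i].trait_value for i in study.low_bulk_ids])
        high_mean = np.mean([by_id[i].trait_value for i in study.high_bulk_ids])
        assert low_mean == pytest.approx(1.03, abs=0.15)
        assert high_mean == pytest.approx(1.48, abs=0.15)

    def test_placement_error_when_requesting_too_many_sites(self):
        cfg = tb.SimConfig(seed=1, n_contigs=1, contig_length=20_000, n_genes_per_contig=6,
                           n_neutral_sites=100_000)
        ref = tb.generate_reference(cfg)
        with pytest.raises(PlacementError):
            tb.assign_genotypes_and_trait(cfg, ref)

    def test_expected_freqs_are_exact_pooled_dosage_means(self, small_study):
        by_id = {g.individual_id: g for g in small_study.population}
        for t in small_study.truth[:10]:
            manual = sum(by_id[i].dosages[t.site_id] for i in small_study.low_bulk_ids) / (
                4 * len(small_study.low_bulk_ids)
            )
            assert t.expected_freq_low_bulk == manual


class TestSelectBulks:
    def test_full_population_disjoint_bulks(self, small_study):
        low, high = small_study.low_bulk_ids, small_study.high_bulk_ids
        assert len(low) == len(high) == 18
        assert not set(low) & set(high)

    def test_identical_traits_tie_break_by_id(self):
        pop = [tb.IndividualGenotype(individual_id=i, dosages={}, trait_value=1.0) for i in range(40)]
        low, high = tb.select_bulks(pop, 5)
        assert low == (0, 1, 2, 3, 4)
        assert high == (35, 36, 37, 38, 39)

    def test_population_of_exactly_twice_bulk_size_partitions(self):
        rng = np.random.default_rng(8)
        pop = [tb.IndividualGenotype(individual_id=i, dosages={}, trait_value=float(v))
               for i, v in enumerate(rng.normal(size=36))]
        low, high = tb.select_bulks(pop, 18)
        assert sorted(low + high) == list(range(36))

    def test_too_small_population_rejected(self):
        pop = [tb.IndividualGenotype(individual_id=i, dosages={}, trait_value=float(i)) for i in range(10)]
        with pytest.raises(ValueError):
            tb.select_bulks(pop, 18)


class TestPileups:
    def test_homozygous_alternate_no_error_gives_pure_alt_column(self):
        cfg = tb.SimConfig(seed=6, n_contigs=1, contig_length=20_000, n_genes_per_contig=6,
                           n_neutral_sites=2, seq_error_from_phred=False)
        ref = tb.generate_reference(cfg)
        population, truth = tb.assign_genotypes_and_trait(cfg, ref)
        site = truth[0]
        for g in population:
            g.dosages[site.site_id] = 4  # fix the bulk homozygous alternate
        low, _ = tb.select_bulks(population, cfg.bulk_size)
        pileup = tb.simulate_bulk_pileup(low, population, truth, cfg, 30, seed=1)
        obs = pileup[(site.contig, site.position)]
        assert (obs.bases == site.alt_allele).all()

    def test_high_depth_frequency_converges_to_pool_fraction(self):
        """Binomial law-of-large-numbers check at depth 10^4, error off."""
        cfg = tb.SimConfig(seed=9, n_contigs=1, contig_length=20_000, n_genes_per_contig=6,
                           n_neutral_sites=5, seq_error_from_phred=False)
        ref = tb.generate_reference(cfg)
        population, truth = tb.assign_genotypes_and_trait(cfg, ref)
        low, _ = tb.select_bulks(population, cfg.bulk_size)
        pileup = tb.simulate_bulk_pileup(low, population, truth, cfg, 10_000, seed=2)
        for t in truth:
            p = tb.pooled_alt_fraction(population, low, t.site_id, cfg.ploidy)
            obs = pileup[(t.contig, t.position)]
            observed = (obs.bases == t.alt_allele).mean()
            assert observed == pytest.approx(p, abs=0.02)

    def test_mean_depth_tracks_configured_coverage(self):
        study = tb.simulate_study(tb.SimConfig(seed=3))
        mean_low = np.mean([o.depth for o in study.pileup_low.values()])
        mean_high = np.mean([o.depth for o in study.pileup_high.values()])
        assert mean_low == pytest.approx(28, rel=0.10)
        assert mean_high == pytest.approx(40, rel=0.10)

    def test_allele_counts_conserve_depth(self, small_study):
        for obs in small_study.pileup_low.values():
            counts = sum(int((obs.bases == b).sum()) for b in "ACGT")
            assert counts == obs.depth

    def test_replayable_under_fixed_seed(self, small_config):
        a = tb.simulate_study(small_config)
        b = tb.simulate_study(small_config)
        for key in a.pileup_low:
            assert (a.pileup_low[key].bases == b.pileup_low[key].bases).all()
            assert (a.pileup_low[key].quals == b.pileup_low[key].quals).all()

    def test_coordinate_error_outside_reference(self, small_study):
        bad = [tb.TruthSite(site_id="x", contig="contig1", position=10**7, ref_allele="A",
                            alt_allele="C", is_causal=False, placement="intergenic")]
        for g in small_study.population:
            g.dosages["x"] = 0
        with pytest.raises(Exception):
            tb.simulate_bulk_pileup(
                small_study.low_bulk_ids, small_study.population, bad,
                small_study.config, 30, seed=0, reference=small_study.reference,
            )


class TestNullCalibration:
    def test_null_significant_fraction_matches_overdispersion_prediction(self, default_params):
        """With zero causal effect the chi-square null rate is NOT nominal:
        between-bulk pool-composition variance (72 chromosomes per bulk)
        inflates the statistic by ~1.4x at these depths. The observed rate
        must sit above the nominal band and near the inflation-corrected
        prediction P(chi2_1 > 3.84 / lambda)."""
        sig = n = 0
        for seed in range(4):
            cfg = tb.SimConfig(seed=seed, n_causal_sites=0, n_neutral_sites=250,
                               causal_effect_size=0.0)
            study = tb.simulate_study(cfg)
            _, _, contrasts = run_contrast_stage(study, default_params)
            comp = [b for b in contrasts if not b.incomparable]
            sig += sum(b.p_value < 0.05 for b in comp)
            n += len(comp)
        rate = sig / n
        keep = (1 - 0.02) * (1 - 0.02)
        d_low, d_high = 28 * keep, 40 * keep
        fpc = (232 - 18) / (232 - 1)
        lam = 1 + (2 * fpc / 72) / (1 / d_low + 1 / d_high)
        predicted = float(chi2_dist.sf(chi2_dist.isf(0.05, 1) / lam, 1))
        assert rate > 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)  # clearly above nominal
        assert rate == pytest.approx(predicted, abs=0.05)
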