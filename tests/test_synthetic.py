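"""Ground-truth landscape generator and read simulator."""

import json
import math

import numpy as np
import pytest

import ribofit as rf
from ribofit.synthetic import _pair_key


class TestLandscapeModel:
    def test_same_seed_gives_identical_models(self, ref69):
        a = rf.sample_landscape_model(ref69, seed=1)
        b = rf.sample_landscape_model(ref69, seed=1)
        assert a.to_json() == b.to_json()

    def test_different_seeds_differ(self, ref69):
        a = rf.sample_landscape_model(ref69, seed=1)
        b = rf.sample_landscape_model(ref69, seed=2)
        assert a.to_json() != b.to_json()

    def test_zero_epistasis_scale_means_no_background_terms(self, ref69):
        m = rf.sample_landscape_model(
            ref69, n_compensatory_pairs=0, epistasis_scale=0.0, seed=3
        )
        assert m.pairwise_terms == {}

    def test_compensatory_double_beats_both_singles(self, ref69):
        m = rf.sample_landscape_model(ref69, n_compensatory_pairs=3, seed=4)
        assert len(m.compensatory_pairs) == 3
        for i, j in m.compensatory_pairs:
            [(a, b)] = [
                pair
                for pair, w in m.pairwise_terms.items()
                if w > 0 and {pair[0].position, pair[1].position} == {i, j}
            ]
            double = rf.true_activity(m, rf.Genotype((a, b)))
            single_a = rf.true_activity(m, rf.Genotype((a,)))
            single_b = rf.true_activity(m, rf.Genotype((b,)))
            assert double > max(single_a, single_b)
            # each single break is deleterious relative to wild-type
            wt = rf.true_activity(m, rf.Genotype.wildtype())
            assert max(single_a, single_b) < wt / 2

    def test_too_many_pairs_rejected(self):
        ref = rf.ReferenceSequence("ACGU")
        with pytest.raises(ValueError):
            rf.sample_landscape_model(ref, n_compensatory_pairs=3, seed=0)

    def test_wildtype_activity_is_link_of_baseline(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=5)
        wt = rf.true_activity(m, rf.Genotype.wildtype())
        assert wt == pytest.approx(1 / (1 + math.exp(-m.baseline)))
        assert wt == pytest.approx(0.8, abs=1e-12)

    def test_activity_always_in_unit_interval(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=6)
        rng = np.random.default_rng(0)
        singles = rf.enumerate_single_mutants(ref69)
        for _ in range(50):
            idx = rng.choice(len(singles), 6, replace=False)
            muts = {singles[i].mutations[0] for i in idx}
            muts = {m_.position: m_ for m_ in muts}
            g = rf.Genotype(tuple(muts.values()))
            assert 0.0 <= rf.true_activity(m, g) <= 1.0

    def test_latent_matches_hand_sum_from_json_dump(self, ref69):
        """Order-3 activity equals the independently recomputed link(latent)."""
        m = rf.sample_landscape_model(
            ref69, seed=7, n_threeway_terms=5, threeway_scale=1.0
        )
        dump = json.loads(m.to_json())
        g = rf.Genotype.from_string("G1A;U20C;G25A", ref=ref69)
        latent = dump["baseline"]
        toks = [str(mm) for mm in g.mutations]
        for t in toks:
            latent += dump["additive_effects"][t]
        for key, w in dump["pairwise_terms"].items():
            if set(key.split(";")) <= set(toks):
                latent += w
        for key, w in dump["threeway_terms"].items():
            if set(key.split(";")) <= set(toks):
                latent += w
        expected = 1 / (1 + math.exp(-latent))
        assert rf.true_activity(m, g) == pytest.approx(expected, rel=1e-12)

    def test_json_round_trip(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=8, n_threeway_terms=3, threeway_scale=1.0)
        m2 = rf.LandscapeModel.from_json(m.to_json())
        g = rf.Genotype.from_string("G1A;U20C", ref=ref69)
        assert rf.true_activity(m2, g) == rf.true_activity(m, g)
        assert m2.to_json() == m.to_json()

    def test_exponential_link_is_multiplicative(self, ref69):
        """With the exp link and no epistasis terms, activities multiply."""
        m = rf.sample_landscape_model(
            ref69, n_compensatory_pairs=0, epistasis_scale=0.0, seed=9,
            link="exponential", neutral_prob=0.0,
        )
        wt = rf.true_activity(m, rf.Genotype.wildtype())
        g = rf.Genotype.from_string("G1A;U20C", ref=ref69)
        a, b = (rf.Genotype((mm,)) for mm in g.mutations)
        lhs = rf.true_activity(m, g) * wt
        rhs = rf.true_activity(m, a) * rf.true_activity(m, b)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestDopedLibrary:
    def test_zero_rate_gives_all_wildtype(self, ref69):
        lib = rf.sample_doped_library(
            ref69, rf.DopedLibraryConfig(0.0, 200, seed=1)
        )
        assert all(g.is_wildtype for g in lib)

    def test_mean_order_matches_binomial(self, ref69):
        n = 100_000
        lib = rf.sample_doped_library(
            ref69, rf.DopedLibraryConfig(0.03, n, seed=2)
        )
        orders = np.array([g.order for g in lib])
        expected = 69 * 0.03
        se = math.sqrt(69 * 0.03 * 0.97 / n)
        assert abs(orders.mean() - expected) < 3 * se

    def test_fixed_seed_reproducible(self, ref69):
        cfg = rf.DopedLibraryConfig(0.05, 500, seed=3)
        a = rf.sample_doped_library(ref69, cfg)
        b = rf.sample_doped_library(ref69, cfg)
        assert list(map(str, a)) == list(map(str, b))

    def test_alt_bases_never_equal_reference(self, ref69):
        lib = rf.sample_doped_library(ref69, rf.DopedLibraryConfig(0.1, 200, seed=4))
        for g in lib:
            for m in g.mutations:
                assert m.ref_base == ref69.base_at(m.position)
                assert m.alt_base != m.ref_base


class TestReadSimulation:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            rf.ReadSimulationConfig(upstream_seq="", primer_site="ACGU")
        with pytest.raises(ValueError):
            rf.ReadSimulationConfig(upstream_seq="ACGU", primer_site="ACGUACGU")

    def _reads(self, model, gens, **kw):
        cfg = rf.ReadSimulationConfig(**kw)
        return cfg, list(rf.simulate_reads(model, gens, cfg))

    def test_saturated_activity_means_no_upstream(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=1)
        m.baseline = 60.0  # activity -> 1
        cfg, reads = self._reads(m, [rf.Genotype.wildtype()], mean_depth=50, seed=2)
        up_dna = cfg.upstream_seq.replace("U", "T")
        assert all(up_dna not in r.sequence for r in reads)

    def test_zero_activity_means_all_upstream(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=1)
        m.baseline = -60.0  # activity -> 0
        cfg, reads = self._reads(m, [rf.Genotype.wildtype()], mean_depth=50, seed=2)
        up_dna = cfg.upstream_seq.replace("U", "T")
        assert all(r.sequence.startswith(up_dna) for r in reads)

    def test_cleaved_fraction_within_binomial_error(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=1)
        p = 0.37
        m.baseline = math.log(p / (1 - p))
        depth = 10_000
        cfg, reads = self._reads(m, [rf.Genotype.wildtype()], mean_depth=depth, seed=3)
        up_dna = cfg.upstream_seq.replace("U", "T")
        frac = sum(1 for r in reads if up_dna not in r.sequence) / len(reads)
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / depth)

    def test_depth_dispersion_varies_per_genotype_depth(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=1)
        gens = rf.enumerate_single_mutants(ref69)[:30]
        cfg = rf.ReadSimulationConfig(mean_depth=50, depth_dispersion=1.0, seed=4)
        table, _ = rf.count_genotypes(
            rf.simulate_reads(m, gens, cfg),
            ref69,
            upstream_seq=cfg.upstream_seq,
            primer_site=cfg.primer_site,
            mode="match_list",
            expected_genotypes=gens,
        )
        depths = table.data["total"].to_numpy()
        assert depths.std() > 0  # overdispersion actually varied depth
        # with dispersion 0, every genotype gets exactly the mean depth
        cfg0 = rf.ReadSimulationConfig(mean_depth=50, depth_dispersion=0.0, seed=4)
        table0, _ = rf.count_genotypes(
            rf.simulate_reads(m, gens, cfg0),
            ref69,
            upstream_seq=cfg0.upstream_seq,
            primer_site=cfg0.primer_site,
            mode="match_list",
            expected_genotypes=gens,
        )
        assert set(table0.data["total"]) == {50}

    def test_fastq_output_and_round_trip(self, ref69, tmp_path):
        m = rf.sample_landscape_model(ref69, seed=1)
        gens = [rf.Genotype.wildtype()] + rf.enumerate_single_mutants(ref69)[:5]
        cfg = rf.ReadSimulationConfig(mean_depth=20, seed=5)
        path = tmp_path / "reads.fastq"
        reads = list(rf.simulate_reads(m, gens, cfg, fastq_path=path))
        from ribofit.reads import read_fastq

        parsed = list(read_fastq(path))
        assert len(parsed) == len(reads)
        assert [r.sequence for r in parsed] == [r.sequence for r in reads]


class TestSimulateActivityTable:
    def test_row_per_genotype(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=1)
        gens = [rf.Genotype.wildtype()] + rf.enumerate_single_mutants(ref69)[:10]
        table = rf.simulate_activity_table(m, gens, depth=100, seed=2)
        assert len(table) == len(gens)

    def test_high_depth_converges_to_true_activity(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=1)
        gens = [rf.Genotype.wildtype()] + rf.enumerate_single_mutants(ref69)[:20]
        table = rf.simulate_activity_table(m, gens, depth=1_000_000, seed=3)
        for g in gens:
            assert table.activity_of(g) == pytest.approx(
                rf.true_activity(m, g), abs=5e-3
            )

    def test_fixed_seed_reproducible(self, ref69):
        m = rf.sample_landscape_model(ref69, seed=1)
        gens = rf.enumerate_single_mutants(ref69)[:10]
        a = rf.simulate_activity_table(m, gens, depth=50, seed=7)
        b = rf.simulate_activity_table(m, gens, depth=50, seed=7)
        assert a.data.equals(b.data)

    def test_agrees_with_read_pipeline_within_binomial_bounds(self, ref69):
        """FASTQ-derived fractions match direct binomial sampling to 3 sigma."""
        m = rf.sample_landscape_model(ref69, seed=1)
        gens = [rf.Genotype.wildtype()] + rf.enumerate_single_mutants(ref69)[:20]
        depth = 2000
        cfg = rf.ReadSimulationConfig(mean_depth=depth, seed=11)
        table_reads, summary = rf.count_genotypes(
            rf.simulate_reads(m, gens, cfg),
            ref69,
            upstream_seq=cfg.upstream_seq,
            primer_site=cfg.primer_site,
            mode="match_list",
            expected_genotypes=gens,
        )
        assert summary["rejected"] == 0
        table_binom = rf.simulate_activity_table(m, gens, depth=depth, seed=12)
        for g in gens:
            p = rf.true_activity(m, g)
            bound = 3 * math.sqrt(max(p * (1 - p), 1e-9) / depth)
            assert abs(table_reads.activity_of(g) - p) <= bound + 1e-9
            assert abs(table_binom.activity_of(g) - p) <= bound + 1e-9
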