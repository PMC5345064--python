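"""Forward Wright-Fisher simulator: mutation model, demography, sampling."""

import numpy as np
import pytest
from scipy.stats import spearmanr, wilcoxon

from popdrift import (
    MutationModel,
    SamplingDesign,
    allele_counts,
    expected_heterozygosity,
    make_study_design,
    make_study_scenarios,
    rate_of_change,
    simulate_site,
)
from popdrift.simulate import (
    DemographyScenario,
    constant_scenario,
    crash_scenario,
    feasible_design,
)


class TestMutationModel:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MutationModel(rate=0.2)
        with pytest.raises(ValueError):
            MutationModel(p_multistep=1.5)

    def test_step_law(self):
        m = MutationModel(p_multistep=0.10, multistep_mean=2.8)
        rng = np.random.default_rng(0)
        steps = m.draw_steps(200_000, rng)
        assert set(np.unique(np.sign(steps))) == {-1, 1}
        # ~90% single steps; mean |multistep| ~ 2.8
        multi = np.abs(steps) > 1
        assert abs(multi.mean() - 0.10 * (1 - 1 / 2.8)) < 0.01  # geometric can hit 1
        assert abs(np.abs(steps)[np.abs(steps) > 0].mean()
                   - (0.9 * 1 + 0.1 * 2.8)) < 0.05


class TestDesignArithmetic:
    def test_study_design_has_seven_years(self):
        d = make_study_design()
        assert len(d.sample_years) == 7
        assert d.generation_time == 3 and d.anchor_year == 2015

    def test_generation_index_rounding(self):
        d = make_study_design()
        assert d.generation_index(2005) == round((2015 - 2005) / 3) == 3
        assert d.generation_index(2015) == 0
        assert d.generation_index(2014) == 0  # same generation as anchor
        assert d.generation_index(2012) == 1

    def test_small_sample_override(self):
        d = make_study_design().with_override("Mangokuura", 2013, 12)
        assert d.sample_size("Mangokuura", 2013) == 12
        assert d.sample_size("Mangokuura", 2012) == 43


class TestScenarios:
    def test_no_crash_sites_are_constant(self):
        scen = make_study_scenarios(base_ne=100)
        traj = scen["Sokanzan"].trajectory
        assert len(set(traj.values())) == 1

    def test_severe_crash_magnitude(self):
        scen = make_study_scenarios(base_ne=500)
        t = scen["Torinoumi"].trajectory
        pre, post = t[max(t)], t[0]
        assert rate_of_change(pre, post) == pytest.approx(-99, abs=1.5)

    def test_crash_lands_at_2011_generation(self):
        scen = make_study_scenarios(base_ne=100)
        s = scen["Mangokuura"]
        assert s.crash_generation == 1
        assert s.trajectory[2] == 100 and s.trajectory[1] < 100

    def test_invalid_trajectories_rejected(self):
        with pytest.raises(ValueError):
            DemographyScenario(site="x", trajectory={})
        with pytest.raises(ValueError):
            DemographyScenario(site="x", trajectory={0: 1})


class TestSimulateSite:
    DESIGN = SamplingDesign(sample_years=(2010, 2015), n_default=10,
                            anchor_year=2015)

    def test_no_mutation_is_monomorphic(self):
        samples = simulate_site(
            constant_scenario("x", 30, 2), MutationModel(rate=0.0),
            n_loci=3, design=self.DESIGN, seed=0,
        )
        for s in samples.values():
            for j in range(3):
                assert len(allele_counts(s, j)) == 1

    def test_fixed_seed_is_bit_reproducible(self, tpm):
        a = simulate_site(constant_scenario("x", 30, 2), tpm, 3, self.DESIGN, 5)
        b = simulate_site(constant_scenario("x", 30, 2), tpm, 3, self.DESIGN, 5)
        for y in a:
            assert np.array_equal(a[y].genotypes, b[y].genotypes)

    def test_reflection_floor_respected(self):
        hot = MutationModel(rate=0.05, p_multistep=0.5, reflection_floor=5)
        samples = simulate_site(constant_scenario("x", 30, 2), hot, 3,
                                self.DESIGN, 1, founder_repeats=6)
        for s in samples.values():
            present = s.genotypes[s.genotypes > 0]
            assert (present // 2 >= 5).all()  # repeat units >= floor

    def test_oversized_sample_rejected(self, tpm):
        design = SamplingDesign(sample_years=(2015,), n_default=50,
                                anchor_year=2015)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_site(constant_scenario("x", 30, 0), tpm, 2, design, 0)

    def test_smm_equilibrium_matches_closed_form(self):
        """Mean He over many loci vs the SMM closed form 1 - 1/sqrt(1+8*Ne*mu)."""
        smm = MutationModel(rate=5e-4, p_multistep=0.0)
        design = SamplingDesign(sample_years=(2015,), n_default=100,
                                anchor_year=2015)
        sample = simulate_site(constant_scenario("c", 500, 0), smm,
                               n_loci=200, design=design, seed=7)[2015]
        hes = [expected_heterozygosity(allele_counts(sample, j))
               for j in range(200)]
        closed = 1 - 1 / np.sqrt(1 + 8 * 500 * 5e-4)
        sd = np.std(hes) / np.sqrt(len(hes))
        assert abs(np.mean(hes) - closed) < 3 * sd

    def test_crash_reduces_allele_number(self, tpm_rich):
        """500 -> 25 at the 2011 generation: fewer alleles after, over seeds.

        Sampled two generations post-crash (the study's final survey year):
        a sample cannot see the bottleneck in the founding generation
        itself, because the founders are an i.i.d. draw from the parental
        gene pool; allele loss accrues with WF generations at low Ne.
        """
        design = SamplingDesign(sample_years=(2010, 2015), n_default=20,
                                anchor_year=2015)
        diffs = []
        for seed in range(50):
            samples = simulate_site(crash_scenario("x", 500, 25, 1, 2),
                                    tpm_rich, 6, design, seed=100 + seed)
            k_pre = np.mean([len(allele_counts(samples[2010], j))
                             for j in range(6)])
            k_post = np.mean([len(allele_counts(samples[2015], j))
                              for j in range(6)])
            diffs.append(k_pre - k_post)
        assert wilcoxon(diffs, alternative="greater").pvalue < 0.01

    def test_temporal_variance_tracks_cumulative_drift(self, tpm_rich):
        """Allele-frequency divergence between 2005 and 2015 samples grows
        with 1 - prod(1 - 1/(2N_g)) across demographies."""
        design = SamplingDesign(sample_years=(2005, 2015), n_default=40,
                                anchor_year=2015)
        drifts, divergences = [], []
        for ne in (500, 120, 50):
            expected_f = 1 - (1 - 1 / (2 * ne)) ** 3
            for seed in (1, 2, 3):
                samples = simulate_site(constant_scenario("x", ne, 3),
                                        tpm_rich, 8, design, seed=seed)
                fs = []
                for j in range(8):
                    c0 = allele_counts(samples[2005], j)
                    c1 = allele_counts(samples[2015], j)
                    alleles = sorted(set(c0) | set(c1))
                    n0 = sum(c0.values())
                    n1 = sum(c1.values())
                    p0 = np.array([c0.get(a, 0) / n0 for a in alleles])
                    p1 = np.array([c1.get(a, 0) / n1 for a in alleles])
                    z = (p0 + p1) / 2
                    ok = z > 0
                    fs.append(np.mean((p0 - p1)[ok] ** 2 / (z * (1 - z))[ok]))
                drifts.append(expected_f)
                divergences.append(np.mean(fs))
        rho = spearmanr(drifts, divergences).statistic
        assert rho > 0

    def test_feasible_design_clips_to_ne(self, tpm):
        design = make_study_design(n_default=43)
        scen = make_study_scenarios(base_ne=500)
        clipped = feasible_design(design, scen)
        assert clipped.sample_size("Torinoumi", 2013) == scen["Torinoumi"].trajectory[1]
        assert clipped.sample_size("Sokanzan", 2013) == 43
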