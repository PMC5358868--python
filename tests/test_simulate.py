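"""Synthetic-data generator: expectations, sampling model, reproducibility."""

import math

import numpy as np
import pandas as pd
import pytest

from ddquant import (
    KFactor,
    QpcrSimConfig,
    SimulationScenario,
    SpeciesPair,
    estimate_copies_per_partition,
    expected_concentrations,
    k_from_equal_mass,
    mass_fraction,
    quantify_replicates,
    simulate_study,
    simulate_well,
)
from ddquant.pipeline import pairs_from_counts
from ddquant.io import RunConfig
from ddquant.types import PartitionCount


class TestExpectedConcentrations:
    def test_equal_mass_ratio_equals_k(self):
        sc = SimulationScenario(true_fraction_percent=50.0, k_true=0.8)
        qa, qb = expected_concentrations(sc)
        assert qb / qa == pytest.approx(0.8)

    def test_zero_fraction_has_no_adulterant(self):
        qa, _ = expected_concentrations(
            SimulationScenario(true_fraction_percent=0.0))
        assert qa == 0.0

    def test_ten_percent_copy_ratio_matches_published_series(self):
        # Qc/Qs = (1/9)/0.8 ~ 0.1389; the published triplicate means at
        # 10% give ~0.140 — agreement within 1%
        sc = SimulationScenario(true_fraction_percent=10.0, k_true=0.8)
        qa, qb = expected_concentrations(sc)
        assert qa / qb == pytest.approx((1 / 9) / 0.8, rel=1e-12)
        published = np.mean([103, 100, 99]) / np.mean([714, 718, 721])
        assert qa / qb == pytest.approx(published, rel=0.01)

    def test_retention_scales_each_species(self):
        base = SimulationScenario(true_fraction_percent=50.0)
        degraded = SimulationScenario(true_fraction_percent=50.0,
                                      retention_adulterant=0.7)
        qa0, qb0 = expected_concentrations(base)
        qa1, qb1 = expected_concentrations(degraded)
        assert qa1 == pytest.approx(0.7 * qa0)
        assert qb1 == qb0


class TestSimulateWell:
    def test_zero_concentration_zero_fp_gives_no_positives(self, rng):
        sc = SimulationScenario(true_fraction_percent=50.0)
        w = simulate_well(0.0, sc, rng)
        assert w.positives == 0

    def test_binomial_moments_at_half_occupancy(self, rng):
        # lambda = ln 2 -> p = 1/2 -> mean positives 10000
        sc = SimulationScenario(true_fraction_percent=50.0)
        conc = math.log(2) / (0.85e-3)
        draws = [simulate_well(conc, sc, rng).positives for _ in range(1000)]
        se = math.sqrt(20000 * 0.25 / 1000)
        assert abs(np.mean(draws) - 10000) < 3 * se

    def test_false_positive_rate_floors_occupancy(self, rng):
        sc = SimulationScenario(true_fraction_percent=50.0,
                                false_positive_rate=0.01)
        draws = [simulate_well(0.0, sc, rng).positives for _ in range(200)]
        assert np.mean(draws) == pytest.approx(200.0, rel=0.1)

    def test_deterministic_under_fixed_seed(self):
        sc = SimulationScenario(true_fraction_percent=50.0)
        a = simulate_well(300.0, sc, np.random.default_rng(7)).positives
        b = simulate_well(300.0, sc, np.random.default_rng(7)).positives
        assert a == b


class TestSimulateStudy:
    FRACS = (80.0, 50.0, 20.0, 10.0, 5.0)

    def test_seeded_runs_bit_reproducible(self):
        scens = [SimulationScenario(true_fraction_percent=f) for f in self.FRACS]
        a = simulate_study(scens, seed=11, qpcr=QpcrSimConfig())
        b = simulate_study(scens, seed=11, qpcr=QpcrSimConfig())
        pd.testing.assert_frame_equal(a.droplets, b.droplets)
        pd.testing.assert_frame_equal(a.qpcr_standards, b.qpcr_standards)
        pd.testing.assert_frame_equal(a.qpcr_unknowns, b.qpcr_unknowns)

    def test_truth_record_scores_recovery(self):
        scens = [SimulationScenario(true_fraction_percent=f) for f in self.FRACS]
        ds = simulate_study(scens, seed=3)
        assert set(ds.truth.columns) >= {
            "sample_id", "true_fraction_percent", "k_true",
            "expected_conc_adulterant", "expected_conc_base",
        }
        assert len(ds.truth) == len(self.FRACS)
        # 2 targets x replicates wells per scenario
        assert len(ds.droplets) == sum(2 * s.replicates for s in scens)

    @staticmethod
    def _recover(ds, k):
        config = RunConfig(k_value=k)
        counts = [
            PartitionCount(r.sample_id, r.target, r.replicate,
                           r.positives, r.total_droplets)
            for r in ds.droplets.itertuples()
        ]
        out = {}
        for sample, pairs in pairs_from_counts(counts, config).items():
            out[sample] = quantify_replicates(pairs, k).fraction_percent
        return out

    def test_end_to_end_recovery_within_one_percent(self):
        # simulate -> estimate -> calibrate k on 50/50 -> quantify:
        # mean absolute bias < 1% across 5-80% (clean conditions)
        ref = simulate_study(
            [SimulationScenario(true_fraction_percent=50.0, replicates=6,
                                pipetting_cv=0.0)],
            seed=101,
        )
        config = RunConfig(k_value=0.8)
        counts = [
            PartitionCount(r.sample_id, r.target, r.replicate,
                           r.positives, r.total_droplets)
            for r in ref.droplets.itertuples()
        ]
        pairs = [p for ps in pairs_from_counts(counts, config).values()
                 for p in ps]
        k = k_from_equal_mass(pairs)

        scens = [SimulationScenario(true_fraction_percent=f, pipetting_cv=0.0)
                 for f in self.FRACS]
        ds = simulate_study(scens, seed=102)
        recovered = self._recover(ds, k.value)
        truth = dict(zip(ds.truth.sample_id, ds.truth.true_fraction_percent))
        biases = [abs(100 * (recovered[s] - t) / t) for s, t in truth.items()]
        assert np.mean(biases) < 1.0

    def test_equal_retention_cancels_in_k(self):
        scens = [
            SimulationScenario(true_fraction_percent=50.0, replicates=6,
                               pipetting_cv=0.0,
                               retention_adulterant=r, retention_base=r)
            for r in (1.0, 0.6)
        ]
        ks = []
        for sc in scens:
            qa, qb = expected_concentrations(sc)
            ks.append(qb / qa)
        assert ks[0] == pytest.approx(ks[1], rel=1e-12)

    def test_unequal_retention_bias_matches_closed_form(self):
        # retention 0.7 on the adulterant at f=50% shifts the measured
        # mass ratio to 0.7, i.e. fraction 100*0.7/1.7 = 41.18%
        sc = SimulationScenario(true_fraction_percent=50.0, replicates=8,
                                retention_adulterant=0.7, pipetting_cv=0.0)
        ds = simulate_study([sc], seed=55)
        recovered = self._recover(ds, k=sc.k_true)
        expected = 100 * 0.7 / 1.7
        assert recovered[sc.label] == pytest.approx(expected, abs=0.75)

    def test_bias_grows_with_retention_imbalance(self):
        # noise-free expectation: stronger differential degradation,
        # larger |bias| in the recovered fraction
        biases = []
        for ra in (1.0, 0.9, 0.7, 0.5):
            sc = SimulationScenario(true_fraction_percent=50.0,
                                    retention_adulterant=ra)
            qa, qb = expected_concentrations(sc)
            frac = mass_fraction(SpeciesPair(qa, qb),
                                 KFactor.fixed(sc.k_true)).fraction_percent
            biases.append(abs(frac - 50.0))
        assert biases == sorted(biases)
        assert biases[0] == pytest.approx(0.0, abs=1e-9)

    def test_qpcr_tables_recover_standard_curves(self):
        # noiseless Ct tables must refit to the configured coefficients
        qp = QpcrSimConfig(ct_noise_sd=0.0)
        ds = simulate_study(
            [SimulationScenario(true_fraction_percent=50.0)], seed=1, qpcr=qp)
        from ddquant import fit_standard_curve, CtObservation
        for target, slope, intercept in (
            ("chicken", qp.slope_adulterant, qp.intercept_adulterant),
            ("sheep", qp.slope_base, qp.intercept_base),
        ):
            sub = ds.qpcr_standards[ds.qpcr_standards.target == target]
            obs = [CtObservation(r.sample_id, r.target, r.ct, r.log10_copies)
                   for r in sub.itertuples()]
            curve = fit_standard_curve(obs)
            assert curve.slope == pytest.approx(slope, abs=1e-9)
            assert curve.intercept == pytest.approx(intercept, abs=1e-9)

    def test_qpcr_unknowns_unbiased_without_matrix_shift(self):
        # with the virtual-concentration convention and no Ct shift the
        # qPCR route recovers the mass fraction in expectation
        qp = QpcrSimConfig(ct_noise_sd=0.0)
        sc = SimulationScenario(true_fraction_percent=20.0)
        ds = simulate_study([sc], seed=9, qpcr=qp)
        from ddquant import fit_standard_curve, ct_to_copies, qpcr_fraction, CtObservation
        curves = {}
        for target in ("chicken", "sheep"):
            sub = ds.qpcr_standards[ds.qpcr_standards.target == target]
            curves[target] = fit_standard_curve(
                [CtObservation(r.sample_id, r.target, r.ct, r.log10_copies)
                 for r in sub.itertuples()])
        unk = ds.qpcr_unknowns
        c = {
            t: ct_to_copies(unk[unk.target == t].ct.iloc[0], curves[t])
            for t in ("chicken", "sheep")
        }
        assert qpcr_fraction(c["chicken"], c["sheep"]) == pytest.approx(20.0, abs=0.01)
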