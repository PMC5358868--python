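"""Multiplication-factor calibration and mass-fraction conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddquant import (
    InvalidInputError,
    KFactor,
    SimulationScenario,
    SpeciesPair,
    estimate_copies_per_partition,
    k_from_equal_mass,
    k_from_known_mixture,
    mass_fraction,
    quantify_replicates,
    simulate_well,
)
from ddquant.datasets import equal_mass_parallels, k_mixture_series


class TestEqualMassCalibration:
    def test_reference_parallels_reproduce_reported_summary(self):
        # six 50/50 w/w extractions: k rounds to 0.8, sample RSD to 3.1%
        k = k_from_equal_mass(equal_mass_parallels())
        assert round(k.value, 1) == 0.8
        assert round(k.rsd_percent, 1) == 3.1
        assert k.value == pytest.approx(np.mean(k.replicate_values))

    def test_symmetric_pairs_give_unit_k(self):
        pairs = [SpeciesPair(300.0, 300.0)] * 3
        k = k_from_equal_mass(pairs)
        assert k.value == 1.0
        assert k.rsd_percent == 0.0

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            k_from_equal_mass([SpeciesPair(335.33, 265.0)])

    def test_single_pair_ratio_via_known_mixture(self):
        # one 50/50 pair: Mc/Ms = 1 forces k = Qs/Qc = 265/335.33
        k = k_from_known_mixture(1.0, SpeciesPair(335.33, 265.0))
        assert k == pytest.approx(265.0 / 335.33, rel=1e-12)


class TestKnownMixtureCalibration:
    @staticmethod
    def _row_pair(row, series):
        chicken = np.mean([row[f"chicken_{i}"] for i in (1, 2, 3)])
        sheep = np.mean([row[f"sheep_{i}"] for i in (1, 2, 3)])
        return SpeciesPair(chicken, sheep)

    def test_ten_percent_row_rounds_to_published_k(self):
        series = k_mixture_series()
        row = series[series.chicken_percent == 10.0].iloc[0]
        k = k_from_known_mixture(0.1 / 0.9, self._row_pair(row, series))
        assert round(k, 1) == 0.8

    def test_eighty_percent_row(self):
        series = k_mixture_series()
        row = series[series.chicken_percent == 80.0].iloc[0]
        k = k_from_known_mixture(0.8 / 0.2, self._row_pair(row, series))
        assert k == pytest.approx(0.831, abs=0.001)

    def test_identity_when_ratio_equals_copy_ratio(self):
        assert k_from_known_mixture(1.25, SpeciesPair(500.0, 400.0)) == \
            pytest.approx(1.0)

    def test_invalid_mass_ratio_rejected(self):
        with pytest.raises(InvalidInputError):
            k_from_known_mixture(0.0, SpeciesPair(100.0, 100.0))

    @given(st.floats(min_value=0.02, max_value=0.98))
    def test_k_invariant_to_true_fraction_on_noise_free_input(self, f):
        # constant Cs/Cc: any mixture returns the same k
        k_true, cc = 0.8, 1000.0
        pair = SpeciesPair(f * cc, (1 - f) * k_true * cc)
        k = k_from_known_mixture(f / (1 - f), pair)
        assert k == pytest.approx(k_true, rel=1e-9)


class TestMassFraction:
    def test_absent_adulterant_gives_zero(self):
        res = mass_fraction(SpeciesPair(0.0, 300.0), KFactor.fixed(0.8))
        assert res.fraction_percent == 0.0

    def test_copy_ratio_inverse_of_k_gives_fifty_percent(self):
        res = mass_fraction(SpeciesPair(500.0, 400.0), KFactor.fixed(0.8))
        assert res.mass_ratio == pytest.approx(1.0)
        assert res.fraction_percent == pytest.approx(50.0)

    def test_fifty_percent_mixture_means(self):
        res = mass_fraction(SpeciesPair(376.33, 297.33), KFactor.fixed(0.8))
        assert res.fraction_percent == pytest.approx(50.31, abs=0.01)

    def test_accepts_bare_float_k(self):
        a = mass_fraction(SpeciesPair(100.0, 100.0), 0.8)
        b = mass_fraction(SpeciesPair(100.0, 100.0), KFactor.fixed(0.8))
        assert a.fraction_percent == b.fraction_percent

    @given(
        st.floats(min_value=1.0, max_value=1000.0),
        st.floats(min_value=1.01, max_value=2.0),
    )
    def test_fraction_strictly_increasing_in_adulterant_and_k(self, q, mult):
        base = mass_fraction(SpeciesPair(q, 300.0), 0.8).fraction_percent
        assert mass_fraction(SpeciesPair(q * mult, 300.0), 0.8).fraction_percent > base
        assert mass_fraction(SpeciesPair(q, 300.0), 0.8 * mult).fraction_percent > base

    def test_round_trip_inverts_simulator_construction(self):
        # noise-free: fraction(k_true, expected concentrations) == truth
        from ddquant import expected_concentrations
        for f in (1.0, 5.0, 20.0, 50.0, 80.0, 99.0):
            sc = SimulationScenario(true_fraction_percent=f)
            qa, qb = expected_concentrations(sc)
            if qa == 0:
                continue
            res = mass_fraction(SpeciesPair(qa, qb), sc.k_true)
            assert res.fraction_percent == pytest.approx(f, rel=1e-9)


class TestQuantifyReplicates:
    def test_identical_pairs_have_zero_rsd(self):
        pairs = [SpeciesPair(500.0, 400.0)] * 3
        res = quantify_replicates(pairs, 0.8)
        assert res.rsd_percent == 0.0
        assert res.fraction_percent == pytest.approx(50.0)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            quantify_replicates([], 0.8)

    def test_reported_repeatability_values_reproduced(self):
        # pairs constructed so the per-replicate fractions equal the
        # six published operator-A 10% measurements
        k = 0.8
        fracs = [9.22, 9.26, 9.03, 9.19, 9.39, 9.01]
        pairs = [
            SpeciesPair((f / (100 - f)) / k * 100.0, 100.0) for f in fracs
        ]
        res = quantify_replicates(pairs, k, true_fraction=10.0)
        assert round(res.fraction_percent, 2) == 9.18
        assert round(res.bias_percent, 2) == -8.17

    def test_simulated_twenty_percent_recovered(self, rng):
        # k calibrated on a simulated 50/50 reference, then applied to
        # simulated 20% wells: the mean fraction must sit within 3 SE
        def pairs_for(f, reps):
            sc = SimulationScenario(true_fraction_percent=f, replicates=reps,
                                    pipetting_cv=0.0)
            from ddquant import expected_concentrations
            qa, qb = expected_concentrations(sc)
            out = []
            for r in range(reps):
                wa = simulate_well(qa, sc, rng, target="chicken", replicate=r)
                wb = simulate_well(qb, sc, rng, target="sheep", replicate=r)
                out.append(SpeciesPair(
                    estimate_copies_per_partition(wa).conc,
                    estimate_copies_per_partition(wb).conc,
                ))
            return out

        k = k_from_equal_mass(pairs_for(50.0, 6))
        res = quantify_replicates(pairs_for(20.0, 12), k, true_fraction=20.0)
        se = res.rsd_percent / 100 * res.fraction_percent / np.sqrt(12)
        assert abs(res.fraction_percent - 20.0) < max(3 * se, 0.2)
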