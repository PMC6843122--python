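"""Soil P pool state and daily transfer kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pspacsys.pools import (
    POOL_NAMES,
    ConfigurationError,
    LayerEnvironment,
    PoolState,
    TransferRates,
    apply_fertiliser,
    leach_soluble,
    mineralise_immobilise,
    step_pools,
)

REF_ENV = LayerEnvironment.reference()


def make_state(**kw):
    return PoolState(**kw)


class TestStepPools:
    def test_zero_rates_identity(self):
        state = make_state(soluble=3.0, adsorbed=5.0, mineral=2.0)
        new, ledger = step_pools(state, TransferRates(), REF_ENV)
        assert new.as_dict() == state.as_dict()
        assert all(rec.flux == 0 for rec in ledger)

    def test_single_first_order_step(self):
        # dissolution of mineral P at 0.1 d-1 from a 5 kg/ha pool moves 0.5
        state = make_state(soluble=10.0, mineral=5.0)
        rates = TransferRates(rates={("mineral", "soluble"): 0.1})
        new, ledger = step_pools(state, rates, REF_ENV, dt=1.0, max_rate_dt=10.0)
        assert new.mineral == pytest.approx(4.5)
        assert new.soluble == pytest.approx(10.5)
        assert new.total == pytest.approx(state.total)
        (rec,) = [r for r in ledger if r.flux]
        assert (rec.source, rec.sink) == ("mineral", "soluble")
        assert rec.flux == pytest.approx(0.5)

    def test_flux_clamped_to_donor(self):
        # single-step Euler: proposed flux 0.5 exceeds the 0.1 donor pool
        state = make_state(soluble=0.1)
        rates = TransferRates(rates={("soluble", "adsorbed"): 5.0})
        new, ledger = step_pools(state, rates, REF_ENV, dt=1.0, max_rate_dt=10.0)
        assert new.soluble == 0.0
        assert new.adsorbed == pytest.approx(0.1)
        (rec,) = [r for r in ledger if r.flux]
        assert rec.flux == pytest.approx(0.1)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            TransferRates(rates={("soluble", "adsorbed"): -0.1})

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            step_pools(make_state(soluble=1.0), TransferRates(), REF_ENV, dt=0.0)

    def test_flux_cap_limits_transfer(self):
        state = make_state(adsorbed=100.0)
        rates = TransferRates(
            rates={("adsorbed", "soluble"): 0.05},
            caps={("adsorbed", "soluble"): 1.0},
        )
        new, _ = step_pools(state, rates, REF_ENV, dt=1.0)
        assert state.adsorbed - new.adsorbed == pytest.approx(1.0)

    def test_reversible_equal_rates_fixed_point(self):
        # equal pools with symmetric rate constants stay put
        state = make_state(soluble=4.0, adsorbed=4.0)
        rates = TransferRates(
            rates={("soluble", "adsorbed"): 0.3, ("adsorbed", "soluble"): 0.3}
        )
        new, _ = step_pools(state, rates, REF_ENV, dt=1.0)
        assert new.soluble == pytest.approx(4.0, abs=1e-12)
        assert new.adsorbed == pytest.approx(4.0, abs=1e-12)


pools_strategy = st.lists(
    st.floats(min_value=0.0, max_value=100.0), min_size=8, max_size=8
)
rate_strategy = st.dictionaries(
    st.tuples(st.sampled_from(POOL_NAMES), st.sampled_from(POOL_NAMES)).filter(
        lambda p: p[0] != p[1]
    ),
    st.floats(min_value=0.0, max_value=2.0),
    max_size=10,
)
env_strategy = st.builds(
    LayerEnvironment,
    soil_temperature=st.floats(min_value=-5.0, max_value=35.0),
    volumetric_water=st.floats(min_value=0.05, max_value=0.5),
)


class TestStepPoolsProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(vals=pools_strategy, rates=rate_strategy, env=env_strategy)
    def test_conservation_and_nonnegativity(self, vals, rates, env):
        state = PoolState(**dict(zip(POOL_NAMES, vals)))
        tr = TransferRates(rates=rates)
        new, _ = step_pools(state, tr, env, dt=1.0)
        assert all(getattr(new, n) >= 0 for n in POOL_NAMES)
        assert abs(new.total - state.total) <= 1e-9 * max(state.total, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        amount=st.floats(min_value=0.1, max_value=50.0),
        k=st.floats(min_value=0.001, max_value=0.5),
    )
    def test_substep_convergence(self, amount, k):
        """Halving the daily step changes the flux by <1% for rates <= 0.5/d,
        and both agree with a 1000-substep brute-force solution."""
        state = make_state(adsorbed=amount)
        rates = TransferRates(rates={("adsorbed", "soluble"): k})
        full, _ = step_pools(state, rates, REF_ENV, dt=1.0)
        half, _ = step_pools(state, rates, REF_ENV, dt=0.5)
        half, _ = step_pools(half, rates, REF_ENV, dt=0.5)
        # brute-force oracle: 1000 explicit substeps over the day
        v = amount
        for _ in range(1000):
            v -= k / 1000.0 * v
        moved_full = amount - full.adsorbed
        moved_half = amount - half.adsorbed
        moved_oracle = amount - v
        assert abs(moved_full - moved_half) <= 0.01 * max(moved_half, 1e-12)
        assert moved_full == pytest.approx(moved_oracle, rel=0.01)


class TestFertiliser:
    def test_triple_superphosphate_all_soluble(self):
        state = make_state(soluble=1.0)
        new = apply_fertiliser(state, 15.0, "triple_superphosphate")
        assert new.soluble == pytest.approx(16.0)
        assert new.total == pytest.approx(state.total + 15.0)

    def test_zero_amount_noop(self):
        state = make_state(soluble=1.0, adsorbed=2.0)
        assert apply_fertiliser(state, 0.0).as_dict() == state.as_dict()

    def test_manure_split(self):
        state = make_state()
        new = apply_fertiliser(state, 20.0, "manure", manure_soluble_fraction=0.4)
        assert new.soluble == pytest.approx(8.0)
        assert new.active_organic == pytest.approx(12.0)

    def test_unknown_form_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_fertiliser(make_state(), 1.0, "guano")


class TestLeaching:
    def test_no_drainage_noop(self):
        state = make_state(soluble=2.0)
        new, leached = leach_soluble(state, LayerEnvironment(drainage_flux=0.0))
        assert leached == 0.0
        assert new.soluble == 2.0

    def test_proportional_mixing(self):
        # drainage removing 10% of layer water carries 10% of soluble P
        env = LayerEnvironment(volumetric_water=0.30, layer_thickness=23.0)
        env.drainage_flux = 0.1 * env.water_depth_mm
        new, leached = leach_soluble(make_state(soluble=2.0), env)
        assert leached == pytest.approx(0.2)
        assert new.soluble == pytest.approx(1.8)

    def test_drainage_fraction_capped_at_one(self):
        env = LayerEnvironment(volumetric_water=0.30)
        env.drainage_flux = 5.0 * env.water_depth_mm
        new, leached = leach_soluble(make_state(soluble=2.0), env)
        assert leached == pytest.approx(2.0)
        assert new.soluble == 0.0

    def test_mobile_fraction_scales(self):
        env = LayerEnvironment(volumetric_water=0.30)
        env.drainage_flux = 0.1 * env.water_depth_mm
        _, leached = leach_soluble(make_state(soluble=2.0), env, mobile_fraction=0.05)
        assert leached == pytest.approx(0.01)

    def test_dry_layer_with_drainage_is_error(self):
        env = LayerEnvironment(volumetric_water=0.0, drainage_flux=1.0)
        with pytest.raises(ArithmeticError):
            leach_soluble(make_state(soluble=1.0), env)


class TestMineraliseImmobilise:
    def test_zero_net_no_flux(self):
        state = make_state(microbial=3.0, mineral=1.0)
        new, ledger = mineralise_immobilise(state, 0.0, REF_ENV)
        assert new.as_dict() == state.as_dict()
        assert ledger == []

    def test_mineralisation_direction(self):
        state = make_state(microbial=3.0, mineral=1.0)
        new, _ = mineralise_immobilise(state, 0.3, REF_ENV)
        assert new.microbial == pytest.approx(2.7)
        assert new.mineral == pytest.approx(1.3)

    def test_immobilisation_capped_by_mineral(self):
        state = make_state(microbial=1.0, mineral=0.2)
        new, _ = mineralise_immobilise(state, -0.5, REF_ENV)
        assert new.mineral == 0.0
        assert new.microbial == pytest.approx(1.2)


def test_negative_pool_rejected():
    with pytest.raises(ValueError):
        PoolState(soluble=-0.1)
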