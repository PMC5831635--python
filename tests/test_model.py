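"""Core clock RHS, gene-regulation function, mutants and variant assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from per2as import simulate
from per2as.antisense import ModelVariant
from per2as.model import (
    CORE_SPECIES,
    MutantSpec,
    assemble_rhs,
    core_rhs,
    initial_state,
    regulation_R,
    species_names,
    state_dimension,
)


def literal_regulation(x, y, a, Kt1, b, Ki1, c):
    """Independent re-evaluation of the Hill-type regulation function,
    written as a direct transcription of its closed form."""
    num = (1.0 / a) + (x / Kt1) ** b
    den = 1.0 + ((x / Kt1) ** b) * (1.0 + (y / Ki1) ** c)
    return num / den


class TestRegulation:
    def test_basal_value_without_activator(self, wt):
        # no CLOCK/BMAL: transcription sits at the basal fraction 1/a
        assert regulation_R(0.0, 5.0, wt) == pytest.approx(1.0 / wt["a"])

    def test_saturating_activator_approaches_one(self, wt):
        val = regulation_R(5.0, 0.0, wt)   # activator >> Kt1
        assert 0.999 < val < 1.0

    def test_bounded_in_unit_interval(self, wt, rng):
        for _ in range(50):
            x, y = rng.uniform(0, 20, size=2)
            val = regulation_R(x, y, wt)
            assert 0.0 < val <= 1.0

    def test_matches_literal_reimplementation(self, wt, rng):
        for _ in range(100):
            x, y = rng.uniform(0, 10, size=2)
            expected = literal_regulation(
                x, y, wt["a"], wt["Kt1"], wt["b"], wt["Ki1"], wt["c"])
            assert regulation_R(x, y, wt) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors_identify_symbol(self, wt):
        with pytest.raises(ValueError, match="Kt1"):
            regulation_R(1.0, 1.0, wt.replace(Kt1=0.0))
        with pytest.raises(ValueError, match="non-finite"):
            regulation_R(float("nan"), 1.0, wt)


class TestCoreRhs:
    def test_zero_state_has_only_nonnegative_production(self, wt):
        d = core_rhs(np.zeros(19), wt)
        assert np.all(d >= 0)
        assert d[0] > 0          # basal Per2 transcription

    def test_dimension_mismatch_raises(self, wt):
        with pytest.raises(ValueError, match="shape"):
            core_rhs(np.zeros(10), wt)

    def test_missing_symbol_raises_named_error(self, wt):
        from per2as.parameters import ParameterSet

        partial = ParameterSet({"a": 12.0})
        with pytest.raises(KeyError, match="unparameterized"):
            core_rhs(np.ones(19), partial)

    def test_exogenous_ror_adds_exact_constant(self, wt, rng):
        # the plasmid term is a constant source in the Ror mRNA equation
        i_ror = CORE_SPECIES.index("Ror")
        for _ in range(10):
            state = rng.uniform(0, 5, size=19)
            base = core_rhs(state, wt)
            mut = core_rhs(state, wt, MutantSpec(y4_0=5.0))
            assert mut[i_ror] - base[i_ror] == pytest.approx(5.0, abs=1e-12)
            others = np.delete(mut - base, i_ror)
            assert np.all(others == 0)

    def test_mutant_neutrality_is_bitwise(self, wt, rng):
        neutral = MutantSpec(y4_0=0.0, dosage={"Per2": 1.0, "Cry": 1.0})
        state = rng.uniform(0, 5, size=19)
        assert np.array_equal(core_rhs(state, wt),
                              core_rhs(state, wt, neutral))

    def test_rev_clamp_zeroes_derivative_and_substitutes(self, wt, rng):
        i_revn = CORE_SPECIES.index("REV_n")
        state = rng.uniform(0.5, 3, size=19)
        clamped = core_rhs(state, wt, MutantSpec(x5_0=2.4))
        assert clamped[i_revn] == 0.0
        # every other derivative must equal the unclamped RHS evaluated with
        # REV_n replaced by the clamp value
        state_sub = state.copy()
        state_sub[i_revn] = 2.4
        ref = core_rhs(state_sub, wt)
        ref[i_revn] = 0.0
        assert np.allclose(clamped, ref, rtol=0, atol=0)

    def test_knockout_dosage_removes_transcription(self, wt):
        # Per2 knock-out: V1max scaled to 0 leaves only degradation
        state = np.ones(19)
        d = core_rhs(state, wt, MutantSpec(dosage={"Per2": 0.0}))
        assert d[0] == pytest.approx(-wt["d_y1"] * 1.0)


class TestAssembleRhs:
    @pytest.mark.parametrize("variant,dim", [
        ("relogio", 19), ("pre", 20), ("combined", 20), ("post", 21),
    ])
    def test_dimensions(self, wt, variant, dim):
        assert state_dimension(variant) == dim
        assert assemble_rhs(variant, wt).dimension == dim
        assert len(species_names(variant)) == dim

    def test_relogio_variant_equals_core_rhs(self, wt, rng):
        rhs = assemble_rhs("relogio", wt)
        state = rng.uniform(0, 5, size=19)
        assert np.allclose(rhs(0.0, state), core_rhs(state, wt),
                           rtol=0, atol=0)

    def test_pre_reduces_to_core_when_interference_off(self, wt, rng):
        """With mu=1, a huge K_AS and no antisense present, the Per2
        equation reduces to the unmodified core model equation."""
        p = wt.replace(mu=1.0, K_AS=1e12, lam=0.0)
        rhs = assemble_rhs("pre", p)
        for _ in range(20):
            state = np.concatenate([rng.uniform(0, 5, 19), [0.0]])
            d_pre = rhs(0.0, state)
            d_core = core_rhs(state[:19], p)
            assert np.allclose(d_pre[:19], d_core, rtol=1e-9, atol=1e-12)

    def test_post_decouples_without_duplex_formation(self, wt, rng):
        p = wt.replace(k_assn=0.0, k_diss=0.0)
        rhs = assemble_rhs("post", p)
        state = np.concatenate([rng.uniform(0, 5, 19), [0.7, 0.3]])
        d = rhs(0.0, state)
        assert np.allclose(d[:19], core_rhs(state[:19], p))
        # Per2AS then obeys dAS/dt = lam0 - d_AS * AS
        assert d[19] == pytest.approx(p["lam0"] - p["d_AS"] * 0.7)

    def test_missing_extension_parameter_is_named(self, wt):
        from per2as.parameters import ParameterSet

        core_only = ParameterSet({k: wt[k] for k in wt if k != "k_assn"})
        with pytest.raises(KeyError, match="k_assn"):
            assemble_rhs("post", core_only)


class TestInvariants:
    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_nonnegativity_from_random_initial_states(self, wt, seed):
        """Rate laws have no negative production and mass-action loss, so
        trajectories from non-negative states stay non-negative (up to
        integration tolerance)."""
        local = np.random.default_rng(seed)
        variant = ["relogio", "pre", "post", "combined"][seed % 4]
        y0 = local.uniform(0.0, 4.0, size=state_dimension(variant))
        traj = simulate(variant, wt, t_end=150.0, transient=0.0, dt=0.5, y0=y0)
        assert traj.states.min() >= -1e-9

    def test_mutual_inhibition_sign_structure(self, wt, rng):
        """dPer2/dt decreases with Per2AS and dPer2AS/dt decreases with
        Per2, in every antisense-coupled variant."""
        eps = 1e-6
        for variant in ("pre", "post", "combined"):
            rhs = assemble_rhs(variant, wt)
            dim = state_dimension(variant)
            for _ in range(20):
                state = rng.uniform(0.1, 4.0, size=dim)
                up = state.copy()
                up[19] += eps       # more Per2AS
                assert rhs(0.0, up)[0] <= rhs(0.0, state)[0] + 1e-12
                up2 = state.copy()
                up2[0] += eps       # more Per2
                assert rhs(0.0, up2)[19] <= rhs(0.0, state)[19] + 1e-12
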