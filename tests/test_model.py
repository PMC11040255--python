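"""Parameter validation and reaction-network structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tritroph as tt
from tritroph.model import REFERENCE_PARAMS, network_arrays


class TestParams:
    def test_defaults_are_reference_set(self):
        p = tt.make_params()
        assert p.gx == 2 and p.dx == 0.1 and p.K == 2000 and p.S == 5e-4
        assert p.nz == 6 and p.dz == 0.09 and p.fy == 0.01 and p.ky == 0.2
        assert p.dy == 1 and p.rx == p.re == p.rp == p.Qx == p.Qy == 1

    @pytest.mark.parametrize("bad", [
        {"Qx": 1.5}, {"Qy": -0.1}, {"gx": 0.0}, {"dz": -1.0},
        {"nz": 0}, {"nz": 2.5}, {"K": 0.5}, {"rx": 2.0},
    ])
    def test_out_of_range_raises_naming_field(self, bad):
        (field,) = bad.keys()
        with pytest.raises(tt.ValidationError, match=field):
            tt.make_params(bad)

    def test_unknown_key_rejected(self):
        with pytest.raises(tt.ValidationError, match="bogus"):
            tt.make_params({"bogus": 1.0})

    def test_infection_cost_must_exceed_exposure_cost(self):
        with pytest.raises(tt.ConstraintError):
            tt.make_params({"rp": 0.9, "re": 0.5})
        tt.make_params({"rp": 0.5, "re": 0.9})  # the allowed ordering

    def test_yaml_roundtrip(self, tmp_path):
        p = tt.make_params({"Qy": 0.35, "rp": 0.7})
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert tt.Params.from_yaml(path) == p

    def test_yaml_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("gx: 2.0\nnot_a_param: 3\n")
        with pytest.raises(tt.ValidationError, match="not_a_param"):
            tt.Params.from_yaml(path)

    def test_negative_abundance_rejected(self):
        with pytest.raises(tt.ValidationError):
            tt.SystemState(xU=-1, xI=0, yU=0, yI=0, z=0)


class TestReactionNetwork:
    def test_predator_infection_channel_hand_value(self, ref_params):
        """rp ky Qy fy xI yU with conversion + birth cancelling in yU."""
        net = tt.build_reaction_network(ref_params)
        (ch,) = [c for c in net if c.label == "predator infection with offspring"]
        state = np.array([0.0, 10.0, 5.0, 0.0, 0.0])  # xU, xI, yU, yI, z
        assert ch.propensity(state) == pytest.approx(1 * 0.2 * 1 * 0.01 * 10 * 5)
        assert ch.delta == (0, -1, 0, +1, ref_params.nz)

    def test_qy_zero_silences_predator_infection(self, rng):
        """No channel may convert yU->yI or release parasites when Qy=0."""
        net = tt.build_reaction_network(tt.make_params({"Qy": 0.0}))
        for _ in range(5):
            s = rng.integers(0, 100, size=5).astype(float)
            for ch in net:
                if ch.delta[3] > 0 or ch.delta[4] > 0:
                    assert ch.propensity(s) == 0.0

    def test_total_predation_prey_removal_rate(self, ref_params, rng):
        """Prey-removal propensity from predation sums to fy * x * y."""
        net = tt.build_reaction_network(ref_params)
        predation = [c for c in net
                     if not ("competition" in c.label or "birth" in c.label
                             or c.label.startswith("death")
                             or c.label == "prey infection")]
        assert len(predation) == 12  # 4 prey-predator pairings, exclusive outcomes
        for _ in range(5):
            s = rng.integers(0, 200, size=5).astype(float)
            removed = sum(c.propensity(s) for c in predation)
            x, y = s[0] + s[1], s[2] + s[3]
            assert removed == pytest.approx(ref_params.fy * x * y, rel=1e-12)

    def test_parasite_bookkeeping(self, ref_params):
        """z changes only via prey infection (-1), successful predator
        infection (+nz) and parasite death (-1)."""
        net = tt.build_reaction_network(ref_params)
        for ch in net:
            dz = ch.delta[4]
            if dz == 0:
                continue
            if dz == -1:
                assert ch.label in ("prey infection", "death z")
            else:
                assert dz == ref_params.nz
                assert "infection" in ch.label and ch.delta[1] == -1

    def test_infected_prey_offspring_are_uninfected(self, ref_params):
        net = tt.build_reaction_network(ref_params)
        births = [c for c in net if "birth" in c.label]
        assert len(births) == 2
        for ch in births:
            assert ch.delta == (1, 0, 0, 0, 0)

    def test_no_channel_creates_negative_state(self, ref_params, rng):
        """Applying a channel's delta where its propensity is positive
        never yields a negative abundance."""
        net = tt.build_reaction_network(ref_params)
        for _ in range(20):
            s = rng.integers(0, 3, size=5).astype(float)
            for ch in net:
                if ch.propensity(s) > 0:
                    assert np.all(s + np.asarray(ch.delta) >= 0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=2000),
                    min_size=5, max_size=5))
    def test_drift_matches_rate_equations(self, counts):
        """Mean drift of the jump process equals the ODE right-hand side
        up to the exact ordered-pair competition correction."""
        p = tt.make_params({"Qy": 0.6, "rp": 0.5, "re": 0.8, "rx": 0.9})
        net = tt.build_reaction_network(p)
        s = np.array(counts, float)
        drift = tt.mean_field_drift(net, s)
        correction = np.array([s[0] / p.K, s[1] / p.K, 0, 0, 0])
        assert np.max(np.abs(tt.rhs(s, p) - (drift - correction))) < 1e-9

    def test_network_arrays_shapes(self, ref_params):
        net = tt.build_reaction_network(ref_params)
        coef, kind, ii, jj, deltas = network_arrays(net)
        assert coef.shape == kind.shape == ii.shape == jj.shape == (len(net),)
        assert deltas.shape == (len(net), 5)
        assert np.all(coef >= 0)
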