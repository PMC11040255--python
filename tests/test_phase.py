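"""Outcome classification, sweeps and threshold bisection."""

import numpy as np
import pytest

import tritroph as tt
from tritroph.phase import Coexistence, Composition, OutcomeLabel


def _label(co, comp=Composition.NOT_APPLICABLE):
    return OutcomeLabel(co, comp)


class TestClassify:
    def test_reference_run_is_three_species(self, ref_trajectory):
        lab = tt.classify(ref_trajectory)
        assert lab.coexistence is Coexistence.ALL_THREE
        assert lab.composition is Composition.BOTH_INFECTED

    def test_reference_run_stochastic_agrees(self, ref_params, ref_state):
        traj = tt.gillespie_run(ref_state, ref_params, t_max=300.0, seed=21)
        lab = tt.classify(traj)
        assert lab.coexistence is Coexistence.ALL_THREE
        assert lab.composition is Composition.BOTH_INFECTED

    def test_unmaintainable_parasite_leaves_prey_predator(self, ref_params,
                                                          ref_state):
        traj = tt.integrate(ref_state, ref_params.replace(Qy=0.0), t_max=2000.0)
        assert tt.classify(traj) == _label(Coexistence.PREY_PREDATOR)

    def test_full_predator_virulence_collapses_to_prey_only(self, ref_state):
        """rp = 0 stochastic majority outcome: predator and parasite go
        extinct, the prey persists."""
        p = tt.make_params({"rp": 0.0})
        labels = [tt.classify(tt.gillespie_run(ref_state, p, t_max=40.0,
                                               seed=300 + k))
                  for k in range(15)]
        n_prey_only = sum(lab.coexistence is Coexistence.PREY_ONLY
                          for lab in labels)
        assert n_prey_only > 7

    def test_composition_requires_three_species(self):
        with pytest.raises(ValueError):
            OutcomeLabel(Coexistence.PREY_ONLY, Composition.BOTH_INFECTED)

    def test_label_text_roundtrip(self):
        lab = OutcomeLabel(Coexistence.ALL_THREE, Composition.PRED_I_PREY_U)
        assert OutcomeLabel.parse(str(lab)) == lab


class TestAggregate:
    def test_unanimous_and_split(self):
        a = _label(Coexistence.PREY_ONLY)
        b = _label(Coexistence.PREY_PREDATOR)
        assert tt.aggregate_ensemble([a] * 100) == {a: 1.0}
        assert tt.aggregate_ensemble([a, b] * 50) == {a: 0.5, b: 0.5}

    def test_permutation_invariant(self, rng):
        labs = [_label(Coexistence.PREY_ONLY)] * 3 + [_label(Coexistence.PREY_PREDATOR)] * 7
        shuffled = list(labs)
        rng.shuffle(shuffled)
        assert tt.aggregate_ensemble(labs) == tt.aggregate_ensemble(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tt.aggregate_ensemble([])


class TestFindThreshold:
    def test_synthetic_step_located_to_tolerance(self, ref_params):
        step = 0.3123

        def evaluate(v):
            return _label(Coexistence.ALL_THREE if v >= step
                          else Coexistence.PREY_PREDATOR)

        found = tt.find_threshold(ref_params, "Qy", Coexistence.ALL_THREE,
                                  (0.1, 0.9), tol=0.005, evaluate=evaluate)
        assert abs(found - step) <= 0.005

    def test_no_crossing_raises(self, ref_params):
        def evaluate(v):
            return _label(Coexistence.ALL_THREE)

        with pytest.raises(ValueError, match="no crossing"):
            tt.find_threshold(ref_params, "Qy", Coexistence.ALL_THREE,
                              (0.1, 0.9), evaluate=evaluate)

    def test_invalid_axis(self, ref_params):
        with pytest.raises(ValueError, match="axis"):
            tt.find_threshold(ref_params, "zz", Coexistence.ALL_THREE, (0, 1))


class TestSweep:
    def test_single_cell_matches_classify(self, ref_params, ref_state):
        res = tt.sweep_plane(ref_params, "Qx", [1.0], "Qy", [0.6],
                             engine="deterministic", t_max=800.0)
        direct = tt.classify(tt.integrate(ref_state,
                                          ref_params.replace(Qx=1.0, Qy=0.6),
                                          t_max=800.0))
        assert res.labels[0, 0] == direct

    def test_invalid_axis_name(self, ref_params):
        with pytest.raises(ValueError, match="axis"):
            tt.sweep_plane(ref_params, "nope", [0.1], "Qy", [0.5])

    def test_stochastic_frequencies_sum_to_one(self, ref_params):
        res = tt.sweep_plane(ref_params, "Qx", [0.5, 1.0], "Qy", [0.3],
                             engine="stochastic", n_reps=5, base_seed=9,
                             t_max=30.0)
        for i in range(2):
            assert sum(res.frequencies[i, 0].values()) == pytest.approx(1.0)

    def test_write_and_plot(self, ref_params, tmp_path):
        res = tt.sweep_plane(ref_params, "Qx", [0.5, 1.0], "Qy", [0.2, 0.6],
                             engine="deterministic", t_max=400.0)
        res.write(tmp_path / "sweep.csv")
        assert (tmp_path / "sweep.csv").exists()
        assert (tmp_path / "sweep.json").exists()
        df = res.to_dataframe()
        assert set(df.columns) == {"Qx", "Qy", "coexistence", "composition",
                                   "frequency"}
        res.plot(tmp_path / "sweep.png")
        assert (tmp_path / "sweep.png").stat().st_size > 0


class TestCrossEngineStructure:
    def test_infected_prey_fraction_monotone_in_qx(self, ref_params, ref_state):
        """Within the coexistence region the long-run infected-prey
        fraction grows with the prey infection probability."""
        fracs = []
        for qx in (0.3, 0.5, 0.7, 1.0):
            traj = tt.integrate(ref_state, ref_params.replace(Qx=qx),
                                t_max=2000.0)
            m = tt.long_run_summary(traj, 0.2).mean
            fracs.append(m["xI"] / (m["xI"] + m["xU"]))
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_deterministic_coexistence_contains_stochastic(self, ref_params,
                                                           ref_state):
        """Along a Qy transect the stochastic three-species region never
        extends beyond the deterministic one."""
        for qy in (0.22, 0.26, 0.30, 0.40):
            p = ref_params.replace(Qy=qy)
            det = tt.classify(tt.integrate(ref_state, p, t_max=2000.0))
            reps = tt.run_ensemble(ref_state, p, t_max=400.0, n_reps=10,
                                   base_seed=77)
            freq = tt.aggregate_ensemble([tt.classify(r) for r in reps])
            coex = sum(v for k, v in freq.items()
                       if k.coexistence is Coexistence.ALL_THREE)
            if det.coexistence is not Coexistence.ALL_THREE:
                assert coex <= 0.2
            elif qy >= 0.4:  # deep inside the deterministic region
                assert coex >= 0.8
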