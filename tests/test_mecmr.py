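"""MECMR likelihood against path enumeration, fitting, derived quantities."""

import itertools

import numpy as np
import pytest

from carryover import (
    EncounterHistory,
    MecmrModel,
    MecmrSpec,
    SimulationConfig,
    empirical_transition_matrix,
    fit_mecmr,
    history_loglik,
    longrun_success,
    model_table,
    simulate_encounter_histories,
)
from carryover.mecmr import stationary_distribution

PSI = np.array([[0.6, 0.3, 0.1], [0.5, 0.3, 0.2], [0.79, 0.11, 0.10]])


def path_enumeration_loglik(history, phi, psi, p, u=0.0, pi=None):
    """Brute-force likelihood: sum over all latent state paths.

    States 0..2 alive, 3 dead.  Conditions on the first encounter exactly as
    the forward recursion does: initial state weights proportional to the
    event's state compatibility.
    """
    psi_list = psi if isinstance(psi, list) else [psi]
    pi = pi if pi is not None else [1.0]
    events = list(history.events)
    f = history.first_occasion
    T = len(events)
    phi = np.broadcast_to(np.asarray(phi, float), (3,))

    def event_prob(state, e):
        if state == 3:
            return 1.0 if e == 0 else 0.0
        if e == 0:
            return 1.0 - p
        if e == 4:
            return p * u
        return p * (1.0 - u) if e - 1 == state else 0.0

    def init_weight(state, e):
        if e == 4:
            return 1.0 / 3.0  # uncertain first event: uniform over alive states
        return 1.0 if e - 1 == state else 0.0

    total = 0.0
    for c, psi_c in enumerate(psi_list):
        L = 0.0
        for path in itertools.product(range(4), repeat=T - f):
            if path[0] == 3:
                continue
            w = init_weight(path[0], events[f])
            if w == 0:
                continue
            for s_prev, s_next, t in zip(path, path[1:], range(f + 1, T)):
                if s_prev == 3:
                    w *= 1.0 if s_next == 3 else 0.0
                elif s_next == 3:
                    w *= 1.0 - phi[s_prev]
                else:
                    w *= phi[s_prev] * psi_c[s_prev, s_next]
                if w == 0:
                    break
            else:
                for s, t in zip(path[1:], range(f + 1, T)):
                    w *= event_prob(s, events[t])
                    if w == 0:
                        break
                L += w
        total += pi[c] * L
    return np.log(total) if total > 0 else -np.inf


class TestHistoryLoglik:
    def test_two_occasion_closed_form(self):
        # seen SUCCESS then missed: died (0.1) or survived and undetected
        h = EncounterHistory("b", "F", [1, 0])
        ll = history_loglik(h, {"phi": 0.9, "psi": np.eye(3), "p": 0.8})
        assert np.exp(ll) == pytest.approx(0.1 + 0.9 * 0.2, abs=1e-12)

    def test_perfect_detection_certain_history(self):
        h = EncounterHistory("b", "F", [1, 1])
        ll = history_loglik(h, {"phi": 1.0, "psi": np.eye(3), "p": 1.0})
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_impossible_history_minus_inf(self):
        # identity transitions cannot take SUCCESS to FAIL
        h = EncounterHistory("b", "F", [1, 2])
        ll = history_loglik(h, {"phi": 1.0, "psi": np.eye(3), "p": 1.0})
        assert ll == -np.inf

    def test_forward_equals_path_enumeration_with_unknown_events(self, rng):
        phi, p, u = 0.88, 0.8, 0.15
        h = EncounterHistory("b", "F", [4, 0, 2, 4, 1])
        ll = history_loglik(
            h, {"phi": phi, "psi": PSI, "p": p, "uncertainty": u}
        )
        oracle = path_enumeration_loglik(h, phi, PSI, p, u)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_forward_equals_path_enumeration_randomised(self, rng):
        for _ in range(25):
            T = int(rng.integers(2, 6))
            phi = rng.uniform(0.5, 1.0, size=3)
            p = rng.uniform(0.3, 1.0)
            u = rng.uniform(0, 0.3)
            raw = rng.random((3, 3))
            psi = raw / raw.sum(axis=1, keepdims=True)
            events = [int(rng.integers(1, 5))] + [
                int(rng.integers(0, 5)) for _ in range(T - 1)
            ]
            h = EncounterHistory("b", "M", events)
            ll = history_loglik(
                h, {"phi": phi, "psi": psi, "p": p, "uncertainty": u}
            )
            oracle = path_enumeration_loglik(h, phi, psi, p, u)
            if np.isinf(oracle):
                assert np.isinf(ll)
            else:
                assert ll == pytest.approx(oracle, abs=1e-10)

    def test_mixture_combines_before_log(self):
        h = EncounterHistory("b", "F", [1, 1, 3])
        psi_a = np.eye(3)
        raw = np.full((3, 3), 1 / 3)
        params = {
            "phi": 0.9,
            "psi": [psi_a, raw],
            "p": 0.8,
            "mixture_weights": [0.4, 0.6],
        }
        ll = history_loglik(h, params)
        la = path_enumeration_loglik(h, 0.9, psi_a, 0.8)
        lb = path_enumeration_loglik(h, 0.9, raw, 0.8)
        expected = np.log(0.4 * np.exp(la) + 0.6 * np.exp(lb))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_not_seen_first_event_rejected(self):
        with pytest.raises(ValueError):
            EncounterHistory("b", "F", [0, 1])

    def test_invalid_simplex_rejected(self):
        h = EncounterHistory("b", "F", [1, 1])
        with pytest.raises(ValueError):
            history_loglik(h, {"phi": 0.9, "psi": np.full((3, 3), 0.5), "p": 0.8})

    def test_total_loglik_additive_and_order_invariant(self, rng):
        cfg = SimulationConfig(psi=PSI, n_occasions=5, seed=8)
        hists, _ = simulate_encounter_histories(cfg, n_birds=30)
        params = {"phi": 0.9, "psi": PSI, "p": 0.85}
        lls = [history_loglik(h, params) for h in hists]
        total = sum(lls)
        shuffled = [lls[i] for i in rng.permutation(len(lls))]
        assert sum(shuffled) == pytest.approx(total, abs=1e-9)


class TestFit:
    def test_boundary_mle_flagged_on_perfect_data(self):
        cfg = SimulationConfig(
            phi=1.0, p_detect=1.0, psi=PSI, n_occasions=5, seed=1
        )
        hists, _ = simulate_encounter_histories(cfg, n_birds=150)
        fit = fit_mecmr(hists, n_starts=2, seed=0, compute_se=False)
        assert fit.natural["phi[ALL,ALL]"] > 0.999
        assert fit.natural["p[ALL]"] > 0.999
        assert any(b.startswith("phi") for b in fit.boundary)
        assert any(b.startswith("p[") for b in fit.boundary)

    def test_parameter_recovery_single_dataset(self):
        cfg = SimulationConfig(
            phi=0.9, p_detect=0.85, psi=PSI, n_occasions=8, seed=33
        )
        hists, _ = simulate_encounter_histories(cfg, n_birds=300)
        fit = fit_mecmr(hists, n_starts=3, seed=0)
        truth = {"phi[ALL,ALL]": 0.9, "p[ALL]": 0.85}
        for i, sf in enumerate(("SUCCESS", "FAIL", "SKIP")):
            for j, stt in enumerate(("SUCCESS", "FAIL", "SKIP")):
                truth[f"psi[{sf}->{stt}]"] = PSI[i, j]
        for k, v in truth.items():
            assert abs(fit.natural[k] - v) <= 3 * fit.natural_se[k], k

    def test_single_class_mixture_equals_plain_fit(self):
        cfg = SimulationConfig(psi=PSI, n_occasions=6, seed=5)
        hists, _ = simulate_encounter_histories(cfg, n_birds=120)
        plain = fit_mecmr(hists, MecmrSpec(), n_starts=1, seed=0, compute_se=False)
        mix1 = fit_mecmr(
            hists, MecmrSpec(n_mixture_classes=1), n_starts=1, seed=0,
            compute_se=False,
        )
        assert mix1.loglik == pytest.approx(plain.loglik, abs=1e-6)

    def test_estimator_get_set_params(self):
        m = MecmrModel(psi_by_sex=True)
        assert m.get_params()["psi_by_sex"] is True
        m.set_params(n_starts=3)
        assert m.n_starts == 3
        with pytest.raises(ValueError):
            m.set_params(nonsense=1)

    def test_empty_histories_rejected(self):
        with pytest.raises(ValueError):
            MecmrModel().fit([])


class TestModelTable:
    def test_single_fit_zero_delta(self):
        cfg = SimulationConfig(psi=PSI, n_occasions=5, seed=2)
        hists, _ = simulate_encounter_histories(cfg, n_birds=80)
        fit = fit_mecmr(hists, n_starts=1, seed=0, compute_se=False)
        table = model_table([fit])
        assert table["delta_aic"].iloc[0] == 0.0
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_generating_model_beats_saturated(self):
        wins = 0
        for r in range(8):
            cfg = SimulationConfig(psi=PSI, n_occasions=7, seed=100 + r)
            hists, _ = simulate_encounter_histories(cfg, n_birds=250)
            base = fit_mecmr(hists, MecmrSpec(name="base"), n_starts=1,
                             seed=r, compute_se=False)
            rich = fit_mecmr(
                hists,
                MecmrSpec(phi_by_state=True, psi_by_sex=True, name="rich"),
                n_starts=1, seed=r, compute_se=False,
            )
            if base.aic < rich.aic:
                wins += 1
        assert wins >= 6  # >= 90% asymptotically; small-sample slack

    def test_mixture_on_homogeneous_data_penalised(self):
        # a 2-class mixture rarely buys back its 7-parameter AIC penalty
        # when the generator is homogeneous
        wins = 0
        for r in range(6):
            cfg = SimulationConfig(psi=PSI, n_occasions=7, seed=200 + r)
            hists, _ = simulate_encounter_histories(cfg, n_birds=250)
            base = fit_mecmr(hists, MecmrSpec(name="base"), n_starts=2,
                             seed=0, compute_se=False)
            mix = fit_mecmr(
                hists, MecmrSpec(n_mixture_classes=2, name="mix2"),
                n_starts=2, seed=0, compute_se=False,
            )
            table = model_table([base, mix])
            assert list(table["aic"]) == sorted(table["aic"])
            if mix.aic >= base.aic:
                wins += 1
        assert wins >= 4

    def test_mixed_datasets_rejected(self):
        cfg = SimulationConfig(psi=PSI, n_occasions=5, seed=3)
        h1, _ = simulate_encounter_histories(cfg, n_birds=40)
        h2, _ = simulate_encounter_histories(cfg, n_birds=40, seed=99)
        f1 = fit_mecmr(h1, n_starts=1, seed=0, compute_se=False)
        f2 = fit_mecmr(h2, n_starts=1, seed=0, compute_se=False)
        with pytest.raises(ValueError):
            model_table([f1, f2])


class TestDerived:
    def test_identity_psi_next_year(self):
        cfg = SimulationConfig(
            phi=1.0, p_detect=1.0, psi=np.eye(3),
            initial_state_probs=[0.5, 0.3, 0.2], seed=4,
        )
        hists, _ = simulate_encounter_histories(cfg, n_birds=100)
        fit = fit_mecmr(hists, n_starts=1, seed=0, compute_se=False)
        lr = longrun_success(fit, "next_year", n_boot=0)
        probs = dict(zip(lr["from_state"], lr["prob_success"]))
        assert probs["SUCCESS"] > 0.99
        assert probs["FAIL"] < 0.01 and probs["SKIP"] < 0.01

    def test_uniform_psi_stationary_thirds(self):
        sd = stationary_distribution(np.full((3, 3), 1 / 3))
        np.testing.assert_allclose(sd, [1 / 3] * 3, atol=1e-12)

    def test_stationary_matches_power_iteration_oracle(self, rng):
        for _ in range(10):
            raw = rng.random((3, 3)) + 0.05
            psi = raw / raw.sum(axis=1, keepdims=True)
            sd = stationary_distribution(psi)
            v = np.full(3, 1 / 3)
            for _ in range(10_000):
                v = v @ psi
            np.testing.assert_allclose(sd, v, atol=1e-10)
            np.testing.assert_allclose(sd @ psi, sd, atol=1e-12)
            assert sd.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reducible_psi_rejected_in_stationary_mode(self):
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(np.eye(3))

    def test_stationary_mode_start_independent(self):
        cfg = SimulationConfig(psi=PSI, n_occasions=8, seed=6)
        hists, _ = simulate_encounter_histories(cfg, n_birds=200)
        fit = fit_mecmr(hists, n_starts=1, seed=0)
        lr = longrun_success(fit, "stationary", n_boot=100, seed=0)
        assert lr["prob_success"].nunique() == 1
        assert (lr["ci_lo"] <= lr["prob_success"]).all()
        assert (lr["prob_success"] <= lr["ci_hi"]).all()


class TestEmpiricalMatrix:
    def test_single_transition(self):
        h = EncounterHistory("b", "F", [1, 2])
        freq, counts, excl = empirical_transition_matrix([h])
        np.testing.assert_allclose(freq[0], [0, 1, 0])
        assert counts.sum() == 1 and excl == 0

    def test_rows_sum_to_one(self):
        cfg = SimulationConfig(psi=PSI, n_occasions=6, seed=7)
        hists, _ = simulate_encounter_histories(cfg, n_birds=200)
        freq, counts, _ = empirical_transition_matrix(hists)
        rows = counts.sum(axis=1) > 0
        np.testing.assert_allclose(freq[rows].sum(axis=1), 1.0, atol=1e-12)

    def test_perfect_observation_recovers_psi(self):
        cfg = SimulationConfig(
            phi=1.0, p_detect=1.0, psi=PSI, n_occasions=8, seed=10
        )
        hists, _ = simulate_encounter_histories(cfg, n_birds=400)
        freq, counts, excl = empirical_transition_matrix(hists)
        assert excl == 0
        n = counts.sum(axis=1, keepdims=True)
        se = np.sqrt(PSI * (1 - PSI) / n)
        assert (np.abs(freq - PSI) <= 3 * se + 1e-12).all()

    def test_no_pairs_errors(self):
        h = EncounterHistory("b", "F", [1, 0, 0])
        with pytest.raises(ValueError):
            empirical_transition_matrix([h])
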