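import math

import numpy as np
import pytest

from spomlab import (
    ModelSpec,
    OccupancySeries,
    ParameterVector,
    aicc,
    apply_missing_years,
    build_transitions,
    fit_model,
    generate_network,
    select_model,
    simulate_series,
    transition_loglik,
)
from spomlab.inference import _make_negloglik
from spomlab.spom_models import MODEL_LABELS, UNOBSERVED

from conftest import brute_force_loglik, random_params, random_series


def series_from_states(states, years=None, ids=None):
    states = np.asarray(states)
    years = tuple(years) if years else tuple(range(2000, 2000 + states.shape[1]))
    ids = tuple(ids) if ids else tuple(f"p{i}" for i in range(states.shape[0]))
    return OccupancySeries("s", ids, years, states)


class TestBuildTransitions:
    def test_gap_year_dropped(self):
        rng = np.random.default_rng(0)
        states = (rng.random((100, 7)) < 0.5).astype(np.int8)
        series = series_from_states(states, years=range(2009, 2016))
        series = apply_missing_years(series, [2013])
        data = build_transitions(series)
        year_pairs = [(p.year_t, p.year_u) for p in data.pairs]
        assert year_pairs == [(2009, 2010), (2010, 2011), (2011, 2012), (2014, 2015)]
        assert data.n_transitions == 400

    def test_gap_retained_under_keep_gaps(self):
        states = np.ones((10, 4), dtype=np.int8)
        series = apply_missing_years(
            series_from_states(states, years=(2009, 2010, 2011, 2012)), [2010]
        )
        data = build_transitions(series, gap_policy="keep_gaps")
        assert [(p.year_t, p.year_u, p.gap) for p in data.pairs] == [
            (2009, 2011, True),
            (2011, 2012, False),
        ]

    def test_two_observed_years(self):
        states = np.zeros((31, 2), dtype=np.int8)
        data = build_transitions(series_from_states(states))
        assert data.n_transitions == 31

    def test_fully_observed_seven_years(self):
        states = np.zeros((13, 7), dtype=np.int8)
        data = build_transitions(series_from_states(states))
        assert data.n_transitions == 6 * 13

    def test_blank_first_year(self):
        states = np.ones((5, 4), dtype=np.int8)
        series = apply_missing_years(
            series_from_states(states, years=(2009, 2010, 2011, 2012)), [2009]
        )
        data = build_transitions(series)
        assert data.n_transitions == 5 * 2

    def test_never_observed_patches_dropped(self):
        states = np.ones((4, 3), dtype=np.int8)
        states[2, :] = UNOBSERVED
        data = build_transitions(series_from_states(states))
        assert data.patch_indices == (0, 1, 3)
        assert data.n_transitions == 3 * 2


class TestTransitionLoglik:
    def test_single_colonization_term(self):
        states = np.array([[0, 1]])
        data = build_transitions(series_from_states(states))
        ll = transition_loglik(ModelSpec("PRM"), ParameterVector(E=0.5, C=0.3), data)
        assert ll == pytest.approx(math.log(0.3), abs=1e-12)

    def test_survival_term_couples_extinction_to_colonization(self):
        # 1 -> 1 under PRM: survive with 1 - E(1-C) = 1 - 0.5*0.7 = 0.65
        states = np.array([[1, 1]])
        data = build_transitions(series_from_states(states))
        ll = transition_loglik(ModelSpec("PRM"), ParameterVector(E=0.5, C=0.3), data)
        assert ll == pytest.approx(math.log(0.65), abs=1e-12)

    @pytest.mark.parametrize("label", MODEL_LABELS)
    def test_matches_brute_force_oracle(self, label):
        spec = ModelSpec.from_label(label)
        rng = np.random.default_rng(99)
        for _ in range(20):
            net, series = random_series(rng, int(rng.integers(2, 7)), int(rng.integers(2, 5)))
            params = random_params(rng, spec)
            data = build_transitions(series)
            got = transition_loglik(spec, params, data, net)
            want = brute_force_loglik(spec, params, series, net)
            assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("label", MODEL_LABELS)
    def test_fast_path_matches_reference(self, label):
        spec = ModelSpec.from_label(label)
        rng = np.random.default_rng(7)
        net, series = random_series(rng, 6, 4)
        data = build_transitions(series)
        negll = _make_negloglik(spec, data, net, "eq_coupled")
        from spomlab.inference import _to_params

        for _ in range(10):
            z = rng.normal(size=spec.k)
            assert -negll(z) == pytest.approx(
                transition_loglik(spec, _to_params(spec, z), data, net), abs=1e-9
            )

    def test_lm_requires_network(self):
        states = np.array([[0, 1], [1, 0]])
        data = build_transitions(series_from_states(states))
        with pytest.raises(ValueError, match="network"):
            transition_loglik(
                ModelSpec("LM"), ParameterVector(E=0.5, alpha=0.1, y=1.0), data
            )

    def test_nonfinite_params_rejected(self):
        states = np.array([[0, 1], [1, 0]])
        data = build_transitions(series_from_states(states))
        with pytest.raises(ValueError, match="C must be"):
            ParameterVector(E=0.5, C=float("nan"))
        net = generate_network(2, 8.0, jitter=0.0, seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            transition_loglik(
                ModelSpec("LM"),
                ParameterVector(E=0.5, alpha=float("inf"), y=1.0),
                data,
                net,
            )


class TestAicc:
    def test_closed_form(self):
        assert aicc(-5.0, 2, 10) == pytest.approx(10 + 4 + 12 / 7, abs=1e-12)

    def test_large_n_approaches_aic(self):
        assert aicc(-5.0, 2, 10**7) == pytest.approx(14.0, abs=1e-5)

    def test_k3_n5(self):
        assert aicc(0.0, 3, 5) == pytest.approx(30.0, abs=1e-12)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 2, 3)


def simulate_dataset(spec, params, n_patches=150, n_years=7, seed=0, spacing=8.0):
    net = generate_network(n_patches, spacing, jitter=1.0, seed=seed, street_id="sim")
    rng = np.random.default_rng(seed + 1000)
    init = (rng.random(n_patches) < 0.4).astype(np.int8)
    series = simulate_series(net, spec, params, init, n_years - 1, seed=seed + 2000)
    return net, series


class TestFitModel:
    def test_prm_recovery_vs_grid_oracle(self):
        spec = ModelSpec("PRM")
        truth = ParameterVector(E=0.2, C=0.3)
        net, series = simulate_dataset(spec, truth, seed=4)
        data = build_transitions(series)
        fit = fit_model(spec, data, net)
        assert abs(fit.mle.C - 0.3) < 0.05
        assert abs(fit.mle.E - 0.2) < 0.05

        # Independent oracle: exhaustive grid search at 0.001 resolution.
        grid = np.arange(0.001, 1.0, 0.001)
        best = (-np.inf, None, None)
        n01 = sum(((p.state_t == 0) & (p.state_u == 1)).sum() for p in data.pairs)
        n00 = sum(((p.state_t == 0) & (p.state_u == 0)).sum() for p in data.pairs)
        n10 = sum(((p.state_t == 1) & (p.state_u == 0)).sum() for p in data.pairs)
        n11 = sum(((p.state_t == 1) & (p.state_u == 1)).sum() for p in data.pairs)
        for c in grid:
            e_grid = grid
            ext = e_grid * (1 - c)
            ll = (
                n01 * math.log(c)
                + n00 * math.log(1 - c)
                + n10 * np.log(ext)
                + n11 * np.log(1 - ext)
            )
            j = int(np.argmax(ll))
            if ll[j] > best[0]:
                best = (ll[j], c, e_grid[j])
        assert fit.mle.C == pytest.approx(best[1], abs=2e-3)
        assert fit.mle.E == pytest.approx(best[2], abs=2e-3)
        assert fit.loglik >= best[0] - 1e-6

    def test_all_empty_series_flagged_non_identifiable(self):
        states = np.zeros((30, 4), dtype=np.int8)
        data = build_transitions(series_from_states(states))
        fit = fit_model(ModelSpec("PRM"), data)
        assert fit.mle.C < 1e-4
        assert not fit.identifiable

    def test_lm_mle_beats_truth(self):
        spec = ModelSpec("LM")
        truth = ParameterVector(E=0.2, alpha=0.1, y=1.0)
        net, series = simulate_dataset(spec, truth, seed=8)
        data = build_transitions(series)
        fit = fit_model(spec, data, net)
        assert fit.loglik >= transition_loglik(spec, truth, data, net) - 1e-6
        assert fit.converged

    def test_aicc_consistent_with_formula(self):
        spec = ModelSpec("PRM")
        net, series = simulate_dataset(spec, ParameterVector(E=0.2, C=0.3), 30, seed=1)
        data = build_transitions(series)
        fit = fit_model(spec, data, net)
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k, fit.n), abs=1e-12)
        assert fit.k == 2 and fit.n == data.n_transitions

    def test_too_few_transitions(self):
        states = np.array([[0, 1], [1, 0], [1, 1]])
        data = build_transitions(series_from_states(states))
        with pytest.raises(ValueError, match="k\\+2"):
            fit_model(ModelSpec("LM", rescue=True), data, generate_network(3, 8.0))

    @pytest.mark.parametrize("family", ["LM", "PRM"])
    def test_rescue_nests_base(self, family):
        if family == "LM":
            truth = ParameterVector(E=0.25, alpha=0.1, y=1.0)
        else:
            truth = ParameterVector(E=0.25, C=0.3)
        spec = ModelSpec(family)
        net, series = simulate_dataset(spec, truth, n_patches=60, seed=13)
        data = build_transitions(series)
        base = fit_model(spec, data, net)
        rescue = fit_model(ModelSpec(family, rescue=True), data, net)
        assert rescue.loglik >= base.loglik - 1e-6


class TestSelectModel:
    def test_unobserved_patches_do_not_change_ordering(self):
        spec = ModelSpec("PRM")
        net, series = simulate_dataset(spec, ParameterVector(E=0.2, C=0.35), 40, seed=21)
        sel = select_model(series, net)

        # Pad with 3 patches that are never observed plus matching network rows.
        pad = 3
        states = np.vstack(
            [series.states, np.full((pad, len(series.years)), UNOBSERVED, dtype=np.int8)]
        )
        big_series = OccupancySeries(
            series.network_ref,
            series.patch_ids + tuple(f"extra{i}" for i in range(pad)),
            series.years,
            states,
        )
        from spomlab.spom_models import PatchNetwork

        coords = np.vstack([net.coords, net.coords[-1] + [[50, 0], [60, 0], [70, 0]]])
        big_net = PatchNetwork(
            net.street_id,
            net.patch_ids + tuple(f"extra{i}" for i in range(pad)),
            coords,
        )
        sel_big = select_model(big_series, big_net)
        assert sel_big.best == sel.best
        order = sorted(MODEL_LABELS, key=lambda m: sel.fits[m].aicc)
        order_big = sorted(MODEL_LABELS, key=lambda m: sel_big.fits[m].aicc)
        assert order == order_big
        for m in MODEL_LABELS:
            assert sel_big.fits[m].aicc == pytest.approx(sel.fits[m].aicc, rel=1e-6)

    def test_best_has_zero_delta(self):
        net, series = simulate_dataset(
            ModelSpec("PRM"), ParameterVector(E=0.2, C=0.35), 40, seed=3
        )
        sel = select_model(series, net)
        assert sel.delta_aicc[sel.best] == 0.0
        assert len(sel.fits) == 4
        assert all(d >= 0 for d in sel.delta_aicc.values())

    def test_all_absent_rejected(self):
        net = generate_network(10, 8.0, jitter=0.0, seed=0)
        states = np.zeros((10, 4), dtype=np.int8)
        series = OccupancySeries(
            net.street_id, net.patch_ids, (2009, 2010, 2011, 2012), states
        )
        with pytest.raises(ValueError, match="all-absent"):
            select_model(series, net)

    def test_prm_selected_on_strong_prm_data(self):
        hits = 0
        for seed in range(8):
            net, series = simulate_dataset(
                ModelSpec("PRM"), ParameterVector(E=0.2, C=0.4), 50, seed=100 + seed
            )
            sel = select_model(series, net)
            hits += sel.best in ("PRM", "PRM+R")
        assert hits >= 6

    def test_lm_family_selected_on_steep_kernel_data(self):
        hits = 0
        for seed in range(8):
            net, series = simulate_dataset(
                ModelSpec("LM"),
                ParameterVector(E=0.2, alpha=0.1, y=1.0),
                50,
                seed=200 + seed,
            )
            sel = select_model(series, net)
            hits += sel.best in ("LM", "LM+R")
        assert hits >= 5


class TestParameterRecovery:
    """Fitting the generating model recovers its parameters (smoke scale).

    The full 20-seed, 150-patch version required by the acceptance
    criteria lives in test_acceptance.py.
    """

    @pytest.mark.parametrize(
        "label,truth,jitter",
        [
            ("PRM", ParameterVector(E=0.2, C=0.3), 1.0),
            ("LM", ParameterVector(E=0.2, alpha=0.15, y=1.0), 3.0),
        ],
    )
    def test_recovery_smoke(self, label, truth, jitter):
        # Positional jitter spreads the pairwise distances, which is what
        # identifies alpha separately from y on a near-regular street.
        spec = ModelSpec.from_label(label)
        estimates = {p: [] for p in spec.param_names}
        for seed in range(5):
            net = generate_network(150, 8.0, jitter=jitter, seed=300 + seed)
            rng = np.random.default_rng(seed + 1300)
            init = (rng.random(150) < 0.5).astype(np.int8)
            series = simulate_series(net, spec, truth, init, 6, seed=seed + 2300)
            fit = fit_model(spec, build_transitions(series), net)
            for p in spec.param_names:
                estimates[p].append(getattr(fit.mle, p))
        for p in spec.param_names:
            true = getattr(truth, p)
            assert abs(np.mean(estimates[p]) - true) / true < 0.15
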