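import numpy as np
import pytest

from vetowalk import (
    GenerationExhaustedError,
    GeneratorConfig,
    TrialSet,
    average_position_curve,
    expected_position_curve,
    estimate_flash_next_step_probability,
    flash_next_step_probability,
    generate_trials,
    generate_trials_literal,
    generate_trials_reversed,
    simulate_veto_switch,
    t_step_matrix,
)


def tv_distance(samples_a, samples_b, n_states):
    ha = np.bincount(samples_a, minlength=n_states) / len(samples_a)
    hb = np.bincount(samples_b, minlength=n_states) / len(samples_b)
    return 0.5 * np.abs(ha - hb).sum()


def pmf_tv(samples, pmf):
    h = np.bincount(samples, minlength=len(pmf)) / len(samples)
    return 0.5 * np.abs(h - pmf).sum()


class TestVetoSwitch:
    def test_bernoulli_mean(self):
        rng = np.random.default_rng(0)
        s = simulate_veto_switch(10**5, 0.5, rng)
        assert s.dtype == bool
        assert abs(s.mean() - 0.5) < 3 * np.sqrt(0.25 / 10**5)

    def test_small_p_mostly_off(self):
        rng = np.random.default_rng(1)
        s = simulate_veto_switch(100, 1e-6, rng)
        assert s.sum() == 0

    def test_seeded_determinism(self):
        a = simulate_veto_switch(1000, 0.3, np.random.default_rng(42))
        b = simulate_veto_switch(1000, 0.3, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_p(self, p):
        with pytest.raises(ValueError):
            simulate_veto_switch(10, p, np.random.default_rng(0))

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            simulate_veto_switch(0, 0.5, np.random.default_rng(0))


class TestGeneratorConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"N": 1},
            {"M": 1},
            {"k": 0},
            {"p_switch": 0.0},
            {"p_switch": 1.0},
            {"mode": "backwards"},
        ],
    )
    def test_invalid(self, line5, kwargs):
        base = dict(chain=line5, N=10, M=5, k=1, p_switch=0.2, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            GeneratorConfig(**base)

    def test_roundtrip(self, line5):
        cfg = GeneratorConfig(chain=line5, N=10, M=5, k=2, p_switch=0.2, seed=3)
        back = GeneratorConfig.from_dict(cfg.to_dict())
        assert back == cfg


class TestReversedGenerator:
    def test_structure(self, small_reversed_line5):
        ts = small_reversed_line5
        ts.validate()
        assert ts.positions.shape == (20, 20, 20)
        # exact M/M quota and boundary lock at t=0
        assert np.all((ts.labels == 0).sum(axis=1) == 10)
        assert np.all(ts.positions[ts.labels == 0][:, -1] == 0)
        assert np.all(ts.positions[ts.labels == 1][:, -1] == 6)
        np.testing.assert_array_equal(ts.times, np.arange(-19, 1))

    def test_seeded_determinism(self, line5):
        cfg = GeneratorConfig(chain=line5, N=6, M=4, k=3, p_switch=0.2, seed=5)
        a = generate_trials_reversed(cfg)
        b = generate_trials_reversed(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_two_step_law_line1(self, line1):
        # distribution of the t=-2 position given "left" is row 0 of P^2
        cfg = GeneratorConfig(chain=line1, N=3, M=5000, k=1, p_switch=0.2, seed=7)
        ts = generate_trials_reversed(cfg)
        left = ts.positions[0][ts.labels[0] == 0]
        expected = t_step_matrix(line1, 2)[0]  # (0.5, 0.25, 0.25)
        assert pmf_tv(left[:, 0], expected) <= 0.05

    def test_dispatch(self, line5):
        cfg = GeneratorConfig(chain=line5, N=5, M=3, k=1, p_switch=0.2, seed=1,
                              mode="reversed")
        assert generate_trials(cfg).provenance["mode"] == "reversed"


@pytest.fixture(scope="module")
def literal_line5(line5):
    cfg = GeneratorConfig(chain=line5, N=10, M=100, k=1, p_switch=0.2,
                          seed=13, mode="literal")
    return generate_trials_literal(cfg)


class TestLiteralGenerator:
    def test_structure(self, literal_line5):
        literal_line5.validate()
        assert np.all(literal_line5.positions[0][literal_line5.labels[0] == 0][:, -1] == 0)

    def test_one_step_law(self, line5):
        # pmf of t=-1 positions of left trials ~ row 0 of P: (1/2, 1/2, 0, ...)
        cfg = GeneratorConfig(chain=line5, N=10, M=400, k=1, p_switch=0.2,
                              seed=17, mode="literal")
        ts = generate_trials_literal(cfg)
        left = ts.positions[0][ts.labels[0] == 0]
        assert pmf_tv(left[:, -2], line5.transition[0]) <= 0.05

    def test_complete_one_step_uniform(self, complete5):
        cfg = GeneratorConfig(chain=complete5, N=8, M=400, k=1, p_switch=0.2,
                              seed=19, mode="literal")
        ts = generate_trials_literal(cfg)
        allpos = ts.positions[0][:, -2]
        assert pmf_tv(allpos, np.full(7, 1 / 7)) <= 0.05

    def test_exhaustion_error(self, line5):
        cfg = GeneratorConfig(chain=line5, N=10, M=2, k=1, p_switch=0.001,
                              seed=1, mode="literal", max_series_steps=2048)
        with pytest.raises(GenerationExhaustedError, match="p_switch"):
            generate_trials_literal(cfg)

    def test_seeded_determinism(self, line5):
        cfg = GeneratorConfig(chain=line5, N=5, M=3, k=2, p_switch=0.3, seed=23,
                              mode="literal")
        a = generate_trials_literal(cfg)
        b = generate_trials_literal(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestAveragePositionCurve:
    def test_time_lock_means(self, small_reversed_line5):
        curve = average_position_curve(small_reversed_line5)
        assert curve.loc[0, "left"] == 0.0
        assert curve.loc[0, "right"] == 6.0

    def test_line1_one_step_mean(self, line1):
        cfg = GeneratorConfig(chain=line1, N=3, M=3000, k=1, p_switch=0.2, seed=2)
        curve = average_position_curve(generate_trials_reversed(cfg))
        # row 0 of P gives mean 0.5*0 + 0.5*1
        assert curve.loc[-1, "left"] == pytest.approx(0.5, abs=0.05)

    def test_complete_uniform_mean(self, complete5):
        cfg = GeneratorConfig(chain=complete5, N=4, M=3000, k=1, p_switch=0.2, seed=3)
        curve = average_position_curve(generate_trials_reversed(cfg))
        for label in ("left", "right"):
            assert curve.loc[-1, label] == pytest.approx(3.0, abs=0.15)

    def test_matches_analytic(self, line5, small_reversed_line5):
        emp = average_position_curve(small_reversed_line5)
        ana = expected_position_curve(line5, 20)
        # 200 trials per class: agree within a loose sampling band
        assert np.abs(emp["left"] - ana["left"]).max() < 0.5

    def test_walls_approached_towards_lock(self, line5):
        ana = expected_position_curve(line5, 40)
        assert ana["left"].is_monotonic_decreasing  # mean drifts towards wall 0
        assert ana["right"].is_monotonic_increasing


class TestPersistence:
    def test_csv_roundtrip(self, tmp_path, small_reversed_line5):
        path = tmp_path / "trials.csv"
        small_reversed_line5.to_csv(path)
        back = TrialSet.from_csv(path)
        np.testing.assert_array_equal(back.positions, small_reversed_line5.positions)
        np.testing.assert_array_equal(back.labels, small_reversed_line5.labels)
        assert back.config == small_reversed_line5.config
        assert back.provenance == small_reversed_line5.provenance

    def test_npz_roundtrip(self, tmp_path, small_reversed_line5):
        path = tmp_path / "trials.npz"
        small_reversed_line5.to_npz(path)
        back = TrialSet.from_npz(path)
        np.testing.assert_array_equal(back.positions, small_reversed_line5.positions)
        assert back.config == small_reversed_line5.config

    def test_validate_catches_tampering(self, small_reversed_line5):
        bad = TrialSet(
            small_reversed_line5.positions.copy(),
            1 - small_reversed_line5.labels,
            small_reversed_line5.config,
        )
        with pytest.raises(ValueError):
            bad.validate()


class TestFlashNextStep:
    def test_unconditioned_half(self, line5):
        assert flash_next_step_probability(line5, 1) == 0.5

    def test_conditioned_certain(self, line5):
        assert flash_next_step_probability(line5, 1, conditioned=True) == 1.0

    def test_monte_carlo_agreement(self, line5):
        rng = np.random.default_rng(0)
        p = estimate_flash_next_step_probability(line5, 1, 10**5, rng)
        assert p == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 10**5))
        rng = np.random.default_rng(1)
        pc = estimate_flash_next_step_probability(
            line5, 1, 10**5, rng, conditioned=True
        )
        assert pc == 1.0

    def test_interior_state_unreachable_boundary(self, line5):
        with pytest.raises(ValueError):
            flash_next_step_probability(line5, 3, conditioned=True)

    def test_invalid_state(self, line5):
        with pytest.raises(ValueError):
            flash_next_step_probability(line5, 9)
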