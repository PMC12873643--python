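"""AROC statistic, bootstrap inference, and epoch contrasts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, norm

from sc_attention import discriminability as disc
from sc_attention import synthetic_data as syn
from sc_attention.types import RateKernelParams, UnitRecord


def brute_force_auroc(signal, noise):
    """Independent oracle: explicit pairwise comparison with tie half-credit."""
    total = 0.0
    for s in signal:
        for n in noise:
            total += 1.0 if s > n else (0.5 if s == n else 0.0)
    return total / (len(signal) * len(noise))


counts = st.lists(st.integers(0, 20), min_size=1, max_size=25)


class TestAuroc:
    @pytest.mark.parametrize(
        "signal,noise,expected",
        [
            ([5, 6, 7], [1, 2, 3], 1.0),
            ([2, 2, 2], [2, 2, 2], 0.5),
            ([1, 2, 3], [0, 1, 2], 7 / 9),
        ],
    )
    def test_reference_values(self, signal, noise, expected):
        assert disc.auroc(signal, noise) == pytest.approx(expected, abs=1e-12)

    @given(counts, counts)
    def test_matches_brute_force(self, signal, noise):
        assert disc.auroc(signal, noise) == pytest.approx(
            brute_force_auroc(signal, noise), abs=1e-12
        )

    @given(counts, counts)
    def test_symmetry(self, signal, noise):
        assert disc.auroc(signal, noise) == pytest.approx(
            1.0 - disc.auroc(noise, signal), abs=1e-12
        )

    @given(counts, counts, st.integers(-5, 5))
    def test_shift_invariance(self, signal, noise, c):
        shifted = disc.auroc(np.asarray(signal) + c, np.asarray(noise) + c)
        assert shifted == pytest.approx(disc.auroc(signal, noise), abs=1e-12)

    @given(counts, counts)
    def test_equals_normalized_mann_whitney_u(self, signal, noise):
        u = mannwhitneyu(signal, noise, alternative="two-sided").statistic
        assert disc.auroc(signal, noise) == pytest.approx(
            u / (len(signal) * len(noise)), abs=1e-12
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            disc.auroc([], [1, 2])

    def test_monotone_in_gaussian_shift(self, rng):
        estimates = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            s = rng.normal(delta, 1, 2000)
            n = rng.normal(0, 1, 2000)
            estimates.append(disc.auroc(s, n))
        assert np.all(np.diff(estimates) > 0)
        # converges toward the closed form Phi(delta / sqrt(2))
        for est, delta in zip(estimates, (0.0, 0.5, 1.0, 2.0)):
            assert est == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.03)


class TestBootstrapCi:
    def test_degenerate_identical_sets(self):
        lo, hi = disc.bootstrap_auroc_ci([3, 3, 3], [3, 3, 3], rng_seed=0)
        assert (lo, hi) == (0.5, 0.5)

    def test_fully_separated_sets(self):
        lo, hi = disc.bootstrap_auroc_ci([10, 11, 12], [1, 2, 3], rng_seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            disc.bootstrap_auroc_ci([1, 2], [3, 4], n_boot=1)

    def test_coverage_of_closed_form_auroc(self, rng):
        """95% percentile-bootstrap CI covers Phi(delta/sqrt(2)) ~95% of
        the time for Gaussian-shifted samples."""
        delta = 1.0
        true_a = norm.cdf(delta / np.sqrt(2))
        covered = 0
        n_sets = 500
        for _ in range(n_sets):
            s = rng.normal(delta, 1, 50)
            n = rng.normal(0, 1, 50)
            lo, hi = disc.bootstrap_auroc_ci(s, n, 1000, rng)
            covered += lo <= true_a <= hi
        assert 0.92 <= covered / n_sets <= 0.98

    def test_significance_rule(self):
        assert disc.significance_from_ci(0.52, 0.70) == "positive"
        assert disc.significance_from_ci(0.30, 0.48) == "negative"
        assert disc.significance_from_ci(0.45, 0.55) == "ns"


@pytest.fixture(scope="module")
def expert_trials_200():
    from sc_attention.types import CohortSpec

    spec = CohortSpec("expert", 1, 200, True, "change_locked")
    return syn.simulate_trial_timeline(spec, 21)


class TestEpochDiscriminability:
    def test_null_units_auroc_near_half(self, expert_trials_200):
        """Pure-baseline units: the 95% CI covers 0.5 at its nominal rate."""
        p = RateKernelParams(cue_amp_hz=0, change_amp_hz=0, delay_contra_bias_hz=0)
        rng = np.random.default_rng(31)
        covered = 0
        n_units = 20
        for k in range(n_units):
            spikes = syn.simulate_unit_spikes(expert_trials_200, p, "expert", "deep", rng)
            unit = UnitRecord(f"u{k}", "s", "deep", 500, spikes)
            r = disc.epoch_discriminability(
                unit, expert_trials_200, disc.epoch_spec("cue_onset"), rng_seed=rng
            )
            covered += r.ci_lo <= 0.5 <= r.ci_hi
        assert covered >= 0.8 * n_units

    def test_strong_cue_transient_positive(self, expert_trials_200):
        p = RateKernelParams(cue_amp_hz=60, change_amp_hz=0, delay_contra_bias_hz=0)
        spikes = syn.simulate_unit_spikes(expert_trials_200, p, "expert", "superficial", 33)
        unit = UnitRecord("u", "s", "superficial", -200, spikes)
        r = disc.epoch_discriminability(
            unit, expert_trials_200, disc.epoch_spec("cue_onset"), rng_seed=34
        )
        assert r.significance == "positive"
        assert r.auroc > 0.7

    def test_delay_null_type_one_control(self, expert_trials_200):
        """Units without delay bias are called ns in >= 90% of cases."""
        p = RateKernelParams(delay_contra_bias_hz=0)
        ns = 0
        rng = np.random.default_rng(35)
        n_units = 100
        for k in range(n_units):
            spikes = syn.simulate_unit_spikes(expert_trials_200, p, "expert", "deep", rng)
            unit = UnitRecord(f"u{k}", "s", "deep", 500, spikes)
            r = disc.epoch_discriminability(
                unit, expert_trials_200, disc.epoch_spec("delay_spatial"),
                n_boot=500, rng_seed=rng,
            )
            ns += r.significance == "ns"
        assert ns >= 0.90 * n_units

    def test_min_trials_exclusion(self, expert_trials_200):
        unit = UnitRecord("u", "s", "deep", 500, np.array([1.0, 2.0]))
        r = disc.epoch_discriminability(
            unit, expert_trials_200[:6], disc.epoch_spec("cue_onset"), min_trials=5
        )
        assert r is None  # only ~1-2 contra change trials among 6

    def test_population_summary(self):
        from sc_attention.types import AurocResult

        results = [
            AurocResult(f"u{i}", "cue_onset", a, a - 0.05, a + 0.05, "ns", 10, 10)
            for i, a in enumerate([0.4, 0.5, 0.6])
        ]
        s = disc.population_summary(results, rng_seed=0)
        assert s["median"] == 0.5
        single = disc.population_summary(results[:1], rng_seed=0)
        assert single["median"] == 0.4
        assert single["median_ci"] == (0.4, 0.4)
        with pytest.raises(ValueError):
            disc.population_summary([])


class TestTimecourse:
    def test_flip_symmetry_and_delay_bias(self, expert_trials_200):
        p = RateKernelParams(cue_amp_hz=0, change_amp_hz=0, delay_contra_bias_hz=30)
        spikes = syn.simulate_unit_spikes(expert_trials_200, p, "expert", "deep", 36)
        unit = UnitRecord("u", "s", "deep", 500, spikes)
        starts, vals = disc.auroc_timecourse(unit, expert_trials_200, "twopatch_on", (-400, 400), 20)
        pre = vals[starts < -100]
        post = vals[starts >= 100]
        assert abs(pre.mean() - 0.5) < 0.05  # no bias before the delay epoch
        assert post.mean() > 0.6  # strong contra bias once the delay starts

        # flipping contra/ipsi labels maps each bin AROC x -> 1 - x
        flipped = []
        for tr in expert_trials_200:
            import copy

            tr2 = copy.copy(tr)
            tr2.cue_side = "ipsi" if tr.cue_side == "contra" else "contra"
            flipped.append(tr2)
        _, vals_f = disc.auroc_timecourse(unit, flipped, "twopatch_on", (-400, 400), 20)
        assert np.allclose(vals_f, 1.0 - vals, atol=1e-12)
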