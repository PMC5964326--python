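import numpy as np
import pytest

from xylreg.cytometry import (
    CytometrySample,
    classify_on_off,
    coefficient_of_variation,
    cv_dose_profile,
)
from xylreg.errors import DegenerateSampleError, GridAlignmentError
from xylreg.synth import CytometryTruth, generate_cytometry


def mixture_sample(frac_on, n=10_000, off=(0.0, 0.2), on=(2.0, 0.2), seed=7,
                   conc=1.0, arch="dual_feedback"):
    rng = np.random.default_rng(seed)
    is_on = rng.random(n) < frac_on
    logs = np.where(is_on, rng.normal(on[0], on[1], n), rng.normal(off[0], off[1], n))
    return CytometrySample(10.0**logs, conc, arch, f"{arch}_{conc}")


class TestClassifyOnOff:
    def test_recovers_mixture_fraction(self):
        smp = mixture_sample(0.4)
        res = classify_on_off(smp)
        assert not res.unimodal
        assert res.fraction_on == pytest.approx(0.4, abs=0.02)
        assert res.mean_off_log < np.log10(res.threshold) < res.mean_on_log

    def test_all_off_is_unimodal_zero(self):
        smp = mixture_sample(0.0)
        res = classify_on_off(smp, off_reference=1.0)
        assert res.unimodal
        assert res.fraction_on == 0.0

    def test_all_on_is_unimodal_one(self):
        smp = mixture_sample(1.0)
        res = classify_on_off(smp, off_reference=1.0)
        assert res.unimodal
        assert res.fraction_on == 1.0

    def test_unimodal_without_reference_raises(self):
        with pytest.raises(ValueError, match="off_reference"):
            classify_on_off(mixture_sample(0.0))

    def test_identical_events_degenerate(self):
        smp = CytometrySample(np.full(500, 3.0), 1.0)
        with pytest.raises(DegenerateSampleError):
            classify_on_off(smp)

    def test_needs_enough_events(self):
        with pytest.raises(ValueError):
            classify_on_off(mixture_sample(0.5, n=50))

    def test_matches_bayes_threshold_for_separated_mixture(self):
        """EM assignment agrees with the truth-optimal split on >=98% of events."""
        off, on, frac = (0.0, 0.2), (2.0, 0.2), 0.35
        smp = mixture_sample(frac, off=off, on=on)  # separation = 10 log-sds
        res = classify_on_off(smp)
        x = np.log10(smp.events)
        # Bayes boundary from generator truth (equal sds -> closed form)
        b = 0.5 * (off[0] + on[0]) + off[1] ** 2 / (on[0] - off[0]) * np.log(
            (1 - frac) / frac
        )
        agree = np.mean((x > np.log10(res.threshold)) == (x > b))
        assert agree >= 0.98

    def test_consistency_with_sample_size(self):
        """fraction_on error shrinks as event count grows (fixed truth, seeds)."""
        errs = {}
        for n in (1_000, 10_000, 100_000):
            e = [
                abs(classify_on_off(mixture_sample(0.4, n=n, seed=seed)).fraction_on - 0.4)
                for seed in range(5)
            ]
            errs[n] = np.mean(e)
        assert errs[100_000] < errs[1_000]


class TestCoefficientOfVariation:
    def test_constant_sample_is_zero(self):
        assert coefficient_of_variation(CytometrySample(np.full(10, 4.0), 0.0)) == 0.0

    def test_two_point_closed_form(self):
        """Half events at 1, half at 3: CV = sqrt(n/(n-1)) / 2 with sample sd."""
        n = 1000
        ev = np.concatenate([np.ones(n // 2), np.full(n // 2, 3.0)])
        want = np.sqrt(n / (n - 1)) / 2.0
        assert coefficient_of_variation(CytometrySample(ev, 0.0)) == pytest.approx(
            want, rel=1e-12
        )

    def test_scale_invariance(self):
        smp = mixture_sample(0.4, n=2000)
        a = coefficient_of_variation(smp)
        b = coefficient_of_variation(
            CytometrySample(137.5 * smp.events, smp.concentration)
        )
        assert b == pytest.approx(a, rel=1e-12)

    def test_wider_separation_raises_cv(self):
        """Same mean, wider ON/OFF split => more heterogeneity."""
        n = 20_000
        narrow = CytometrySample(np.concatenate([np.full(n, 1.9), np.full(n, 2.1)]), 0.0)
        wide = CytometrySample(np.concatenate([np.full(n, 1.0), np.full(n, 3.0)]), 0.0)
        assert np.mean(wide.events) == np.mean(narrow.events)
        assert coefficient_of_variation(wide) > coefficient_of_variation(narrow)


class TestCvDoseProfile:
    def test_identical_samples_identical_rows(self):
        samples = [
            mixture_sample(0.4, n=2000, seed=1, conc=c, arch=a)
            for c in (0.1, 1.0, 4.0)
            for a in ("single_feedback", "dual_feedback")
        ]
        # regenerate dual with same seed/noise as single so rows match
        samples = [
            CytometrySample(s.events, s.concentration, a, f"{a}_{s.concentration}")
            for s in samples[:3]
            for a in ("single_feedback", "dual_feedback")
        ]
        df = cv_dose_profile(samples)
        assert np.allclose(df.loc["single_feedback"], df.loc["dual_feedback"])

    def test_lower_noise_architecture_has_lower_cv(self):
        concs = [0.2, 0.5, 1.0, 4.0]
        single = generate_cytometry(CytometryTruth(noise_multiplier=1.0), concs, seed=3,
                                    architecture="single_feedback")
        dual = generate_cytometry(CytometryTruth(noise_multiplier=0.5), concs, seed=3,
                                  architecture="dual_feedback")
        df = cv_dose_profile(single + dual)
        assert np.all(df.loc["dual_feedback"].values <= df.loc["single_feedback"].values)

    def test_single_group_gives_one_row(self):
        samples = [mixture_sample(0.4, n=1000, conc=c, arch="dual_feedback")
                   for c in (0.1, 1.0, 4.0)]
        df = cv_dose_profile(samples)
        assert df.shape[0] == 1

    def test_mismatched_grids_listed(self):
        samples = [
            mixture_sample(0.4, n=1000, conc=0.1, arch="single_feedback"),
            mixture_sample(0.4, n=1000, conc=1.0, arch="single_feedback"),
            mixture_sample(0.4, n=1000, conc=0.1, arch="dual_feedback"),
        ]
        with pytest.raises(GridAlignmentError) as exc:
            cv_dose_profile(samples)
        assert ("dual_feedback", 1.0) in exc.value.missing
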