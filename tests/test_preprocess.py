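import numpy as np
import pytest

from pupilcascade.core import PupilTrace
from pupilcascade.preprocess import (
    PreprocessConfig,
    PreprocessReport,
    flag_invalid,
    interpolate_gaps,
    preprocess_trace,
    qc_accept,
    trim_acclimation,
)
from pupilcascade.synth import SyntheticParams, generate_trace


def make_trace(y, valid=None, rate=25.0):
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.isfinite(y) & (y > 0)
    return PupilTrace("T", rate, np.arange(len(y)) / rate, y, valid)


class TestTrim:
    def test_removes_acclimation_phase(self):
        trace, _, _ = generate_trace(SyntheticParams(seed=0))
        out = trim_acclimation(trace, PreprocessConfig())
        assert out.duration == pytest.approx(2370.0)
        assert out.t[0] == 0.0

    def test_zero_trim_is_identity(self):
        tr = make_trace(np.full(100, 4.0))
        out = trim_acclimation(tr, PreprocessConfig(trim_seconds=0))
        np.testing.assert_array_equal(out.y, tr.y)
        np.testing.assert_array_equal(out.t, tr.t)

    def test_short_trace_rejected(self):
        tr = make_trace(np.full(250, 4.0))  # 10 s at 25 Hz
        with pytest.raises(ValueError, match="trim"):
            trim_acclimation(tr, PreprocessConfig())


class TestFlagInvalid:
    def test_ten_percent_jump_flagged(self):
        tr = make_trace([4.0, 4.0, 4.6, 4.0])
        mask, rep = flag_invalid(tr, PreprocessConfig())
        assert mask.tolist() == [True, True, False, True]
        assert rep.n_jump == 1

    def test_jump_reference_is_last_valid_value(self):
        # 4.6 is a glitch; 4.05 is compared to 4.0 (not 4.6) and survives
        tr = make_trace([4.0, 4.6, 4.05, 4.0])
        mask, _ = flag_invalid(tr, PreprocessConfig())
        assert mask.tolist() == [True, False, True, True]

    def test_jump_run_reanchors_after_persistent_level_change(self):
        y = [4.0] * 5 + [4.6] * 20
        tr = make_trace(y)
        mask, _ = flag_invalid(tr, PreprocessConfig())
        # at most max_jump_run samples of the new level are flagged
        assert (~mask).sum() <= 5
        assert mask[-1]

    def test_blink_margin_two_samples_each_side(self):
        y = np.full(25, 4.0)
        valid = np.ones(25, bool)
        y[10:13] = 0.0
        valid[10:13] = False
        tr = make_trace(y, valid)
        mask, rep = flag_invalid(tr, PreprocessConfig())
        assert not mask[8:15].any()
        assert mask[:8].all() and mask[15:].all()
        assert rep.n_blink == 3 and rep.n_margin == 4

    def test_constant_trace_nothing_flagged(self):
        tr = make_trace(np.full(50, 4.0))
        mask, rep = flag_invalid(tr, PreprocessConfig())
        assert mask.all()
        assert rep.valid_fraction == 1.0

    def test_three_sd_outlier_flagged(self, rng):
        y = 4.0 + 0.01 * rng.standard_normal(100)
        y[50] = 4.3  # < 10% of preceding value, but tens of SDs off the mean
        tr = make_trace(y)
        mask, rep = flag_invalid(tr, PreprocessConfig())
        assert not mask[50]
        assert rep.n_outlier >= 1 and rep.n_jump == 0

    def test_counts_are_non_overlapping_and_sum(self, rng):
        trace, _, _ = generate_trace(SyntheticParams(duration=300, seed=5))
        mask, rep = flag_invalid(trace, PreprocessConfig())
        assert rep.n_blink + rep.n_margin + rep.n_jump + rep.n_outlier == rep.n_interpolated
        assert rep.n_interpolated == rep.n_total - mask.sum()

    def test_matches_independent_single_pass_oracle(self, rng):
        """Precedence blink > margin > jump > outlier, checked on random
        traces against a separately written rule-by-rule oracle."""
        cfg = PreprocessConfig()
        for _ in range(10):
            n = 400
            y = 4.0 + np.cumsum(0.004 * rng.standard_normal(n))
            valid = np.ones(n, bool)
            for s in rng.integers(0, n - 5, size=4):
                y[s:s + 3] = 0.0
                valid[s:s + 3] = False
            for i in rng.integers(0, n, size=3):
                y[i] = 8.0 if valid[i] else y[i]
            tr = make_trace(y, valid)
            mask, _ = flag_invalid(tr, cfg)
            np.testing.assert_array_equal(mask, _oracle_mask(y, valid, cfg))


def _oracle_mask(y, valid, cfg):
    """Brute-force re-implementation of the flagging cascade using sets."""
    n = len(y)
    blink = {i for i in range(n) if not valid[i]}
    margin = set()
    for i in blink:
        for o in range(1, cfg.blink_margin_samples + 1):
            for j in (i - o, i + o):
                if 0 <= j < n and j not in blink:
                    margin.add(j)
    jump = set()
    ref, run = None, 0
    for i in range(n):
        if i in blink or i in margin:
            continue
        if (
            ref is not None
            and abs(y[i] - ref) / abs(ref) > cfg.jump_fraction
            and run < cfg.max_jump_run
        ):
            jump.add(i)
            run += 1
        else:
            ref, run = y[i], 0
    alive = [i for i in range(n) if i not in blink | margin | jump]
    out = set()
    if alive:
        mu = np.mean([y[i] for i in alive])
        sd = np.std([y[i] for i in alive])
        if sd > 0:
            out = {i for i in alive if abs(y[i] - mu) > cfg.outlier_sd * sd}
    bad = blink | margin | jump | out
    return np.array([i not in bad for i in range(n)])


class TestInterpolate:
    def test_midpoint_fill(self):
        tr = make_trace([4.0, 1.0, 5.0], valid=np.array([True, False, True]))
        out = interpolate_gaps(tr, tr.valid)
        assert out.y[1] == pytest.approx(4.5)

    def test_no_gaps_is_identity(self):
        tr = make_trace([4.0, 4.1, 4.2])
        out = interpolate_gaps(tr, tr.valid)
        np.testing.assert_array_equal(out.y, tr.y)

    def test_leading_gap_constant_extension(self):
        tr = make_trace([0.0, 0.0, 4.2, 4.4], valid=np.array([False, False, True, True]))
        out = interpolate_gaps(tr, tr.valid)
        np.testing.assert_allclose(out.y[:2], 4.2)

    def test_idempotent(self, rng):
        y = 4.0 + 0.1 * rng.standard_normal(100)
        valid = rng.random(100) > 0.3
        valid[[0, -1]] = True
        tr = make_trace(y, valid)
        once = interpolate_gaps(tr, valid)
        twice = interpolate_gaps(once, once.valid)
        np.testing.assert_array_equal(once.y, twice.y)

    def test_too_few_valid_samples_rejected(self):
        tr = make_trace([4.0, 0.0, 0.0], valid=np.array([True, False, False]))
        with pytest.raises(ValueError):
            interpolate_gaps(tr, tr.valid)


class TestQcGate:
    @pytest.mark.parametrize(
        "fraction,accepted", [(0.80, True), (0.75, True), (0.74, False)]
    )
    def test_75_percent_rule_boundary_inclusive(self, fraction, accepted):
        rep = PreprocessReport(valid_fraction=fraction)
        assert qc_accept(rep, PreprocessConfig()) is accepted


class TestOnSyntheticTraces:
    def test_injected_blinks_and_margins_are_flagged(self):
        hits = total = 0
        for seed in range(3):
            trace, truth, _ = generate_trace(SyntheticParams(duration=600, seed=seed))
            mask, _ = flag_invalid(trace, PreprocessConfig())
            for s, e in truth.blink_intervals:
                lo, hi = max(0, s - 2), min(trace.n_samples, e + 2)
                total += hi - lo
                hits += int((~mask[lo:hi]).sum())
        assert hits / total >= 0.95

    def test_full_pass_yields_continuous_accepted_trace(self):
        trace, _, _ = generate_trace(SyntheticParams(seed=2))
        cleaned, rep = preprocess_trace(trace)
        assert rep.accepted
        assert np.isfinite(cleaned.y).all()
        assert cleaned.duration == pytest.approx(2370.0)
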