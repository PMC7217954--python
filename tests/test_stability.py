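"""Normalization, decay fitting, filter cascade and stability classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabiloc.stability import (
    DESTABILIZED,
    EXCLUDED_BASELINE,
    EXCLUDED_CENSORED,
    EXCLUDED_FIT,
    EXCLUDED_RAPID,
    STABILIZED,
    UNCHANGED,
    DecayModelFit,
    FilterParams,
    FitError,
    NormalizationError,
    TimeCourseMatrix,
    classify_stability,
    filter_fits,
    fit_decay,
    funnel_counts,
    normalize_timecourse,
    stability_pipeline,
)

T7 = np.array([0.0, 3.0, 6.0, 9.0, 12.0, 24.0, 30.0])


def _matrix(rows: dict, timepoints=T7, condition="c") -> TimeCourseMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(timepoints))
    return TimeCourseMatrix(condition=condition, values=df.astype(float))


def _refs_const(level=4.0):
    return {r: [level] * len(T7) for r in ("RPLP0", "PGK1", "TRAP1")}


class TestNormalize:
    def test_constant_refs_identity_scaling(self):
        m = _matrix({**_refs_const(), "TX": [10, 5, 2.5, 1.25, 0.625, 0.0390625, 0.009765625]})
        rel, excluded = normalize_timecourse(m)
        np.testing.assert_allclose(
            rel.loc["TX"].to_numpy(), [1, 0.5, 0.25, 0.125, 0.0625, 0.00390625, 0.0009765625]
        )
        assert excluded == []
        assert "RPLP0" not in rel.index  # references removed from output

    def test_scale_factor_from_reference_geometric_mean(self):
        """refs geomean 4 at t=0 and 2 at t=3 -> s(3)=0.5; R(3)=(3/0.5)/10=0.6."""
        refs = {
            "RPLP0": [8, 4, 2, 1, 1, 1, 1],
            "PGK1": [4, 2, 1, 1, 1, 1, 1],
            "TRAP1": [2, 1, 0.5, 1, 1, 1, 1],
        }
        m = _matrix({**refs, "TX": [10, 3, 1, 1, 1, 1, 1]})
        rel, _ = normalize_timecourse(m)
        assert rel.loc["TX"].iloc[0] == 1.0
        assert rel.loc["TX"].iloc[1] == pytest.approx(0.6)

    @given(st.lists(st.floats(0.1, 10.0), min_size=7, max_size=7))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, g):
        """Multiplying every value at time t by g(t) leaves R unchanged."""
        base = {**_refs_const(), "TX": [12, 8, 5, 3, 2, 0.7, 0.3]}
        m1 = _matrix(base)
        scaled = {k: np.asarray(v, dtype=float) * np.asarray(g) for k, v in base.items()}
        m2 = _matrix(scaled)
        r1, _ = normalize_timecourse(m1)
        r2, _ = normalize_timecourse(m2)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), rtol=1e-10)

    def test_low_baseline_excluded_not_raised(self):
        m = _matrix({**_refs_const(), "LOW": [0.5, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1],
                     "OK": [10, 5, 2, 1, 1, 1, 1]})
        rel, excluded = normalize_timecourse(m, params=FilterParams(min_baseline_expression=1.0))
        assert excluded == ["LOW"]
        assert list(rel.index) == ["OK"]

    def test_zero_reference_names_transcript(self):
        refs = _refs_const()
        refs["PGK1"] = [4, 0, 4, 4, 4, 4, 4]
        m = _matrix({**refs, "TX": [10, 5, 2, 1, 1, 1, 1]})
        with pytest.raises(NormalizationError, match="PGK1"):
            normalize_timecourse(m)

    def test_missing_reference_rejected(self):
        m = _matrix({"TX": [10, 5, 2, 1, 1, 1, 1]})
        with pytest.raises(NormalizationError):
            normalize_timecourse(m)


def _grid_oracle(t, r):
    """Brute-force model fit: k on a log grid, aux on linear grids.

    Independent of the optimizer path; returns the half-life of the
    grid-minimal weighted RSS across all three model shapes.
    """
    ks = np.exp(np.linspace(np.log(0.01), np.log(2.0), 400))
    best = (np.inf, math.inf)
    w = np.maximum(r, 0.05)
    for k in ks:
        resid = (np.exp(-k * t) - r) / w
        rss = resid @ resid
        if rss < best[0]:
            best = (rss, math.log(2) / k)
        for t0 in np.linspace(0, 0.9 * t[-1], 40):
            m = np.where(t <= t0, 1.0, np.exp(-k * np.maximum(t - t0, 0)))
            resid = (m - r) / w
            rss = resid @ resid
            if rss < best[0]:
                best = (rss, math.log(2) / k)
        for c in np.linspace(0, 0.95, 40):
            m = (1 - c) * np.exp(-k * t) + c
            resid = (m - r) / w
            rss = resid @ resid
            if rss < best[0]:
                t_half = (
                    -math.log((0.5 - c) / (1 - c)) / k if c < 0.5 else math.inf
                )
                best = (rss, t_half)
    return best[1]


class TestFitDecay:
    def test_noiseless_exponential_recovered_exactly(self):
        fit = fit_decay(T7, np.exp(-np.log(2) / 6.0 * T7))
        assert fit.model == "EXP"
        assert fit.t_half == pytest.approx(6.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_constant_series_censored_without_error(self):
        fit = fit_decay(T7, np.ones(7))
        assert fit.censored and math.isinf(fit.t_half)
        assert fit.k is None

    def test_plateau_recovery_matches_closed_form_crossing(self):
        """R(t) = 0.7 exp(-0.3 t) + 0.3 crosses 0.5 at -ln(2/7)/0.3."""
        fit = fit_decay(T7, 0.7 * np.exp(-0.3 * T7) + 0.3)
        assert fit.model == "PLATEAU_EXP"
        assert fit.k == pytest.approx(0.3, rel=1e-4)
        assert fit.aux == pytest.approx(0.3, abs=1e-4)
        expected = -math.log((0.5 - 0.3) / 0.7) / 0.3
        assert fit.t_half == pytest.approx(expected, rel=1e-4)
        assert fit.t_half == pytest.approx(_grid_oracle(T7, 0.7 * np.exp(-0.3 * T7) + 0.3), rel=0.05)

    def test_delayed_onset_half_life_is_decay_phase_only(self):
        r = np.where(T7 <= 4.0, 1.0, np.exp(-0.2 * (T7 - 4.0)))
        fit = fit_decay(T7, r)
        assert fit.model == "DELAY_EXP"
        assert fit.t_half == pytest.approx(math.log(2) / 0.2, rel=1e-4)

    def test_plateau_above_half_is_censored(self):
        fit = fit_decay(T7, 0.3 * np.exp(-0.5 * T7) + 0.7)
        assert fit.model == "PLATEAU_EXP"
        assert fit.censored

    def test_agrees_with_grid_search_oracle_on_random_noiseless_series(self):
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(50):
            kind = rng.integers(3)
            k = rng.uniform(0.05, 0.4)
            if kind == 0:
                r = np.exp(-k * T7)
            elif kind == 1:
                t0 = rng.uniform(0, 6)
                r = np.where(T7 <= t0, 1.0, np.exp(-k * (T7 - t0)))
            else:
                c = rng.uniform(0, 0.4)
                r = (1 - c) * np.exp(-k * T7) + c
            fit = fit_decay(T7, r)
            oracle = _grid_oracle(T7, r)
            assert fit.t_half == pytest.approx(oracle, rel=0.06)
            checked += 1
        assert checked == 50

    @pytest.mark.parametrize(
        "t,r",
        [
            (T7[:3], np.ones(3)),
            (T7, np.array([1, np.nan, 0.5, 0.2, 0.1, 0.05, 0.01])),
        ],
    )
    def test_bad_series_rejected(self, t, r):
        with pytest.raises(FitError):
            fit_decay(t, r)

    def test_best_r2_selection_supported(self):
        fit = fit_decay(T7, np.exp(-0.1 * T7), selection="BEST_R2")
        assert fit.t_half == pytest.approx(math.log(2) / 0.1, rel=1e-4)
        with pytest.raises(ValueError):
            fit_decay(T7, np.exp(-0.1 * T7), selection="MAGIC")


def _fit(tid, r2=1.0, t_half=6.0, model="EXP"):
    k = None if math.isinf(t_half) else math.log(2) / t_half
    return DecayModelFit(tid, model, k, None, r2, t_half)


class TestFilterCascade:
    def test_r2_below_threshold_in_either_condition_excluded(self):
        table = filter_fits({"A": _fit("A", r2=0.95)}, {"A": _fit("A", r2=0.85)})
        assert table.loc[0, "class"] == EXCLUDED_FIT

    def test_rapid_decay_in_either_condition_excluded(self):
        table = filter_fits(
            {"A": _fit("A", t_half=2.9)}, {"A": _fit("A", t_half=8.0)}
        )
        assert table.loc[0, "class"] == EXCLUDED_RAPID

    def test_censored_in_either_condition_excluded(self):
        table = filter_fits(
            {"A": _fit("A", t_half=math.inf)}, {"A": _fit("A", t_half=8.0)}
        )
        assert table.loc[0, "class"] == EXCLUDED_CENSORED

    def test_survivor_passes_with_empty_class(self):
        table = filter_fits({"A": _fit("A")}, {"A": _fit("A")})
        assert table.loc[0, "class"] == ""

    def test_single_condition_transcript_excluded_as_fit(self):
        table = filter_fits({"A": _fit("A"), "B": _fit("B")}, {"A": _fit("A")})
        assert dict(zip(table.transcript_id, table["class"]))["B"] == EXCLUDED_FIT

    def test_filter_order_r2_before_rapid(self):
        # violates both r2 and rapid thresholds: r2 wins by the fixed order
        table = filter_fits(
            {"A": _fit("A", r2=0.5, t_half=1.0)}, {"A": _fit("A", r2=0.5, t_half=1.0)}
        )
        assert table.loc[0, "class"] == EXCLUDED_FIT


class TestClassify:
    @pytest.mark.parametrize(
        "tc,tk,expected",
        [
            (8.0, 3.5, STABILIZED),
            (8.0, 4.0, STABILIZED),  # inclusive boundary, ratio = 2
            (4.0, 8.0, DESTABILIZED),  # inclusive boundary, ratio = 0.5
            (3.5, 8.0, DESTABILIZED),
            (6.0, 5.0, UNCHANGED),
        ],
    )
    def test_fold_change_rule(self, tc, tk, expected):
        table = filter_fits({"A": _fit("A", t_half=tc)}, {"A": _fit("A", t_half=tk)})
        out = classify_stability(table)
        assert out.loc[0, "class"] == expected
        assert out.loc[0, "ratio"] == pytest.approx(tc / tk)

    def test_every_transcript_appears_once_with_a_class(self):
        fits_c = {t: _fit(t) for t in ("A", "B", "C")}
        fits_k = {"A": _fit("A"), "B": _fit("B", r2=0.2), "D": _fit("D")}
        out = classify_stability(filter_fits(fits_c, fits_k, excluded_baseline=["E"]))
        assert sorted(out.transcript_id) == ["A", "B", "C", "D", "E"]
        assert (out["class"] != "").all()


class TestPipeline:
    def test_noiseless_end_to_end(self, noiseless_experiment):
        control, knockdown, truth = noiseless_experiment
        table, counts = stability_pipeline(control, knockdown)
        merged = table.merge(truth.table, on="transcript_id", suffixes=("_fit", "_true"))
        nonref = merged[~merged.is_reference]
        assert (nonref["class"] == nonref["true_class"]).all()
        for cond in ("control", "knockdown"):
            rel_err = np.abs(
                nonref[f"t_half_{cond}_fit"] / nonref[f"t_half_{cond}_true"] - 1
            )
            assert rel_err.max() < 0.01

    def test_funnel_counts_are_monotone_and_sum(self, noisy_pipeline):
        table, counts, _ = noisy_pipeline
        assert (
            counts["input"]
            >= counts["total_fitted"]
            >= counts["r2_pass"]
            >= counts["rapid_pass"]
            >= counts["analyzable"]
            >= counts["changed"]
        )
        assert counts["changed"] == counts["stabilized"] + counts["destabilized"]
        excl = sum(
            counts[k]
            for k in ("excluded_baseline", "excluded_fit", "excluded_rapid", "excluded_censored")
        )
        assert counts["analyzable"] + excl == counts["input"] == len(table)

    def test_scale_invariance_of_calls(self, timepoints):
        """A per-time-point global factor leaves fits and calls unchanged."""
        from stabiloc.simulate import SimDecayConfig, simulate_decay_experiment

        cfg = SimDecayConfig(n_transcripts=25, noise_cv=0.05, seed=8)
        control, knockdown, _ = simulate_decay_experiment(cfg)
        g = np.array([1.0, 0.8, 1.3, 0.5, 2.0, 0.9, 1.7])
        scaled = TimeCourseMatrix(
            condition="c", values=control.values * g[np.newaxis, :]
        )
        t1, _ = stability_pipeline(control, knockdown)
        t2, _ = stability_pipeline(scaled, knockdown)
        pd.testing.assert_series_equal(t1["class"], t2["class"])
        np.testing.assert_allclose(
            t1["t_half_control"], t2["t_half_control"], rtol=1e-6
        )

    def test_disjoint_conditions_rejected(self):
        a = _matrix({**_refs_const(), "TX1": [10, 5, 2, 1, 1, 1, 1]})
        b = _matrix({**_refs_const(), "TX2": [10, 5, 2, 1, 1, 1, 1]})
        b.values.index = ["RPLP0", "PGK1", "TRAP1", "TX2"]
        with pytest.raises(ValueError):
            stability_pipeline(a, b)


class TestMatrixIO:
    def test_tsv_round_trip(self, tmp_path, noiseless_experiment):
        control, _, _ = noiseless_experiment
        path = tmp_path / "control.tsv"
        control.to_tsv(path)
        back = TimeCourseMatrix.from_tsv(path, "control")
        np.testing.assert_allclose(back.values.to_numpy(), control.values.to_numpy(), rtol=1e-12)
        assert list(back.transcripts) == list(control.transcripts)
        np.testing.assert_array_equal(back.timepoints, control.timepoints)

    @pytest.mark.parametrize(
        "values,err",
        [
            ({"A": [1, 2, 3]}, "4 time points"),
            ({"A": [1, 2, 3, -1]}, "non-negative"),
        ],
    )
    def test_invalid_matrix_rejected(self, values, err):
        cols = [0.0, 3.0, 6.0, 9.0][: len(next(iter(values.values())))]
        df = pd.DataFrame.from_dict(values, orient="index", columns=cols)
        with pytest.raises(ValueError, match=err):
            TimeCourseMatrix(condition="c", values=df.astype(float))
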