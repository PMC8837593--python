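import numpy as np
import pandas as pd
import pytest
from types import SimpleNamespace

from mtpa.behavior import _top_pcs, partial_correlation, pc_partial, screen_measures, task_identifiability
from mtpa.errors import UndefinedResultError
from mtpa.networks import NetworkAssignment, ThresholdedConfig
from mtpa.simulate import CohortSpec, simulate_cohort
from scipy import stats


def result_stub(connection, subjects, proba_task, proba_rest=None):
    n = len(subjects)
    if proba_rest is None:
        proba_rest = [0.5] * n
    return SimpleNamespace(
        connection=connection,
        subjects=np.array(list(subjects) * 2),
        labels=np.array([1] * n + [0] * n),
        proba=np.array(list(proba_task) + list(proba_rest)),
    )


TWO_NET = NetworkAssignment(labels={0: "A", 1: "A", 2: "B", 3: "B"})


def full_mask(n=2):
    return ThresholdedConfig(networks=["A", "B"][:n], mask=np.ones((n, n), int), threshold=0.7)


class TestTaskIdentifiability:
    def test_constant_probabilities(self):
        res = [result_stub((0, 1), ["s1", "s2"], [0.9, 0.9])]
        scores = task_identifiability(res, full_mask(), TWO_NET)
        np.testing.assert_allclose(scores["score"], 0.9)

    def test_mean_of_two_connections(self):
        res = [
            result_stub((0, 1), ["s1"], [0.6]),
            result_stub((2, 3), ["s1"], [0.8]),
        ]
        scores = task_identifiability(res, full_mask(), TWO_NET)
        assert np.isclose(scores.loc[0, "score"], 0.7)
        assert scores.loc[0, "n_connections"] == 2

    def test_empty_configuration_errors(self):
        cfg = ThresholdedConfig(networks=["A", "B"], mask=np.zeros((2, 2), int), threshold=0.7)
        with pytest.raises(UndefinedResultError):
            task_identifiability([result_stub((0, 1), ["s1"], [0.9])], cfg, TWO_NET)

    def test_subthreshold_blocks_excluded(self):
        mask = np.zeros((2, 2), int)
        mask[0, 0] = 1  # only A-A survives
        cfg = ThresholdedConfig(networks=["A", "B"], mask=mask, threshold=0.7)
        res = [
            result_stub((0, 1), ["s1"], [0.6]),  # A-A
            result_stub((2, 3), ["s1"], [0.9]),  # B-B, masked out
        ]
        scores = task_identifiability(res, cfg, TWO_NET)
        assert np.isclose(scores.loc[0, "score"], 0.6)

    def test_include_rest_variant(self):
        res = [result_stub((0, 1), ["s1"], [0.8], proba_rest=[0.4])]
        scores = task_identifiability(res, full_mask(), TWO_NET, include_rest=True)
        assert np.isclose(scores.loc[0, "score"], (0.8 + 0.6) / 2)


class TestPartialCorrelation:
    def test_identity_with_independent_covariate(self, rng):
        x = rng.standard_normal(50)
        z = rng.standard_normal(50)
        r, p, n = partial_correlation(x, x.copy(), z)
        assert np.isclose(r, 1.0)
        assert p < 1e-12 and n == 50

    def test_y_equal_to_covariate_errors(self, rng):
        z = rng.standard_normal(30)
        with pytest.raises(UndefinedResultError):
            partial_correlation(rng.standard_normal(30), z.copy(), z)

    def test_recursive_formula_oracle(self, rng):
        # 12-row table, one covariate: r_xy.z from pairwise correlations
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        z = rng.standard_normal(12)
        r, _, _ = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert abs(r - oracle) < 1e-10

    def test_no_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(40)
        y = 0.3 * x + rng.standard_normal(40)
        r, p, n = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert np.isclose(r, r_ref) and np.isclose(p, p_ref)

    def test_pairwise_complete_rows(self, rng):
        x = rng.standard_normal(30)
        y = x + 0.1 * rng.standard_normal(30)
        y[5] = np.nan
        r, p, n = partial_correlation(x, y)
        assert n == 29 and r > 0.9

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="complete rows"):
            partial_correlation(np.ones(3), np.ones(3), np.ones((3, 2)))


def with_corr(x, r0, rng):
    """A vector whose empirical correlation with x is exactly r0."""
    xs = (x - x.mean()) / x.std()
    b = rng.standard_normal(len(x))
    b = b - b.mean()
    b -= xs * (xs @ b) / (xs @ xs)
    b /= b.std()
    return r0 * xs + np.sqrt(1 - r0**2) * b


class TestScreenMeasures:
    def test_threshold_arithmetic(self, rng):
        n = 4000
        scores = rng.standard_normal(n)
        strong = with_corr(scores, 0.3, rng)
        weak = with_corr(scores, 0.07, rng)
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{k}" for k in range(n)],
                "age": rng.integers(22, 38, n),
                "sex": rng.integers(0, 2, n),
                "strong": strong,
                "weak": weak,
            }
        )
        sc = pd.DataFrame({"subject_id": frame["subject_id"], "score": scores})
        out = screen_measures(sc, frame, m=192).set_index("measure")
        # strong: p << .05/192 and |r| > .1 -> significant
        assert out.loc["strong", "significant"]
        # weak: p tiny at n=4000 but |r| <= .1 -> filtered by effect size
        assert out.loc["weak", "p"] < 0.05 / 192
        assert not out.loc["weak", "significant"]

    def test_bonferroni_bar(self, rng):
        # borderline p: r=.3 with p~.01 must not pass .05/192
        n = 70
        scores = rng.standard_normal(n)
        y = with_corr(scores, 0.3, rng)
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{k}" for k in range(n)],
                "age": np.zeros(n) + rng.standard_normal(n),
                "sex": rng.integers(0, 2, n),
                "m": y,
            }
        )
        sc = pd.DataFrame({"subject_id": frame["subject_id"], "score": scores})
        out = screen_measures(sc, frame, m=192).set_index("measure")
        assert out.loc["m", "p"] > 0.05 / 192
        assert not out.loc["m", "significant"]

    def test_paper_case_thresholds(self):
        # the decision rule itself: r=-.11, p=2.4e-4 clears .05/192
        assert 2.4e-4 < 0.05 / 192
        assert abs(-0.11) > 0.1

    def test_non_numeric_skipped(self, rng, caplog):
        import logging

        n = 30
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{k}" for k in range(n)],
                "age": rng.integers(22, 38, n),
                "sex": rng.integers(0, 2, n),
                "notes": ["x"] * n,
                "ok": rng.standard_normal(n),
            }
        )
        sc = pd.DataFrame({"subject_id": frame["subject_id"], "score": rng.standard_normal(n)})
        with caplog.at_level(logging.WARNING):
            out = screen_measures(sc, frame, m=192)
        assert "notes" not in out["measure"].tolist()
        assert "ok" in out["measure"].tolist()

    def test_m_smaller_than_measures_rejected(self, rng):
        n = 30
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{k}" for k in range(n)],
                "age": rng.integers(22, 38, n),
                "sex": rng.integers(0, 2, n),
                "a": rng.standard_normal(n),
                "b": rng.standard_normal(n),
            }
        )
        sc = pd.DataFrame({"subject_id": frame["subject_id"], "score": rng.standard_normal(n)})
        with pytest.raises(ValueError, match="m must be"):
            screen_measures(sc, frame, m=1)


class TestPcPartial:
    def _toy(self, rng, n=200):
        e = rng.standard_normal(n)
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{k}" for k in range(n)],
                "age": rng.integers(22, 38, n),
                "sex": rng.integers(0, 2, n),
                "performance": e + 0.3 * rng.standard_normal(n),
                "perf_alt": e + 0.3 * rng.standard_normal(n),
                "cognition": e + 0.3 * rng.standard_normal(n),
                "cog_alt": e + 0.3 * rng.standard_normal(n),
            }
        )
        sc = pd.DataFrame(
            {"subject_id": frame["subject_id"], "score": e + 0.3 * rng.standard_normal(n)}
        )
        return sc, frame

    def test_zero_components_is_noop(self, rng):
        sc, frame = self._toy(rng)
        plain = screen_measures(sc, frame, m=192)
        same = pc_partial(
            sc, frame, ["cognition", "cog_alt"], ["performance", "perf_alt"], n_components=0, m=192
        )
        pd.testing.assert_frame_equal(plain, same)

    def test_single_column_pc_is_standardized_column(self, rng):
        col = pd.DataFrame({"c": rng.standard_normal(50)})
        pcs = _top_pcs(col, 1)
        z = (col["c"] - col["c"].mean()) / col["c"].std(ddof=0)
        agree = min(np.abs(pcs[:, 0] - z).max(), np.abs(pcs[:, 0] + z).max())
        assert agree < 1e-10

    def test_partialling_attenuates_driven_association(self, rng):
        sc, frame = self._toy(rng)
        before = screen_measures(sc, frame, m=192).set_index("measure")
        after = pc_partial(
            sc, frame, ["cognition", "cog_alt"], ["performance", "perf_alt"], m=192
        ).set_index("measure")
        assert abs(after.loc["performance", "r"]) < abs(before.loc["performance", "r"])

    def test_empty_column_set_rejected(self, rng):
        sc, frame = self._toy(rng)
        with pytest.raises(ValueError, match="nonempty"):
            pc_partial(sc, frame, [], ["performance"], m=192)


class TestScreeningPower:
    # the full 25-replicate n=400 power/FWE property runs in the
    # acceptance suite; this is a single-replicate smoke of the same path
    def test_planted_measure_detected_single_replicate(self):
        spec = CohortSpec(
            n_subjects=400,
            n_regions=4,
            n_frames=10,
            planted_pairs=(),
            engagement_sd=0.5,
            behavior_loading=1.5,
            seed=1000,
            n_behavior_measures=192,
        )
        _, behavior = simulate_cohort(spec)
        rng = np.random.default_rng(2000)
        scores = pd.DataFrame(
            {
                "subject_id": behavior["subject_id"],
                "score": behavior["engagement"] + 0.3 * rng.standard_normal(400),
            }
        )
        out = screen_measures(scores, behavior, m=192).set_index("measure")
        assert out.loc["performance", "significant"]
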