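"""QC filter, nonpositive replacement, CRS reduction, PQN, batch correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epmet.preprocess import (Preprocessor, annotation_rate, batch_correct,
                              crs_reduce, crs_scores, pqn_log2,
                              qc_filter_fwhm, replace_nonpositive)


def _series(values):
    return pd.Series(values, index=[f"S{i}" for i in range(len(values))])


class TestQCFilter:
    def test_zero_variance_keeps_everything(self):
        assert qc_filter_fwhm(_series([1.0] * 5)) == [f"S{i}" for i in range(5)]

    def test_broad_line_excluded(self):
        # mean 1.667, sample SD 1.633 -> threshold 4.93 excludes the 5.0
        kept = qc_filter_fwhm(_series([1.0, 1.0, 1.0, 1.0, 1.0, 5.0]))
        assert kept == [f"S{i}" for i in range(5)]

    def test_moderate_outlier_within_two_sd_kept(self):
        # threshold mean + 2 SD = 2.875 exceeds the maximum 2.5
        kept = qc_filter_fwhm(_series([1.0, 1.0, 1.0, 2.5]))
        assert kept == [f"S{i}" for i in range(4)]

    def test_filter_is_one_sided(self):
        kept = qc_filter_fwhm(_series([0.01, 1.0, 1.0, 1.0, 1.05]))
        assert "S0" in kept

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            qc_filter_fwhm(_series([1.0]))


class TestReplaceNonpositive:
    def test_stated_replacement_rule(self):
        m = pd.DataFrame({"b1": [-2.0, 5.0, 10.0]})
        out = replace_nonpositive(m)
        assert out["b1"].tolist() == [1.0, 5.0, 10.0]

    def test_all_positive_untouched(self):
        m = pd.DataFrame({"b1": [0.5, 5.0, 10.0], "b2": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(replace_nonpositive(m), m)

    def test_zero_counts_as_nonpositive(self):
        m = pd.DataFrame({"b1": [0.0, 0.5, 2.0]})
        assert replace_nonpositive(m)["b1"].tolist() == [0.1, 0.5, 2.0]

    def test_bin_without_positive_named_in_error(self):
        m = pd.DataFrame({"good": [1.0, 2.0], "dead": [-1.0, 0.0]})
        with pytest.raises(ValueError, match="dead"):
            replace_nonpositive(m)


class TestCRS:
    def test_single_bin_metabolite_kept_as_representative(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.lognormal(size=(30, 2)), columns=["a", "b"])
        ann = pd.DataFrame({"metabolite": ["solo"]}, index=["a"])
        reduced, res = crs_reduce(m, ann)
        assert res.representative["solo"] == "a"
        assert res.passed["solo"]
        assert list(reduced.columns) == ["a", "b"]

    def test_representative_matches_bruteforce_mean_correlation(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=60)
        m = pd.DataFrame({
            "A": z + 0.2 * rng.normal(size=60),
            "B": z + 0.8 * rng.normal(size=60),
            "C": z + 0.8 * rng.normal(size=60),
            "free": rng.normal(size=60),
        })
        m = np.exp2(m + 10)  # positive intensities, log-linear structure
        ann = pd.DataFrame({"metabolite": ["met"] * 3},
                           index=["A", "B", "C"])
        _, res = crs_reduce(m, ann)
        # independent oracle: mean pairwise Pearson on the log scale
        corr = np.log2(m[["A", "B", "C"]]).corr().to_numpy()
        np.fill_diagonal(corr, np.nan)
        expect = ["A", "B", "C"][int(np.nanargmax(np.nanmean(corr, axis=1)))]
        assert res.representative["met"] == expect
        assert expect == "A"
        got = dict(res.scores["met"])
        oracle = dict(zip(["A", "B", "C"], np.nanmean(corr, axis=1)))
        for k in oracle:
            assert got[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_failing_metabolite_keeps_all_bins(self):
        rng = np.random.default_rng(2)
        n = 80
        cols = {}
        ann_rows = {}
        for i in range(6):  # five tight metabolites and one incoherent one
            z = rng.normal(size=n)
            rho = 0.98 if i < 5 else 0.0
            for j in range(3):
                name = f"m{i}_b{j}"
                noise = rng.normal(size=n)
                cols[name] = np.exp2(np.sqrt(rho) * z
                                     + np.sqrt(1 - rho) * noise + 12)
                ann_rows[name] = f"met{i}"
        m = pd.DataFrame(cols)
        ann = pd.DataFrame({"metabolite": pd.Series(ann_rows)})
        reduced, res = crs_reduce(m, ann)
        assert not res.passed["met5"]
        assert all(res.passed[f"met{i}"] for i in range(5))
        # 5 reduced to one bin each + 3 kept for the failing metabolite
        assert reduced.shape[1] == 5 + 3

    def test_passing_fixture_reduces_to_102_columns(self):
        from epmet.simulate import SimConfig, generate_cohort, generate_spectra
        cfg = SimConfig(group_sizes={"LNSP": 150, "MISCARRIAGE": 50,
                                     "PUL": 50, "TEP": 50},
                        within_metabolite_rho=(0.99,) * 12 + (0.95,) * 20,
                        planted_signals={}, batch_effect_sd=0.0,
                        dilution_sd=0.0, nonpositive_rate=0.0, seed=0)
        cohort = generate_cohort(cfg)
        matrix, annotation = generate_spectra(cohort, cfg)
        reduced, res = crs_reduce(replace_nonpositive(matrix), annotation)
        assert all(res.passed.values())
        assert reduced.shape[1] == 102

    def test_missing_bin_in_annotation_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        ann = pd.DataFrame({"metabolite": ["x"]}, index=["ghost"])
        with pytest.raises(ValueError, match="ghost"):
            crs_reduce(m, ann)

    def test_kept_bin_accounting(self, small_sim):
        _, _, _, matrix, annotation = small_sim
        m = replace_nonpositive(matrix)
        reduced, res = crs_reduce(m, annotation)
        n_unannotated = matrix.shape[1] - len(annotation)
        expected = n_unannotated
        for met, sc in res.scores.items():
            expected += 1 if res.passed[met] else len(sc)
        assert reduced.shape[1] == expected
        unannotated = [c for c in matrix.columns if c not in annotation.index]
        assert set(unannotated) <= set(reduced.columns)


class TestPQN:
    def test_reference_sample_has_unit_factor(self):
        ref = np.array([1.0, 2.0, 4.0, 8.0])
        m = pd.DataFrame([ref, ref, ref], columns=list("abcd"))
        out = pqn_log2(m)
        assert np.allclose(out.dilution_factor, 1.0)
        assert np.allclose(out.matrix.iloc[0], np.log2(ref))

    def test_pure_dilution_removed(self):
        ref = np.array([1.0, 2.0, 4.0, 8.0])
        m = pd.DataFrame([ref, ref, 3.0 * ref], columns=list("abcd"))
        out = pqn_log2(m)
        assert out.dilution_factor.iloc[2] == pytest.approx(3.0)
        assert np.allclose(out.matrix.iloc[2], np.log2(ref))

    def test_idempotence_of_normalization(self):
        # bins with their own baselines, moderate per-cell log-noise and a
        # strong per-sample dilution component
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.lognormal(mean=2.0, sigma=0.2, size=(50, 20)))
        m = m.mul(rng.lognormal(sigma=1.0, size=20), axis=1)
        m = m.mul(rng.lognormal(sigma=0.5, size=50), axis=0)
        out = pqn_log2(m)
        renorm = pqn_log2(np.exp2(out.matrix))
        assert renorm.dilution_factor.between(0.95, 1.05).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 100.0))
    def test_scale_invariance(self, seed, c):
        # against a given reference spectrum, a sample's dilution level
        # cannot influence its normalized profile
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.lognormal(size=(12, 8)))
        ref = m.median(axis=0)
        base = pqn_log2(m, reference=ref).matrix
        m2 = m.copy()
        m2.iloc[3] *= c
        scaled = pqn_log2(m2, reference=ref).matrix
        assert np.allclose(base.iloc[3], scaled.iloc[3], atol=1e-9)

    def test_nonpositive_input_rejected(self):
        m = pd.DataFrame({"a": [1.0, -1.0]})
        with pytest.raises(ValueError, match="replace_nonpositive"):
            pqn_log2(m)


def _batched_data(seed=0, n_per=150, p=40, shift=1.0, scale=1.0):
    rng = np.random.default_rng(seed)
    y1 = rng.normal(size=(n_per, p))
    y2 = shift + scale * rng.normal(size=(n_per, p))
    m = pd.DataFrame(np.vstack([y1, y2]),
                     index=[f"S{i}" for i in range(2 * n_per)])
    m.columns = [f"b{j}" for j in range(p)]
    batch = pd.Series(["B1"] * n_per + ["B2"] * n_per, index=m.index)
    return m, batch


class TestBatchCorrect:
    def test_single_batch_is_identity(self):
        m, _ = _batched_data()
        batch = pd.Series(["B1"] * len(m), index=m.index)
        out, _ = batch_correct(m, batch)
        pd.testing.assert_frame_equal(out, m)

    def test_location_shift_removed(self):
        # per-bin mean shifts between two large batches vanish after EB
        # correction (true across-bin shift variance keeps shrinkage mild)
        rng = np.random.default_rng(21)
        m, batch = _batched_data(seed=21, n_per=1000, shift=0.0)
        shifts = rng.normal(1.0, 0.5, m.shape[1])
        m.loc[batch == "B2"] += shifts
        out, _ = batch_correct(m, batch, method="eb")
        means = out.groupby(batch).mean()
        diff = (means.loc["B1"] - means.loc["B2"]).abs()
        assert (diff <= 0.05).all()

    def test_non_eb_matches_standardization_oracle(self):
        m, batch = _batched_data(seed=4, shift=0.7, scale=1.6)
        out, _ = batch_correct(m, batch, method="standardize")
        # closed form: per bin per batch standardize, rescale to pooled
        # within-batch SD, recenter at the weighted grand mean
        y = m.to_numpy()
        expect = np.empty_like(y)
        for j in range(y.shape[1]):
            col = y[:, j]
            grand = 0.0
            sse = 0.0
            for b in ("B1", "B2"):
                rows = (batch == b).to_numpy()
                grand += rows.mean() * col[rows].mean()
                sse += ((col[rows] - col[rows].mean()) ** 2).sum()
            pooled_sd = np.sqrt(sse / len(col))
            for b in ("B1", "B2"):
                rows = (batch == b).to_numpy()
                z = (col[rows] - col[rows].mean()) / col[rows].std(ddof=1)
                expect[rows, j] = z * pooled_sd + grand
        assert np.allclose(out.to_numpy(), expect, atol=1e-10)

    def test_dimensions_and_order_preserved(self):
        m, batch = _batched_data(seed=5)
        out, _ = batch_correct(m, batch)
        assert list(out.index) == list(m.index)
        assert list(out.columns) == list(m.columns)

    def test_covariate_signal_preserved(self):
        rng = np.random.default_rng(6)
        m, batch = _batched_data(seed=6, shift=1.5)
        lab = pd.Series(rng.choice(["LNSP", "CAO"], size=len(m)),
                        index=m.index)
        m2 = m.add((lab == "LNSP").astype(float) * 0.8, axis=0)
        out, _ = batch_correct(m2, batch, covariates=lab.to_frame("label"))
        diff = out[lab == "LNSP"].mean() - out[lab == "CAO"].mean()
        assert diff.mean() == pytest.approx(0.8, abs=0.1)

    def test_single_sample_batch_rejected(self):
        m, batch = _batched_data()
        batch = batch.copy()
        batch.iloc[0] = "B9"
        with pytest.raises(ValueError, match="B9"):
            batch_correct(m, batch)

    def test_frozen_transform_matches_infit_adjustment(self):
        m, batch = _batched_data(seed=7, shift=0.9)
        out, model = batch_correct(m, batch, method="standardize")
        again = model.transform(m, batch)
        assert np.allclose(out.to_numpy(), again.to_numpy(), atol=1e-10)


def test_annotation_rate_formatting():
    assert annotation_rate(92, 162) == 56.8
    assert annotation_rate(0, 10) == 0.0
    with pytest.raises(ValueError):
        annotation_rate(1, 0)


class TestPreprocessor:
    def test_stage_log_counts_monotone(self, preprocessed_default):
        prep, matrix, _ = preprocessed_default
        samples = [n for _, n, _ in prep.log_]
        bins = [b for _, _, b in prep.log_]
        assert samples == sorted(samples, reverse=True)
        assert bins == sorted(bins, reverse=True)
        assert matrix.shape == (samples[-1], bins[-1])

    def test_transform_applies_frozen_parameters(self, default_sim):
        _, _, df, matrix, annotation = default_sim
        disc = df.index[:240]
        val = df.index[240:]
        prep = Preprocessor().fit(matrix.loc[disc], annotation,
                                  df.loc[disc, "fwhm"], df.loc[disc, "batch"],
                                  df.loc[disc, ["binary_label"]])
        out = prep.transform(matrix.loc[val], df.loc[val, "fwhm"],
                             df.loc[val, "batch"])
        assert list(out.columns) == list(prep.matrix_.columns)
        assert set(out.index) <= set(val)
        assert np.isfinite(out.to_numpy()).all()
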