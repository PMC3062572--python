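"""Standard curves, replicate CV, titration summaries, group averaging
and cross-platform concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inscount import (
    NormState,
    SampleMeta,
    SyntheticConfig,
    fit_standard_curve,
    group_average,
    normalize_positive_controls,
    platform_concordance,
    replicate_cv,
    simulate_hybridization,
    simulate_titration,
    titration_summary,
)
from inscount.errors import AlignmentError, FitError, ValidationError

from conftest import make_matrix


class TestStandardCurve:
    def test_exact_log_linear(self):
        fmol = np.array([0.1, 0.5, 1, 5, 10])
        fit = fit_standard_curve(100 * fmol, fmol)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_three_point_closed_form(self):
        fit = fit_standard_curve([10, 100, 1000], [0.1, 1, 10])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.n_points == 3

    def test_identical_amounts_rejected(self):
        with pytest.raises(FitError):
            fit_standard_curve([10, 20, 30], [1, 1, 1])

    def test_zero_counts_dropped_then_too_few(self):
        with pytest.raises(FitError):
            fit_standard_curve([0, 0, 50], [0.1, 1, 10])

    def test_curve_independent_of_mass(self):
        """Spike-ins are mass-independent: curves fitted at two simulated
        masses agree within a few standard errors of the slope."""
        config = SyntheticConfig(seed=7)
        fits = []
        for mass in (0.1, 10.0):
            cm = simulate_hybridization(config, mass, n_replicates=3)
            fmols = cm.codeset.spike_fmols
            mean_counts = cm.counts.loc[fmols.index].mean(axis=1)
            fits.append(fit_standard_curve(mean_counts, fmols))
        se = np.hypot(fits[0].slope_se, fits[1].slope_se)
        assert abs(fits[0].slope - fits[1].slope) < 3 * se


class TestReplicateCV:
    def _grouped(self, factory, cols, condition="g1"):
        meta = [SampleMeta(s, condition=condition, replicate=i + 1) for i, s in enumerate(cols)]
        return factory(cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)

    def test_identical_replicates_cv_zero(self, matrix_factory):
        col = [10, 20, 30, 5, 5, 2, 2]
        cm = self._grouped(matrix_factory, {"a": col, "b": col, "c": col})
        summary = replicate_cv(cm)
        assert (summary.per_gene_cv["g1"] == 0).all()
        assert summary.median_cv["g1"] == 0

    def test_hand_computed_ten_percent(self, matrix_factory):
        cm = self._grouped(
            matrix_factory,
            {"a": [90, 90, 90, 1, 1, 1, 1], "b": [100, 100, 100, 1, 1, 1, 1],
             "c": [110, 110, 110, 1, 1, 1, 1]},
        )
        summary = replicate_cv(cm)
        assert summary.per_gene_cv.loc["geneA", "g1"] == pytest.approx(10.0)
        assert summary.median_cv["g1"] == pytest.approx(10.0)

    def test_zero_mean_flagged_not_zero(self, matrix_factory):
        cm = self._grouped(
            matrix_factory,
            {"a": [0, 90, 90, 1, 1, 1, 1], "b": [0, 100, 100, 1, 1, 1, 1],
             "c": [0, 110, 110, 1, 1, 1, 1]},
        )
        summary = replicate_cv(cm)
        assert np.isnan(summary.per_gene_cv.loc["geneA", "g1"])
        assert summary.undefined["g1"] == ["geneA"]
        assert summary.median_cv["g1"] == pytest.approx(10.0)  # median over defined genes

    def test_singleton_group_rejected(self, matrix_factory):
        cm = self._grouped(matrix_factory, {"a": [1, 2, 3, 4, 5, 6, 7]})
        with pytest.raises(ValidationError, match="g1"):
            replicate_cv(cm)

    def test_poisson_cv_matches_closed_form(self, tiny_codeset, rng):
        """Poisson replicates at mean 1000 have CV near 100/sqrt(1000) ~= 3.16%."""
        n = 200
        cols = {f"r{i}": rng.poisson(1000.0, size=7).astype(float) for i in range(n)}
        meta = [SampleMeta(s, condition="g", replicate=i + 1) for i, s in enumerate(cols)]
        cm = make_matrix(tiny_codeset, cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)
        summary = replicate_cv(cm)
        assert summary.median_cv["g"] == pytest.approx(100 / np.sqrt(1000), rel=0.15)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, tiny_codeset, c):
        cols = {"a": [90, 10, 30, 1, 1, 1, 1], "b": [100, 12, 33, 1, 1, 1, 1],
                "c": [110, 14, 27, 1, 1, 1, 1]}
        meta = [SampleMeta(s, condition="g", replicate=i + 1) for i, s in enumerate(cols)]
        cm1 = make_matrix(tiny_codeset, cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)
        cm2 = make_matrix(
            tiny_codeset, {k: [v * c for v in vals] for k, vals in cols.items()},
            norm_state=NormState.POSITIVE_NORMALIZED, meta=meta,
        )
        pd.testing.assert_frame_equal(
            replicate_cv(cm1).per_gene_cv, replicate_cv(cm2).per_gene_cv, rtol=1e-9
        )

    def test_median_cv_decreases_with_mass(self):
        """More RNA -> more counts -> lower relative Poisson noise."""
        cm, _ = normalize_positive_controls(simulate_titration(SyntheticConfig(seed=13)))
        summary = replicate_cv(cm)
        medians = [summary.median_cv[f"{m:g}ug"] for m in (0.1, 1.0, 10.0)]
        assert medians[0] > medians[1] > medians[2]


class TestTitrationSummary:
    def test_exact_proportionality(self, tiny_codeset):
        cols = {"m0.1_1": [24, 24, 24, 9, 9, 3, 3], "m0.1_2": [24, 24, 24, 9, 9, 3, 3],
                "m1_1": [240, 240, 240, 9, 9, 3, 3], "m1_2": [240, 240, 240, 9, 9, 3, 3]}
        meta = [
            SampleMeta("m0.1_1", rna_mass=0.1, condition="m0.1", replicate=1),
            SampleMeta("m0.1_2", rna_mass=0.1, condition="m0.1", replicate=2),
            SampleMeta("m1_1", rna_mass=1.0, condition="m1", replicate=1),
            SampleMeta("m1_2", rna_mass=1.0, condition="m1", replicate=2),
        ]
        cm = make_matrix(tiny_codeset, cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)
        tit = titration_summary(cm)
        assert tit.fold_ratio(1.0, 0.1) == pytest.approx(10.0)

    def test_single_mass_rejected(self, tiny_codeset):
        cols = {"a": [1] * 7, "b": [1] * 7}
        meta = [SampleMeta(s, rna_mass=1.0, condition="c", replicate=i + 1) for i, s in enumerate(cols)]
        cm = make_matrix(tiny_codeset, cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)
        with pytest.raises(ValidationError):
            titration_summary(cm)

    def test_simulated_fold_scaling(self):
        """Default generator: target counts scale ~10x per decade of RNA and
        negative-control background roughly doubles from 1 to 10 ug."""
        cm, _ = normalize_positive_controls(simulate_titration(SyntheticConfig(seed=17)))
        tit = titration_summary(cm)
        assert tit.fold_ratio(1.0, 0.1) == pytest.approx(10.0, rel=0.2)
        assert tit.fold_ratio(10.0, 1.0, row="average_negatives") == pytest.approx(2.0, rel=0.25)


class TestGroupAverage:
    def test_identical_samples(self, matrix_factory):
        col = [5, 6, 7, 8, 9, 10, 11]
        meta = [SampleMeta(s, condition="g", replicate=i + 1) for i, s in enumerate("abc")]
        cm = matrix_factory({"a": col, "b": col, "c": col}, meta=meta)
        means, sds, ns = group_average(cm)
        assert means["g"].tolist() == col
        assert (sds["g"] == 0).all()
        assert ns["g"] == 3

    def test_paper_style_design_shapes(self, tiny_codeset, rng):
        """53 samples in 18 biological-replicate groups (all but one of 3)
        average to an 18-column profile."""
        groups = {f"grp{i}": [f"grp{i}_r{j}" for j in range(3)] for i in range(17)}
        groups["grp17"] = ["grp17_r0", "grp17_r1"]
        all_ids = [s for ids in groups.values() for s in ids]
        assert len(all_ids) == 53
        cols = {s: rng.poisson(100, size=7).astype(float) for s in all_ids}
        meta = [SampleMeta(s) for s in all_ids]
        cm = make_matrix(tiny_codeset, cols, meta=meta)
        means, sds, ns = group_average(cm, groups)
        assert means.shape == (7, 18)
        assert ns.sum() == 53

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_brute_force_oracle(self, tiny_codeset, data):
        n = data.draw(st.integers(min_value=2, max_value=6))
        values = data.draw(
            st.lists(
                st.lists(st.floats(min_value=0, max_value=1e5), min_size=7, max_size=7),
                min_size=n, max_size=n,
            )
        )
        cols = {f"s{i}": v for i, v in enumerate(values)}
        cm = make_matrix(tiny_codeset, cols, meta=[SampleMeta(s) for s in cols])
        means, sds, _ = group_average(cm, {"g": list(cols)})
        for gi, gene in enumerate(tiny_codeset.gene_ids):
            vals = [values[s][gi] for s in range(n)]
            mu = sum(vals) / n
            var = sum((v - mu) ** 2 for v in vals) / (n - 1)
            assert means.loc[gene, "g"] == pytest.approx(mu, rel=1e-9, abs=1e-9)
            assert sds.loc[gene, "g"] == pytest.approx(var**0.5, rel=1e-9, abs=1e-6)


class TestConcordance:
    def _profile(self, rng, genes=20, groups=5):
        vals = 10 ** rng.normal(2.0, 0.8, size=(genes, groups))
        return pd.DataFrame(vals, index=[f"g{i}" for i in range(genes)],
                            columns=[f"grp{j}" for j in range(groups)])

    def test_self_concordance_is_one(self, rng):
        a = self._profile(rng)
        res = platform_concordance(a, a)
        assert res.r == pytest.approx(1.0)

    def test_scaling_invariance_on_log(self, rng):
        a = self._profile(rng)
        res = platform_concordance(a, 7.3 * a, scale="log10")
        assert res.r == pytest.approx(1.0)

    def test_exclusions_reduce_pairs(self, rng):
        a = self._profile(rng)
        res_all = platform_concordance(a, a)
        res_excl = platform_concordance(a, a, exclude=["g0", "g1"])
        assert res_excl.n_pairs == res_all.n_pairs - 2 * a.shape[1]

    def test_nonpositive_pairs_dropped_with_warning(self, rng):
        a = self._profile(rng)
        b = a.copy()
        b.iloc[0, 0] = 0.0
        with pytest.warns(UserWarning, match="nonpositive"):
            res = platform_concordance(a, b)
        assert res.n_dropped == 1

    def test_too_few_shared_genes(self, rng):
        a = self._profile(rng, genes=3)
        with pytest.raises(AlignmentError):
            platform_concordance(a, a, exclude=["g0"])

    def test_attenuation_matches_closed_form(self, rng):
        """Two noisy re-measurements of one log-scale signal correlate at
        r ~= s^2/(s^2+n^2); simulated r must sit within Monte-Carlo error."""
        genes, groups = 60, 6
        sig_sd, noise_cv = 0.8, 0.25
        truth = rng.normal(2.0, sig_sd, size=(genes, groups))
        noise_sd_log10 = np.sqrt(np.log1p(noise_cv**2)) / np.log(10)
        mk = lambda: pd.DataFrame(
            10 ** (truth + rng.normal(0, noise_sd_log10, size=truth.shape)),
            index=[f"g{i}" for i in range(genes)], columns=[f"grp{j}" for j in range(groups)],
        )
        res = platform_concordance(mk(), mk())
        expected = sig_sd**2 / (sig_sd**2 + noise_sd_log10**2)
        # MC tolerance: Fisher-z SE for n pairs, ~3 SE
        se = 1 / np.sqrt(genes * groups - 3)
        assert np.arctanh(res.r) == pytest.approx(np.arctanh(expected), abs=3 * se)
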