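"""Background thresholds (negative-control and deletion-calibrated) and
detection calling, including brute-force oracle checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inscount import (
    BackgroundModel,
    DeletionSummary,
    NormState,
    SampleMeta,
    call_detection,
    deletion_threshold,
    detection_summary,
    negative_control_threshold,
    simulate_hybridization,
    SyntheticConfig,
)
from inscount.errors import BackgroundModelError

from conftest import make_matrix


def _normed(factory, columns, conditions=None):
    meta = None
    if conditions is not None:
        meta = [
            SampleMeta(sample_id=s, condition=c, replicate=i + 1)
            for i, (s, c) in enumerate(zip(columns, conditions))
        ]
    return factory(columns, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)


class TestNegativeControlThreshold:
    def test_hand_arithmetic_mean25_sd8(self):
        """Pooled negatives {17,25,33} have mean 25, SD 8 (n-1), so k=3
        gives the 49-count cutoff."""
        from inscount import CodeSet, ProbeClass, ProbeDef

        cs = CodeSet(
            (
                ProbeDef("geneA", ProbeClass.TARGET),
                ProbeDef("POS_A", ProbeClass.POSITIVE, spike_fmol=1.0),
                ProbeDef("NEG_A", ProbeClass.NEGATIVE),
                ProbeDef("NEG_B", ProbeClass.NEGATIVE),
                ProbeDef("NEG_C", ProbeClass.NEGATIVE),
            )
        )
        cm = make_matrix(cs, {"s1": [500, 100, 17, 25, 33]},
                         norm_state=NormState.POSITIVE_NORMALIZED)
        model = negative_control_threshold(cm, k=3)
        assert model.mean == pytest.approx(25.0)
        assert model.sd == pytest.approx(8.0)
        assert model.threshold == pytest.approx(49.0)
        assert model.method == "negctrl_mean_sd"

    def test_zero_variance_gives_mean(self, matrix_factory):
        cm = _normed(matrix_factory, {"s1": [1, 1, 1, 9, 9, 7, 7], "s2": [1, 1, 1, 9, 9, 7, 7]})
        for k in (0, 3, 10):
            assert negative_control_threshold(cm, k=k).threshold == pytest.approx(7.0)

    def test_k_zero_gives_mean(self, matrix_factory):
        cm = _normed(matrix_factory, {"s1": [1, 1, 1, 9, 9, 10, 30], "s2": [1, 1, 1, 9, 9, 20, 40]})
        assert negative_control_threshold(cm, k=0).threshold == pytest.approx(25.0)

    def test_requires_normalized_counts(self, matrix_factory):
        cm = matrix_factory({"s1": [1, 1, 1, 9, 9, 7, 7], "s2": [1, 1, 1, 9, 9, 8, 8]})
        with pytest.raises(BackgroundModelError):
            negative_control_threshold(cm)

    def test_threshold_monotone_in_k(self, matrix_factory):
        cm = _normed(matrix_factory, {"s1": [1, 1, 1, 9, 9, 5, 30], "s2": [1, 1, 1, 9, 9, 12, 44]})
        ts = [negative_control_threshold(cm, k=k).threshold for k in (0, 1, 2, 3, 5)]
        assert ts == sorted(ts)


class TestDeletionThreshold:
    # replicate summaries of residual counts in the three deletion strains
    SUMMARIES = (
        DeletionSummary("ins-4", 1500.0, 31.0, 2.0),
        DeletionSummary("ins-5", 1500.0, 124.0, 55.0),
        DeletionSummary("ins-6", 2000.0, 137.0, 53.0),
    )

    def test_max_plus_4sd(self):
        model = deletion_threshold(self.SUMMARIES, k=4)
        assert model.threshold == pytest.approx(137 + 4 * 53)  # 349
        assert model.scope == "ins-6"
        assert model.method == "deletion_calibrated"

    @pytest.mark.parametrize(
        "rounding,expected", [("none", 349.0), ("ceil_to_50", 350.0), ("ceil_to_100", 400.0)]
    )
    def test_rounding_policies(self, rounding, expected):
        assert deletion_threshold(self.SUMMARIES, k=4, rounding=rounding).threshold == expected

    def test_single_summary_zero_sd(self):
        model = deletion_threshold([DeletionSummary("g", 500.0, 100.0, 0.0)], k=4)
        assert model.threshold == 100.0

    def test_empty_collection_rejected(self):
        with pytest.raises(BackgroundModelError):
            deletion_threshold([])

    def test_sd_of_max_gene_is_used(self):
        """k multiplies the SD of the summary attaining the max mean, not the
        largest SD overall."""
        summaries = [
            DeletionSummary("a", 900.0, 100.0, 50.0),
            DeletionSummary("b", 900.0, 120.0, 1.0),
        ]
        assert deletion_threshold(summaries, k=4).threshold == pytest.approx(124.0)


class TestDetection:
    def _two_condition_matrix(self, factory):
        cols = {
            "wt_1": [1500, 600, 31, 10, 10, 5, 5],
            "wt_2": [1500, 600, 31, 10, 10, 5, 5],
        }
        meta = [SampleMeta(s, condition="wt", replicate=i + 1) for i, s in enumerate(cols)]
        return factory(cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)

    def test_calls_against_400_cutoff(self, matrix_factory):
        """Residual-level counts (31) fall below the 400 cutoff; wild-type
        levels (1500) exceed it."""
        cm = self._two_condition_matrix(matrix_factory)
        model = BackgroundModel(threshold=400.0, method="fixed", scope="wt")
        calls = call_detection(cm, model)
        assert calls.calls.loc["geneA", "wt"]  # 1500 > 400
        assert calls.calls.loc["geneB", "wt"]  # 600 > 400
        assert not calls.calls.loc["geneC", "wt"]  # 31 < 400

    def test_tie_is_not_detected(self, matrix_factory):
        cm = self._two_condition_matrix(matrix_factory)
        model = BackgroundModel(threshold=1500.0, method="fixed", scope="wt")
        assert not call_detection(cm, model).calls.loc["geneA", "wt"]
        just_below = BackgroundModel(threshold=1500.0 - 1e-9, method="fixed", scope="wt")
        assert call_detection(cm, just_below).calls.loc["geneA", "wt"]

    def test_detection_summary_counts_by_class(self, matrix_factory):
        cm = self._two_condition_matrix(matrix_factory)
        model = BackgroundModel(threshold=400.0, method="fixed", scope="wt")
        summary = detection_summary(call_detection(cm, model), cm.codeset)
        assert summary.loc["target (n=3)", "wt"] == 2
        assert summary.loc["positive (n=2)", "wt"] == 0
        assert summary.loc["negative (n=2)", "wt"] == 0

    def test_all_zero_counts_threshold_zero(self, matrix_factory):
        cols = {"a_1": [0] * 7, "a_2": [0] * 7}
        meta = [SampleMeta(s, condition="a", replicate=i + 1) for i, s in enumerate(cols)]
        cm = matrix_factory(cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)
        model = BackgroundModel(threshold=0.0, method="fixed", scope="a")
        summary = detection_summary(call_detection(cm, model), cm.codeset)
        assert (summary["a"] == 0).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_brute_force_oracle(self, tiny_codeset, data):
        """detection_summary equals a per-cell recount on random matrices."""
        n_samp = data.draw(st.integers(min_value=2, max_value=5))
        values = data.draw(
            st.lists(
                st.lists(st.floats(min_value=0, max_value=1000), min_size=7, max_size=7),
                min_size=n_samp,
                max_size=n_samp,
            )
        )
        threshold = data.draw(st.floats(min_value=0, max_value=900))
        cols = {f"c_{i}": v for i, v in enumerate(values)}
        meta = [SampleMeta(s, condition="c", replicate=i + 1) for i, s in enumerate(cols)]
        cm = make_matrix(tiny_codeset, cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)
        model = BackgroundModel(threshold=threshold, method="fixed", scope="c")
        summary = detection_summary(call_detection(cm, model), tiny_codeset)
        # oracle: loop over probes, compare replicate mean to threshold
        by_class = {"target": 0, "positive": 0, "negative": 0}
        for probe in tiny_codeset.probes:
            vals = [cols[s][tiny_codeset.gene_ids.index(probe.gene_id)] for s in cols]
            if sum(vals) / len(vals) > threshold:
                by_class[probe.probe_class.value] += 1
        assert summary.loc["target (n=3)", "c"] == by_class["target"]
        assert summary.loc["positive (n=2)", "c"] == by_class["positive"]
        assert summary.loc["negative (n=2)", "c"] == by_class["negative"]

    def test_monotone_in_abundance(self, matrix_factory):
        """Raising one probe's counts never flips it detected -> undetected."""
        base = {"c_1": [100, 50, 10, 5, 5, 2, 2], "c_2": [100, 50, 10, 5, 5, 2, 2]}
        meta = [SampleMeta(s, condition="c", replicate=i + 1) for i, s in enumerate(base)]
        model = BackgroundModel(threshold=40.0, method="fixed", scope="c")
        detected_before = None
        for bump in (0, 10, 50, 500):
            cols = {k: list(v) for k, v in base.items()}
            for k in cols:
                cols[k][1] += bump
            cm = matrix_factory(cols, norm_state=NormState.POSITIVE_NORMALIZED, meta=meta)
            detected = call_detection(cm, model).calls.loc["geneB", "c"]
            if detected_before is not None:
                assert detected >= detected_before
            detected_before = detected

    def test_detected_targets_nondecreasing_in_mass(self):
        """With per-mass thresholds, more input RNA never detects fewer targets
        (the qualitative titration behavior)."""
        config = SyntheticConfig(seed=23)
        from inscount import normalize_positive_controls, simulate_titration

        cm, _ = normalize_positive_controls(simulate_titration(config))
        detected = []
        for mass in (0.0, 0.1, 1.0, 10.0):
            cond = f"{mass:g}ug"
            model = negative_control_threshold(cm, scope=cond, k=3)
            calls = call_detection(cm.subset_samples(cm.samples_where(condition=cond)), model)
            n = sum(calls.calls.loc[g, cond] for g in cm.codeset.targets)
            detected.append(n)
        assert detected == sorted(detected)
        # negative controls stay undetected under their own mean+3SD model
        for mass in (0.1, 1.0, 10.0):
            cond = f"{mass:g}ug"
            model = negative_control_threshold(cm, scope=cond, k=3)
            calls = call_detection(cm, model)
            assert sum(calls.calls.loc[g, cond] for g in cm.codeset.negatives) == 0
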