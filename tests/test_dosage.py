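"""Amplicon-dosage normalization chain, LR calling, and dropout flagging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from panelseq.dosage import (
    call_lr,
    dosage_chain,
    failed_samples,
    flag_dropout,
    normalize_batch,
    normalize_sample,
    region_dosage,
    summarize_region,
)
from panelseq.simulate import (
    DropoutSpec,
    LREventSpec,
    SimulationConfig,
    simulate_count_matrix,
    simulate_panel,
)


def _matrix(values, samples=None, amps=None):
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(arr.shape[0])]
    amps = amps or [f"a{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=samples, columns=amps)


class TestNormalizeSample:
    def test_uniform_matrix_gives_unit_ratios(self):
        ratios = normalize_sample(_matrix(np.full((4, 6), 500)))
        assert np.allclose(ratios.values, 1.0)

    def test_amplicon_at_twice_mean(self):
        m = _matrix(np.full((1, 4), 100))
        m.iloc[0, 0] = 250  # mean becomes 137.5; check direct arithmetic
        ratios = normalize_sample(m)
        assert ratios.iloc[0, 0] == pytest.approx(250 / 137.5)

    def test_all_zero_sample_marked_failed_and_excluded(self):
        m = _matrix(np.full((9, 4), 100))
        m.iloc[2] = 0
        assert failed_samples(m) == ["S2"]
        ratios = normalize_sample(m)
        assert "S2" not in ratios.index

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize_sample(_matrix([[-1, 2]]))


class TestNormalizeBatch:
    def test_systematic_amplicon_efficiency_cancelled(self):
        m = _matrix(np.full((10, 4), 100))
        m["a1"] = 200  # 2x efficiency across all samples
        adjusted = normalize_batch(normalize_sample(m))
        assert np.allclose(adjusted.values, 1.0)

    def test_single_sample_deletion_survives_median(self):
        # 40 amplicons: one halved amplicon barely moves the sample mean,
        # and the per-amplicon median is untouched by a 1/96 outlier
        m = _matrix(np.full((96, 40), 1000))
        m.loc["S0", "a0"] = 500
        adjusted = normalize_batch(normalize_sample(m))
        assert adjusted.loc["S0", "a0"] == pytest.approx(0.5, rel=0.02)
        others = adjusted.drop(index="S0")
        assert np.allclose(others.values, 1.0, atol=0.02)

    def test_minimum_batch_size_enforced(self):
        with pytest.raises(ValueError, match=">= 8"):
            normalize_batch(normalize_sample(_matrix(np.full((4, 4), 10))))

    def test_zero_median_amplicon_masked(self):
        m = _matrix(np.full((10, 4), 100))
        m["a2"] = 0
        adjusted = normalize_batch(normalize_sample(m))
        assert adjusted.attrs["masked_amplicons"] == ["a2"]
        assert "a2" not in adjusted.columns

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.integers(200, 2000, size=(12, 8)))
        once = normalize_batch(normalize_sample(m))
        twice = normalize_batch(once)
        assert np.allclose(once.values, twice.values)


class TestRegionSummaryAndDosage:
    def test_summary_is_mean_of_overlapping_amplicons(self, tiny_panel):
        adjusted = pd.DataFrame(
            [[0.5, 0.5, 0.5, 0.5, 1.0]] + [[1.0] * 5] * 9,
            index=[f"S{i}" for i in range(10)],
            columns=[f"amp{i}" for i in range(5)])
        summaries = summarize_region(adjusted, tiny_panel)
        assert summaries.loc["S0", "GENE_A/exon 1"] == pytest.approx(0.6)

    def test_dropout_attenuates_summary(self, tiny_panel):
        adjusted = pd.DataFrame([[1.0, 1.0, 0.5, 1.0, 1.0]] + [[1.0] * 5] * 9,
                                index=[f"S{i}" for i in range(10)],
                                columns=[f"amp{i}" for i in range(5)])
        summaries = summarize_region(adjusted, tiny_panel)
        assert summaries.loc["S0", "GENE_A/exon 1"] == pytest.approx(0.9)

    def test_wild_type_batch_dosage_is_two(self, tiny_panel):
        adjusted = pd.DataFrame(np.ones((10, 5)),
                                index=[f"S{i}" for i in range(10)],
                                columns=[f"amp{i}" for i in range(5)])
        dosages = region_dosage(summarize_region(adjusted, tiny_panel))
        assert np.allclose(dosages.values, 2.0)

    def test_untestable_region_propagates_null(self, tiny_panel):
        adjusted = pd.DataFrame(np.ones((10, 1)),
                                index=[f"S{i}" for i in range(10)],
                                columns=["unrelated"])
        summaries = summarize_region(adjusted, tiny_panel)
        assert summaries["GENE_A/exon 1"].isna().all()


class TestScaleInvariance:
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scaling_one_sample_leaves_dosages_unchanged(self, factor):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(seed=5, n_samples=12, n_genes=2,
                               regions_per_gene=2, amplicon_count_noise_cv=0.05)
        panel, _ = simulate_panel(cfg)
        m, _ = simulate_count_matrix(cfg, panel)
        _, base = dosage_chain(m, panel)
        scaled = m.astype(float).copy()
        scaled.iloc[3] *= factor
        _, after = dosage_chain(scaled, panel)
        assert np.allclose(base.values, after.values, atol=1e-9)


class TestCallLR:
    def _dosages(self, panel, rows):
        cols = [f"{r.gene_name}/{r.region_label}" for r in panel.regions]
        return pd.DataFrame(rows, index=[f"S{i}" for i in range(len(rows))],
                            columns=cols)

    def test_contiguous_deletion_merged_into_one_call(self):
        cfg = SimulationConfig(seed=0, n_genes=1, regions_per_gene=3)
        panel, _ = simulate_panel(cfg)
        d = self._dosages(panel, [[1.0, 1.05, 0.95], [2.0, 2.0, 2.0]])
        calls = call_lr(d, panel)
        assert len(calls) == 1
        assert calls[0].type == "deletion"
        assert calls[0].region_labels == ("exon 1", "exon 2", "exon 3")
        assert calls[0].sample_id == "S0"

    def test_wild_type_range_yields_no_calls(self):
        cfg = SimulationConfig(seed=0, n_genes=1, regions_per_gene=3)
        panel, _ = simulate_panel(cfg)
        d = self._dosages(panel, [[1.8, 2.2, 2.0]])
        assert call_lr(d, panel) == []

    def test_single_region_duplication(self):
        cfg = SimulationConfig(seed=0, n_genes=1, regions_per_gene=3)
        panel, _ = simulate_panel(cfg)
        d = self._dosages(panel, [[2.0, 2.9, 2.0]])
        calls = call_lr(d, panel)
        assert len(calls) == 1
        assert calls[0].type == "duplication"
        assert calls[0].region_labels == ("exon 2",)

    def test_lr_untested_region_excluded(self):
        cfg = SimulationConfig(seed=0, n_genes=1, regions_per_gene=3)
        panel, _ = simulate_panel(cfg)
        object.__setattr__(panel.regions[0], "tested_by_lr", False)
        adjusted = pd.DataFrame(np.ones((10, len(panel.amplicons))),
                                index=[f"S{i}" for i in range(10)],
                                columns=[a.amplicon_id for a in panel.amplicons])
        summaries = summarize_region(adjusted, panel)
        assert "GENE00/exon 1" not in summaries.columns


class TestFlagDropout:
    def test_single_amplicon_at_half_flagged(self, tiny_panel):
        adjusted = pd.DataFrame(np.ones((20, 5)),
                                index=[f"S{i}" for i in range(20)],
                                columns=[f"amp{i}" for i in range(5)])
        adjusted.loc["S3", "amp2"] = 0.5
        flags = flag_dropout(adjusted, tiny_panel)
        assert [(f.sample_id, f.amplicon_id) for f in flags] == [("S3", "amp2")]

    def test_uniform_batch_unflagged(self, tiny_panel):
        adjusted = pd.DataFrame(np.ones((20, 5)),
                                index=[f"S{i}" for i in range(20)],
                                columns=[f"amp{i}" for i in range(5)])
        assert flag_dropout(adjusted, tiny_panel) == []

    def test_lr_call_consumes_dropout_flags(self, tiny_panel):
        adjusted = pd.DataFrame(np.ones((20, 5)),
                                index=[f"S{i}" for i in range(20)],
                                columns=[f"amp{i}" for i in range(5)])
        adjusted.loc["S3"] = 0.5  # whole-region deletion
        dosages = region_dosage(summarize_region(adjusted, tiny_panel))
        lr_calls = call_lr(dosages, tiny_panel)
        assert len(lr_calls) == 1 and lr_calls[0].type == "deletion"
        assert flag_dropout(adjusted, tiny_panel, lr_calls) == []


class TestSimulatedBatches:
    def test_all_injected_events_called_and_no_false_calls(self):
        """96-sample batches, noise CV 0.08: every injected deletion /
        duplication called with correct type and span; event-free samples
        produce no calls; dropouts flagged, never promoted to LR."""
        total = found = 0
        for seed in range(1, 11):
            cfg = SimulationConfig(
                seed=seed, n_samples=96, n_genes=5, regions_per_gene=4,
                amplicon_count_noise_cv=0.08,
                lr_spec=[
                    LREventSpec("S003", "GENE01", ("exon 2",), -1),
                    LREventSpec("S010", "GENE02",
                                ("exon 1", "exon 2", "exon 3"), +1),
                ],
                dropout_spec=[DropoutSpec("S050", "GENE04_r2_a3")],
            )
            panel, _ = simulate_panel(cfg)
            matrix, truth = simulate_count_matrix(cfg, panel)
            _, dosages = dosage_chain(matrix, panel)
            calls = call_lr(dosages, panel)
            got = {(c.sample_id, c.gene_name, c.region_labels, c.type)
                   for c in calls}
            want = {("S003", "GENE01", ("exon 2",), "deletion"),
                    ("S010", "GENE02", ("exon 1", "exon 2", "exon 3"),
                     "duplication")}
            total += len(want)
            found += len(got & want)
            assert got == want, f"seed {seed}: {got ^ want}"
            adjusted = normalize_batch(normalize_sample(matrix))
            flags = flag_dropout(adjusted, panel, calls)
            assert ("S050", "GENE04_r2_a3") in {
                (f.sample_id, f.amplicon_id) for f in flags}
        assert found == total

    def test_injected_dosage_levels(self):
        cfg = SimulationConfig(seed=2, n_samples=96, n_genes=3,
                               regions_per_gene=3, amplicon_count_noise_cv=0.08,
                               lr_spec=[LREventSpec("S001", "GENE00",
                                                    ("exon 2",), -1),
                                        LREventSpec("S002", "GENE01",
                                                    ("exon 1",), +1)])
        panel, truth_panel = simulate_panel(cfg)
        matrix, truth = simulate_count_matrix(cfg, panel)
        _, dosages = dosage_chain(matrix, panel)
        disp = dosages.attrs["dispersion"]
        assert dosages.loc["S001", "GENE00/exon 2"] == pytest.approx(
            1.0, abs=3 * 2 * max(disp["GENE00/exon 2"], 0.05))
        assert dosages.loc["S002", "GENE01/exon 1"] == pytest.approx(
            3.0, abs=3 * 2 * max(disp["GENE01/exon 1"], 0.05))

    def test_noise_free_batch_is_exactly_wild_type(self):
        cfg = SimulationConfig(seed=4, n_samples=8, n_genes=2,
                               regions_per_gene=2, amplicon_count_noise_cv=0.0)
        panel, _ = simulate_panel(cfg)
        matrix, _ = simulate_count_matrix(cfg, panel)
        _, dosages = dosage_chain(matrix, panel)
        assert np.allclose(dosages.values, 2.0, atol=1e-9)
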