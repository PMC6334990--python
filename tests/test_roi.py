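"""ROI definition, extraction, and the step-wise comparison schedule."""

import numpy as np
import pandas as pd
import pytest

from surpeeg.cluster import Cluster, PermutationResult, TMap, paired_t_map
from surpeeg.hierbayes import GibbsConfig
from surpeeg.montage import make_montage
from surpeeg.ngram import train_ngram
from surpeeg.roi import (
    CONTROL_PREDICTORS,
    HYPOTHESES,
    ROIDefinition,
    define_rois,
    extract_roi,
    fit_hier,
    stepwise_compare,
)
from surpeeg.simulate import build_predictor_table, simulate_epochs
from surpeeg.surprisal import SurprisalSeries, ngram_surprisal

FAST = GibbsConfig(chains=2, warmup=150, draws=150)


@pytest.fixture(scope="module")
def montage8():
    return make_montage(8, 2, seed=0)


def perm_result(clusters, alpha=0.05):
    return PermutationResult(
        clusters=clusters, null_max_mass=np.zeros(500), n_permutations=500, alpha=alpha
    )


def tmap(t):
    from scipy import stats

    return TMap(
        t=t, p=2 * stats.t.sf(np.abs(t), 9), df=9,
        zero_variance=np.zeros_like(t, dtype=bool),
    )


class TestDefineROIs:
    def make_cluster(self, members, t):
        mass = float(sum(t[e, s] for e, s in members))
        return Cluster(members=members, sign=int(np.sign(mass)), mass=mass, corrected_p=0.01)

    def test_small_cluster_keeps_all_electrodes(self, montage8):
        # three electrodes on the same side of the midline
        side = np.flatnonzero(montage8.positions[:, 0] < 0)[:3]
        t = np.zeros((8, 20))
        members = [(int(e), s) for e in side for s in range(5, 9)]
        for e, s in members:
            t[e, s] = 4.0
        rois = define_rois(
            {"X-content": (perm_result([self.make_cluster(members, t)]), tmap(t))},
            montage8,
            times=np.linspace(0, 1, 20),
        )
        assert len(rois) == 1
        assert set(rois[0].electrodes) == set(int(e) for e in side)

    def test_midline_split_yields_two_rois(self, montage8):
        left = np.flatnonzero(montage8.positions[:, 0] < 0)[:2]
        right = np.flatnonzero(montage8.positions[:, 0] >= 0)[:2]
        t = np.zeros((8, 20))
        members = [(int(e), s) for e in (*left, *right) for s in range(5, 9)]
        for e, s in members:
            t[e, s] = 4.0
        rois = define_rois(
            {"X-content": (perm_result([self.make_cluster(members, t)]), tmap(t))},
            montage8,
            times=np.linspace(0, 1, 20),
        )
        assert len(rois) == 2
        ids = {r.id for r in rois}
        assert any(i.endswith("-L") for i in ids) and any(i.endswith("-R") for i in ids)
        for r in rois:
            xs = montage8.positions[list(r.electrodes), 0]
            assert np.all(xs < 0) or np.all(xs >= 0)

    def test_electrode_ranking_matches_sort_oracle(self, montage8):
        rng = np.random.default_rng(3)
        t = rng.normal(0, 4, (8, 20))
        members = [(e, s) for e in range(8) for s in range(4, 10)]
        # force one sign so it is a single valid cluster
        t[:, 4:10] = np.abs(t[:, 4:10])
        cl = self.make_cluster(members, t)
        rois = define_rois(
            {"X": (perm_result([cl]), tmap(t))}, montage8, np.linspace(0, 1, 20)
        )
        chosen = set()
        for r in rois:
            chosen |= set(r.electrodes)
        scores = np.abs(t[:, 4:10]).sum(axis=1)
        oracle = set(np.argsort(-scores)[:5].tolist())
        assert chosen == oracle
        assert all(len(r.electrodes) <= 5 for r in rois)

    def test_no_significant_clusters_warns_and_empty(self, montage8):
        t = np.zeros((8, 20))
        with pytest.warns(UserWarning, match="no significant"):
            rois = define_rois(
                {"X": (perm_result([]), tmap(t))}, montage8, np.linspace(0, 1, 20)
            )
        assert rois == []

    def test_roi_electrode_cap(self):
        with pytest.raises(ValueError):
            ROIDefinition("big", tuple(range(6)), (0.1, 0.2), "X", 1)


@pytest.fixture(scope="module")
def roi_setup(small_corpus, montage8):
    ng = ngram_surprisal(train_ngram(small_corpus), small_corpus)
    # stand-in series so all three model columns exist
    rng = np.random.default_rng(0)
    srn = SurprisalSeries("SRN", np.abs(ng.values + rng.normal(0, 0.4, len(ng))))
    cfg = SurprisalSeries("CFG", np.abs(ng.values + rng.normal(0, 0.8, len(ng))))
    table = build_predictor_table(small_corpus, [ng, srn, cfg], seed=1)
    epochs = simulate_epochs(table, [], montage8, 4, fs=50, noise_sd=1.0, seed=2)
    roi = ROIDefinition("test-roi", (0, 1), (0.2, 0.4), "X", 1)
    return table, epochs, roi


class TestExtractROI:
    def test_constant_epochs_give_constant_amplitude(self, roi_setup):
        table, epochs, roi = roi_setup
        ep = epochs
        ep.data[:] = 2.5
        data = extract_roi(ep, roi, table)
        np.testing.assert_allclose(data["amplitude"], 2.5, atol=1e-12)

    def test_single_point_roi_equals_raw_value(self, roi_setup):
        table, epochs, roi = roi_setup
        rng = np.random.default_rng(1)
        epochs.data[:] = rng.normal(size=epochs.data.shape)
        r1 = ROIDefinition("pt", (2,), (0.3, 0.3), "X", 1)
        data = extract_roi(epochs, r1, table)
        t_idx = epochs.time_index(0.3)
        first = data[data.subject == 0]["amplitude"].to_numpy()
        keep = np.flatnonzero(epochs.mask[0])
        np.testing.assert_allclose(first, epochs.data[0, keep, 2, t_idx])

    def test_predictors_scaled_into_pm10(self, roi_setup):
        table, epochs, roi = roi_setup
        data = extract_roi(epochs, roi, table)
        for col in data.columns:
            if col in ("subject", "amplitude"):
                continue
            assert data[col].abs().max() <= 10.0 + 1e-9
            assert abs(data[col].mean()) < 1e-9 or col == "word_class"

    def test_word_class_sum_coded_and_centered(self, roi_setup):
        table, epochs, roi = roi_setup
        data = extract_roi(epochs, roi, table)
        assert data["word_class"].nunique() == 2
        assert abs(data["word_class"].mean()) < 1e-9

    def test_one_row_per_retained_trial(self, roi_setup):
        table, epochs, roi = roi_setup
        data = extract_roi(epochs, roi, table)
        assert len(data) == int(epochs.mask.sum())

    def test_empty_window_errors(self, roi_setup):
        table, epochs, _ = roi_setup
        bad = ROIDefinition("bad", (0,), (0.4, 0.2), "X", 1)
        with pytest.raises(ValueError, match="window"):
            extract_roi(epochs, bad, table)


class TestStepwise:
    def test_ledger_row_count_and_schedule(self, roi_setup):
        table, epochs, roi = roi_setup
        rng = np.random.default_rng(5)
        epochs.data[:] = rng.normal(size=epochs.data.shape)
        data = {roi.id: extract_roi(epochs, roi, table)}
        ledger = stepwise_compare(data, seed=0, config=FAST)
        assert len(ledger.rows) == 1 * len(HYPOTHESES) * 2
        assert set(ledger.rows["candidate"]) == {"main", "main+interaction"}
        assert set(ledger.rows["hypothesis"]) == set(HYPOTHESES)

    def test_pure_noise_mostly_not_significant(self, roi_setup):
        table, epochs, roi = roi_setup
        rng = np.random.default_rng(6)
        epochs.data[:] = rng.normal(size=epochs.data.shape)
        data = {roi.id: extract_roi(epochs, roi, table)}
        ledger = stepwise_compare(data, seed=1, config=FAST)
        ok = ledger.rows[~ledger.rows["failed"]]
        assert (ok["significant"].sum()) <= 1

    def test_identical_draws_delta_zero(self):
        from surpeeg.hierbayes import compare_waic, waic

        rng = np.random.default_rng(7)
        loglik = rng.normal(-1, 0.1, size=(40, 13))
        w = waic(loglik)
        delta, se = compare_waic(w, w)
        assert delta == 0.0
        assert se == 0.0

    def test_ledger_serialization(self, roi_setup, tmp_path):
        table, epochs, roi = roi_setup
        rng = np.random.default_rng(8)
        epochs.data[:] = rng.normal(size=epochs.data.shape)
        data = {roi.id: extract_roi(epochs, roi, table)}
        ledger = stepwise_compare(data, seed=2, config=FAST)
        ledger.to_tsv(tmp_path / "ledger.tsv")
        ledger.to_json(tmp_path / "ledger.json")
        back = pd.read_csv(tmp_path / "ledger.tsv", sep="\t")
        assert len(back) == len(ledger.rows)


class TestFitHier:
    def test_interaction_column_is_product(self, roi_setup):
        table, epochs, roi = roi_setup
        data = extract_roi(epochs, roi, table)
        fit = fit_hier(
            data,
            ("word_class", "surprisal_Ngram", "surprisal_Ngram:word_class"),
            config=FAST,
            check=False,
        )
        assert "surprisal_Ngram:word_class" in fit.columns
        assert fit.beta.shape[-1] == 4  # intercept + 3 terms
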