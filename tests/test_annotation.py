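import numpy as np
import pytest
from scipy import stats as sps

from ofmap import annotation as ann
from ofmap.events import CalciumTraces, EventRateMatrix, bin_events, detect_events
from ofmap.session import SessionLayout, make_shock_schedule


@pytest.fixture(scope="module")
def schedule():
    return make_shock_schedule(SessionLayout())


class TestHolmBonferroni:
    def test_stepdown_rejection(self):
        p = np.array([0.001, 0.02, 0.04, 0.5])
        # thresholds 0.05/4, 0.05/3, 0.05/2, 0.05: reject only the first
        rej = ann.holm_bonferroni(p, alpha=0.05)
        assert rej.tolist() == [True, False, False, False]

    def test_all_tiny_all_rejected(self):
        assert ann.holm_bonferroni(np.array([1e-5, 1e-6, 1e-4])).all()


class TestClusterSpecific:
    def test_planted_cluster_locked_cell_flagged(self, layout):
        rng = np.random.default_rng(0)
        n_bouts = 450
        bout_labels = rng.choice(5, size=n_bouts, p=[0.2, 0.2, 0.2, 0.2, 0.2])
        fpb = int(2 * layout.imaging_hz)
        cluster3_frames = np.flatnonzero(np.repeat(bout_labels == 3, fpb))
        events = np.sort(rng.choice(cluster3_frames, size=120, replace=False))
        out = ann.cluster_specific_neurons(
            [events], bout_labels, 2.0, layout, n_perm=500, seed=1
        )
        i3 = np.flatnonzero(out["clusters_tested"] == 3)[0]
        assert out["significant"][0, i3]

    def test_rare_cluster_not_tested(self, layout):
        bout_labels = np.zeros(450, dtype=int)
        bout_labels[:2] = 1  # 0.44% of bouts
        fpb = int(2 * layout.imaging_hz)
        events = np.arange(0, 2 * fpb)  # fires only during the rare cluster
        out = ann.cluster_specific_neurons(
            [events], bout_labels, 2.0, layout, n_perm=200, seed=0
        )
        assert 1 in out["clusters_skipped"]
        assert 1 not in out["clusters_tested"]

    def test_zero_event_cell_not_tested(self, layout):
        bout_labels = np.tile([0, 1], 225)
        out = ann.cluster_specific_neurons(
            [np.array([], dtype=int)], bout_labels, 2.0, layout, n_perm=100, seed=0
        )
        assert not out["testable"][0]
        assert not out["significant"].any()

    def test_null_preserves_event_count(self, layout):
        # the circular-shift null is a pure rotation: per-cell totals conserved
        rng = np.random.default_rng(2)
        events = np.sort(rng.choice(layout.n_imaging_frames, size=80, replace=False))
        shift = 12345
        shifted = (events + shift) % layout.n_imaging_frames
        assert shifted.size == events.size
        assert np.array_equal(np.sort(shifted % layout.n_imaging_frames), np.unique(shifted))


class TestComponentSpecific:
    def test_planted_component_locked_cell(self, layout):
        rng = np.random.default_rng(3)
        n_bouts = 450
        i1 = np.zeros(n_bouts, dtype=bool)
        i1[rng.choice(n_bouts, size=90, replace=False)] = True
        i23 = ~i1 & (rng.random(n_bouts) < 0.3)
        fpb = int(2 * layout.imaging_hz)
        i1_frames = np.flatnonzero(np.repeat(i1, fpb))
        events = np.sort(rng.choice(i1_frames, size=100, replace=False))
        out = ann.component_specific_neurons(
            [events], {"i1": i1, "i2+i3": i23}, 2.0, layout, n_perm=500, seed=4
        )
        assert out["significant"][0, out["components"].index("i1")]

    def test_silent_cell_no_flags(self, layout):
        masks = {"i1": np.tile([True, False], 225), "i2+i3": np.tile([False, True], 225)}
        out = ann.component_specific_neurons(
            [np.array([], dtype=int)], masks, 2.0, layout, n_perm=100, seed=0
        )
        assert not out["significant"].any()


class TestShockResponse:
    def test_noise_free_planted_activation(self, schedule, layout):
        fr = layout.imaging_hz
        dff = np.zeros((1, layout.n_imaging_frames))
        for onset in schedule.onsets:
            f = int(onset * fr)
            dff[0, f : f + int(2 * fr)] = 1.0 + 0.01 * np.sin(np.arange(int(2 * fr)))
        traces = CalciumTraces(dff=dff, frame_rate_hz=fr)
        out = ann.shock_response_test(traces, schedule)
        assert out["shock_class"][0] == "activated"
        assert out["p"][0] < 1e-20

    def test_suppression_detected(self, schedule, layout):
        fr = layout.imaging_hz
        rng = np.random.default_rng(5)
        dff = 1.0 + 0.05 * rng.standard_normal((1, layout.n_imaging_frames))
        for onset in schedule.onsets:
            f = int(onset * fr)
            dff[0, f : f + int(2 * fr)] -= 0.8
        out = ann.shock_response_test(CalciumTraces(dff=dff, frame_rate_hz=fr), schedule)
        assert out["shock_class"][0] == "suppressed"

    def test_constant_trace_is_ns(self, schedule, layout):
        traces = CalciumTraces(dff=np.ones((1, layout.n_imaging_frames)), frame_rate_hz=25.0)
        out = ann.shock_response_test(traces, schedule)
        assert out["shock_class"][0] == "ns"

    def test_untuned_false_positive_rate_nominal(self, schedule, layout):
        # 1000 white-noise cells: activated+suppressed fraction ~ alpha
        rng = np.random.default_rng(6)
        dff = rng.standard_normal((1000, layout.n_imaging_frames))
        out = ann.shock_response_test(CalciumTraces(dff=dff, frame_rate_hz=25.0), schedule)
        fpr = np.mean(out["shock_class"] != "ns")
        sd = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(fpr - 0.05) < 3 * sd

    def test_too_few_cycles_rejected(self):
        layout = SessionLayout(habituation_s=300.0, conditioning_s=40.0)
        sched = make_shock_schedule(layout)
        traces = CalciumTraces(dff=np.zeros((1, layout.n_imaging_frames)), frame_rate_hz=25.0)
        with pytest.raises(ValueError, match=">= 5"):
            ann.shock_response_test(traces, sched)


class TestFreezingCorrelation:
    def test_identical_and_inverted_rates(self, rng):
        fz = rng.uniform(0, 1, size=450)
        rates = EventRateMatrix(counts=np.vstack([fz, 1 - fz]))
        out = ann.freezing_correlation(rates, fz)
        assert np.isclose(out["r"][0], 1.0)
        assert out["freezing_class"][0] == "positive"
        assert np.isclose(out["r"][1], -1.0)
        assert out["freezing_class"][1] == "negative"

    def test_zero_variance_cell_ns(self, rng):
        fz = rng.uniform(0, 1, size=450)
        out = ann.freezing_correlation(EventRateMatrix(counts=np.ones((1, 450))), fz)
        assert np.isnan(out["r"][0]) and out["freezing_class"][0] == "ns"

    def test_independent_noise_false_positive_rate(self, rng):
        fz = rng.uniform(0, 1, size=450)
        counts = rng.poisson(0.5, size=(1000, 450))
        out = ann.freezing_correlation(EventRateMatrix(counts=counts), fz, alpha=0.01)
        frac = np.mean(out["freezing_class"] != "ns")
        sd = np.sqrt(0.01 * 0.99 / 1000)
        assert abs(frac - 0.01) < 3 * sd


class TestShockCorrelation:
    def test_indicator_rates_give_unit_correlation(self, schedule, layout):
        ind = schedule.indicator_2s.astype(float)
        counts = np.zeros((2, layout.n_chunks))
        counts[0, 150:] = ind
        counts[1, 150:] = 1 - ind
        r = ann.shock_correlation(EventRateMatrix(counts=counts), schedule)
        assert np.isclose(r[0], 1.0) and np.isclose(r[1], -1.0)

    def test_zero_event_cell_excluded(self, schedule, layout):
        counts = np.zeros((1, layout.n_chunks))
        counts[0, :150] = 3  # events only in habituation
        r = ann.shock_correlation(EventRateMatrix(counts=counts), schedule)
        assert np.isnan(r[0])

    def test_matches_hand_computed_pearson(self):
        layout = SessionLayout(habituation_s=20.0, conditioning_s=20.0)
        sched = make_shock_schedule(layout)  # indicator: 1,0,0,0,0,1,0,0,0,0
        rate = np.array([3.0, 1.0, 0.0, 2.0, 1.0, 4.0, 0.0, 1.0, 1.0, 0.0])
        counts = np.zeros((1, layout.n_chunks))
        counts[0, layout.n_habituation_chunks :] = rate
        r = ann.shock_correlation(EventRateMatrix(counts=counts), sched)
        x = sched.indicator_2s.astype(float)
        expect = np.sum((rate - rate.mean()) * (x - x.mean())) / (
            np.sqrt(np.sum((rate - rate.mean()) ** 2)) * np.sqrt(np.sum((x - x.mean()) ** 2))
        )
        assert np.isclose(r[0], expect, atol=1e-12)


class TestGroupComparisons:
    def test_planted_shift_detected_with_sign(self, rng):
        groups = {
            "activated": rng.normal(-0.3, 0.1, size=40),
            "suppressed": rng.normal(0.1, 0.1, size=40),
            "ns": rng.normal(0.0, 0.1, size=100),
        }
        out = ann.compare_group_correlations(groups)
        assert out["p"] < 1e-4
        assert np.mean(groups["activated"]) < np.mean(groups["ns"])

    def test_degenerate_groups_handled(self):
        out = ann.compare_group_correlations({"a": np.array([0.5]), "b": np.array([0.5])})
        assert out["p"] == 1.0


class TestShockTriggeredAverage:
    def test_planted_activated_group_post_exceeds_pre(self, schedule, layout):
        fr = layout.imaging_hz
        rng = np.random.default_rng(8)
        z = 0.1 * rng.standard_normal((12, layout.n_imaging_frames))
        for onset in schedule.onsets:
            f = int(onset * fr)
            z[:6, f : f + int(2 * fr)] += 1.0
        out = ann.shock_triggered_average(
            z, schedule, fr, groups={"act": np.arange(6), "untuned": np.arange(6, 12)}
        )
        act = out["groups"]["act"]
        assert act["wilcoxon_p"] < 0.05
        assert act["post"].mean() > act["pre"].mean()
        flat = out["groups"]["untuned"]
        assert abs(flat["mean"].mean()) < 0.05

    def test_small_group_test_skipped(self, schedule, layout):
        z = np.zeros((3, layout.n_imaging_frames))
        out = ann.shock_triggered_average(z, schedule, 25.0, groups={"g": np.arange(3)})
        assert out["groups"]["g"]["wilcoxon_p"] is None

    def test_oversized_window_rejected(self, schedule, layout):
        z = np.zeros((6, layout.n_imaging_frames))
        with pytest.raises(ValueError, match="cycle"):
            ann.shock_triggered_average(
                z, schedule, 25.0, groups={"g": np.arange(6)}, window_s=(-10.0, 10.0)
            )


class TestTemporalSimilarity:
    def test_constant_population_state_r_one(self):
        counts = np.tile(np.arange(1, 21)[:, None], (1, 450))
        out = ann.temporal_population_similarity(EventRateMatrix(counts=counts))
        assert np.allclose(out["mean_r"], 1.0)

    def test_iid_chunks_r_near_zero(self, rng):
        counts = rng.poisson(2.0, size=(50, 450))
        out = ann.temporal_population_similarity(EventRateMatrix(counts=counts))
        se = 1 / np.sqrt(50 * 400)
        assert np.abs(out["mean_r"]).max() < 0.05

    def test_planted_ar1_timescale_recovered(self, rng):
        # population rates with 12-s correlation time: mean r decays ~ rho^k
        rho = np.exp(-2.0 / 12.0)
        n_cells, n_chunks = 60, 450
        x = np.zeros((n_cells, n_chunks))
        x[:, 0] = rng.standard_normal(n_cells)
        for t in range(1, n_chunks):
            x[:, t] = rho * x[:, t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_cells)
        counts = (x - x.min()) * 10
        out = ann.temporal_population_similarity(EventRateMatrix(counts=counts))
        # fit log-linear decay over the first 10 lags
        k = np.arange(1, 11)
        slope = np.polyfit(k, np.log(out["mean_r"][:10]), 1)[0]
        tau_est = -2.0 / slope  # seconds
        assert abs(tau_est - 12.0) / 12.0 < 0.25


class TestSpatialClustering:
    def test_whole_population_group_p_near_one(self, rng):
        centroids = rng.uniform(0, 300, size=(40, 2))
        out = ann.spatial_clustering_test(centroids, np.arange(40), n_perm=200, seed=0)
        assert out["p"] > 0.99
        assert np.isclose(out["observed"], out["null_mean"])

    def test_planted_contiguous_group_detected(self, rng):
        centroids = rng.uniform(0, 300, size=(100, 2))
        group = np.arange(12)
        centroids[group] = rng.uniform(0, 40, size=(12, 2))  # one corner
        out = ann.spatial_clustering_test(centroids, group, n_perm=500, seed=1)
        assert out["p"] < 0.01

    def test_tiny_group_skipped(self, rng):
        out = ann.spatial_clustering_test(rng.uniform(0, 1, size=(10, 2)), np.array([3]))
        assert out["p"] is None

    def test_across_mice_paired_test(self, rng):
        per_mouse = []
        for i in range(5):
            centroids = rng.uniform(0, 300, size=(60, 2))
            group = np.arange(8)
            centroids[group] = rng.uniform(0, 30, size=(8, 2))
            per_mouse.append(ann.spatial_clustering_test(centroids, group, n_perm=300, seed=i))
        out = ann.spatial_clustering_across_mice(per_mouse)
        assert out["p"] < 0.01
        assert out["t"] < 0


class TestAnnotationTable:
    def test_planted_classes_recovered_in_table(self, small_cells_session):
        s = small_cells_session
        traces = CalciumTraces(dff=s.calcium, frame_rate_hz=25.0, centroids=s.centroids)
        rates = bin_events(detect_events(traces), s.layout)
        df = ann.annotate_cells(traces, rates, s.freezing.values, s.schedule)
        assert len(df) == 30
        cls = s.truth_cell_class
        act = df["shock_class"][cls == "shock_activated"]
        assert (act == "activated").mean() > 0.6
        pos = df["freezing_class"][cls == "freezing_pos"]
        assert (pos == "positive").mean() > 0.6
        assert {"shock_r", "centroid_x"} <= set(df.columns)
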