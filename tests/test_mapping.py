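import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from ofmap import mapping as mp
from ofmap.tracking import BACK_CENTER, BODY_POINTS, FreezingTrace, PoseTrack

from conftest import make_separated_modes


def make_track_from_features(features, fps=7.5, bout_s=10.0):
    fpb = int(round(bout_s * fps))
    coords = np.asarray(features, float).reshape(-1, len(BODY_POINTS), 2)
    return PoseTrack(
        coords=coords, likelihood=np.ones(coords.shape[:2]), frame_rate_hz=fps
    )


class TestSegmentBouts:
    def test_paper_scale_dimensions(self, default_session):
        b10 = mp.segment_bouts(default_session.pose, bout_s=10.0)
        assert b10.features.shape == (90, 1950)
        b2 = mp.segment_bouts(default_session.pose, bout_s=2.0)
        assert b2.features.shape == (450, 390)

    def test_single_bout_equals_flattened_track(self, rng):
        coords = rng.uniform(0, 100, size=(75, 13, 2))
        track = PoseTrack(coords=coords, likelihood=np.ones((75, 13)), frame_rate_hz=7.5)
        b = mp.segment_bouts(track, bout_s=10.0)
        assert b.n_bouts == 1
        assert np.array_equal(b.features[0], coords.ravel())

    def test_feature_row_layout_is_frame_major(self, rng):
        coords = rng.uniform(0, 100, size=(15, 13, 2))
        track = PoseTrack(coords=coords, likelihood=np.ones((15, 13)), frame_rate_hz=7.5)
        b = mp.segment_bouts(track, bout_s=2.0)
        # frame f, point p, coordinate d sits at f*26 + p*2 + d
        assert b.features[0, 1 * 26 + 4 * 2 + 1] == coords[1, 4, 1]

    def test_non_divisible_session_rejected_with_remainder(self, rng):
        coords = rng.uniform(0, 100, size=(80, 13, 2))
        track = PoseTrack(coords=coords, likelihood=np.ones((80, 13)), frame_rate_hz=7.5)
        with pytest.raises(ValueError, match="remainder 5"):
            mp.segment_bouts(track, bout_s=10.0)

    def test_dimensionality_law(self, rng):
        # D = 26 * fps * bout_s across configurations
        for fps, bout_s in [(7.5, 10.0), (7.5, 2.0), (10.0, 3.0)]:
            fpb = int(round(bout_s * fps))
            coords = rng.uniform(0, 1, size=(fpb * 3, 13, 2))
            track = PoseTrack(
                coords=coords, likelihood=np.ones((fpb * 3, 13)), frame_rate_hz=fps
            )
            b = mp.segment_bouts(track, bout_s=bout_s)
            assert b.features.shape[1] == int(26 * fps * bout_s)


class TestMobilitySplit:
    def _bouts(self, n, rng):
        feats = rng.uniform(0, 1, size=(n, 390))
        return mp.BoutFeatureMatrix(features=feats, bout_s=2.0, frame_rate_hz=7.5)

    def test_all_mobile_all_immobile(self, rng):
        bouts = self._bouts(20, rng)
        mob, imm = mp.split_by_mobility(bouts, FreezingTrace(values=np.zeros(20)))
        assert mob.size == 20 and imm.size == 0
        mob, imm = mp.split_by_mobility(bouts, FreezingTrace(values=np.ones(20)))
        assert mob.size == 0 and imm.size == 20

    def test_boundary_bout_counts_as_mobile(self, rng):
        bouts = self._bouts(3, rng)
        mob, imm = mp.split_by_mobility(bouts, FreezingTrace(values=np.array([0.5, 0.51, 0.49])))
        assert mob.tolist() == [0, 2] and imm.tolist() == [1]

    def test_uniform_freezing_half_mobile(self, rng):
        n = 450
        bouts = self._bouts(n, rng)
        fz = FreezingTrace(values=rng.uniform(0, 1, size=n))
        mob, imm = mp.split_by_mobility(bouts, fz)
        assert np.intersect1d(mob, imm).size == 0
        assert mob.size + imm.size == n
        sd = np.sqrt(0.25 / n)
        assert abs(mob.size / n - 0.5) < 3 * sd

    def test_misaligned_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            mp.split_by_mobility(self._bouts(5, rng), FreezingTrace(values=np.zeros(4)))


class TestEmbedding:
    def test_planted_modes_separate(self):
        X, labels = make_separated_modes(n_per_mode=50, n_modes=3, seed=3)
        emb = mp.embed_bouts(X, perplexity=20.0, seed=0)
        assert emb.shape == (150, 2)
        assert silhouette_score(emb, labels) > 0.5

    def test_duplicated_rows_land_together(self):
        X, _ = make_separated_modes(n_per_mode=40, n_modes=2, seed=4)
        X[1] = X[0]
        emb = mp.embed_bouts(X, perplexity=15.0, seed=0)
        span = np.linalg.norm(emb.max(axis=0) - emb.min(axis=0))
        assert np.linalg.norm(emb[1] - emb[0]) < 0.01 * span

    def test_fixed_seed_reproducible(self):
        X, _ = make_separated_modes(n_per_mode=35, n_modes=2, seed=5)
        a = mp.embed_bouts(X, perplexity=15.0, seed=42)
        b = mp.embed_bouts(X, perplexity=15.0, seed=42)
        assert np.array_equal(a, b)

    def test_too_few_bouts_rejected_with_minimum(self):
        X = np.random.default_rng(0).normal(size=(50, 10))
        with pytest.raises(ValueError, match="90"):
            mp.embed_bouts(X, perplexity=30.0)


class TestWatershed:
    def test_two_blobs_two_pure_regions(self, rng):
        emb = np.vstack(
            [rng.normal((0, 0), 1, size=(150, 2)), rng.normal((20, 20), 1, size=(150, 2))]
        )
        atlas = mp.cluster_watershed(emb, grid_n=128, bandwidth_mult=1.5)
        assert atlas.n_regions == 2
        truth = np.repeat([0, 1], 150)
        # label purity: each blob maps to exactly one region
        for t in (0, 1):
            assert np.unique(atlas.bout_labels[truth == t]).size == 1
        assert atlas.bout_labels[0] != atlas.bout_labels[-1]

    def test_single_blob_single_region(self, rng):
        emb = rng.normal(0, 1, size=(300, 2))
        atlas = mp.cluster_watershed(emb, grid_n=128, bandwidth_mult=1.5)
        assert atlas.n_regions == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            mp.cluster_watershed(np.ones((10, 2)))

    def test_regions_partition_grid(self, rng):
        emb = np.vstack(
            [rng.normal((0, 0), 1, size=(100, 2)), rng.normal((12, 0), 1, size=(100, 2))]
        )
        atlas = mp.cluster_watershed(emb, grid_n=64)
        assert atlas.region_labels.min() >= 1
        assert np.array_equal(
            np.unique(atlas.region_labels), np.arange(1, atlas.n_regions + 1)
        )
        assert (atlas.density >= 0).all()

    def test_atlas_roundtrip(self, tmp_path, rng):
        emb = np.vstack(
            [rng.normal((0, 0), 1, size=(80, 2)), rng.normal((15, 0), 1, size=(80, 2))]
        )
        atlas = mp.cluster_watershed(emb, grid_n=64, reference_features=rng.normal(size=(160, 20)))
        atlas.save(tmp_path / "atlas.h5")
        back = mp.BehaviorAtlas.load(tmp_path / "atlas.h5")
        assert np.array_equal(back.bout_labels, atlas.bout_labels)
        assert np.array_equal(back.region_labels, atlas.region_labels)
        assert np.allclose(back.reference_features, atlas.reference_features)


@pytest.fixture(scope="module")
def toy_atlas():
    """Well-separated two-mode atlas with reference features attached."""
    X, labels = make_separated_modes(n_per_mode=60, n_modes=2, dim=390, sep=50.0, seed=6)
    emb = mp.embed_bouts(X, perplexity=20.0, seed=1)
    atlas = mp.cluster_watershed(emb, grid_n=128, bandwidth_mult=1.5, reference_features=X)
    return atlas, X, labels


class TestPositioning:
    def test_identical_bout_top_neighbor_is_itself(self, toy_atlas):
        atlas, X, _ = toy_atlas
        x = X[5]
        r = np.array([np.corrcoef(x, ref)[0, 1] for ref in X])
        assert np.argmax(r) == 5 and np.isclose(r[5], 1.0)

    def test_matches_bruteforce_oracle(self, toy_atlas):
        atlas, X, _ = toy_atlas
        new = X[:25]
        coords, labels = mp.position_on_atlas(
            mp.BoutFeatureMatrix(features=new, bout_s=2.0, frame_rate_hz=7.5), atlas, k=10
        )
        for i in range(25):
            r = np.array([np.corrcoef(new[i], ref)[0, 1] for ref in X])
            order = np.argsort(-r, kind="stable")
            cutoff = r[order[9]]
            neigh = np.flatnonzero(r >= cutoff)
            expect = np.median(atlas.embedding[neigh], axis=0)
            assert np.allclose(coords[i], expect, atol=1e-10)

    def test_reference_self_positioning_recovers_labels(self, toy_atlas):
        atlas, X, _ = toy_atlas
        coords, labels = mp.position_on_atlas(X, atlas, k=10)
        assert (labels == atlas.bout_labels).mean() >= 0.8

    def test_constant_bout_unassignable(self, toy_atlas):
        atlas, X, _ = toy_atlas
        new = np.vstack([np.full(X.shape[1], 3.0), X[0]])
        coords, labels = mp.position_on_atlas(new, atlas, k=10)
        assert labels[0] == 0 and np.isnan(coords[0]).all()
        assert labels[1] == atlas.bout_labels[0]

    def test_coordinates_inside_neighbor_bounding_box(self, toy_atlas):
        # componentwise median lies within the neighbors' coordinate range,
        # hence within the embedding's bounding box
        atlas, X, _ = toy_atlas
        coords, _ = mp.position_on_atlas(X[::7], atlas, k=10)
        lo, hi = atlas.embedding.min(axis=0), atlas.embedding.max(axis=0)
        assert (coords >= lo - 1e-9).all() and (coords <= hi + 1e-9).all()

    def test_dimension_mismatch_rejected(self, toy_atlas):
        atlas, X, _ = toy_atlas
        with pytest.raises(ValueError, match="dimensionality"):
            mp.position_on_atlas(X[:, :100], atlas)


class TestClusterSummaries:
    def test_stationary_bout_zero_displacement(self):
        coords = np.full((75, 13, 2), 40.0)
        track = PoseTrack(coords=coords, likelihood=np.ones((75, 13)), frame_rate_hz=7.5)
        bouts = mp.segment_bouts(track, bout_s=10.0)
        out = mp.summarize_clusters(track, bouts, np.array([1]))
        assert np.allclose(out[1]["displacement"], 0.0)

    def test_translation_recovered_in_displacement(self):
        coords = np.full((75, 13, 2), 40.0)
        coords[:, :, 0] += np.linspace(0, 10, 75)[:, None]
        track = PoseTrack(coords=coords, likelihood=np.ones((75, 13)), frame_rate_hz=7.5)
        bouts = mp.segment_bouts(track, bout_s=10.0)
        out = mp.summarize_clusters(track, bouts, np.array([1]))
        assert np.isclose(out[1]["displacement"][0, -1, 0], 10.0)

    def test_skeleton_back_center_at_origin(self, default_session):
        bouts = mp.segment_bouts(default_session.pose, bout_s=10.0)
        labels = np.ones(bouts.n_bouts, dtype=int)
        out = mp.summarize_clusters(default_session.pose, bouts, labels)
        skel = out[1]["skeleton"]
        bc_col = mp.SKELETON_POINTS.index("back center")
        assert np.allclose(skel[:, :, bc_col, :], 0.0)
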