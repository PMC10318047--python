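"""Behavioral atlas: bout featurization, t-SNE embedding, watershed clusters,
and correlation-kNN positioning of new sessions on a reference atlas.

Sessions are parsed into fixed-duration bouts (10 s for the cluster atlas, 2 s
for the mobility-split component analysis).  Each bout is the flattened
arena-frame trajectory of all 13 body points — D = 13 points x 2 coordinates
x frame_rate x bout_s, i.e. 1950-D for 10-s and 390-D for 2-s bouts at
7.5 Hz.  Features stay allocentric because the behavioral categories encode
arena position (near/far from the demonstrator) as well as posture.

Reference bouts are embedded in 2-D with Barnes-Hut t-SNE (perplexity 30, no
PCA pre-reduction), a Gaussian kernel density is rasterized on a grid, and a
watershed transform of the negated density partitions the plane into regions
(behavioral clusters).  New bouts are positioned without re-embedding: each is
placed at the coordinate-wise median of its k = 10 highest-Pearson-correlation
reference bouts and labeled by the watershed region containing that point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.stats import gaussian_kde
from skimage.measure import label as _cc_label
from skimage.morphology import local_minima
from skimage.segmentation import watershed
from sklearn.manifold import TSNE

from .session import CHUNK_S
from .tracking import BACK_CENTER, BODY_POINTS, FreezingTrace, PoseTrack

log = logging.getLogger(__name__)


@dataclass
class BoutFeatureMatrix:
    """Bouts x D matrix of flattened per-frame (x, y) coordinates.

    Row layout is frame-major: for each frame in the bout, the 13 points'
    (x, y) pairs are appended in canonical point order — so
    D = 26 * frame_rate * bout_s.
    """

    features: np.ndarray
    bout_s: float
    frame_rate_hz: float
    bout_index: list = field(default_factory=list)  # (mouse_id, start_s) per row

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        expected = int(round(len(BODY_POINTS) * 2 * self.frame_rate_hz * self.bout_s))
        if self.features.ndim != 2 or self.features.shape[1] != expected:
            raise ValueError(
                f"feature matrix must be (bouts, {expected}); got {self.features.shape}"
            )

    @property
    def n_bouts(self) -> int:
        return self.features.shape[0]


@dataclass
class BehaviorAtlas:
    """A reference 2-D behavior map: embedding, density field, watershed
    regions, per-bout labels, and the reference features for positioning."""

    embedding: np.ndarray  # (n_ref, 2)
    density: np.ndarray  # (grid_n, grid_n)
    region_labels: np.ndarray  # (grid_n, grid_n) ints >= 1
    bout_labels: np.ndarray  # (n_ref,) ints >= 1
    reference_features: np.ndarray  # (n_ref, D)
    grid_x: np.ndarray  # (grid_n,) grid cell centers
    grid_y: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return int(self.region_labels.max())

    def label_at(self, xy: np.ndarray) -> np.ndarray:
        """Watershed region id for each 2-D coordinate (nearest grid cell)."""
        xy = np.atleast_2d(xy)
        ix = np.clip(np.searchsorted(self.grid_x, xy[:, 0]), 1, self.grid_x.size - 1)
        ix -= (self.grid_x[ix] - xy[:, 0]) > (xy[:, 0] - self.grid_x[ix - 1])
        iy = np.clip(np.searchsorted(self.grid_y, xy[:, 1]), 1, self.grid_y.size - 1)
        iy -= (self.grid_y[iy] - xy[:, 1]) > (xy[:, 1] - self.grid_y[iy - 1])
        return self.region_labels[iy, ix]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("embedding", "density", "region_labels", "bout_labels",
                         "reference_features", "grid_x", "grid_y"):
                f.create_dataset(name, data=getattr(self, name))
            for k, v in self.params.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "BehaviorAtlas":
        with h5py.File(path, "r") as f:
            kw = {
                name: f[name][()]
                for name in ("embedding", "density", "region_labels", "bout_labels",
                             "reference_features", "grid_x", "grid_y")
            }
            params = dict(f.attrs)
        return cls(params=params, **kw)


# ---------------------------------------------------------------------------
# Featurization


def segment_bouts(
    track: PoseTrack, bout_s: float = 10.0, mouse_id: str = "m0"
) -> BoutFeatureMatrix:
    """Parse a session into consecutive bouts of ``bout_s`` seconds and
    flatten each into one feature row (frame-major, (x, y)-interleaved per
    point).  The session must divide evenly into bouts."""
    fpb = bout_s * track.frame_rate_hz
    if abs(fpb - round(fpb)) > 1e-9:
        raise ValueError(f"{bout_s} s is not a whole number of frames at {track.frame_rate_hz} Hz")
    fpb = int(round(fpb))
    n_bouts, rem = divmod(track.n_frames, fpb)
    if rem:
        raise ValueError(
            f"session of {track.n_frames} frames does not divide into {bout_s}-s "
            f"bouts ({fpb} frames): remainder {rem} frames"
        )
    feats = track.coords.reshape(n_bouts, fpb * len(BODY_POINTS) * 2)
    index = [(mouse_id, i * bout_s) for i in range(n_bouts)]
    return BoutFeatureMatrix(
        features=feats, bout_s=bout_s, frame_rate_hz=track.frame_rate_hz, bout_index=index
    )


def concat_bouts(matrices: list[BoutFeatureMatrix]) -> BoutFeatureMatrix:
    """Stack per-mouse bout matrices (same bout_s and frame rate)."""
    if not matrices:
        raise ValueError("no bout matrices to concatenate")
    b0 = matrices[0]
    if any(m.bout_s != b0.bout_s or m.frame_rate_hz != b0.frame_rate_hz for m in matrices):
        raise ValueError("bout matrices have inconsistent bout_s / frame rate")
    feats = np.vstack([m.features for m in matrices])
    index = [ix for m in matrices for ix in m.bout_index]
    return BoutFeatureMatrix(
        features=feats, bout_s=b0.bout_s, frame_rate_hz=b0.frame_rate_hz, bout_index=index
    )


def split_by_mobility(
    bouts: BoutFeatureMatrix, freezing: FreezingTrace, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Partition 2-s bouts into mobile and immobile by freezing rate.

    Immobile <=> freezing rate strictly greater than ``threshold`` (a bout
    exactly at the boundary counts as mobile).  Returns (mobile_idx,
    immobile_idx), a disjoint exhaustive partition of row indices.
    """
    if abs(bouts.bout_s - CHUNK_S) > 1e-9:
        raise ValueError("mobility split is defined for 2-s bouts")
    if len(freezing) != bouts.n_bouts:
        raise ValueError(
            f"freezing trace ({len(freezing)}) not aligned to bouts ({bouts.n_bouts})"
        )
    immobile = freezing.values > threshold
    return np.flatnonzero(~immobile), np.flatnonzero(immobile)


# ---------------------------------------------------------------------------
# Embedding and clustering


def embed_bouts(
    bouts: BoutFeatureMatrix | np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
    learning_rate: float | str = "auto",
) -> np.ndarray:
    """Barnes-Hut t-SNE of bout features into 2-D (no PCA pre-reduction).

    Requires at least 3 * perplexity bouts; deterministic for a fixed seed.
    """
    X = bouts.features if isinstance(bouts, BoutFeatureMatrix) else np.asarray(bouts, float)
    n = X.shape[0]
    minimum = int(np.ceil(3 * perplexity))
    if n < minimum:
        raise ValueError(
            f"t-SNE with perplexity {perplexity} needs at least {minimum} bouts, got {n}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        method="barnes_hut",
        angle=0.5,
        init="random",
        learning_rate=learning_rate,
        max_iter=n_iter,
        random_state=seed,
    )
    return tsne.fit_transform(X)


def cluster_watershed(
    embedding: np.ndarray,
    grid_n: int = 512,
    bandwidth_mult: float = 1.0,
    pad_frac: float = 0.05,
    density_floor: float = 1e-6,
    reference_features: np.ndarray | None = None,
    params: dict | None = None,
) -> BehaviorAtlas:
    """Watershed clustering of a 2-D embedding.

    A Gaussian kernel density (Scott's-rule bandwidth times
    ``bandwidth_mult``) is rasterized on a ``grid_n`` x ``grid_n`` grid over
    the padded bounding box, and a watershed transform of the negated density
    partitions the grid into regions with contiguous ids from 1.  Every grid
    cell receives exactly one region (no ridge cells are left unassigned).

    Density below ``density_floor`` x max is flattened to zero so that
    floating-point noise in the empty background cannot seed spurious basins;
    the flat background is flooded from the real density peaks.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[1] != 2:
        raise ValueError("embedding must be (n, 2)")
    if np.ptp(embedding[:, 0]) == 0 or np.ptp(embedding[:, 1]) == 0:
        raise ValueError("embedding has zero variance; cannot build a density field")

    lo = embedding.min(axis=0)
    hi = embedding.max(axis=0)
    pad = pad_frac * (hi - lo)
    lo, hi = lo - pad, hi + pad
    gx = np.linspace(lo[0], hi[0], grid_n)
    gy = np.linspace(lo[1], hi[1], grid_n)
    kde = gaussian_kde(embedding.T, bw_method=lambda k: k.scotts_factor() * bandwidth_mult)
    xx, yy = np.meshgrid(gx, gy)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_n, grid_n)
    density[density < density_floor * density.max()] = 0.0

    # markers = connected plateaus of local density maxima; skimage's
    # implicit marker detection would fragment flat plateaus
    markers = _cc_label(local_minima(-density))
    regions = watershed(-density, markers=markers, watershed_line=False)
    # re-index to contiguous ids starting at 1
    uniq = np.unique(regions)
    remap = np.zeros(uniq.max() + 1, dtype=np.int32)
    remap[uniq] = np.arange(1, uniq.size + 1)
    regions = remap[regions]

    atlas = BehaviorAtlas(
        embedding=embedding,
        density=density,
        region_labels=regions,
        bout_labels=np.zeros(embedding.shape[0], dtype=np.int32),
        reference_features=(
            np.asarray(reference_features, float)
            if reference_features is not None
            else np.zeros((embedding.shape[0], 0))
        ),
        grid_x=gx,
        grid_y=gy,
        params={"grid_n": grid_n, "bandwidth_mult": bandwidth_mult,
                "pad_frac": pad_frac, **(params or {})},
    )
    atlas.bout_labels = atlas.label_at(embedding).astype(np.int32)
    log.info("watershed produced %d regions from %d bouts", atlas.n_regions, embedding.shape[0])
    return atlas


def build_atlas(
    bouts: BoutFeatureMatrix,
    perplexity: float = 30.0,
    seed: int = 0,
    grid_n: int = 512,
    bandwidth_mult: float = 1.0,
) -> BehaviorAtlas:
    """Embed reference bouts and watershed-cluster the result."""
    emb = embed_bouts(bouts, perplexity=perplexity, seed=seed)
    return cluster_watershed(
        emb,
        grid_n=grid_n,
        bandwidth_mult=bandwidth_mult,
        reference_features=bouts.features,
        params={"perplexity": perplexity, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Positioning new data


def position_on_atlas(
    new_bouts: BoutFeatureMatrix | np.ndarray,
    atlas: BehaviorAtlas,
    k: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Place new bouts on a reference atlas by correlation-kNN.

    Per new bout: Pearson correlation against every reference bout's feature
    vector; the bout is positioned at the coordinate-wise median of the
    embedding locations of the k most-correlated references (ties at rank k
    are all included) and labeled by the watershed region containing that
    coordinate.  Bouts with a constant feature vector (undefined correlation)
    get coordinate NaN and label 0 (unassignable).
    """
    X = new_bouts.features if isinstance(new_bouts, BoutFeatureMatrix) else np.asarray(new_bouts, float)
    R = atlas.reference_features
    if R.size == 0 or X.shape[1] != R.shape[1]:
        raise ValueError(
            f"new bout dimensionality {X.shape[1]} does not match atlas reference "
            f"{R.shape[1] if R.size else '(absent)'}"
        )
    Rc = R - R.mean(axis=1, keepdims=True)
    Rn = np.linalg.norm(Rc, axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = np.linalg.norm(Xc, axis=1)

    coords = np.full((X.shape[0], 2), np.nan)
    labels = np.zeros(X.shape[0], dtype=np.int32)
    degenerate_ref = Rn == 0
    for i in range(X.shape[0]):
        if Xn[i] == 0:
            log.warning("bout %d has a constant feature vector; unassignable", i)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Rc @ Xc[i]) / (Rn * Xn[i])
        r[degenerate_ref] = -np.inf
        kk = min(k, np.isfinite(r).sum())
        order = np.argsort(-r, kind="stable")
        cutoff = r[order[kk - 1]]
        neigh = np.flatnonzero(r >= cutoff)  # includes ties at rank k
        coords[i] = np.median(atlas.embedding[neigh], axis=0)
        labels[i] = atlas.label_at(coords[i : i + 1])[0]
    return coords, labels


# ---------------------------------------------------------------------------
# Cluster summaries


SKELETON_POINTS = ("left ear", "right ear", "back center", "tail root")


def summarize_clusters(
    track: PoseTrack, bouts: BoutFeatureMatrix, labels: np.ndarray
) -> dict[int, dict]:
    """Per-cluster posture and position summaries.

    For each cluster: (a) the four-point skeleton (left ear, right ear, back
    center, tail root) with the back center translated to (0, 0) per frame;
    (b) raw back-center positions; (c) back-center displacement with each
    bout's first frame at (0, 0).
    """
    labels = np.asarray(labels)
    if labels.size != bouts.n_bouts:
        raise ValueError("labels not aligned to bouts")
    fpb = int(round(bouts.bout_s * bouts.frame_rate_hz))
    coords = bouts.features.reshape(bouts.n_bouts, fpb, len(BODY_POINTS), 2)
    skel_idx = [BODY_POINTS.index(p) for p in SKELETON_POINTS]

    out: dict[int, dict] = {}
    for c in np.unique(labels):
        sel = coords[labels == c]
        if sel.size == 0:
            log.info("cluster %d is empty", c)
            out[int(c)] = {"skeleton": np.zeros((0, fpb, len(skel_idx), 2)),
                           "back_center": np.zeros((0, fpb, 2)),
                           "displacement": np.zeros((0, fpb, 2))}
            continue
        bc = sel[:, :, BACK_CENTER, :]
        skel = sel[:, :, skel_idx, :] - bc[:, :, None, :]
        disp = bc - bc[:, :1, :]
        out[int(c)] = {"skeleton": skel, "back_center": bc, "displacement": disp}
    return out
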