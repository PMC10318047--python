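"""Neural tuning annotation.

Classifies each imaged cell by its relation to the session's covariates:

* cluster-specific / component-specific — within-bout event counts against a
  circular-shift permutation null with within-cell Holm-Bonferroni
  correction;
* other-shock responding — paired t-test of mean dF/F in the 2-s shock
  window vs the preceding 2 s across the 60 shock cycles (activated /
  suppressed / ns);
* self-freezing correlated — Pearson correlation of the 2-s event rate with
  the 2-s freezing rate (two-sided, p < 0.01);
* shock correlation — Pearson r of the conditioning-period event rate
  against the repeating 1-0-0-0-0 shock indicator (cells with no
  conditioning events are excluded).

Group-level utilities compare correlation distributions across tuning
classes (Kruskal-Wallis), average shock-triggered z-scored traces, quantify
temporal population similarity across 2-s chunks, and test spatial
clustering of annotated subpopulations by pairwise centroid distances
against random subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import CalciumTraces, EventRateMatrix
from .session import CHUNK_S, SessionLayout, ShockSchedule

log = logging.getLogger(__name__)


@dataclass
class NeuronAnnotation:
    """Per-cell tuning record."""

    cell_id: int
    cluster_specific: dict  # cluster id -> corrected-significant flag
    cluster_p: dict  # cluster id -> raw one-sided p
    shock_class: str  # 'activated' | 'suppressed' | 'ns'
    shock_p: float
    freezing_r: float
    freezing_p: float
    freezing_class: str  # 'positive' | 'negative' | 'ns'
    shock_r: float  # NaN when undefined (no conditioning events)
    centroid: tuple | None = None


# ---------------------------------------------------------------------------
# Circular-shift permutation machinery


def holm_bonferroni(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down rejection flags."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def _shift_statistics(
    events: list[np.ndarray],
    frame_groups: np.ndarray,
    n_groups: int,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and null per-group event counts under shared circular shifts.

    ``frame_groups`` maps each imaging frame to a group id (or -1 for
    untested frames).  Each permutation draws ONE shift, shared by all cells
    (the cells were recorded from one mouse), and circularly shifts every
    cell's event train by it.  Returns (obs (cells, groups), exceed counts
    (cells, groups) of null >= obs).
    """
    n_frames = frame_groups.size
    n_cells = len(events)

    def counts(ev_list: list[np.ndarray]) -> np.ndarray:
        out = np.zeros((n_cells, n_groups), dtype=np.int64)
        for i, ev in enumerate(ev_list):
            if ev.size == 0:
                continue
            g = frame_groups[ev]
            g = g[g >= 0]
            np.add.at(out[i], g, 1)
        return out

    obs = counts(events)
    exceed = np.zeros_like(obs)
    shifts = rng.integers(1, n_frames, size=n_perm)
    for s in shifts:
        shifted = [(ev + s) % n_frames for ev in events]
        exceed += counts(shifted) >= obs
    return obs, exceed


def cluster_specific_neurons(
    raster: list[np.ndarray],
    bout_labels: np.ndarray,
    bout_s: float,
    layout: SessionLayout,
    n_perm: int = 10000,
    min_frac: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Identify cluster-specific neurons by circular-shift permutation.

    Statistic per (cell, cluster): total calcium events falling inside bouts
    of that cluster.  Null: the cell's event train circularly shifted at
    frame resolution, one shared random shift per permutation (10,000 by
    default).  One-sided p = P(null >= obs) with add-one smoothing.  Clusters
    occupying <= ``min_frac`` of bouts are not tested; Holm-Bonferroni is
    applied within each cell across its tested clusters (p < ``alpha``,
    one-sided).  Cells with zero events are not tested.
    """
    bout_labels = np.asarray(bout_labels)
    fpb = int(round(bout_s * layout.imaging_hz))
    n_frames = layout.n_imaging_frames
    if bout_labels.size * fpb != n_frames:
        raise ValueError("bout labels do not tile the imaging session")

    clusters = np.unique(bout_labels)
    frac = np.array([(bout_labels == c).mean() for c in clusters])
    tested = clusters[frac > min_frac]
    skipped = clusters[frac <= min_frac]
    if skipped.size:
        log.info("clusters occupying <= %.1f%% of bouts not tested: %s",
                 100 * min_frac, list(skipped))
    lut = {int(c): i for i, c in enumerate(tested)}
    frame_groups = np.full(n_frames, -1, dtype=np.int64)
    per_frame = np.repeat(bout_labels, fpb)
    for c, i in lut.items():
        frame_groups[per_frame == c] = i

    rng = np.random.default_rng(seed)
    obs, exceed = _shift_statistics(raster, frame_groups, tested.size, n_perm, rng)

    n_cells = len(raster)
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    flags = np.zeros((n_cells, tested.size), dtype=bool)
    testable = np.array([ev.size > 0 for ev in raster])
    for i in range(n_cells):
        if not testable[i]:
            log.info("cell %d has zero events; not tested", i)
            continue
        flags[i] = holm_bonferroni(pvals[i], alpha=alpha)
    return {
        "clusters_tested": tested,
        "clusters_skipped": skipped,
        "obs_counts": obs,
        "p": pvals,
        "significant": flags,
        "testable": testable,
        "n_perm": n_perm,
    }


def component_specific_neurons(
    raster: list[np.ndarray],
    component_masks: dict[str, np.ndarray],
    bout_s: float,
    layout: SessionLayout,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Component-specific neurons (e.g. i1 vs i2+i3) with the same
    circular-shift null as :func:`cluster_specific_neurons`.

    ``component_masks`` maps component name -> boolean per-2-s-bout mask.
    Flags for different components may co-occur.
    """
    names = list(component_masks)
    fpb = int(round(bout_s * layout.imaging_hz))
    n_frames = layout.n_imaging_frames
    n_bouts = n_frames // fpb
    frame_groups = np.full(n_frames, -1, dtype=np.int64)
    for gi, name in enumerate(names):
        mask = np.asarray(component_masks[name], dtype=bool)
        if mask.size != n_bouts:
            raise ValueError(f"component mask {name!r} not aligned to bouts")
        frame_groups[np.repeat(mask, fpb)] = gi

    rng = np.random.default_rng(seed)
    obs, exceed = _shift_statistics(raster, frame_groups, len(names), n_perm, rng)
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    testable = np.array([ev.size > 0 for ev in raster])
    flags = np.zeros_like(pvals, dtype=bool)
    for i in range(len(raster)):
        if testable[i]:
            flags[i] = holm_bonferroni(pvals[i], alpha=alpha)
    return {"components": names, "obs_counts": obs, "p": pvals,
            "significant": flags, "testable": testable, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# Shock response and correlations


def shock_window_means(
    traces: CalciumTraces, schedule: ShockSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell, per-cycle mean dF/F in the pre (-2-0 s) and post (0-2 s)
    windows around each shock onset.  The first cycle's pre window is the
    last 2 s of habituation."""
    fr = traces.frame_rate_hz
    w = int(round(CHUNK_S * fr))
    onset_frames = np.round(schedule.onsets * fr).astype(int)
    if onset_frames.size and (onset_frames.min() - w < 0 or onset_frames.max() + w > traces.n_frames):
        raise ValueError("shock windows fall outside the recorded traces")
    pre = np.stack([traces.dff[:, f - w : f].mean(axis=1) for f in onset_frames], axis=1)
    post = np.stack([traces.dff[:, f : f + w].mean(axis=1) for f in onset_frames], axis=1)
    return pre, post


def shock_response_test(
    traces: CalciumTraces,
    schedule: ShockSchedule,
    alpha: float = 0.05,
) -> dict:
    """Other-shock responding neurons.

    Per cell: paired two-sided t-test of the mean dF/F of the shock moment
    (0-2 s) vs the preceding 2 s (-2-0 s) across the shock cycles (60 in the
    full paradigm).  Activated if post > pre and p < alpha, suppressed if
    post < pre and p < alpha, else ns.  Constant traces (undefined t) are ns.
    """
    n_cycles = schedule.n_shocks
    if n_cycles < 5:
        raise ValueError(f"shock-response test needs >= 5 shock cycles, got {n_cycles}")
    if n_cycles < 30:
        log.warning("only %d shock cycles available; test power is reduced", n_cycles)
    pre, post = shock_window_means(traces, schedule)
    diff = post - pre
    classes = np.array(["ns"] * traces.n_cells, dtype=object)
    pvals = np.ones(traces.n_cells)
    for i in range(traces.n_cells):
        if np.allclose(diff[i], 0) or diff[i].std() == 0:
            log.info("cell %d: degenerate pre/post differences; ns", i)
            continue
        t, p = sps.ttest_rel(post[i], pre[i])
        pvals[i] = p
        if p < alpha:
            classes[i] = "activated" if diff[i].mean() > 0 else "suppressed"
    return {"shock_class": classes, "p": pvals, "mean_diff": diff.mean(axis=1),
            "n_cycles": n_cycles}


def freezing_correlation(
    rates: EventRateMatrix,
    freezing: np.ndarray,
    alpha: float = 0.01,
) -> dict:
    """Self-freezing correlated neurons.

    Pearson correlation (two-sided) between each cell's 2-s event rate and
    the 2-s freezing rate; positive / negative class at p < ``alpha``.
    Zero-variance rate vectors get r = NaN and class ns.
    """
    fz = np.asarray(freezing, dtype=float)
    if fz.size != rates.n_bins:
        raise ValueError("freezing trace not aligned to event-rate bins")
    r = np.full(rates.n_cells, np.nan)
    p = np.ones(rates.n_cells)
    classes = np.array(["ns"] * rates.n_cells, dtype=object)
    if fz.std() == 0:
        log.warning("freezing trace has zero variance; all correlations undefined")
        return {"r": r, "p": p, "freezing_class": classes, "n": fz.size}
    for i in range(rates.n_cells):
        x = rates.counts[i].astype(float)
        if x.std() == 0:
            log.info("cell %d: zero-variance event rate; freezing r undefined", i)
            continue
        ri, pi = sps.pearsonr(x, fz)
        r[i], p[i] = ri, pi
        if pi < alpha:
            classes[i] = "positive" if ri > 0 else "negative"
    return {"r": r, "p": p, "freezing_class": classes, "n": fz.size}


def shock_correlation(rates: EventRateMatrix, schedule: ShockSchedule) -> np.ndarray:
    """Shock-correlation coefficient per cell.

    Pearson r between the conditioning-period 2-s event rate and the
    repeating 1-0-0-0-0 shock indicator.  Cells without any conditioning-
    period event are excluded (r = NaN).
    """
    layout = schedule.layout
    ind = schedule.indicator_2s.astype(float)
    cond = rates.counts[:, layout.n_habituation_chunks :].astype(float)
    if cond.shape[1] != ind.size:
        raise ValueError("event-rate bins not aligned to the shock indicator")
    r = np.full(rates.n_cells, np.nan)
    for i in range(rates.n_cells):
        if cond[i].sum() == 0:
            log.info("cell %d: no conditioning-period events; shock r excluded", i)
            continue
        if cond[i].std() == 0:
            continue
        r[i] = sps.pearsonr(cond[i], ind)[0]
    return r


def compare_group_correlations(values_by_group: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis comparison of a correlation statistic across tuning
    groups (e.g. freezing r across shock classes).  Degenerate groups
    (< 2 finite values) are skipped with a log entry."""
    usable = {}
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            log.info("group %r has < 2 finite values; skipped", name)
            continue
        usable[name] = v
    if len(usable) < 2:
        return {"H": np.nan, "p": 1.0, "groups": list(usable), "message": "fewer than 2 usable groups"}
    pooled = np.concatenate(list(usable.values()))
    if np.ptp(pooled) == 0:
        return {"H": 0.0, "p": 1.0, "groups": list(usable), "message": "all values identical"}
    H, p = sps.kruskal(*usable.values())
    return {"H": float(H), "p": float(p), "groups": list(usable),
            "n": {k: v.size for k, v in usable.items()}}


# ---------------------------------------------------------------------------
# Shock-triggered averages, temporal similarity, spatial clustering


def shock_triggered_average(
    ztraces: np.ndarray,
    schedule: ShockSchedule,
    frame_rate_hz: float,
    groups: dict[str, np.ndarray],
    window_s: tuple[float, float] = (-2.0, 8.0),
    min_group: int = 5,
) -> dict:
    """Per-group mean z-scored trace aligned to shock onsets, with a
    two-sided Wilcoxon signed-rank test on per-cell (pre -2-0 s, post 0-2 s)
    means.  Groups smaller than ``min_group`` get no test."""
    layout = schedule.layout
    if window_s[1] - window_s[0] > layout.shock_period_s + CHUNK_S:
        raise ValueError("window exceeds the shock cycle length")
    f0 = int(round(window_s[0] * frame_rate_hz))
    f1 = int(round(window_s[1] * frame_rate_hz))
    w = int(round(CHUNK_S * frame_rate_hz))
    onsets = np.round(schedule.onsets * frame_rate_hz).astype(int)
    onsets = onsets[(onsets + f0 >= 0) & (onsets + f1 <= ztraces.shape[1])]

    out: dict = {"time_s": np.arange(f0, f1) / frame_rate_hz, "groups": {}}
    for name, idx in groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            continue
        segs = np.stack([ztraces[idx][:, f + f0 : f + f1] for f in onsets], axis=1)
        mean_tc = np.nanmean(segs, axis=(0, 1))
        pre = np.nanmean(np.stack([ztraces[idx][:, f - w : f] for f in onsets], 1), axis=(1, 2))
        post = np.nanmean(np.stack([ztraces[idx][:, f : f + w] for f in onsets], 1), axis=(1, 2))
        entry = {"mean": mean_tc, "n_cells": int(idx.size), "pre": pre, "post": post}
        if idx.size >= min_group and not np.allclose(pre, post):
            stat, p = sps.wilcoxon(pre, post)
            entry["wilcoxon_p"] = float(p)
        else:
            entry["wilcoxon_p"] = None
            if idx.size < min_group:
                log.info("group %r has < %d cells; test skipped", name, min_group)
        out["groups"][name] = entry
    return out


def temporal_population_similarity(
    rates: EventRateMatrix, max_lag: int = 30
) -> dict:
    """Mean Pearson correlation between population vectors at chunk lags
    1..max_lag, with paired t-tests of each lag against lag 1.

    Chunk pairs where either population vector has zero variance are skipped
    (and logged once)."""
    X = rates.counts.astype(float)
    n_bins = X.shape[1]
    if n_bins < max_lag + 1:
        raise ValueError(f"need >= {max_lag + 1} chunks, got {n_bins}")
    sd = X.std(axis=0)
    valid = sd > 0
    n_skipped = int((~valid).sum())
    if n_skipped:
        log.info("%d zero-variance chunks skipped pairwise", n_skipped)
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)

    per_lag_r: list[np.ndarray] = []
    for k in range(1, max_lag + 1):
        ok = valid[:-k] & valid[k:]
        num = (Xc[:, :-k] * Xc[:, k:]).sum(axis=0)
        r = np.full(n_bins - k, np.nan)
        r[ok] = num[ok] / (norms[:-k][ok] * norms[k:][ok])
        per_lag_r.append(r)

    mean_r = np.array([np.nanmean(r) for r in per_lag_r])
    tests = []
    base = per_lag_r[0]
    for k in range(2, max_lag + 1):
        r = per_lag_r[k - 1]
        m = min(base.size, r.size)
        a, b = base[:m], r[:m]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2 or np.allclose(a[ok], b[ok]):
            tests.append({"lag": k, "t": 0.0, "p": 1.0})
            continue
        t, p = sps.ttest_rel(a[ok], b[ok])
        tests.append({"lag": k, "t": float(t), "p": float(p)})
    return {"lags": np.arange(1, max_lag + 1), "mean_r": mean_r, "tests_vs_lag1": tests}


def spatial_clustering_test(
    centroids: np.ndarray,
    group_idx: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Spatial clustering of an annotated subpopulation within one mouse.

    Observed mean pairwise centroid distance of the group vs a null of
    equally sized random cell subsets drawn ``n_perm`` times; one-sided
    p = P(null <= obs) with add-one smoothing (small distances = clustered).
    """
    centroids = np.asarray(centroids, dtype=float)
    group_idx = np.asarray(group_idx)
    n_cells = centroids.shape[0]
    m = group_idx.size
    if m < 2:
        log.info("group of size %d; spatial test skipped", m)
        return {"observed": np.nan, "null_mean": np.nan, "p": None, "n_group": int(m)}

    from scipy.spatial.distance import pdist

    obs = pdist(centroids[group_idx]).mean()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for j in range(n_perm):
        sub = rng.choice(n_cells, size=m, replace=False)
        null[j] = pdist(centroids[sub]).mean()
    p = (1.0 + np.sum(null <= obs)) / (n_perm + 1.0)
    return {"observed": float(obs), "null_mean": float(null.mean()),
            "p": float(p), "n_group": int(m), "n_perm": n_perm}


def spatial_clustering_across_mice(per_mouse_results: list[dict]) -> dict:
    """Paired t-test of observed vs mean-shuffled pairwise distance across
    mice (each element from :func:`spatial_clustering_test`)."""
    obs = np.array([r["observed"] for r in per_mouse_results if r["p"] is not None])
    null = np.array([r["null_mean"] for r in per_mouse_results if r["p"] is not None])
    if obs.size < 2:
        return {"t": np.nan, "p": None, "n_mice": int(obs.size)}
    if np.allclose(obs, null):
        return {"t": 0.0, "p": 1.0, "n_mice": int(obs.size)}
    t, p = sps.ttest_rel(obs, null)
    return {"t": float(t), "p": float(p), "n_mice": int(obs.size)}


# ---------------------------------------------------------------------------
# Assembled annotation table


def annotate_cells(
    traces: CalciumTraces,
    rates: EventRateMatrix,
    freezing: np.ndarray,
    schedule: ShockSchedule,
    shock_alpha: float = 0.05,
    freezing_alpha: float = 0.01,
) -> pd.DataFrame:
    """One row per cell: shock class, freezing correlation class, shock
    correlation, centroid."""
    shock = shock_response_test(traces, schedule, alpha=shock_alpha)
    fz = freezing_correlation(rates, freezing, alpha=freezing_alpha)
    sr = shock_correlation(rates, schedule)
    df = pd.DataFrame(
        {
            "cell_id": np.asarray(traces.cell_ids),
            "shock_class": shock["shock_class"],
            "shock_p": shock["p"],
            "freezing_r": fz["r"],
            "freezing_p": fz["p"],
            "freezing_class": fz["freezing_class"],
            "shock_r": sr,
        }
    )
    if traces.centroids is not None:
        df["centroid_x"] = traces.centroids[:, 0]
        df["centroid_y"] = traces.centroids[:, 1]
    return df
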