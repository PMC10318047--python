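"""Sequence- and position-level behavioral statistics.

All resampling tests follow the same conventions: permutation p-values use
add-one smoothing, p = (1 + #extreme) / (n_perm + 1), so they lie in
[1/(n_perm+1), 1]; two-tailed permutation p-values use the doubling
convention 2 * min(P(null >= obs), P(null <= obs)) clipped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .session import CHUNK_S, SessionLayout, ShockSchedule
from .tracking import BACK_CENTER, FreezingTrace, PoseTrack

log = logging.getLogger(__name__)


@dataclass
class ClusterSequence:
    """One mouse's ordered bout labels with habituation/conditioning tags."""

    labels: np.ndarray  # per-bout cluster id
    periods: np.ndarray  # per-bout 'habituation' | 'conditioning'
    mouse_id: str = "m0"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.periods = np.asarray(self.periods, dtype=object)
        if self.labels.shape != self.periods.shape:
            raise ValueError("labels and periods must align")

    def in_period(self, period: str) -> np.ndarray:
        return self.labels[self.periods == period]


def tag_bout_periods(n_bouts: int, bout_s: float, layout: SessionLayout) -> np.ndarray:
    """Period tag per bout given the session layout."""
    starts = np.arange(n_bouts) * bout_s
    return np.where(starts < layout.habituation_s, "habituation", "conditioning").astype(object)


# ---------------------------------------------------------------------------
# Freezing by cluster


def freezing_by_cluster(
    sequences: list[ClusterSequence],
    freezings: list[np.ndarray],
) -> dict:
    """Per-cluster freezing distributions with omnibus one-way ANOVA and
    Tukey-Kramer post-hoc pairwise comparisons.

    ``freezings[i]`` holds the per-bout mean freezing rate aligned to
    ``sequences[i]``.  Clusters with fewer than 2 bouts are excluded from the
    post-hoc (and the omnibus is skipped if fewer than 2 clusters remain).
    """
    labels = np.concatenate([s.labels for s in sequences])
    fr = np.concatenate([np.asarray(f, float) for f in freezings])
    if labels.size != fr.size:
        raise ValueError("freezing values not aligned to bout labels")

    groups = {int(c): fr[labels == c] for c in np.unique(labels)}
    usable = {c: v for c, v in groups.items() if v.size >= 2}
    dropped = sorted(set(groups) - set(usable))
    if dropped:
        log.info("clusters with < 2 bouts excluded from posthoc: %s", dropped)

    out: dict = {"per_cluster": groups, "excluded": dropped}
    if len(usable) < 2:
        out["anova"] = None
        out["message"] = "fewer than 2 clusters with >= 2 bouts; omnibus skipped"
        log.info(out["message"])
        return out
    F, p = sps.f_oneway(*usable.values())
    out["anova"] = {"F": float(F), "p": float(p),
                    "n_groups": len(usable), "n_bouts": int(sum(v.size for v in usable.values()))}
    vals = np.concatenate(list(usable.values()))
    grp = np.concatenate([[c] * v.size for c, v in usable.items()])
    tk = pairwise_tukeyhsd(vals, grp)
    from itertools import combinations

    out["tukey"] = {
        # statsmodels reports pairs in combination order of the sorted groups
        "pairs": [(int(a), int(b)) for a, b in combinations(tk.groupsunique, 2)],
        "p": np.asarray(tk.pvalues, dtype=float),
        "reject": np.asarray(tk.reject, dtype=bool),
    }
    return out


# ---------------------------------------------------------------------------
# Markov-order analysis


def _build_markov_tables(seqs: list[np.ndarray], order: int) -> list[dict]:
    """Maximum-likelihood transition-frequency tables for orders 0..order,
    pooled over the given sequences."""
    tables: list[dict] = [dict() for _ in range(order + 1)]
    for seq in seqs:
        n = seq.size
        for m in range(order + 1):
            tab = tables[m]
            for t in range(m, n):
                key = tuple(seq[t - m : t])
                d = tab.setdefault(key, {})
                d[seq[t]] = d.get(seq[t], 0) + 1
    return tables


def _modal(d: dict):
    """Modal continuation; ties pick the smallest label (deterministic)."""
    best = max(d.values())
    return min(k for k, v in d.items() if v == best)


def _markov_accuracy(seq: np.ndarray, tables: list[dict], order: int) -> float:
    """Accuracy of the order-m modal predictor on ``seq``.

    Each bout from index ``order`` on is predicted from its m predecessors;
    histories unseen in the tables fall back to order m-1 (recursively, down
    to the order-0 marginal mode).
    """
    n = seq.size

    def predict(t: int) -> object:
        for m in range(order, 0, -1):
            d = tables[m].get(tuple(seq[t - m : t]))
            if d:
                return _modal(d)
        return _modal(tables[0][()])

    correct = sum(predict(t) == seq[t] for t in range(order, n))
    return correct / (n - order)


def fit_markov_models(
    sequences: list[ClusterSequence] | list[np.ndarray],
    max_order: int = 5,
    alpha: float = 0.025,
    evaluation: str = "insample",
) -> dict:
    """Markov-order analysis of behavioral sequences.

    The behavioral clusters are modeled as states of a Markov process; an
    order-m model predicts each bout from the preceding m bouts via
    maximum-likelihood transition frequencies (order 0 uses the marginal
    distribution).  Per-mouse prediction accuracy is computed for orders
    0..max_order and adjacent orders are compared with paired two-tailed
    t-tests across mice, Bonferroni-corrected at alpha / max_order
    (0.025/5 = 0.005 by default).

    ``evaluation`` selects where the tables are fitted: 'insample' (each
    mouse's own sequence, the comparative convention) or 'loo' (tables
    pooled over the other mice — out-of-sample, immune to the monotone
    in-sample overfitting of higher orders).
    """
    seqs = [s.labels if isinstance(s, ClusterSequence) else np.asarray(s) for s in sequences]
    if len(seqs) < 2:
        raise ValueError("Markov-order comparison needs >= 2 mice (paired test)")
    if evaluation not in ("insample", "loo"):
        raise ValueError(f"unknown evaluation {evaluation!r}")
    shortest = min(s.size for s in seqs)
    if shortest < max_order + 1:
        new_max = max(1, shortest - 1)
        log.warning("sequences too short for order %d; reducing to %d", max_order, new_max)
        max_order = new_max

    acc = np.empty((len(seqs), max_order + 1))
    for i, s in enumerate(seqs):
        for m in range(max_order + 1):
            if evaluation == "insample":
                tables = _build_markov_tables([s], m)
            else:
                tables = _build_markov_tables([q for j, q in enumerate(seqs) if j != i], m)
            acc[i, m] = _markov_accuracy(s, tables, m)
    corrected = alpha / max_order
    comparisons = []
    for m in range(max_order):
        a, b = acc[:, m], acc[:, m + 1]
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(b, a)
        comparisons.append(
            {"orders": (m, m + 1), "t": float(t), "p": float(p),
             "significant": bool(p < corrected), "mean_gain": float((b - a).mean())}
        )
    return {"accuracy": acc, "orders": np.arange(max_order + 1),
            "comparisons": comparisons, "alpha_corrected": corrected}


# ---------------------------------------------------------------------------
# Transition permutation test


@dataclass
class TransitionTestResult:
    transition_counts: np.ndarray  # K x K observed counts
    p_two_tailed: np.ndarray  # K x K
    n_perm: int
    period: str
    clusters: np.ndarray = field(default_factory=lambda: np.array([]))
    null_mean: np.ndarray | None = None  # K x K mean counts under the null

    @property
    def enriched(self) -> np.ndarray:
        """Transitions significantly MORE frequent than the shuffle null
        (p < 0.05 and observed above the null mean)."""
        return (self.p_two_tailed < 0.05) & (self.transition_counts > self.null_mean)


def transition_permutation_test(
    sequences: list[ClusterSequence],
    period: str,
    n_perm: int = 1000,
    seed: int = 0,
    clusters: np.ndarray | None = None,
) -> TransitionTestResult:
    """Permutation test of cluster-to-cluster transition counts.

    Observed ordered-pair transition counts are pooled over mice within the
    given period.  The null shuffles each mouse's within-period label
    sequence (destroying order, preserving composition) ``n_perm`` times.
    Two-tailed p per transition = 2 * min(P(null >= obs), P(null <= obs))
    with add-one smoothing, clipped to 1.
    """
    if n_perm < 100:
        log.warning("n_perm = %d is low; p-value resolution is limited", n_perm)
    rng = np.random.default_rng(seed)
    per_mouse = [s.in_period(period) for s in sequences]
    if clusters is None:
        clusters = np.unique(np.concatenate(per_mouse))
    K = clusters.size
    lut = {int(c): i for i, c in enumerate(clusters)}

    def count(seqs: list[np.ndarray]) -> np.ndarray:
        C = np.zeros((K, K), dtype=np.int64)
        for s in seqs:
            if s.size < 2:
                continue
            a = np.array([lut[int(v)] for v in s])
            np.add.at(C, (a[:-1], a[1:]), 1)
        return C

    obs = count(per_mouse)
    ge = np.zeros((K, K), dtype=np.int64)
    le = np.zeros((K, K), dtype=np.int64)
    null_sum = np.zeros((K, K), dtype=np.int64)
    for _ in range(n_perm):
        shuffled = [rng.permutation(s) for s in per_mouse]
        null = count(shuffled)
        ge += null >= obs
        le += null <= obs
        null_sum += null
    p = 2.0 * np.minimum(ge + 1, le + 1) / (n_perm + 1)
    p = np.minimum(p, 1.0)
    return TransitionTestResult(
        transition_counts=obs, p_two_tailed=p, n_perm=n_perm, period=period,
        clusters=clusters, null_mean=null_sum / n_perm,
    )


# ---------------------------------------------------------------------------
# Cluster-proportion group comparison


def cluster_proportion_test(
    group_a: list[ClusterSequence],
    group_b: list[ClusterSequence],
    period: str,
    n_perm: int = 10000,
    seed: int = 0,
    clusters: np.ndarray | None = None,
    alpha: float = 0.025,
) -> dict:
    """Two-group permutation test on per-cluster bout proportions.

    Statistic: difference (A - B) of the pooled proportion of each cluster
    within the period's bouts.  Null: mouse-level group labels permuted
    ``n_perm`` times.  Two-tailed p per cluster with add-one smoothing;
    significance threshold alpha / n_clusters (0.025/8 = 0.003125 for eight
    clusters).  Clusters absent from both groups get p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 mice")
    rng = np.random.default_rng(seed)
    all_seqs = [s.in_period(period) for s in group_a + group_b]
    n_a = len(group_a)
    if clusters is None:
        clusters = np.unique(np.concatenate(all_seqs))
    K = clusters.size

    def proportions(seqs: list[np.ndarray]) -> np.ndarray:
        pooled = np.concatenate(seqs) if seqs else np.array([])
        total = pooled.size
        if total == 0:
            return np.zeros(K)
        return np.array([(pooled == c).sum() for c in clusters]) / total

    obs = proportions(all_seqs[:n_a]) - proportions(all_seqs[n_a:])
    n_mice = len(all_seqs)
    ge = np.zeros(K, dtype=np.int64)
    le = np.zeros(K, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_mice)
        null = proportions([all_seqs[i] for i in perm[:n_a]]) - proportions(
            [all_seqs[i] for i in perm[n_a:]]
        )
        ge += null >= obs
        le += null <= obs
    p = np.minimum(2.0 * np.minimum(ge + 1, le + 1) / (n_perm + 1), 1.0)
    corrected = alpha / K
    return {
        "clusters": clusters,
        "diff": obs,
        "p": p,
        "significant": p < corrected,
        "alpha_corrected": corrected,
        "n_perm": n_perm,
        "period": period,
    }


# ---------------------------------------------------------------------------
# Side preference


@dataclass
class SidePreferenceResult:
    near_frames_adj: np.ndarray  # per mouse
    far_frames_adj: np.ndarray
    t: float | None
    p: float | None
    layout: SessionLayout = field(repr=False, default=SessionLayout())


def _compartment_counts(
    track: PoseTrack, layout: SessionLayout
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Frame counts of the back center inside the near and far x-fifths,
    split by (habituation, conditioning)."""
    x = track.coords[:, BACK_CENTER, 0]
    fifth = layout.arena_w_px / 5.0
    if layout.demonstrator_side == "left":
        near = x < fifth
        far = x >= layout.arena_w_px - fifth
    else:
        near = x >= layout.arena_w_px - fifth
        far = x < fifth
    n_hab = int(round(layout.habituation_s * track.frame_rate_hz))
    return (
        (int(near[:n_hab].sum()), int(near[n_hab:].sum())),
        (int(far[:n_hab].sum()), int(far[n_hab:].sum())),
    )


def side_preference(
    tracks: list[PoseTrack], layout: SessionLayout
) -> SidePreferenceResult:
    """Side-preference analysis: adjusted frame counts in the demonstrator-
    near and -far fifths of the arena.

    The arena is split into five equal x-divisions; the fifth closest to the
    demonstrator is 'near' and the farthest 'far'.  Adjusted count =
    conditioning frames - 2 x habituation frames (the factor 2 compensates
    for the 600 s / 300 s period lengths, so a time-homogeneous occupancy
    yields 0 in expectation).  Paired two-tailed t-test across mice on
    adjusted near vs far.
    """
    near_adj, far_adj = [], []
    for tr in tracks:
        (nh, nc), (fh, fc) = _compartment_counts(tr, layout)
        near_adj.append(nc - 2 * nh)
        far_adj.append(fc - 2 * fh)
    near_adj = np.array(near_adj, dtype=float)
    far_adj = np.array(far_adj, dtype=float)
    if len(tracks) >= 2 and not np.allclose(near_adj, far_adj):
        t, p = sps.ttest_rel(near_adj, far_adj)
        t, p = float(t), float(p)
    elif len(tracks) >= 2:
        t, p = 0.0, 1.0
    else:
        t = p = None
    return SidePreferenceResult(
        near_frames_adj=near_adj, far_frames_adj=far_adj, t=t, p=p, layout=layout
    )


# ---------------------------------------------------------------------------
# Shock-cycle profile


def shock_cycle_profile(signal_2s: np.ndarray, schedule: ShockSchedule) -> dict:
    """Average a conditioning-period 2-s signal over the shock cycle.

    ``signal_2s`` must hold one value per conditioning 2-s chunk (e.g. 300
    for a 600-s conditioning period).  Returns per-phase (0-2, 2-4, ... s)
    mean and SEM across cycles plus a one-way ANOVA across phases.
    """
    signal_2s = np.asarray(signal_2s, dtype=float)
    layout = schedule.layout
    cpp = layout.chunks_per_period
    n_cycles = schedule.n_shocks
    if signal_2s.size != n_cycles * cpp:
        raise ValueError(
            f"signal length {signal_2s.size} does not match {n_cycles} cycles "
            f"x {cpp} phases"
        )
    cycles = signal_2s.reshape(n_cycles, cpp)
    mean = cycles.mean(axis=0)
    sem = cycles.std(axis=0, ddof=1) / np.sqrt(n_cycles) if n_cycles > 1 else np.zeros(cpp)
    if n_cycles > 1 and np.ptp(cycles) > 0:
        F, p = sps.f_oneway(*cycles.T)
        F, p = float(F), float(p)
    else:
        F, p = 0.0, 1.0
    phases = [(i * CHUNK_S, (i + 1) * CHUNK_S) for i in range(cpp)]
    return {"phases_s": phases, "mean": mean, "sem": sem, "anova_F": F, "anova_p": p,
            "n_cycles": n_cycles}
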