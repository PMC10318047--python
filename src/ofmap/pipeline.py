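"""End-to-end orchestration: simulate a cohort, build / apply the behavioral
atlas, run sequence statistics, process calcium, annotate neurons, decode.

Each runner writes its artifacts under the config's output directory and
returns a report dict; a manifest records every written file with a SHA-256
checksum, the config hash and the seed, so any stage can be reproduced and
verified from its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import decoding as dec
from . import events as ev
from . import mapping as mp
from . import stats as st
from .config import RunConfig, stage_seed
from .session import CHUNK_S
from .synthetic import SyntheticSession, generate_session

log = logging.getLogger(__name__)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, files: list[Path]) -> Path:
    from . import __version__

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "files": {str(p.relative_to(out)): _checksum(p) for p in files},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def simulate_cohort(cfg: RunConfig, n_mice: int, stage: str) -> list[SyntheticSession]:
    base = stage_seed(cfg.seed, stage)
    return [
        generate_session(cfg.layout, cfg.behavior, cfg.cells, seed=(base + i) % (2**31))
        for i in range(n_mice)
    ]


def per_bout_freezing(session: SyntheticSession, bout_s: float) -> np.ndarray:
    """Mean freezing per bout (bouts of ``bout_s`` seconds)."""
    cpb = int(round(bout_s / CHUNK_S))
    fz = session.freezing.values
    n_bouts = fz.size // cpb
    return fz[: n_bouts * cpb].reshape(n_bouts, cpb).mean(axis=1)


def run_behavior(cfg: RunConfig, sessions: list[SyntheticSession] | None = None) -> dict:
    """Behavior pipeline: atlas from the cohort's 10-s bouts, per-mouse
    cluster sequences, freezing-by-cluster, Markov orders, transition
    permutation tests, side preference."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.params
    if sessions is None:
        sessions = simulate_cohort(cfg, cfg.n_behavior_mice, "behavior_cohort")

    bout_s = p["bout_s"]
    per_mouse = [
        mp.segment_bouts(s.pose, bout_s=bout_s, mouse_id=f"m{i}")
        for i, s in enumerate(sessions)
    ]
    ref = mp.concat_bouts(per_mouse)
    atlas = mp.build_atlas(
        ref,
        perplexity=p["perplexity"],
        seed=stage_seed(cfg.seed, "tsne"),
        grid_n=p["grid_n"],
        bandwidth_mult=p["bandwidth_mult"],
    )
    atlas_path = out / "atlas.h5"
    atlas.save(atlas_path)

    # per-mouse label sequences from the reference embedding
    sizes = [m.n_bouts for m in per_mouse]
    splits = np.cumsum(sizes)[:-1]
    label_chunks = np.split(atlas.bout_labels, splits)
    sequences = [
        st.ClusterSequence(
            labels=lab,
            periods=st.tag_bout_periods(lab.size, bout_s, cfg.layout),
            mouse_id=f"m{i}",
        )
        for i, lab in enumerate(label_chunks)
    ]
    rows = []
    for seq, m in zip(sequences, per_mouse):
        for (mouse, start), lab, per in zip(m.bout_index, seq.labels, seq.periods):
            rows.append((mouse, start, int(lab), per))
    labels_path = out / "bout_labels.tsv"
    pd.DataFrame(rows, columns=["mouse", "start_s", "cluster", "period"]).to_csv(
        labels_path, sep="\t", index=False
    )

    freezings = [per_bout_freezing(s, bout_s) for s in sessions]
    fz_stats = st.freezing_by_cluster(sequences, freezings)
    markov = st.fit_markov_models(sequences)
    trans = {
        period: st.transition_permutation_test(
            sequences, period, n_perm=p["n_perm_transition"],
            seed=stage_seed(cfg.seed, f"trans_{period}"),
        )
        for period in ("habituation", "conditioning")
    }
    side = st.side_preference([s.pose for s in sessions], cfg.layout)

    summary = {
        "n_mice": len(sessions),
        "n_reference_bouts": ref.n_bouts,
        "feature_dim": int(ref.features.shape[1]),
        "n_clusters": atlas.n_regions,
        "anova_F": fz_stats["anova"]["F"] if fz_stats["anova"] else None,
        "markov_alpha": markov["alpha_corrected"],
        "side_preference_p": side.p,
    }
    (out / "behavior_summary.json").write_text(json.dumps(summary, indent=1))
    manifest = _write_manifest(
        out, cfg, [atlas_path, labels_path, out / "behavior_summary.json"]
    )
    log.info("behavior run: %d mice, %d bouts, %d clusters",
             len(sessions), ref.n_bouts, atlas.n_regions)
    return {
        "atlas": atlas, "sequences": sequences, "freezing_stats": fz_stats,
        "markov": markov, "transitions": trans, "side_preference": side,
        "summary": summary, "manifest": str(manifest),
    }


def run_imaging(
    cfg: RunConfig,
    sessions: list[SyntheticSession] | None = None,
    cluster_sequences: list[st.ClusterSequence] | None = None,
) -> dict:
    """Imaging pipeline: event detection, 2-s rates, neuron annotation,
    decoding of freezing and (when labels are provided) behavioral clusters."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.params
    if sessions is None:
        sessions = simulate_cohort(cfg, cfg.n_imaging_mice, "imaging_cohort")

    per_mouse_reports = []
    annotations = []
    real_acc, null_acc = [], []
    for i, s in enumerate(sessions):
        if s.calcium.shape[0] == 0:
            log.info("mouse %d has zero cells; empty report", i)
            per_mouse_reports.append({"mouse": f"m{i}", "n_cells": 0})
            continue
        traces = ev.CalciumTraces(
            dff=s.calcium, frame_rate_hz=cfg.layout.imaging_hz, centroids=s.centroids
        )
        raster = ev.detect_events(traces, sd_mult=p["sd_mult"])
        rates = ev.bin_events(raster, cfg.layout)
        df = ann.annotate_cells(
            traces, rates, s.freezing.values, s.schedule,
            shock_alpha=p["shock_alpha"], freezing_alpha=p["freezing_alpha"],
        )
        df.insert(0, "mouse", f"m{i}")
        annotations.append(df)

        feats = dec.build_decoder_features(rates)
        fz_bout = per_bout_freezing(s, 10.0)
        labels = dec.binarize_freezing(fz_bout)
        ds = dec.DecoderDataset(features=feats, labels=labels, mouse_id=f"m{i}")
        res = dec.shuffle_null(
            ds,
            n_shuffles=p["decode_shuffles"],
            n_repeats_real=p["decode_repeats"],
            n_repeats_per_shuffle=p["decode_repeats_per_shuffle"],
            seed=stage_seed(cfg.seed, f"decode_{i}"),
        )
        real_acc.append(res.accuracy_real)
        null_acc.append(float(res.null_accuracies.mean()))
        per_mouse_reports.append(
            {"mouse": f"m{i}", "n_cells": traces.n_cells,
             "n_events": int(sum(e.size for e in raster)),
             "decode_accuracy": res.accuracy_real, "decode_p": res.p_one_sided}
        )

    ann_path = out / "annotations.tsv"
    if annotations:
        pd.concat(annotations, ignore_index=True).to_csv(ann_path, sep="\t", index=False)
    else:
        pd.DataFrame().to_csv(ann_path, sep="\t", index=False)
    group_test = dec.compare_across_mice(np.array(real_acc), np.array(null_acc)) if real_acc else None
    report = {
        "per_mouse": per_mouse_reports,
        "decode_group_test": group_test,
    }

    def _json_safe(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return float(o)

    (out / "imaging_summary.json").write_text(json.dumps(report, indent=1, default=_json_safe))
    manifest = _write_manifest(out, cfg, [ann_path, out / "imaging_summary.json"])
    return {"annotations": annotations, "report": report, "manifest": str(manifest)}


def run_full(cfg: RunConfig) -> dict:
    """Behavior + imaging, sharing the synthetic cohorts."""
    behavior = run_behavior(cfg)
    imaging = run_imaging(cfg)
    return {"behavior": behavior, "imaging": imaging}
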