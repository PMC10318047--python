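"""Run configuration: one structured YAML file holding the session layout,
per-stage parameter blocks, input paths or synthetic-generation blocks, the
global seed and the output directory.

Every stochastic stage derives its own seed deterministically from the global
seed and the stage name, so a config + seed pair fully determines a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .session import SessionLayout
from .synthetic import BehaviorGenConfig, CellGenConfig


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    layout: SessionLayout = field(default_factory=SessionLayout)
    behavior: BehaviorGenConfig = field(default_factory=BehaviorGenConfig)
    cells: CellGenConfig = field(default_factory=CellGenConfig)
    seed: int = 0
    out_dir: str = "ofmap_out"
    n_behavior_mice: int = 13
    n_imaging_mice: int = 4
    # stage parameter blocks (thresholds visible and versioned in one place)
    params: dict = field(
        default_factory=lambda: {
            "bout_s": 10.0,
            "perplexity": 30.0,
            "grid_n": 512,
            "bandwidth_mult": 1.0,
            "knn_k": 10,
            "mobility_threshold": 0.5,
            "sd_mult": 2.5,
            "n_perm_transition": 1000,
            "n_perm_proportion": 10000,
            "n_perm_cluster_specific": 10000,
            "n_perm_spatial": 10000,
            "freezing_alpha": 0.01,
            "shock_alpha": 0.05,
            "decode_repeats": 100,
            "decode_shuffles": 100,
            "decode_repeats_per_shuffle": 5,
        }
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "layout" in d and isinstance(d["layout"], dict):
            d["layout"] = SessionLayout(**d["layout"])
        if "behavior" in d and isinstance(d["behavior"], dict):
            b = dict(d["behavior"])
            if b.get("mode_anchors") is not None:
                b["mode_anchors"] = tuple(tuple(a) for a in b["mode_anchors"])
            if b.get("mode_motion_px") is not None:
                b["mode_motion_px"] = tuple(b["mode_motion_px"])
            d["behavior"] = BehaviorGenConfig(**b)
        if "cells" in d and isinstance(d["cells"], dict):
            c = dict(d["cells"])
            if "clustered_classes" in c:
                c["clustered_classes"] = tuple(c["clustered_classes"])
            d["cells"] = CellGenConfig(**c)
        base = cls()
        if "params" in d:
            merged = dict(base.params)
            merged.update(d["params"])
            d["params"] = merged
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
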