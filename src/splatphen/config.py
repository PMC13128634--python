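"""Pipeline configuration: every tunable with its default, TOML-loadable.

The pipeline carries many calibrated constants; every CLI run serializes
the resolved configuration and seed next to its outputs so results are
reproducible from the logs alone.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    # lifting
    q: float = 0.88
    k_sigma: float = 3.0
    visibility: str = "opacity"        # or "accumulated"
    # clustering
    xi: float = 0.1
    beta: float = 2.0
    min_samples: int | None = None     # default: max(5, 0.005 * |F|)
    # refinement
    zeta: float = 0.80
    zeta_relaxed: float = 0.90
    gmm_max_components: int = 4
    subsample_cap: int = 50000
    # export
    cloud_density: float = 20.0
    cloud_trunc_sigma: float = 2.0
    # organ grouping / remap
    delta: float = 0.02
    knn_k: int = 8
    gamma: float = 2.5
    min_points: int = 30
    tau_op: float = 0.05
    alpha_r: float = 3.0
    # traits
    a_plot_m2: float = 0.036
    ref_length_m: float = 0.42
    leaf_k_sigma: float = 2.0
    height_operator: str = "closing"
    # frame selection
    keep_fraction: float = 0.25
    min_motion_px: float = 2.0
    # global
    seed: int = 0

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, directory) -> Path:
        path = Path(directory) / "resolved_config.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)
        return path
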