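"""End-to-end extraction: lift -> cluster (+retain) -> refine.

Convenience orchestration of the three stages with the published defaults
(q = 0.88, xi = 0.1, beta = 2, zeta = 0.80), plus the staged variants used
by ablation sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cameras import CameraView
from .cluster import (DEFAULT_BETA, DEFAULT_XI, build_descriptors, nn_retain,
                      optics_cluster_merge)
from .cues import CueSet
from .lift import DEFAULT_Q, LiftResult, foreground_select, support_scores
from .refine import DEFAULT_ZETA, refine
from .splats import SplatSet

STAGES = ("lift", "cluster", "retain", "refine")


@dataclass
class ExtractionConfig:
    q: float = DEFAULT_Q
    xi: float = DEFAULT_XI
    beta: float = DEFAULT_BETA
    zeta: float = DEFAULT_ZETA
    k_sigma: float = 3.0
    min_samples: int | None = None
    rng_seed: int = 0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


@dataclass
class ExtractionResult:
    lift: LiftResult
    selected: np.ndarray              # final extracted positional indices
    stage_sets: dict[str, np.ndarray] = field(default_factory=dict)


def run_stages(scene: SplatSet, views: list[CameraView], lift_result: LiftResult,
               config: ExtractionConfig) -> ExtractionResult:
    """Apply the enabled stages downstream of precomputed lift scores."""
    sets: dict[str, np.ndarray] = {}
    fg = foreground_select(lift_result, q=config.q)
    sets["lift"] = fg
    current = fg
    if "cluster" in config.stages and len(fg) > 0:
        features = build_descriptors(fg, scene, views)
        outcome = optics_cluster_merge(features, lift_result.support,
                                       xi=config.xi, min_samples=config.min_samples)
        current = outcome.kept
        sets["cluster"] = current
    if "retain" in config.stages:
        current = nn_retain(current, scene, beta=config.beta)
        sets["retain"] = current
    if "refine" in config.stages and len(current) >= 10:
        current, _ = refine(scene, current, zeta=config.zeta, rng_seed=config.rng_seed)
        sets["refine"] = current
    return ExtractionResult(lift=lift_result, selected=current, stage_sets=sets)


def extract_plant(scene: SplatSet, views: list[CameraView], cues: CueSet,
                  config: ExtractionConfig | None = None) -> ExtractionResult:
    """Full extraction from scene + cameras + seeded cue masks."""
    config = config or ExtractionConfig()
    lift_result = support_scores(scene, views, cues, k_sigma=config.k_sigma)
    return run_stages(scene, views, lift_result, config)
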