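"""Pipeline configuration.

A single :class:`PipelineConfig` carries every tunable threshold of the
perturbation-mining pipeline, so that a run is fully described by one
config object plus one RNG seed.  All stochastic operations derive their
own sub-seed deterministically from ``rng_seed`` (see :func:`derive_seed`).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and constants of the perturbation-mining pipeline.

    Attributes
    ----------
    deg_fc_threshold:
        Fold-change cutoff for calling a gene differentially expressed.
        Applied two-sidedly: a gene passes if FC > t or FC < 1/t.
    deg_p_threshold:
        Raw p-value cutoff for the differential test (no multiple-testing
        correction at this stage).
    top_path_fraction:
        Fraction of ranked all-pairs shortest paths retained in the TopNet
        (0.0001 = the top 0.01% of paths).
    min_dataset_count:
        Minimum number of per-dataset TopNets a node must appear in to
        enter the frequently perturbed subnetwork (4-of-5 by default).
    node_weight_epsilon:
        Floor for node weights |log2FC|; keeps edge weights finite for
        unperturbed or unmeasured genes.
    rng_seed:
        Master seed; every stochastic stage derives a sub-seed from it.
    enrichment_alpha:
        Significance level for over-representation calls.
    """

    deg_fc_threshold: float = 1.5
    deg_p_threshold: float = 0.05
    top_path_fraction: float = 0.0001
    min_dataset_count: int = 4
    node_weight_epsilon: float = 1e-6
    rng_seed: int = 0
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.deg_fc_threshold <= 0:
            raise ValueError("deg_fc_threshold must be positive")
        if not 0 < self.deg_p_threshold:
            raise ValueError("deg_p_threshold must be positive")
        if not 0 < self.top_path_fraction < 1:
            raise ValueError("top_path_fraction must lie in (0, 1)")
        if self.min_dataset_count < 1:
            raise ValueError("min_dataset_count must be >= 1")
        if self.node_weight_epsilon < 0:
            raise ValueError("node_weight_epsilon must be nonnegative")
        if not 0 < self.enrichment_alpha:
            raise ValueError("enrichment_alpha must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML or JSON; unknown keys are rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic sub-seed for a named stochastic stage.

    Mixes the master seed with a stable hash of the stage label so that
    distinct stages get independent streams while a fixed (seed, label)
    pair always yields the same sub-seed.  Result is kept below 2**31.
    """
    h = zlib.crc32(label.encode("utf-8"))
    return (int(master_seed) * 1_000_003 + h) % (2**31 - 1)
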