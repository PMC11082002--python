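"""Pipeline configuration: validated flat key-value (TOML) config with seeds.

A single master seed is split deterministically into per-module seeds so
every stochastic step (rarefaction, NMDS restarts, permutation tests,
simulation) is reproducible from one integer.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields

from ._util import split_seed


@dataclass
class PipelineConfig:
    # inputs / outputs
    table: str = ""
    chronology: str = ""
    outdir: str = "sedshift_out"
    # taxonomy & selection
    rank: str = "class"
    min_mean_abund: float = 0.01
    max_taxa: int = 12          # ordination/diversity taxon cap
    max_taxa_glv: int = 4       # gLV modeled set (must stay < stage window - 1)
    # ordination
    nmds_k: int = 2
    nmds_restarts: int = 20
    # tests
    n_perm: int = 999
    # transition detection
    ews_window: int = 5
    max_breaks: int = 3
    min_segment: int = 5
    arima_p: int = 1
    arima_d: int = 1
    arima_q: int = 0
    # gLV staging
    stage_window: int = 10
    stage_step: int = 5
    k_folds: int = 5
    lambda_min: float = 1e-4
    lambda_max: float = 1e2
    lambda_points: int = 25
    per_taxon_lambda: bool = False
    classify_on: str = "effects"
    # simulation
    sim_taxa: int = 12
    sim_samples: int = 35
    sim_depth: int = 20_000
    sim_noise_sd: float = 0.05
    sim_transition: bool = True
    # master seed
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.stage_window > self.stage_step, "stage_window must exceed stage_step"),
            (self.ews_window >= 3, "ews_window must be >= 3"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (0 <= self.min_mean_abund < 1, "min_mean_abund must be in [0, 1)"),
            (self.max_taxa >= 2 and self.max_taxa_glv >= 2, "taxon caps must be >= 2"),
            (self.k_folds >= 2, "k_folds must be >= 2"),
            (0 < self.lambda_min <= self.lambda_max, "lambda range invalid"),
            (self.lambda_points >= 1, "lambda_points must be >= 1"),
            (self.nmds_k >= 1 and self.nmds_restarts >= 1, "NMDS settings invalid"),
            (self.sim_samples >= 20, "sim_samples must be >= 20"),
            (self.sim_depth > 0, "sim_depth must be positive"),
            (self.classify_on in ("effects", "raw"), "classify_on must be effects|raw"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def module_seeds(self) -> dict[str, int]:
        names = ["rarefy", "nmds", "anosim", "permanova", "simulate", "glv"]
        return dict(zip(names, split_seed(self.seed, len(names))))


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a TOML config file; keyword overrides win.  Unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)
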