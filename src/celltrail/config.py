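"""Run configuration: one seed, one TOML file, every stage's knobs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from .cartography import BundleConfig
from .cluster import LtrwParams
from .graphs import GraphParams
from .walks import MemoryConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All pipeline parameters plus the global seed.

    The seed governs clustering, MCMC refinement, walks, layout, the
    embedding and kmeans, so a run is reproducible from the config and
    input alone.  Sub-configs inherit the global seed unless their own
    seed is set explicitly in the file.
    """

    seed: int = 0
    root: Optional[int] = None          # root cluster; None -> auto-detect
    resolution: float = 1.0
    n_milestones: int = 0               # 0 -> min(max(150, n/100), 1000)
    embed_epochs: int = 150
    graph: GraphParams = field(default_factory=GraphParams)
    ltrw: LtrwParams = field(default_factory=LtrwParams)
    walk: MemoryConfig = field(default_factory=MemoryConfig)
    bundle: BundleConfig = field(default_factory=BundleConfig)

    def __post_init__(self) -> None:
        self.ltrw.seed = int(self.seed)
        self.walk.seed = int(self.seed)

    def milestones_for(self, n_cells: int) -> int:
        if self.n_milestones > 0:
            return self.n_milestones
        return int(min(max(150, n_cells // 100), min(1000, n_cells - 1)))


_SECTIONS = {"graph": GraphParams, "ltrw": LtrwParams, "walk": MemoryConfig,
             "bundle": BundleConfig}
_TOP_KEYS = {"seed", "root", "resolution", "n_milestones", "embed_epochs"}


def load_config(path: str) -> RunConfig:
    """Load a RunConfig from TOML; unknown keys are rejected."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    top = {}
    subs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            allowed = {f.name for f in dataclasses.fields(cls)
                       if f.name != "distance_to_weight"}
            unknown = set(val) - allowed
            if unknown:
                raise ValueError(f"unknown keys in [{key}]: {sorted(unknown)}")
            subs[key] = cls(**val)
        elif key in _TOP_KEYS:
            top[key] = val
        else:
            raise ValueError(f"unknown config key: {key}")
    cfg = RunConfig(**top, **subs)
    # sub-seeds follow the global seed unless set in the file
    for sec in ("ltrw", "walk"):
        if sec in raw and "seed" in raw[sec]:
            getattr(cfg, sec).seed = int(raw[sec]["seed"])
    return cfg
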