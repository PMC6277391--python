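"""Run configuration: one flat YAML file, strict keys, seed hierarchy.

A run is reproduced from a single plain-text config plus a master seed;
per-stage seeds are derived from the master so stages stay independent of
one another's draw counts.  Unknown keys are rejected rather than ignored,
and every run writes its resolved config next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_seed"]

#: fixed offsets give each stage its own substream of the master seed
_STAGE_OFFSETS = {
    "feeding": 1, "relaxometry": 2, "proteome": 3, "melt": 4, "spectra": 5,
}


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a per-stage (and per-repeat) seed below 2^31 from the master."""
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([master_seed, _STAGE_OFFSETS[stage], index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters of a full synthetic demonstration run."""

    seed: int = 0
    outdir: str = "results/demo"
    # feeding / composition
    scenario: str = "willow"
    n_batches: int = 10
    cv: float = 0.05
    # relaxometry
    acquisition: str = "control"
    full_length_decay: bool = False
    n_components: str | int = 3
    regularization: str | float = "auto"
    rho_nm_per_s: float | None = None  # pore map only computed when supplied
    # proteomics
    proteome_depth: int = 10_000
    expect_cutoff: float = 0.05
    min_peptides: int = 2
    # thermal shift
    melt_presets: tuple[str, ...] = ("native", "seawater", "buffer", "chelator")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "melt_presets" in raw:
            raw = dict(raw, melt_presets=tuple(raw["melt_presets"]))
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["melt_presets"] = list(data["melt_presets"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
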