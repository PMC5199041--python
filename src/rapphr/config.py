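"""Pipeline configuration: profiles, parameter blocks, YAML round trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._util import ConfigError
from .simulate import SimulationConfig


@dataclass
class SearchBlock:
    evalue_max: float = 1e-20
    min_homology_len_aa: int = 300


@dataclass
class ScanBlock:
    window: tuple[int, int] = (-100, 600)
    orf_len_aa: tuple[int, int] = (35, 120)
    signal_threshold: float = 0.3
    same_strand_required: bool = True


@dataclass
class TreeBlock:
    n_bootstrap: int = 25
    orphan_merge_distance: float | None = 0.2
    # conservation screen: a propeptide is rejected when the receptor has
    # relatives within this tree distance and none shares its C-terminal
    # pentamer (None disables the screen)
    conservation_screen_distance: float | None = 0.2


@dataclass
class MobilityBlock:
    alpha: float = 0.05
    min_orf_len_nt: int = 300


@dataclass
class RarefactionBlock:
    n_resamples: int = 500
    tail_window: int = 10


#: parameter overrides per profile; the receptor-family profiles differ only
#: in homology stringency and propeptide window, the species-tree profile
#: searches a single long marker and skips the propeptide stage entirely.
PROFILES: dict[str, dict] = {
    "rap": {},
    "nprr": {"search": {"evalue_max": 1e-30},
             "scan": {"window": (-100, 500)}},
    "gyra-species-tree": {"search": {"min_homology_len_aa": 500},
                          "scan": None},
}


@dataclass
class PipelineConfig:
    profile: str = "rap"
    seed: int = 0
    out_dir: str = "results"
    simulate: bool = True
    genomes_dir: str | None = None
    species_map: str | None = None
    queries_fasta: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    search: SearchBlock = field(default_factory=SearchBlock)
    scan: ScanBlock | None = field(default_factory=ScanBlock)
    tree: TreeBlock = field(default_factory=TreeBlock)
    mobility: MobilityBlock = field(default_factory=MobilityBlock)
    rarefaction: RarefactionBlock = field(default_factory=RarefactionBlock)

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ConfigError(f"unknown profile {self.profile!r}; "
                              f"choose from {sorted(PROFILES)}")
        self.apply_profile()
        self.simulation.seed = self.seed

    def apply_profile(self) -> None:
        for block_name, overrides in PROFILES[self.profile].items():
            if overrides is None:
                setattr(self, block_name, None)
                continue
            block = getattr(self, block_name)
            for k, v in overrides.items():
                setattr(block, k, v)

    def resolved(self) -> dict:
        """Fully resolved parameter echo (deterministic key order)."""
        return _asdict_clean(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        blocks = {"simulation": SimulationConfig, "search": SearchBlock,
                  "scan": ScanBlock, "tree": TreeBlock,
                  "mobility": MobilityBlock, "rarefaction": RarefactionBlock}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            if key in blocks and isinstance(value, dict):
                fieldnames = {f.name for f in dataclasses.fields(blocks[key])}
                bad = set(value) - fieldnames
                if bad:
                    raise ConfigError(f"unknown key(s) in {key!r}: {sorted(bad)}")
                value = {k: tuple(v) if isinstance(v, list) else v
                         for k, v in value.items()}
                kwargs[key] = blocks[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _asdict_clean(obj) -> dict:
    def conv(v):
        if dataclasses.is_dataclass(v):
            return {k: conv(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, tuple):
            return list(v)
        return v

    return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
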