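"""Study configuration: a flat key/value file (YAML subset) round-tripping StudyGrid."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .power import StudyGrid
from .simulate import CONSTRUCTIONS

__all__ = ["ConfigError", "StudyConfig"]


class ConfigError(ValueError):
    """A configuration file contains an unknown or invalid entry."""


@dataclass(frozen=True)
class StudyConfig:
    """Everything :class:`~unbalanced_anova.power.StudyGrid` needs, plus output options."""

    replicates: int = 1000
    alpha: float = 0.05
    beta3_values: tuple[float, ...] = (0.0, 4.0, 8.0)
    constructions: tuple[str, ...] = CONSTRUCTIONS
    design_ids: tuple[int, ...] | None = None
    base_seed: int = 0
    scale: int = 10
    beta0: float = 10.0
    beta1: float = 4.0
    beta2: float = 4.0
    sigma: float = 10.0
    out_dir: str = "study_out"
    formats: tuple[str, ...] = ("tsv", "json")
    verbosity: str = "info"

    def __post_init__(self) -> None:
        for construction in self.constructions:
            if construction not in CONSTRUCTIONS:
                raise ConfigError(f"unknown construction {construction!r}")
        if self.verbosity not in ("quiet", "info", "debug"):
            raise ConfigError(f"verbosity must be quiet/info/debug, got {self.verbosity!r}")

    def grid(self) -> StudyGrid:
        return StudyGrid(
            beta3_values=tuple(self.beta3_values),
            constructions=tuple(self.constructions),
            replicates=self.replicates,
            alpha=self.alpha,
            base_seed=self.base_seed,
            scale=self.scale,
            design_ids=None if self.design_ids is None else tuple(self.design_ids),
            beta0=self.beta0,
            beta1=self.beta1,
            beta2=self.beta2,
            sigma=self.sigma,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = {}
        for key, value in data.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key/value mapping")
        return cls.from_dict(data)
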