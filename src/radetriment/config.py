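"""Run configuration: grid, site catalogue tweaks, policies, output control."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .grids import AgeGrid
from .lethality import CLAMP, ERROR


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a pipeline run.

    Attributes
    ----------
    grid : AgeGrid
        Age axis; defaults to 18 five-year groups, 85+ open top.
    q_min_overrides : dict
        Site name -> q_min replacing the catalogue rule.
    clamp_policy : str
        "clamp" (default: k > 1 clamped to 1 with a warning) or "error".
    q_source : str
        "computed" (q from k; the pipeline default) or "printed"
        (tabulated q supplied externally, used for reproductions only).
    l_rel_sites : str
        Which sites enter the relative-life-lost average: "computed"
        (default: the non-fixed sites with a computed L) — fixed rows carry
        their frozen L_rel and never enter the average.
    survival_convention : str
        "end" (survival through the end of group i; the literal default) or
        "start" (conventional life-table reading).
    """

    grid: AgeGrid = field(default_factory=AgeGrid)
    q_min_overrides: dict[str, float] = field(default_factory=dict)
    clamp_policy: str = CLAMP
    q_source: str = "computed"
    l_rel_sites: str = "computed"
    survival_convention: str = "end"
    output_dir: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.clamp_policy not in (CLAMP, ERROR):
            raise ConfigError(f"unknown clamp policy {self.clamp_policy!r}")
        if self.q_source not in ("computed", "printed"):
            raise ConfigError(f"unknown q source {self.q_source!r}")
        if self.l_rel_sites != "computed":
            raise ConfigError(f"unknown l_rel site policy {self.l_rel_sites!r}")
        if self.survival_convention not in ("end", "start"):
            raise ConfigError(
                f"unknown survival convention {self.survival_convention!r}"
            )
        for name, q in self.q_min_overrides.items():
            if not 0.0 <= q < 1.0:
                raise ConfigError(f"q_min override for {name!r} outside [0, 1)")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {
            "lower_bounds": list(self.grid.lower_bounds),
            "width": self.grid.width,
            "open_top": self.grid.open_top,
            "top_midpoint": self.grid.top_midpoint,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            g = d["grid"]
            d["grid"] = AgeGrid(
                lower_bounds=tuple(float(x) for x in g.get("lower_bounds",
                                                           AgeGrid().lower_bounds)),
                width=float(g.get("width", 5.0)),
                open_top=bool(g.get("open_top", True)),
                top_midpoint=float(g.get("top_midpoint", 87.5)),
            )
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(payload)

    def write(self, directory: str | Path) -> Path:
        """Serialize a provenance copy next to the outputs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = directory / "run_config.yaml"
        with open(out, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return out

    def digest(self) -> str:
        """Stable hash of the configuration, for manifests and logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
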