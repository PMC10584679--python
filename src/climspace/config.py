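"""Run configuration: defaults, strict validation, YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Every pipeline option with its default.

    Unknown keys are rejected at load time so a misspelled option fails
    before any computation.  The resolved config is written alongside the
    outputs of every run.
    """

    mode: str = "synthetic"  # synthetic | real
    output_dir: str = "climspace_out"

    # real-mode inputs
    grid_csv: str | None = None
    variable_csvs: list = field(default_factory=list)
    pam_csv: str | None = None

    # synthetic world
    n_lat_bands: int = 24
    n_lon: int = 48
    land_fraction: float = 0.7
    temp_gradient: float = 0.45
    grf_length_scale: float = 2000.0
    grf_sd: float = 3.0
    n_variables: int = 12
    n_species: int = 200
    niche_breadth: float = 1.5
    seed: int = 0

    # climate space
    resolutions: list = field(default_factory=lambda: [20])
    log_vars: list = field(default_factory=list)
    raw_axes: list | None = None  # e.g. ["temp_mean", "prec_annual"] bypasses PCA

    # geography
    adjacency: str = "queen"
    wrap: bool = True

    # diversity
    beta_resample_sites: int | None = None
    beta_n_resamples: int = 100

    # model
    k: int = 4
    log_area: bool = True
    drop_zero_richness: bool = True
    residual_kind: str = "deviance"

    # diagnostics
    n_distance_classes: int = 10
    n_permutations: int = 999
    envelope_taus: list = field(default_factory=lambda: [0.05, 0.95])

    def __post_init__(self):
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be synthetic or real, got {self.mode!r}")
        if self.adjacency not in ("queen", "rook"):
            raise ValueError("adjacency must be queen or rook")
        for r in self.resolutions:
            if not (1 <= r <= 200):
                raise ValueError(f"resolution {r} out of range")
        if self.mode == "real" and not (self.grid_csv or self.variable_csvs):
            raise ValueError("real mode needs grid_csv or variable_csvs")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
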