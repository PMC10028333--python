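"""Run configuration: validated parameter sets and sweep fixtures.

The default configuration is the reference operating point of the
model (alpha = 0.5, tau = 1, phi_hnf = 0.02 split equally, Pr = 21,
Re = 1.2, Gr = 4, G = 2, lambda = 3, beta = 1.2).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .solution import SolutionConfig
from .thermophysics import (DEFAULT_MATERIALS, MixtureState, ModelParameters,
                            assemble_mixture, dimensionless_groups)

__all__ = ["RunConfig", "load_config", "dump_config", "generate_sweep_fixtures"]


@dataclass(frozen=True)
class RunConfig:
    """Fully validated inputs for a profile / table run."""

    alpha: float = 0.5
    casson: float = 1.2
    lam: float = 3.0
    pressure: float = 2.0
    gr: float = 4.0
    pr: float = 21.0
    re: float = 1.2
    phi1: float = 0.02 / 3
    phi2: float = 0.02 / 3
    phi3: float = 0.02 / 3
    taus: tuple = (1.0,)
    xi_points: int = 41
    n_modes: int = 500
    series_tol: float = 1e-9
    out_dir: str = "ternaflow_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1]")
        if self.casson <= 0:
            raise ValueError("casson parameter must be > 0")
        if self.lam < 0:
            raise ValueError("couple-stress parameter must be >= 0")
        if any(p < 0 for p in (self.phi1, self.phi2, self.phi3)):
            raise ValueError("volume fractions must be >= 0")
        if self.phi1 + self.phi2 + self.phi3 >= 1:
            raise ValueError("total volume fraction must be < 1")
        if any(t <= 0 for t in self.taus):
            raise ValueError("all tau values must be positive")
        if self.xi_points < 2:
            raise ValueError("xi_points must be >= 2")
        if self.n_modes < 1 or self.series_tol <= 0:
            raise ValueError("n_modes >= 1 and series_tol > 0 required")
        object.__setattr__(self, "taus", tuple(float(t) for t in self.taus))

    def build(self, materials=DEFAULT_MATERIALS,
              ) -> tuple[MixtureState, ModelParameters, SolutionConfig]:
        mix = assemble_mixture(self.phi1, self.phi2, self.phi3, materials)
        params = dimensionless_groups(
            mix, alpha=self.alpha, beta_casson=self.casson, lam=self.lam,
            G=self.pressure, Gr=self.gr, Pr=self.pr, Re=self.re)
        sol = SolutionConfig(n_modes=self.n_modes, series_tol=self.series_tol)
        return mix, params, sol


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected with the offending names listed.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "taus" in data:
        data["taus"] = tuple(data["taus"])
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back as normalized YAML."""
    data = asdict(cfg)
    data["taus"] = list(data["taus"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# Sweeps mirroring the model's reference operating points.
_SWEEPS = {
    "alpha": (0.3, 0.5, 0.7, 0.9),
    "phi": (0.0, 0.01, 0.02, 0.03, 0.04),
    "re": (1.2, 1.5, 2.0),
    "pr": (21.0, 22.0, 25.0),
    "gr": (2.0, 4.0, 6.0),
    "pressure": (0.0, 2.0, 4.0),
    "lam": (1.0, 3.0, 5.0),
    "casson": (0.6, 1.2, 2.4),
}


def generate_sweep_fixtures(base: RunConfig, out_dir: str | Path) -> list[Path]:
    """Write one config file per swept parameter value (deterministic).

    Returns the written paths; file contents are byte-reproducible for
    a fixed base configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, values in _SWEEPS.items():
        for v in values:
            if name == "phi":
                cfg = replace(base, phi1=v / 3, phi2=v / 3, phi3=v / 3)
            else:
                cfg = replace(base, **{name: v})
            path = out / f"sweep_{name}_{v:g}.yaml"
            dump_config(cfg, path)
            written.append(path)
    index = {p.name: p.stat().st_size for p in written}
    with open(out / "index.json", "w") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)
    return written
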