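"""Run configuration: YAML-backed, validated, deterministic.

The config mirrors the published defaults: blood viscosity 0.004 Pa·s,
glucose/lactate diffusivities 5.46e−4 / 7.71e−4 cm²/min, characteristic
element length 11.5 ± 2.5 µm, tissue sleeve d_t = 12.4 µm and the
transporter/enzyme kinetics of the minimal beta-cell model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .coupling import DEFAULT_KINETICS
from .discretize import DEFAULT_CL, DEFAULT_DELTA, DEFAULT_DT
from .flow import DEFAULT_MU, DEFAULT_RHO
from .transport import GLUCOSE_D_CM2_MIN, LACTATE_D_CM2_MIN


@dataclass
class RunConfig:
    network: str = ""
    output: str = "out"
    # physics
    mu: float = DEFAULT_MU                 # Pa·s
    rho: float = DEFAULT_RHO               # kg/m³
    velocity_convention: str = "mean"
    # mesh
    c_l: float = DEFAULT_CL                # µm
    delta: float = DEFAULT_DELTA           # µm
    d_t: float = DEFAULT_DT                # µm
    # species: name -> {diffusivity_cm2_min, inlet_mM (optional),
    #                   initial_mM (optional)}
    species: dict = field(default_factory=lambda: {
        "glucose": {"diffusivity_cm2_min": GLUCOSE_D_CM2_MIN, "inlet_mM": 5.0},
        "lactate": {"diffusivity_cm2_min": LACTATE_D_CM2_MIN, "inlet_mM": 1.2},
    })
    # coupling
    coupled: bool = False
    kinetics: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_KINETICS.items()})
    cell_initial: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.0})
    # solver
    rtol: float = 1e-3
    atol: float = 1e-6
    t_span: tuple = (0.0, 15.0)            # seconds
    n_out: int = 200
    t_ramp: float = 0.1                    # seconds
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.rtol <= 0 or self.atol <= 0:
            problems.append("tolerances must be positive")
        if self.c_l <= 0 or self.delta < 0 or self.delta >= self.c_l:
            problems.append("need c_l > 0 and 0 <= delta < c_l")
        if self.mu <= 0 or self.rho <= 0:
            problems.append("mu and rho must be positive")
        if self.d_t < 0:
            problems.append("d_t must be nonnegative")
        if self.velocity_convention not in ("mean", "centerline"):
            problems.append(f"unknown velocity_convention "
                            f"{self.velocity_convention!r}")
        if not (len(self.t_span) == 2 and self.t_span[1] > self.t_span[0]):
            problems.append("t_span must be (t0, t1) with t1 > t0")
        for name, blk in self.species.items():
            if blk.get("diffusivity_cm2_min", 0) <= 0:
                problems.append(f"species {name!r}: diffusivity must be "
                                "positive")
        if self.network and not Path(self.network).exists():
            problems.append(f"network path {self.network!r} does not exist")
        return problems

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "t_span" in raw:
            raw["t_span"] = tuple(raw["t_span"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["t_span"] = list(d["t_span"])
        return d

    def digest(self) -> str:
        """Stable content hash for the run manifest."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
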