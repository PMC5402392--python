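"""Run configuration: sequence protocols, single-point constraints, phantom
spec, and YAML round-tripping.

The default protocol set reproduces a fast whole-brain mouse MPF mapping
session at 11.7 T: an MT-weighted SPGR with a 900-degree, 10 ms Gaussian
saturation pulse at +4.5 kHz, a T1-/PD-weighted VFA pair, a dual-TE GRE pair
for B0, and a dual-TR AFI acquisition for B1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mpf_reconstruction import SinglePointConstraints
from .mt_physics import MTPulse, SPGRProtocol

__all__ = ["default_protocols", "RunConfig", "load_config", "save_config"]


def default_protocols() -> dict[str, SPGRProtocol]:
    """Protocol bundle for the five acquisitions (times in s, angles deg)."""
    return {
        "mt_w": SPGRProtocol(TR=0.022, flip=9.0, TEs=(0.0025,),
                             mt_pulse=MTPulse(shape="gaussian", duration=0.010,
                                              effective_flip=900.0,
                                              offset=4500.0),
                             label="mt_w"),
        "t1_w": SPGRProtocol(TR=0.016, flip=16.0, TEs=(0.0025,), label="t1_w"),
        "pd_w": SPGRProtocol(TR=0.016, flip=3.0, TEs=(0.0025,), label="pd_w"),
        "b0": SPGRProtocol(TR=0.020, flip=8.0, TEs=(0.0024, 0.0041),
                           label="b0"),
        "afi": SPGRProtocol(TR=0.013, flip=60.0, TEs=(0.0037,), label="afi"),
    }

#: AFI long repetition time (s); the short one is the protocol TR.
AFI_TR2 = 0.065


def _protocol_to_dict(p: SPGRProtocol) -> dict:
    d = {"TR": p.TR, "flip": p.flip, "TEs": list(p.TEs), "label": p.label}
    if p.mt_pulse is not None:
        d["mt_pulse"] = dataclasses.asdict(p.mt_pulse)
    return d


def _protocol_from_dict(d: dict) -> SPGRProtocol:
    pulse = d.get("mt_pulse")
    return SPGRProtocol(TR=d["TR"], flip=d["flip"], TEs=tuple(d.get("TEs", ())),
                        mt_pulse=MTPulse(**pulse) if pulse else None,
                        label=d.get("label", ""))


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    protocols: dict = field(default_factory=default_protocols)
    constraints: SinglePointConstraints = field(
        default_factory=SinglePointConstraints)
    afi_tr2: float = AFI_TR2
    phantom_spec: str | None = None  # path to a phantom YAML, if any
    seed: int = 0
    noise_sigma_fraction: float = 0.01  # Rician sigma / WM MT-w signal
    out_dir: str = "out"
    log_level: str = "info"

    def to_dict(self) -> dict:
        return {
            "protocols": {k: _protocol_to_dict(v)
                          for k, v in self.protocols.items()},
            "constraints": {
                "R": self.constraints.R,
                "T2B_us": self.constraints.T2B * 1e6,
                "T2F_R1F": self.constraints.T2F_R1F_product,
                "R1B": self.constraints.R1B,
            },
            "afi_tr2": self.afi_tr2,
            "phantom_spec": self.phantom_spec,
            "seed": self.seed,
            "noise_sigma_fraction": self.noise_sigma_fraction,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        if "protocols" in d:
            cfg.protocols = {k: _protocol_from_dict(v)
                             for k, v in d["protocols"].items()}
        if "constraints" in d:
            c = d["constraints"]
            cfg.constraints = SinglePointConstraints(
                R=c.get("R", 19.0), T2B=c.get("T2B_us", 10.0) * 1e-6,
                T2F_R1F_product=c.get("T2F_R1F", 0.022),
                R1B=c.get("R1B", 1.0))
        for key in ("afi_tr2", "phantom_spec", "seed",
                    "noise_sigma_fraction", "out_dir", "log_level"):
            if key in d:
                setattr(cfg, key, d[key])
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
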