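"""Scenario configuration files.

INI-style key/value files with sections [arm], [noise], [cost], [task] and
[sim].  All physical quantities are SI; angles are given in degrees in the
file and converted to radians internally.  Missing keys fall back to the
package defaults (the reference reaching task: 7.4 cm N-W reach from
q = (50, 100) deg with sigma = 0.005, d = 0.01, r = 2000, alpha = 0.02).
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np

from .arm import ArmParams, NoiseParams
from .planner import OCPSpec, make_task

__all__ = ["default_config", "load_config", "build_spec", "write_config"]


def default_config() -> dict:
    p = ArmParams()
    return {
        "arm": {"I1": p.I1, "I2": p.I2, "M1": p.M1, "M2": p.M2,
                "L1": p.L1, "L2": p.L2, "Lg1": p.Lg1, "Lg2": p.Lg2,
                "B11": float(p.B[0, 0]), "B12": float(p.B[0, 1]),
                "B22": float(p.B[1, 1])},
        "noise": {"sigma": 0.005, "d": 0.01, "beta": 0.003, "delay": 0.0},
        "cost": {"r": 2000.0, "alpha": 0.02, "rho": 1000.0},
        "task": {"q1_deg": 50.0, "q2_deg": 100.0,
                 "direction_deg": 135.0, "distance": 0.074},
        "sim": {"dt": 0.005, "n_trials": 1000, "seed": 0,
                "n_controls": 21, "n_steps": 100},
    }


def load_config(path: str | Path | None) -> dict:
    """Read a scenario file, overlaying the package defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FileNotFoundError(path)
    for section in parser.sections():
        if section not in cfg:
            raise ValueError(f"unknown config section [{section}]")
        for key, value in parser[section].items():
            # configparser lowercases keys; match case-insensitively
            canon = {k.lower(): k for k in cfg[section]}
            if key.lower() not in canon:
                raise ValueError(f"unknown key '{key}' in section [{section}]")
            cfg[section][canon[key.lower()]] = float(value)
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    parser = configparser.ConfigParser()
    for section, entries in cfg.items():
        parser[section] = {k: repr(float(v)) for k, v in entries.items()}
    with open(path, "w") as fh:
        parser.write(fh)


def build_spec(cfg: dict) -> OCPSpec:
    """Construct the planning problem described by a configuration dict."""
    a = cfg["arm"]
    params = ArmParams(
        I1=a["I1"], I2=a["I2"], M1=a["M1"], M2=a["M2"],
        L1=a["L1"], L2=a["L2"], Lg1=a["Lg1"], Lg2=a["Lg2"],
        B=np.array([[a["B11"], a["B12"]], [a["B12"], a["B22"]]]),
    )
    n = cfg["noise"]
    noise = NoiseParams.symmetric(sigma=n["sigma"], d=n["d"],
                                  beta=n["beta"], delay=n["delay"])
    t = cfg["task"]
    x0, target = make_task([t["q1_deg"], t["q2_deg"]],
                           t["direction_deg"], t["distance"], params)
    s = cfg["sim"]
    return OCPSpec(x0=x0, target=target, r=cfg["cost"]["r"],
                   alpha=cfg["cost"]["alpha"], params=params, noise=noise,
                   n_controls=int(s["n_controls"]), n_steps=int(s["n_steps"]))
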