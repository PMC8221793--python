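"""Text serialization of plans, controllers and trial ensembles.

Plans are stored as a JSON header (parameters, costs, solver status) plus a
tab-separated node table (one row per node: t, u, m, upper-triangular P);
controllers as JSON; ensembles as one columnar file per condition plus a
JSON summary.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .arm import ArmParams, NoiseParams
from ._codegen import vech, unvech, VECH_IDX
from .planner import OCPSpec, FeedforwardPlan
from .lqg import DiscreteSystem, LQGController
from .simulate import TrialEnsemble, endpoint_statistics

__all__ = [
    "save_plan", "load_plan",
    "save_controller", "load_controller",
    "save_ensemble",
]


def _base(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in (".json", ".tsv") else p


def save_plan(plan: FeedforwardPlan, path: str | Path) -> Path:
    """Write ``<base>.json`` (header) and ``<base>.tsv`` (node table)."""
    base = _base(path)
    spec = plan.spec
    header = {
        "T": plan.T,
        "cost_total": plan.cost_total,
        "cost_terms": plan.cost_terms,
        "status": plan.status,
        "target": spec.target.tolist(),
        "x0": spec.x0.tolist(),
        "r": spec.r,
        "alpha": spec.alpha,
        "n_controls": spec.n_controls,
        "n_steps": spec.n_steps,
        "u_nodes": np.asarray(plan.u_nodes).tolist(),
        "arm": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(spec.params).items()},
        "noise": asdict(spec.noise),
    }
    base.parent.mkdir(parents=True, exist_ok=True)
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    cols = {"t": plan.t, "u1": plan.u[:, 0], "u2": plan.u[:, 1]}
    for i in range(6):
        cols[f"m{i + 1}"] = plan.m[:, i]
    V = vech(plan.P)
    for k, (i, j) in enumerate(VECH_IDX):
        cols[f"P{i + 1}{j + 1}"] = V[:, k]
    pd.DataFrame(cols).to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    return base


def load_plan(path: str | Path) -> FeedforwardPlan:
    base = _base(path)
    header = json.loads(base.with_suffix(".json").read_text())
    df = pd.read_csv(base.with_suffix(".tsv"), sep="\t")
    arm_kw = dict(header["arm"])
    arm_kw["B"] = np.asarray(arm_kw["B"])
    spec = OCPSpec(
        x0=np.asarray(header["x0"]), target=np.asarray(header["target"]),
        r=header["r"], alpha=header["alpha"],
        params=ArmParams(**arm_kw), noise=NoiseParams(**header["noise"]),
        n_controls=header["n_controls"], n_steps=header["n_steps"],
    )
    m = df[[f"m{i + 1}" for i in range(6)]].to_numpy()
    V = df[[f"P{i + 1}{j + 1}" for (i, j) in VECH_IDX]].to_numpy()
    return FeedforwardPlan(
        t=df["t"].to_numpy(), u=df[["u1", "u2"]].to_numpy(), m=m,
        P=unvech(V), T=header["T"],
        u_nodes=np.asarray(header["u_nodes"]),
        cost_total=header["cost_total"], cost_terms=header["cost_terms"],
        spec=spec, status=header["status"],
    )


def save_controller(ctl: LQGController, path: str | Path) -> Path:
    base = _base(path)
    sys = ctl.sys
    payload = {
        "rho": ctl.rho, "beta": ctl.beta,
        "dt": sys.dt, "T": sys.T, "T_prime": sys.T_prime,
        "delay_steps": sys.delay_steps,
        "K": ctl.K.tolist(), "L": ctl.L.tolist(),
        "Phi": sys.Phi.tolist(), "Bd": sys.Bd.tolist(), "W": sys.W.tolist(),
        "C": sys.C.tolist(), "V": sys.V.tolist(),
    }
    base.parent.mkdir(parents=True, exist_ok=True)
    out = base.with_suffix(".json")
    out.write_text(json.dumps(payload))
    return out


def load_controller(path: str | Path) -> LQGController:
    base = _base(path)
    d = json.loads(base.with_suffix(".json").read_text())
    N = len(d["Phi"])
    sys = DiscreteSystem(
        t=np.arange(N + 1) * d["dt"],
        Phi=np.asarray(d["Phi"]), Bd=np.asarray(d["Bd"]),
        W=np.asarray(d["W"]), C=np.asarray(d["C"]), V=np.asarray(d["V"]),
        dt=d["dt"], T=d["T"], T_prime=d["T_prime"],
        delay_steps=d["delay_steps"],
    )
    return LQGController(sys=sys, K=np.asarray(d["K"]), L=np.asarray(d["L"]),
                         rho=d["rho"], beta=d["beta"])


def save_ensemble(ens: TrialEnsemble, path: str | Path,
                  store_trajectories: bool = True) -> Path:
    """Write ``<base>.tsv`` (trial, t, q1, q2, hand_x, hand_y, speed) and a
    JSON summary with endpoint statistics and metadata."""
    base = _base(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    st = endpoint_statistics(ens) if ens.n_trials >= 3 else None
    summary = {
        "meta": {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in ens.meta.items()},
        "n_trials": ens.n_trials,
        "mean_duration": float(ens.durations.mean()),
        "mean_peak_speed_cm_s": float(ens.peak_speed.mean() * 100),
        "n_truncated": int(ens.truncated.sum()),
        "n_no_movement": int(ens.no_movement.sum()),
        "endpoints": ens.endpoints.tolist(),
    }
    if st is not None:
        summary["log_endpoint_variance"] = st.log_variance
        summary["endpoint_cov_mm2"] = (st.cov * 1e6).tolist()
        summary["ellipse_axes_mm"] = (st.ellipse_axes * 1e3).tolist()
        summary["ellipse_angle_rad"] = st.ellipse_angle
    base.with_suffix(".json").write_text(json.dumps(summary, indent=1))
    if store_trajectories:
        n, N1 = ens.x.shape[:2]
        df = pd.DataFrame({
            "trial": np.repeat(np.arange(n), N1),
            "t": np.tile(ens.t, n),
            "q1": ens.x[..., 0].ravel(),
            "q2": ens.x[..., 1].ravel(),
            "hand_x": ens.hand[..., 0].ravel(),
            "hand_y": ens.hand[..., 1].ravel(),
            "speed": ens.speed.ravel(),
        })
        df.to_csv(base.with_suffix(".tsv"), sep="\t", index=False,
                  float_format="%.6g")
    return base
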