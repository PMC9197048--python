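"""HDF5 session container and model configuration files.

Layout of a session file:

    /lfp/c<k>            trials x samples dataset, attrs: condition, fs, t0_index
    /spikes/u<j>/c<k>/t<i>   1-D spike-time datasets (s, onset-relative)
    /meta                attrs: fs, t0_index, trial_span, conditions, units
    /truth               attrs: ground-truth JSON string

Model specs load from flat YAML/JSON mappings mirroring the parameter names
(wee, wei, wie, wii or the base/lateral gains, mE, mI, thetaE, thetaI,
tauE, tauI).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .model import ConnectionGains, ModelSpec, PopulationParams, TimeConstants
from .spectral import TrialSet
from .spikes import SpikeSet
from .synth import Session, SessionConfig, SessionGroundTruth

__all__ = ["save_session", "load_session", "spec_from_dict", "load_model_spec"]


def spec_from_dict(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from a flat key-value mapping.

    Effective weights may be given directly (wee, wei, wie, wii -> base
    gains with zero lateral part) or split (Wee/WeELR etc.).  Missing keys
    fall back to the default parameter set.
    """
    d = ModelSpec.default()
    gains = {}
    for eff, (base, lat) in (("wee", ("Wee", "WeELR")), ("wei", ("Wei", "WeILR")),
                             ("wie", ("Wie", "WiELR")), ("wii", ("Wii", "WiILR"))):
        if eff in cfg and (base in cfg or lat in cfg):
            raise ValueError(f"give either {eff} or its base/lateral split, not both")
        gains[base] = float(cfg.get(base, cfg.get(eff, getattr(d.gains, base))))
        gains[lat] = float(cfg.get(lat, getattr(d.gains, lat)))
    return ModelSpec(
        e_params=PopulationParams(
            gain=float(cfg.get("mE", d.e_params.gain)),
            threshold=float(cfg.get("thetaE", d.e_params.threshold)),
        ),
        i_params=PopulationParams(
            gain=float(cfg.get("mI", d.i_params.gain)),
            threshold=float(cfg.get("thetaI", d.i_params.threshold)),
        ),
        gains=ConnectionGains(**gains),
        taus=TimeConstants(
            tau_e=float(cfg.get("tauE", d.taus.tau_e)),
            tau_i=float(cfg.get("tauI", d.taus.tau_i)),
        ),
    )


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load a model configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return spec_from_dict(cfg)


def _truth_to_json(truth: SessionGroundTruth) -> str:
    def keyed(d):
        return {repr(k): v for k, v in d.items()}

    return json.dumps(
        {
            "gamma_amplitude": keyed(truth.gamma_amplitude),
            "gamma_frequency": keyed(truth.gamma_frequency),
            "unit_stim_rates": {repr(u): keyed(v) for u, v in truth.unit_stim_rates.items()},
            "attenuation_deg": truth.attenuation_deg,
            "rf": truth.rf,
        }
    )


def save_session(session: Session, path: str | Path) -> None:
    """Write a session (LFP trials, spikes, ground truth) to HDF5."""
    conds = list(session.lfp)
    units = session.spikes.units
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        first = next(iter(session.lfp.values()))
        meta.attrs["fs"] = first.fs
        meta.attrs["t0_index"] = first.t0_index
        meta.attrs["trial_span"] = session.spikes.trial_span
        meta.attrs["conditions"] = [float(c) for c in conds]
        meta.attrs["n_units"] = len(units)
        meta.attrs["config"] = json.dumps(
            {k: v for k, v in vars(session.config).items()}, default=list
        )
        g = f.create_group("lfp")
        for k, c in enumerate(conds):
            ds = g.create_dataset(f"c{k}", data=session.lfp[c].lfp, compression="gzip")
            ds.attrs["condition"] = float(c)
        s = f.create_group("spikes")
        for j, u in enumerate(units):
            gu = s.create_group(f"u{j}")
            for k, c in enumerate(conds):
                gc = gu.create_group(f"c{k}")
                for i, t in enumerate(session.spikes.trains[u][c]):
                    gc.create_dataset(f"t{i}", data=np.asarray(t, dtype=float))
        f.create_group("truth").attrs["json"] = _truth_to_json(session.truth)


def load_session(path: str | Path) -> Session:
    """Read a session container written by :func:`save_session`."""
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        fs = float(meta["fs"])
        t0 = int(meta["t0_index"])
        span = tuple(float(v) for v in meta["trial_span"])
        conds = [float(c) for c in meta["conditions"]]
        cfg_raw = json.loads(meta["config"])
        cfg_raw["discontinuity_levels"] = tuple(cfg_raw["discontinuity_levels"])
        cfg_raw["stim_span"] = tuple(cfg_raw["stim_span"])
        cfg = SessionConfig(**cfg_raw)
        lfp = {}
        for k, c in enumerate(conds):
            lfp[c] = TrialSet(lfp=f["lfp"][f"c{k}"][()], fs=fs, t0_index=t0, condition=c)
        trains: dict = {}
        for j in range(int(meta["n_units"])):
            gu = f["spikes"][f"u{j}"]
            trains[j] = {}
            for k, c in enumerate(conds):
                gc = gu[f"c{k}"]
                trains[j][c] = [gc[f"t{i}"][()] for i in range(len(gc))]
        spikes = SpikeSet(trains=trains, trial_span=span)
        tr = json.loads(f["truth"].attrs["json"])

    def unkey(d):
        return {float(k): v for k, v in d.items()}

    truth = SessionGroundTruth(
        gamma_amplitude=unkey(tr["gamma_amplitude"]),
        gamma_frequency=unkey(tr["gamma_frequency"]),
        unit_stim_rates={int(u): unkey(v) for u, v in tr["unit_stim_rates"].items()},
        attenuation_deg=tr["attenuation_deg"],
        rf=tr["rf"],
    )
    return Session(lfp=lfp, spikes=spikes, truth=truth, config=cfg)
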