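"""Serialization: trial datasets (HDF5 + JSON sidecar), models (JSON), and a
generic binned-spike-count loader for externally recorded data."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .model import (
    EmissionMap,
    InitialState,
    LinearMode,
    PWLModel,
    RecurrentTransition,
    Trial,
)
from .synthetic import TrialSet

__all__ = [
    "write_trialset",
    "read_trialset",
    "save_model",
    "load_model",
    "load_binned_spikes",
]

_CHOICE_UNSET = -1


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_trialset(trialset: TrialSet, path) -> Path:
    """Write a TrialSet to an HDF5 container plus a JSON provenance sidecar.

    Layout: ``/trials/<i>/{latents,modes,observations}`` with per-trial
    attributes ``choice`` (-1 when unset) and ``split``, and file attributes
    ``family`` and ``seed``.  Arrays round-trip bit-exactly; Poisson counts
    are stored with an integer dtype.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["family"] = trialset.family
        f.attrs["seed"] = _CHOICE_UNSET if trialset.seed is None else int(trialset.seed)
        f.attrs["n_trials"] = len(trialset)
        grp = f.create_group("trials")
        for i, trial in enumerate(trialset):
            g = grp.create_group(str(i))
            obs = trial.observations
            if trialset.family == "poisson":
                obs = np.asarray(obs)
                if obs.dtype.kind not in "iu":
                    if not np.allclose(obs, np.round(obs)):
                        raise ValueError("poisson observations must be integer counts")
                    obs = obs.astype(np.int64)
            g.create_dataset("observations", data=obs)
            if trial.latents is not None:
                g.create_dataset("latents", data=trial.latents)
            if trial.modes is not None:
                g.create_dataset("modes", data=trial.modes.astype(np.int64))
            g.attrs["choice"] = _CHOICE_UNSET if trial.choice is None else int(trial.choice)
            g.attrs["split"] = trial.split or ""
    sidecar = {
        "family": trialset.family,
        "seed": trialset.seed,
        "n_trials": len(trialset),
        "ground_truth_spec": trialset.ground_truth_spec,
        "emission_calibration": trialset.emission_calibration,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_trialset(path) -> TrialSet:
    """Read and validate a TrialSet written by :func:`write_trialset`.

    Validation errors name the offending trial: negative Poisson counts,
    mismatched array lengths within a trial, or missing groups/attributes.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "family" not in f.attrs:
            raise ValueError("missing file attribute 'family'")
        family = str(f.attrs["family"])
        seed = int(f.attrs["seed"])
        if "trials" not in f:
            raise ValueError("missing group '/trials'")
        grp = f["trials"]
        trials = []
        for i in range(len(grp)):
            key = str(i)
            if key not in grp:
                raise ValueError(f"missing group '/trials/{key}'")
            g = grp[key]
            if "observations" not in g:
                raise ValueError(f"trial {i}: missing dataset 'observations'")
            obs = g["observations"][()]
            if family == "poisson":
                bad = np.argwhere(obs < 0)
                if bad.size:
                    t, n = bad[0]
                    raise ValueError(
                        f"trial {i}: negative count at bin {t}, unit {n}")
            latents = g["latents"][()] if "latents" in g else None
            modes = g["modes"][()] if "modes" in g else None
            T = obs.shape[0]
            for name, arr in (("latents", latents), ("modes", modes)):
                if arr is not None and arr.shape[0] != T:
                    raise ValueError(
                        f"trial {i}: '{name}' length {arr.shape[0]} != "
                        f"observations length {T}")
            choice = int(g.attrs.get("choice", _CHOICE_UNSET))
            split = str(g.attrs.get("split", "")) or None
            trials.append(Trial(observations=obs, latents=latents, modes=modes,
                                choice=None if choice == _CHOICE_UNSET else choice,
                                split=split))
    gt_spec = cal = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        gt_spec = meta.get("ground_truth_spec")
        cal = meta.get("emission_calibration")
    return TrialSet(trials, family, seed=None if seed == _CHOICE_UNSET else seed,
                    ground_truth_spec=gt_spec, emission_calibration=cal)


# --------------------------------------------------------------------------
# model serialization (JSON; floats round-trip exactly in binary64)
# --------------------------------------------------------------------------

def _arr(a):
    return None if a is None else np.asarray(a).tolist()


def save_model(model: PWLModel, path) -> Path:
    doc = {
        "format": "pwlds-model",
        "K": model.K,
        "H": model.H,
        "family": model.family,
        "modes": [{"A": _arr(m.A), "b": _arr(m.b), "Q": _arr(m.Q)}
                  for m in model.modes],
        "transition": None if model.transition is None else {
            "R": _arr(model.transition.R),
            "r": _arr(model.transition.r),
            "stick_order": _arr(model.transition.stick_order),
            "hard": bool(model.transition.hard),
        },
        "emission": {"C": _arr(model.emission.C), "d": _arr(model.emission.d),
                     "S": _arr(model.emission.S)},
        "initial": {"mean": _arr(model.initial.mean),
                    "cov": _arr(model.initial.cov),
                    "mode_probs": _arr(model.initial.mode_probs)},
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_model(path) -> PWLModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "pwlds-model":
        raise ValueError(f"{path} is not a serialized model")
    modes = [LinearMode(np.array(m["A"]), np.array(m["b"]), np.array(m["Q"]))
             for m in doc["modes"]]
    trans = None
    if doc["transition"] is not None:
        td = doc["transition"]
        trans = RecurrentTransition(np.array(td["R"]), np.array(td["r"]),
                                    np.array(td["stick_order"]), td["hard"])
    ed = doc["emission"]
    S = None if ed["S"] is None else np.array(ed["S"])
    emission = EmissionMap(np.array(ed["C"]), np.array(ed["d"]),
                           doc["family"], S)
    idoc = doc["initial"]
    initial = InitialState(np.array(idoc["mean"]), np.array(idoc["cov"]),
                           np.array(idoc["mode_probs"]))
    return PWLModel(modes, trans, emission, initial)


# --------------------------------------------------------------------------
# generic binned spike-count loader
# --------------------------------------------------------------------------

def load_binned_spikes(path, bin_width_ms: Optional[float] = None) -> TrialSet:
    """Load externally binned spike counts as a Poisson TrialSet.

    Accepted layouts (HDF5): a single dataset ``/counts`` of shape
    (n_trials, T, n_units), or per-trial datasets ``/trials/<i>/counts``
    (ragged lengths allowed).  Counts must be non-negative integers.
    Optional metadata: file attribute ``bin_width_ms``; optional per-trial or
    top-level dataset ``choices`` (1/2, -1 for unset).  No dataset-specific
    parsing is attempted here — binning and unit selection are the caller's
    responsibility.
    """
    path = Path(path)
    trials = []
    with h5py.File(path, "r") as f:
        if bin_width_ms is None and "bin_width_ms" in f.attrs:
            bin_width_ms = float(f.attrs["bin_width_ms"])
        choices = f["choices"][()] if "choices" in f else None
        if "counts" in f:
            counts = f["counts"][()]
            if counts.ndim != 3:
                raise ValueError("'/counts' must be (n_trials, T, n_units)")
            blocks = list(counts)
        elif "trials" in f:
            grp = f["trials"]
            blocks = [grp[str(i)]["counts"][()] for i in range(len(grp))]
        else:
            raise ValueError("expected '/counts' or '/trials/<i>/counts'")
        for i, c in enumerate(blocks):
            c = np.asarray(c)
            if c.dtype.kind not in "iu":
                if not np.allclose(c, np.round(c)):
                    raise ValueError(f"trial {i}: non-integer spike counts")
                c = c.astype(np.int64)
            if np.any(c < 0):
                raise ValueError(f"trial {i}: negative spike counts")
            choice = None
            if choices is not None and int(choices[i]) in (1, 2):
                choice = int(choices[i])
            trials.append(Trial(observations=c, choice=choice))
    ts = TrialSet(trials, "poisson")
    ts.bin_width_ms = bin_width_ms
    return ts
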