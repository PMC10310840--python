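"""HDF5 container for experiments plus CSV export helpers.

Layout (schema version 1)::

    /                       attrs: schema_version, subject_id
    /neurons                columnar datasets: neuron_id, plane, x, y,
                            redness, red_pixel_fraction, opsin_class
    /sessions/day_<DDD>     attrs: session_day, frame_rate, task_stage
        dff                 float64 neurons x frames
        neuron_ids          utf-8 strings
        trials/<field>      columnar trial datasets (pulse_count,
                            pulse_bins, rewarded_side, choice, outcome,
                            first_lick_time, shutter_close_frame,
                            shutter_open_frame)
    /ground_truth           optional latent quantities from the generator

Round trips are lossless: integers/strings bit-exact, floats at full
precision (float64 throughout).
"""

from __future__ import annotations

from typing import Dict, List

import h5py
import numpy as np

from .datamodel import Experiment, NeuronMeta, SessionRecording, TrialRecord

SCHEMA_VERSION = 1

_STR = h5py.string_dtype(encoding="utf-8")


class ExperimentFormatError(IOError):
    """Raised when an experiment file is missing required content."""


def save_experiment(exp: Experiment, path: str, ground_truth=None) -> None:
    """Write an :class:`Experiment` (and optional generator ground truth)."""
    exp.validate()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subject_id"] = exp.subject_id
        ng = f.create_group("neurons")
        ids = list(exp.neurons.keys())
        ng.create_dataset("neuron_id", data=np.array(ids, dtype=object), dtype=_STR)
        ng.create_dataset("plane", data=np.array([exp.neurons[i].plane for i in ids], dtype=np.int64))
        ng.create_dataset("x", data=np.array([exp.neurons[i].xy[0] for i in ids], dtype=np.float64))
        ng.create_dataset("y", data=np.array([exp.neurons[i].xy[1] for i in ids], dtype=np.float64))
        ng.create_dataset("redness", data=np.array([exp.neurons[i].redness for i in ids], dtype=np.float64))
        ng.create_dataset(
            "red_pixel_fraction",
            data=np.array([exp.neurons[i].red_pixel_fraction for i in ids], dtype=np.float64),
        )
        ng.create_dataset(
            "opsin_class",
            data=np.array([exp.neurons[i].opsin_class for i in ids], dtype=object),
            dtype=_STR,
        )
        sg = f.create_group("sessions")
        for s in exp.sessions:
            g = sg.create_group(f"day_{s.session_day:03d}")
            g.attrs["session_day"] = s.session_day
            g.attrs["frame_rate"] = s.frame_rate
            g.attrs["task_stage"] = s.task_stage
            g.create_dataset("dff", data=np.asarray(s.dff, dtype=np.float64))
            g.create_dataset("neuron_ids", data=np.array(s.neuron_ids, dtype=object), dtype=_STR)
            tg = g.create_group("trials")
            trs = s.trials
            tg.create_dataset("trial_index", data=np.array([t.trial_index for t in trs], dtype=np.int64))
            tg.create_dataset("pulse_count", data=np.array([t.pulse_count for t in trs], dtype=np.int64))
            tg.create_dataset(
                "pulse_bins",
                data=np.array([t.pulse_bins for t in trs], dtype=bool).reshape(len(trs), 9),
            )
            tg.create_dataset("rewarded_side", data=np.array([t.rewarded_side for t in trs], dtype=object), dtype=_STR)
            tg.create_dataset("choice", data=np.array([t.choice for t in trs], dtype=object), dtype=_STR)
            tg.create_dataset("outcome", data=np.array([t.outcome for t in trs], dtype=object), dtype=_STR)
            tg.create_dataset(
                "first_lick_time",
                data=np.array(
                    [np.nan if t.first_lick_time is None else t.first_lick_time for t in trs],
                    dtype=np.float64,
                ),
            )
            tg.create_dataset(
                "shutter_close_frame", data=np.array([t.shutter_close_frame for t in trs], dtype=np.int64)
            )
            tg.create_dataset(
                "shutter_open_frame", data=np.array([t.shutter_open_frame for t in trs], dtype=np.int64)
            )
        if ground_truth is not None:
            ground_truth.to_hdf5(f.create_group("ground_truth"))


def _require(group, name: str, context: str):
    if name not in group:
        raise ExperimentFormatError(f"missing required dataset or group '{name}' in {context}")
    return group[name]


def load_experiment(path: str) -> Experiment:
    """Read an :class:`Experiment` written by :func:`save_experiment`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ExperimentFormatError(
                f"schema_version mismatch: file has {version}, expected {SCHEMA_VERSION}"
            )
        neurons: Dict[str, NeuronMeta] = {}
        ng = _require(f, "neurons", "experiment root")
        ids = [x.decode() if isinstance(x, bytes) else str(x) for x in ng["neuron_id"][()]]
        planes = ng["plane"][()]
        xs, ys = ng["x"][()], ng["y"][()]
        reds = ng["redness"][()]
        fracs = ng["red_pixel_fraction"][()]
        classes = [x.decode() if isinstance(x, bytes) else str(x) for x in ng["opsin_class"][()]]
        for k, nid in enumerate(ids):
            neurons[nid] = NeuronMeta(
                neuron_id=nid,
                plane=int(planes[k]),
                xy=(float(xs[k]), float(ys[k])),
                redness=float(reds[k]),
                red_pixel_fraction=float(fracs[k]),
                opsin_class=classes[k],
            )
        sessions: List[SessionRecording] = []
        sg = _require(f, "sessions", "experiment root")
        for key in sorted(sg.keys()):
            g = sg[key]
            tg = _require(g, "trials", f"session {key}")
            n_trials = tg["pulse_count"].shape[0]
            flt = tg["first_lick_time"][()]
            trials = [
                TrialRecord(
                    trial_index=int(tg["trial_index"][t]),
                    pulse_count=int(tg["pulse_count"][t]),
                    pulse_bins=tg["pulse_bins"][t],
                    rewarded_side=tg["rewarded_side"][t].decode(),
                    choice=tg["choice"][t].decode(),
                    outcome=tg["outcome"][t].decode(),
                    first_lick_time=None if np.isnan(flt[t]) else float(flt[t]),
                    shutter_close_frame=int(tg["shutter_close_frame"][t]),
                    shutter_open_frame=int(tg["shutter_open_frame"][t]),
                )
                for t in range(n_trials)
            ]
            sessions.append(
                SessionRecording(
                    session_day=int(g.attrs["session_day"]),
                    dff=g["dff"][()],
                    frame_rate=float(g.attrs["frame_rate"]),
                    trials=trials,
                    neuron_ids=[x.decode() if isinstance(x, bytes) else str(x) for x in g["neuron_ids"][()]],
                    task_stage=str(g.attrs["task_stage"]),
                )
            )
        exp = Experiment(subject_id=str(f.attrs["subject_id"]), sessions=sessions, neurons=neurons)
    exp.validate()
    return exp


class DepositedDataAdapter:
    """Interface contract for reading the authors' deposited raw-data archive.

    The archive's internal layout is not documented; implementations must
    produce an :class:`Experiment` honouring this package's conventions:
    0-based half-open frame windows, 1-based ``session_day``, lick times in
    seconds from shutter closure, and per-neuron ids stable across days.
    """

    def load(self, path: str) -> Experiment:  # pragma: no cover - interface only
        raise NotImplementedError(
            "No adapter for the deposited archive is bundled; subclass "
            "DepositedDataAdapter and implement load() for its layout."
        )


def write_csv(df, path: str) -> None:
    """Write a summary table deterministically (fixed float repr, no index)."""
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
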