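"""Epoched multichannel container with HDF5 round-trip.

Layout on disk: ``/data`` (trials x channels x time), ``/time_ms``,
``/labels/<dimension>`` (per-trial past-magnitude labels, NaN where
undefined), and a ``meta`` JSON attribute on the root group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from serialdep.params import DIMENSIONS


@dataclass
class EpochSet:
    """Trials x channels x time epochs with per-trial past-magnitude labels.

    ``trial_meta`` holds one row per trial; columns ``past_<dimension>``
    carry the magnitude of the preceding (inducer) stimulus on that
    dimension, which downstream decoding binarizes into the two classes.
    """

    data: np.ndarray
    time_ms: np.ndarray
    sampling_rate: float
    trial_meta: pd.DataFrame
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis mismatch between data and time_ms")
        dt = np.diff(self.time_ms)
        if self.time_ms.size > 1 and not (np.all(dt > 0) and np.allclose(dt, dt[0])):
            raise ValueError("time_ms must be strictly increasing and uniform")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta length must equal the number of trials")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epochs contain missing samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def subset(self, idx) -> "EpochSet":
        """New EpochSet restricted to the given trial indices/boolean mask."""
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            time_ms=self.time_ms,
            sampling_rate=self.sampling_rate,
            trial_meta=self.trial_meta.iloc[idx].reset_index(drop=True),
            channel_labels=list(self.channel_labels),
        )

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time_ms", data=self.time_ms)
            g = f.create_group("labels")
            for dim in DIMENSIONS:
                col = f"past_{dim}"
                if col in self.trial_meta:
                    g.create_dataset(dim, data=self.trial_meta[col].to_numpy(dtype=float))
            meta = {
                "sampling_rate": self.sampling_rate,
                "channel_labels": self.channel_labels,
                "trial_meta": self.trial_meta.to_json(orient="split"),
            }
            f.attrs["meta"] = json.dumps(meta)

    @classmethod
    def load_h5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            trial_meta = pd.read_json(pd.io.common.StringIO(meta["trial_meta"]), orient="split")
            return cls(
                data=f["data"][()],
                time_ms=f["time_ms"][()],
                sampling_rate=meta["sampling_rate"],
                trial_meta=trial_meta,
                channel_labels=list(meta["channel_labels"]),
            )
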