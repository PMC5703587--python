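"""Containers and file IO for amplitude-series recordings and templates.

An *amplitude series* is the set of voltage traces recorded in response to a
single stimulating configuration at J increasing current amplitudes, with
n_j repeated trials at amplitude j.  Traces are stored per amplitude as
``(n_j, E, T)`` arrays (trials x electrodes x time samples); n_j may vary
across amplitudes.  Electrical images (EIs) — the spatiotemporal voltage
footprint of one neuron's spike over the array — are ``(E, T')`` templates.

On disk the primary container is HDF5 (``.h5``/``.hdf5``); ``.npz`` is
accepted as a fallback.  Arrays are stored float32 and promoted to float64
for computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "AmplitudeSeries",
    "ElectricalImages",
    "SchemaError",
    "read_traces",
    "write_traces",
    "read_eis",
    "write_eis",
]


class SchemaError(ValueError):
    """A container file is missing a required field or is inconsistent."""


@dataclass
class AmplitudeSeries:
    """Voltage traces for one stimulating configuration.

    Attributes
    ----------
    traces : list of (n_j, E, T) float arrays, one per amplitude, ascending.
    amplitudes : (J,) current amplitudes in uA, strictly increasing.
    sampling_rate_hz : sampling rate of the time axis.
    stim_electrodes : indices of the stimulating electrode(s).
    pattern_weights : relative current weight per stimulating electrode
        (1-D multi-electrode stimulation: the overall amplitude scales a
        fixed pattern).
    breakpoints : amplitudes (uA) where hardware gain settings switch.
    positions : (E, 2) electrode coordinates in um.
    """

    traces: list[np.ndarray]
    amplitudes: np.ndarray
    sampling_rate_hz: float
    stim_electrodes: list[int]
    positions: np.ndarray
    breakpoints: list[float] = field(default_factory=list)
    pattern_weights: list[float] | None = None

    def __post_init__(self) -> None:
        self.traces = [np.asarray(y, dtype=float) for y in self.traces]
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.stim_electrodes = [int(e) for e in self.stim_electrodes]
        if self.pattern_weights is None:
            self.pattern_weights = [1.0] * len(self.stim_electrodes)
        if len(self.traces) != len(self.amplitudes):
            raise SchemaError(
                f"{len(self.traces)} trace blocks but {len(self.amplitudes)} amplitudes"
            )
        if np.any(np.diff(self.amplitudes) <= 0):
            raise SchemaError("amplitudes must be strictly increasing")
        shapes = {y.shape[1:] for y in self.traces}
        if len(shapes) != 1:
            raise SchemaError(f"inconsistent (E, T) across amplitudes: {shapes}")
        e, _ = shapes.pop()
        if self.positions.shape != (e, 2):
            raise SchemaError(
                f"positions shape {self.positions.shape} does not match E={e}"
            )
        for es in self.stim_electrodes:
            if not 0 <= es < e:
                raise SchemaError(f"stimulating electrode {es} outside array of {e}")

    @property
    def J(self) -> int:
        return len(self.amplitudes)

    @property
    def E(self) -> int:
        return self.traces[0].shape[1]

    @property
    def T(self) -> int:
        return self.traces[0].shape[2]

    @property
    def n_trials(self) -> np.ndarray:
        return np.array([y.shape[0] for y in self.traces])

    @property
    def time_ms(self) -> np.ndarray:
        """Time of each sample since stimulus onset, in ms."""
        return np.arange(self.T) / self.sampling_rate_hz * 1e3

    def electrode_distances(self, reference: int | None = None) -> np.ndarray:
        """Distance of every electrode to ``reference`` (default: the
        pattern-weighted stimulating site)."""
        if reference is not None:
            ref = self.positions[reference]
        else:
            w = np.abs(np.asarray(self.pattern_weights, dtype=float))
            ref = np.average(self.positions[self.stim_electrodes], axis=0, weights=w)
        return np.linalg.norm(self.positions - ref, axis=1)

    def copy(self) -> "AmplitudeSeries":
        return AmplitudeSeries(
            traces=[y.copy() for y in self.traces],
            amplitudes=self.amplitudes.copy(),
            sampling_rate_hz=self.sampling_rate_hz,
            stim_electrodes=list(self.stim_electrodes),
            positions=self.positions.copy(),
            breakpoints=list(self.breakpoints),
            pattern_weights=list(self.pattern_weights),
        )


@dataclass
class ElectricalImages:
    """Per-neuron spike templates, each an (E, T') array in uV."""

    templates: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.templates = {int(n): np.asarray(t, dtype=float) for n, t in self.templates.items()}

    @property
    def neuron_ids(self) -> list[int]:
        return sorted(self.templates)

    def peak_strength(self, neuron: int) -> float:
        """Peak absolute EI amplitude across all electrodes (uV)."""
        return float(np.max(np.abs(self.templates[neuron])))

    def validate_against(self, data: AmplitudeSeries) -> None:
        for n, t in self.templates.items():
            if t.shape[0] != data.E:
                raise SchemaError(
                    f"EI of neuron {n} covers {t.shape[0]} electrodes, traces have {data.E}"
                )


# ---------------------------------------------------------------------------
# file IO

_TRACE_FIELDS = ("amplitudes", "sampling_rate_hz", "stim_electrodes", "positions")


def write_traces(path: str | Path, data: AmplitudeSeries) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        payload = {f"Y{j:04d}": y.astype(np.float32) for j, y in enumerate(data.traces)}
        np.savez(
            path,
            amplitudes=data.amplitudes,
            sampling_rate_hz=np.float64(data.sampling_rate_hz),
            stim_electrodes=np.asarray(data.stim_electrodes, dtype=np.int64),
            pattern_weights=np.asarray(data.pattern_weights, dtype=np.float64),
            breakpoints=np.asarray(data.breakpoints, dtype=np.float64),
            positions=data.positions,
            **payload,
        )
        return
    with h5py.File(path, "w") as f:
        grp = f.create_group("Y")
        for j, y in enumerate(data.traces):
            grp.create_dataset(f"{j:04d}", data=y.astype(np.float32))
        f["amplitudes"] = data.amplitudes
        f["sampling_rate_hz"] = float(data.sampling_rate_hz)
        f["stim_electrodes"] = np.asarray(data.stim_electrodes, dtype=np.int64)
        f["pattern_weights"] = np.asarray(data.pattern_weights, dtype=np.float64)
        f["breakpoints"] = np.asarray(data.breakpoints, dtype=np.float64)
        f["positions"] = data.positions


def _require(container, name: str, path: Path):
    if name not in container:
        raise SchemaError(f"{path}: missing required field '{name}'")
    return container[name]


def read_traces(path: str | Path) -> AmplitudeSeries:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            names = set(z.files)
            for fld in _TRACE_FIELDS:
                if fld not in names:
                    raise SchemaError(f"{path}: missing required field '{fld}'")
            ykeys = sorted(n for n in names if n.startswith("Y"))
            if not ykeys:
                raise SchemaError(f"{path}: missing required field 'Y'")
            return AmplitudeSeries(
                traces=[z[k].astype(float) for k in ykeys],
                amplitudes=z["amplitudes"],
                sampling_rate_hz=float(z["sampling_rate_hz"]),
                stim_electrodes=list(np.atleast_1d(z["stim_electrodes"])),
                pattern_weights=list(z["pattern_weights"]) if "pattern_weights" in names else None,
                breakpoints=list(z["breakpoints"]) if "breakpoints" in names else [],
                positions=z["positions"],
            )
    with h5py.File(path, "r") as f:
        ygrp = _require(f, "Y", path)
        traces = [ygrp[k][()].astype(float) for k in sorted(ygrp)]
        for fld in _TRACE_FIELDS:
            _require(f, fld, path)
        return AmplitudeSeries(
            traces=traces,
            amplitudes=f["amplitudes"][()],
            sampling_rate_hz=float(f["sampling_rate_hz"][()]),
            stim_electrodes=list(f["stim_electrodes"][()]),
            pattern_weights=list(f["pattern_weights"][()]) if "pattern_weights" in f else None,
            breakpoints=list(f["breakpoints"][()]) if "breakpoints" in f else [],
            positions=f["positions"][()],
        )


def write_eis(path: str | Path, eis: ElectricalImages) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, **{f"n{n}": t.astype(np.float32) for n, t in eis.templates.items()})
        return
    with h5py.File(path, "w") as f:
        for n, t in eis.templates.items():
            f.create_dataset(f"n{n}", data=t.astype(np.float32))


def read_eis(path: str | Path) -> ElectricalImages:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            if not z.files:
                raise SchemaError(f"{path}: no EI templates found")
            return ElectricalImages({int(k[1:]): z[k].astype(float) for k in z.files})
    with h5py.File(path, "r") as f:
        keys = list(f)
        if not keys:
            raise SchemaError(f"{path}: no EI templates found")
        return ElectricalImages({int(k[1:]): f[k][()].astype(float) for k in keys})


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
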