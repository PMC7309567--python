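"""Trace and morphology I/O: HDF5 and CSV trace round-trips, SWC export.

HDF5 layout: one group per recording site holding ``voltage`` plus one
dataset per channel/synapse current, a root ``time`` dataset (ms) and the
clamp current when present.  The CSV fallback stores one column per
site/quantity with 17 significant digits, which round-trips IEEE doubles
bit-exactly.
"""

from __future__ import annotations

import io as _io
import math

import h5py
import numpy as np
import pandas as pd

from .morphology import Morphology
from .simulator import TraceSet

__all__ = [
    "save_traces_hdf5",
    "load_traces_hdf5",
    "save_traces_csv",
    "load_traces_csv",
    "morphology_to_swc",
]


def save_traces_hdf5(traces: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=traces.time)
        f.attrs["dt"] = traces.dt
        f.attrs["names"] = traces.names
        f.attrs["sites"] = traces.sites
        if traces.clamp_current is not None:
            f.create_dataset("clamp_current", data=traces.clamp_current)
        for i, site in enumerate(traces.sites):
            grp = f.create_group(f"sites/{site}")
            grp.create_dataset("voltage", data=traces.voltage[i])
            for j, name in enumerate(traces.names):
                grp.create_dataset(name, data=traces.currents[i, j])


def load_traces_hdf5(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        time = f["time"][:]
        names = [str(n) for n in f.attrs["names"]]
        sites = [str(s) for s in f.attrs["sites"]]
        dt = float(f.attrs["dt"])
        clamp = f["clamp_current"][:] if "clamp_current" in f else None
        voltage = np.empty((len(sites), time.size))
        currents = np.empty((len(sites), len(names), time.size))
        for i, site in enumerate(sites):
            grp = f[f"sites/{site}"]
            voltage[i] = grp["voltage"][:]
            for j, name in enumerate(names):
                currents[i, j] = grp[name][:]
    return TraceSet(time, sites, names, voltage, currents, clamp, dt)


def _csv_frame(traces: TraceSet) -> pd.DataFrame:
    cols = {"time": traces.time}
    for i, site in enumerate(traces.sites):
        cols[f"{site}.V"] = traces.voltage[i]
        for j, name in enumerate(traces.names):
            cols[f"{site}.{name}"] = traces.currents[i, j]
    if traces.clamp_current is not None:
        cols["clamp_current"] = traces.clamp_current
    return pd.DataFrame(cols)


def save_traces_csv(traces: TraceSet, path) -> None:
    _csv_frame(traces).to_csv(path, index=False, float_format="%.17g")


def load_traces_csv(path) -> TraceSet:
    df = pd.read_csv(path, float_precision="round_trip")
    site_names: list[str] = []
    names: list[str] = []
    for col in df.columns:
        if col in ("time", "clamp_current"):
            continue
        site, quant = col.split(".", 1)
        if site not in site_names:
            site_names.append(site)
        if quant != "V" and quant not in names:
            names.append(quant)
    time = df["time"].to_numpy()
    voltage = np.stack([df[f"{s}.V"].to_numpy() for s in site_names])
    currents = np.stack([
        np.stack([df[f"{s}.{n}"].to_numpy() for n in names])
        for s in site_names])
    clamp = df["clamp_current"].to_numpy() if "clamp_current" in df else None
    dt = float(time[1] - time[0]) if time.size > 1 else 0.025
    return TraceSet(time, site_names, names, voltage, currents, clamp, dt)


_SWC_TYPE = {"soma": 1, "axon": 2, "dend": 3}


def morphology_to_swc(morph: Morphology) -> str:
    """Serialize a morphology as SWC text (straight-line laid-out chain).

    Compartments are placed along +x from the soma by path distance; branch
    points fan out in y.  Geometry (lengths, diameters, topology) round-trips;
    3-D embedding is synthetic.
    """
    lines = ["# generated by ivlsim; synthetic straight-line embedding"]
    n_children = np.zeros(morph.n, dtype=int)
    y_off = np.zeros(morph.n)
    for i in range(1, morph.n):
        p = morph.parent_index[i]
        y_off[i] = y_off[p] + 5.0 * n_children[p]
        n_children[p] += 1
    for i in range(morph.n):
        c = morph.compartments[i]
        x = morph.path_distance[i]
        parent = morph.parent_index[i] + 1 if morph.parent_index[i] >= 0 else -1
        lines.append(
            f"{i + 1} {_SWC_TYPE[morph.region_label[i]]} "
            f"{x:.6g} {y_off[i]:.6g} 0 {c.diameter / 2:.6g} {parent}")
    return "\n".join(lines) + "\n"
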