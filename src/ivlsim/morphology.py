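"""Compartmental morphologies: builders, SWC import, geometry bookkeeping.

A :class:`Morphology` is a rooted tree of cylindrical compartments.  The root
is always the soma.  Compartments are stored in topological order (every
parent precedes its children), which the solver relies on for its
tree-ordered direct solve.

Units: lengths and diameters in um, axial resistivity in Ohm*cm, specific
capacitance in uF/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CompartmentGeometry",
    "Morphology",
    "MorphologyError",
    "build_chain_morphology",
    "load_swc",
]

REGIONS = ("soma", "dend", "axon")

# SWC structure identifiers (standard 7-column format)
_SWC_REGION = {1: "soma", 2: "axon", 3: "dend", 4: "dend"}


class MorphologyError(ValueError):
    """Raised for structurally invalid morphologies (orphans, cycles, geometry)."""


@dataclass(frozen=True)
class CompartmentGeometry:
    """Geometry and passive electrical properties of one cylindrical compartment."""

    length: float  # um
    diameter: float  # um
    axial_resistivity: float = 150.0  # Ohm*cm
    specific_capacitance: float = 1.0  # uF/cm^2

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise MorphologyError(
                f"length and diameter must be > 0, got {self.length}, {self.diameter}"
            )
        if self.axial_resistivity <= 0 or self.specific_capacitance <= 0:
            raise MorphologyError("axial_resistivity and specific_capacitance must be > 0")

    @property
    def area(self) -> float:
        """Lateral surface area in um^2."""
        return math.pi * self.diameter * self.length


@dataclass
class Morphology:
    """Tree of compartments rooted at the soma.

    ``parent_index[i]`` is the index of compartment ``i``'s parent, ``-1`` for
    the root.  ``path_distance[i]`` is the path length (um) from the soma to
    the distal end of compartment ``i`` (0 for the soma itself).
    ``sites`` maps recording-site names (``"S"``, ``"D1"`` ...) to indices.
    """

    compartments: list[CompartmentGeometry]
    parent_index: np.ndarray
    region_label: list[str]
    sites: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent_index = np.asarray(self.parent_index, dtype=np.int64)
        n = len(self.compartments)
        if n == 0:
            raise MorphologyError("morphology has no compartments")
        if len(self.region_label) != n or self.parent_index.shape != (n,):
            raise MorphologyError("field lengths disagree")
        roots = np.flatnonzero(self.parent_index < 0)
        if roots.size != 1 or roots[0] != 0:
            raise MorphologyError("exactly one root (index 0) required")
        if np.any(self.parent_index[1:] >= np.arange(1, n)):
            raise MorphologyError("compartments must be in topological order")
        for lab in self.region_label:
            if lab not in REGIONS:
                raise MorphologyError(f"unknown region label {lab!r}")
        self.path_distance = self._path_distances()

    def _path_distances(self) -> np.ndarray:
        d = np.zeros(len(self.compartments))
        for i in range(1, len(self.compartments)):
            d[i] = d[self.parent_index[i]] + self.compartments[i].length
        return d

    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def areas(self) -> np.ndarray:
        """Surface areas, um^2."""
        return np.array([c.area for c in self.compartments])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.compartments])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.compartments])

    def region_indices(self, region: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.region_label) == region)

    @property
    def dendritic_indices(self) -> np.ndarray:
        return self.region_indices("dend")

    def terminals(self) -> np.ndarray:
        """Indices of leaf compartments (no children)."""
        has_child = np.zeros(self.n, dtype=bool)
        has_child[self.parent_index[self.parent_index >= 0]] = True
        return np.flatnonzero(~has_child)

    def axial_conductances(self) -> np.ndarray:
        """Coupling conductance (uS) between each compartment and its parent.

        Series resistance of the two adjoining half-cylinders; entry 0 is 0.
        """
        g = np.zeros(self.n)
        for i in range(1, self.n):
            p = self.parent_index[i]
            g[i] = 1.0 / (_half_axial_megaohm(self.compartments[i])
                          + _half_axial_megaohm(self.compartments[p]))
        return g

    def site_names(self) -> list[str]:
        return list(self.sites)


def _half_axial_megaohm(c: CompartmentGeometry) -> float:
    # Ra [Ohm*cm] * (L/2) [um] / cross-section [um^2] * 1e-2 -> MOhm
    cross = math.pi * c.diameter ** 2 / 4.0
    return c.axial_resistivity * (c.length / 2.0) / cross * 1e-2


def build_chain_morphology(
    n_sites: int,
    site_diameters=None,
    site_distances=None,
    passive: CompartmentGeometry | None = None,
    compartment_length: float = 10.0,
) -> Morphology:
    """Soma plus an unbranched dendritic cable with named recording sites.

    ``site_diameters``/``site_distances`` give, for each of the ``n_sites``
    recording sites (soma first, at distance 0), the local diameter and the
    path distance from the soma.  The cable is discretised into compartments
    of at most ``compartment_length`` um; the diameter between two sites is
    the diameter of the distal site, so the compartment ending at a site's
    distance carries exactly that site's diameter.  Sites are named
    ``S, D1, ..., D{n_sites-1}``.
    """
    if passive is None:
        passive = CompartmentGeometry(length=10.0, diameter=1.0)
    if site_diameters is None:
        site_diameters = [10.0] + [1.0] * (n_sites - 1)
    if site_distances is None:
        site_distances = [0.0] + [50.0 * k for k in range(1, n_sites)]
    site_diameters = list(map(float, site_diameters))
    site_distances = list(map(float, site_distances))
    if not (len(site_diameters) == len(site_distances) == n_sites):
        raise MorphologyError("need one diameter and one distance per site")
    if any(d2 <= d1 for d1, d2 in zip(site_distances, site_distances[1:])):
        raise MorphologyError("site distances must be strictly increasing")
    if any(d <= 0 for d in site_diameters):
        raise MorphologyError("site diameters must be > 0")
    if site_distances[0] != 0.0:
        raise MorphologyError("first site is the soma and must sit at distance 0")

    soma_d = site_diameters[0]
    comps = [CompartmentGeometry(length=soma_d, diameter=soma_d,
                                 axial_resistivity=passive.axial_resistivity,
                                 specific_capacitance=passive.specific_capacitance)]
    parents = [-1]
    regions = ["soma"]
    sites = {"S": 0}

    # discretise each inter-site stretch separately so every site distance is
    # hit exactly by a compartment boundary
    pos = 0.0
    prev_index = 0
    for k in range(1, n_sites):
        seg_len = site_distances[k] - pos
        n_sub = max(1, int(math.ceil(seg_len / compartment_length - 1e-9)))
        sub = seg_len / n_sub
        for _ in range(n_sub):
            comps.append(CompartmentGeometry(
                length=sub, diameter=site_diameters[k],
                axial_resistivity=passive.axial_resistivity,
                specific_capacitance=passive.specific_capacitance))
            parents.append(prev_index)
            regions.append("dend")
            prev_index = len(comps) - 1
        sites[f"D{k}"] = prev_index
        pos = site_distances[k]

    return Morphology(comps, np.array(parents), regions, sites)


def load_swc(source: str, axial_resistivity: float = 150.0,
             specific_capacitance: float = 1.0) -> Morphology:
    """Build a :class:`Morphology` from SWC-format text.

    Each non-root sample becomes one compartment spanning from its parent
    sample to itself (length = 3D distance, diameter = 2 x sample radius).
    The root sample becomes the soma compartment (cylinder with L = d = 2r).
    """
    records: dict[int, tuple[int, float, float, float, float, int]] = {}
    for lineno, raw in enumerate(source.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        nid, typ = int(parts[0]), int(parts[1])
        x, y, z, r = map(float, parts[2:6])
        parent = int(parts[6])
        if nid in records:
            raise MorphologyError(f"duplicate node id {nid}")
        records[nid] = (typ, x, y, z, r, parent)
    if not records:
        raise MorphologyError("no SWC records found")

    unknown = [nid for nid, rec in records.items() if rec[0] not in _SWC_REGION]
    if unknown:
        raise MorphologyError(f"unknown SWC type codes at nodes {sorted(unknown)}")
    roots = [nid for nid, rec in records.items() if rec[5] == -1]
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root, found {len(roots)}")
    orphans = [nid for nid, rec in records.items()
               if rec[5] != -1 and rec[5] not in records]
    if orphans:
        raise MorphologyError(f"orphan node(s) {sorted(orphans)}: parent id missing")

    # topological order by walking from the root; leftover nodes mean a cycle
    children: dict[int, list[int]] = {nid: [] for nid in records}
    for nid, rec in records.items():
        if rec[5] != -1:
            children[rec[5]].append(nid)
    order: list[int] = []
    stack = [roots[0]]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(sorted(children[nid], reverse=True))
    if len(order) != len(records):
        cyclic = sorted(set(records) - set(order))
        raise MorphologyError(f"cyclic parent references involving nodes {cyclic}")

    index_of = {nid: i for i, nid in enumerate(order)}
    comps, parents, regions = [], [], []
    for i, nid in enumerate(order):
        typ, x, y, z, r, parent = records[nid]
        if parent == -1:
            comps.append(CompartmentGeometry(2 * r, 2 * r, axial_resistivity,
                                             specific_capacitance))
            parents.append(-1)
        else:
            px, py, pz = records[parent][1:4]
            length = math.dist((x, y, z), (px, py, pz))
            if length <= 0:
                raise MorphologyError(f"node {nid}: zero-length segment")
            comps.append(CompartmentGeometry(length, 2 * r, axial_resistivity,
                                             specific_capacitance))
            parents.append(index_of[parent])
        regions.append(_SWC_REGION[typ])
    return Morphology(comps, np.array(parents), regions)
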