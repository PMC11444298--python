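"""Radial finite-volume discretization of a compartment geometry.

Each radial compartment becomes a run of spherical-shell control volumes;
well-mixed compartments (thylakoid pocket, substomatal gas space) become a
single node.  Interior faces within a compartment are conformal (shared by
exactly two nodes); compartment boundaries are represented by the labelled
interfaces of the geometry and resolved to node pairs at assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Compartment, GeometryModel, shell_volume, sphere_area


class MeshError(ValueError):
    pass


@dataclass
class Mesh:
    geometry: GeometryModel
    # node arrays
    r_lo: np.ndarray
    r_hi: np.ndarray
    r_c: np.ndarray
    volume: np.ndarray
    comp_idx: np.ndarray  # index into geometry.compartments
    # interior faces: (i, j, area, center distance, compartment index)
    faces: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.volume)

    def compartment_name(self, node: int) -> str:
        return self.geometry.compartments[self.comp_idx[node]].name

    def nodes_of(self, name: str) -> np.ndarray:
        idx = [k for k, c in enumerate(self.geometry.compartments) if c.name == name]
        if not idx:
            raise KeyError(name)
        return np.where(self.comp_idx == idx[0])[0]

    def outermost_node(self, name: str) -> int:
        nodes = self.nodes_of(name)
        return int(nodes[np.argmax(self.r_c[nodes])])

    def innermost_node(self, name: str) -> int:
        nodes = self.nodes_of(name)
        return int(nodes[np.argmin(self.r_c[nodes])])

    def compartment_volume(self, name: str) -> float:
        return float(self.volume[self.nodes_of(name)].sum())


def discretize(geometry: GeometryModel, dr: float = 0.2) -> Mesh:
    """Mesh every radial compartment at target spacing ``dr`` (um).

    Raises :class:`MeshError` if ``dr`` exceeds the thickness of any radial
    compartment (at least one node must fit in each shell).
    """
    if dr <= 0:
        raise MeshError(f"dr must be positive, got {dr}")

    r_lo, r_hi, vol, comp = [], [], [], []
    faces = []
    for ci, c in enumerate(geometry.compartments):
        if c.well_mixed:
            r_lo.append(c.r_inner)
            r_hi.append(c.r_outer)
            vol.append(c.volume)
            comp.append(ci)
            continue
        if dr > c.thickness + 1e-12:
            raise MeshError(
                f"dr={dr} is coarser than compartment {c.name!r} "
                f"(thickness {c.thickness:.3g})")
        n = max(1, int(math.ceil(c.thickness / dr - 1e-9)))
        edges = np.linspace(c.r_inner, c.r_outer, n + 1)
        start = len(vol)
        for k in range(n):
            r_lo.append(edges[k])
            r_hi.append(edges[k + 1])
            vol.append(shell_volume(edges[k], edges[k + 1]))
            comp.append(ci)
        for k in range(n - 1):
            i, j = start + k, start + k + 1
            r_face = edges[k + 1]
            # distance between volumetric centroids of adjacent shells
            faces.append((i, j, sphere_area(r_face), ci))

    r_lo = np.asarray(r_lo)
    r_hi = np.asarray(r_hi)
    r_c = 0.5 * (r_lo + r_hi)
    mesh = Mesh(geometry, r_lo, r_hi, r_c, np.asarray(vol), np.asarray(comp))
    mesh.faces = [(i, j, a, r_c[j] - r_c[i], ci) for (i, j, a, ci) in faces]

    # sanity: per-compartment volumes match the analytic shells
    for c in geometry.compartments:
        v = mesh.compartment_volume(c.name)
        if abs(v - c.volume) > 5e-3 * c.volume:
            raise MeshError(f"volume mismatch in {c.name}: {v} vs {c.volume}")
    return mesh
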