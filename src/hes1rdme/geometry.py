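"""Voxelized two-compartment cell geometry for reaction–diffusion simulations.

A cell is modelled as two concentric spheres: an outer sphere of radius
``cell_radius`` (the plasma membrane, default 7.5 μm) and an inner sphere of
radius ``nucleus_radius`` (the nucleus, default 3 μm).  The ball is voxelized
on a regular Cartesian lattice of edge ``voxel_edge``; a lattice voxel belongs
to the cell iff its centre lies inside the outer sphere, and to the nucleus
iff its centre lies within (or exactly on) the inner sphere.  The lattice is aligned so that
one voxel is centred exactly on the origin, which makes the "gene voxel at
maximal depth" the voxel at the cell centre.

Diffusion on this mesh is a continuous-time random walk between face-adjacent
voxels: a molecule of species ``l`` in voxel ``i`` hops to a neighbour ``j``
with rate ``q_lij = D_l / h**2`` per shared face, the exact jump rate of the
discrete Laplacian on a uniform Cartesian grid.  Voxels on the cell boundary
simply have fewer neighbours, which realises a zero-flux outer boundary; the
nuclear membrane carries no extra resistance (continuity of flux), so
nucleus–cytoplasm pairs use the same rate formula as any interior pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Mesh",
    "JumpRateTable",
    "ConfigurationError",
    "build_spherical_cell_mesh",
    "select_gene_voxel",
    "compute_jump_rates",
    "M2_PER_MIN_TO_UM2_PER_MIN",
]

#: 1 m^2 = 1e12 μm^2; diffusion coefficients are quoted in m^2 min^-1.
M2_PER_MIN_TO_UM2_PER_MIN = 1.0e12

NUCLEUS = "nucleus"
CYTOPLASM = "cytoplasm"


class ConfigurationError(ValueError):
    """Raised when geometry or parameter configuration is inadmissible."""


@dataclass
class Mesh:
    """Cartesian voxelization of the two-compartment spherical cell.

    Attributes
    ----------
    voxel_centers : (V, 3) float array, μm
    voxel_volumes : (V,) float array, μm³ (uniform ``voxel_edge**3``)
    adjacency_indptr, adjacency_indices : CSR face-adjacency graph
        (symmetric; row ``i`` lists the face neighbours of voxel ``i``)
    face_areas : (E,) float array, μm² — shared-face area per CSR entry
    center_distances : (E,) float array, μm — centre distance per CSR entry
    subdomain : (V,) array of {"nucleus", "cytoplasm"}
    gene_voxel : int — index of the voxel holding the promoter
    """

    voxel_centers: np.ndarray
    voxel_volumes: np.ndarray
    adjacency_indptr: np.ndarray
    adjacency_indices: np.ndarray
    face_areas: np.ndarray
    center_distances: np.ndarray
    subdomain: np.ndarray
    gene_voxel: int
    cell_radius: float
    nucleus_radius: float
    voxel_edge: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_volumes)

    @property
    def nucleus_mask(self) -> np.ndarray:
        return self.subdomain == NUCLEUS

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.subdomain == CYTOPLASM

    @property
    def total_volume(self) -> float:
        return float(self.voxel_volumes.sum())

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency_indices[
            self.adjacency_indptr[i] : self.adjacency_indptr[i + 1]
        ]

    def degree(self) -> np.ndarray:
        return np.diff(self.adjacency_indptr)

    @classmethod
    def single_voxel(cls, volume: float = 1.0, subdomain: str = NUCLEUS) -> "Mesh":
        """Degenerate one-voxel mesh (useful for well-mixed cross-checks)."""
        h = float(volume) ** (1.0 / 3.0)
        return cls(
            voxel_centers=np.zeros((1, 3)),
            voxel_volumes=np.array([float(volume)]),
            adjacency_indptr=np.array([0, 0], dtype=np.int64),
            adjacency_indices=np.empty(0, dtype=np.int64),
            face_areas=np.empty(0),
            center_distances=np.empty(0),
            subdomain=np.array([subdomain], dtype=object),
            gene_voxel=0,
            cell_radius=h,
            nucleus_radius=h if subdomain == NUCLEUS else h / 2,
            voxel_edge=h,
        )

    # -- serialisation -------------------------------------------------

    def to_json(self, path) -> None:
        """Write the mesh (centres, volumes, adjacency, labels) as JSON."""
        payload = {
            "cell_radius": self.cell_radius,
            "nucleus_radius": self.nucleus_radius,
            "voxel_edge": self.voxel_edge,
            "gene_voxel": int(self.gene_voxel),
            "voxel_centers": self.voxel_centers.tolist(),
            "voxel_volumes": self.voxel_volumes.tolist(),
            "adjacency_indptr": self.adjacency_indptr.tolist(),
            "adjacency_indices": self.adjacency_indices.tolist(),
            "face_areas": self.face_areas.tolist(),
            "center_distances": self.center_distances.tolist(),
            "subdomain": self.subdomain.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Mesh":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            voxel_centers=np.asarray(d["voxel_centers"], dtype=float),
            voxel_volumes=np.asarray(d["voxel_volumes"], dtype=float),
            adjacency_indptr=np.asarray(d["adjacency_indptr"], dtype=np.int64),
            adjacency_indices=np.asarray(d["adjacency_indices"], dtype=np.int64),
            face_areas=np.asarray(d["face_areas"], dtype=float),
            center_distances=np.asarray(d["center_distances"], dtype=float),
            subdomain=np.asarray(d["subdomain"], dtype=object),
            gene_voxel=int(d["gene_voxel"]),
            cell_radius=float(d["cell_radius"]),
            nucleus_radius=float(d["nucleus_radius"]),
            voxel_edge=float(d["voxel_edge"]),
        )

    def summary(self) -> str:
        gx, gy, gz = self.voxel_centers[self.gene_voxel]
        return (
            f"Mesh: {self.n_voxels} voxels (edge {self.voxel_edge} um), "
            f"{int(self.nucleus_mask.sum())} nuclear / "
            f"{int(self.cytoplasm_mask.sum())} cytoplasmic; "
            f"total volume {self.total_volume:.1f} um^3; "
            f"gene voxel {self.gene_voxel} at ({gx:.2f}, {gy:.2f}, {gz:.2f}) um"
        )


def build_spherical_cell_mesh(
    cell_radius: float = 7.5,
    nucleus_radius: float = 3.0,
    voxel_edge: float = 1.0,
) -> Mesh:
    """Voxelize the two-concentric-sphere cell on a Cartesian lattice.

    A voxel is included iff its centre lies strictly inside the cell sphere;
    every included voxel keeps the full volume ``voxel_edge**3`` (no cut
    cells), so the total mesh volume converges to the analytic ball volume as
    ``voxel_edge -> 0``.  Voxels whose centre lies within ``nucleus_radius``
    of the origin are labelled nucleus, all others cytoplasm.  The gene voxel
    defaults to the voxel at the origin (promoter depth ``r = nucleus_radius``).

    Raises
    ------
    ConfigurationError
        If radii are non-positive, ordered incorrectly, or ``voxel_edge`` is
        too coarse to place a nuclear voxel.
    """
    if not (0 < nucleus_radius < cell_radius):
        raise ConfigurationError(
            f"need 0 < nucleus_radius < cell_radius, got {nucleus_radius}, {cell_radius}"
        )
    if voxel_edge <= 0 or voxel_edge > nucleus_radius:
        raise ConfigurationError(
            f"voxel_edge must lie in (0, nucleus_radius]; got {voxel_edge} "
            f"(nucleus_radius={nucleus_radius})"
        )
    h = float(voxel_edge)
    nmax = int(np.floor(cell_radius / h))
    axis = np.arange(-nmax, nmax + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    lattice = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = lattice * h
    radii = np.linalg.norm(centers, axis=1)
    inside = radii < cell_radius
    lattice = lattice[inside]
    centers = centers[inside]
    radii = radii[inside]
    if not np.any(radii < nucleus_radius):
        raise ConfigurationError("no voxel centre falls inside the nucleus")

    # lexicographic voxel order for deterministic indexing
    order = np.lexsort((lattice[:, 2], lattice[:, 1], lattice[:, 0]))
    lattice, centers, radii = lattice[order], centers[order], radii[order]

    key_to_idx = {tuple(t): i for i, t in enumerate(map(tuple, lattice))}
    indptr = [0]
    indices: list[int] = []
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for t in map(tuple, lattice):
        for dx, dy, dz in offsets:
            j = key_to_idx.get((t[0] + dx, t[1] + dy, t[2] + dz))
            if j is not None:
                indices.append(j)
        indptr.append(len(indices))

    # the closed nuclear ball: lattice planes exactly on the membrane belong
    # to the nucleus, which keeps the voxelized nuclear volume close to the
    # analytic (4/3)*pi*R^3 at coarse resolutions
    subdomain = np.where(radii <= nucleus_radius, NUCLEUS, CYTOPLASM).astype(object)
    n_edges = len(indices)
    mesh = Mesh(
        voxel_centers=centers,
        voxel_volumes=np.full(len(centers), h**3),
        adjacency_indptr=np.asarray(indptr, dtype=np.int64),
        adjacency_indices=np.asarray(indices, dtype=np.int64),
        face_areas=np.full(n_edges, h**2),
        center_distances=np.full(n_edges, h),
        subdomain=subdomain,
        gene_voxel=0,
        cell_radius=float(cell_radius),
        nucleus_radius=float(nucleus_radius),
        voxel_edge=h,
    )
    mesh.gene_voxel = select_gene_voxel(mesh, nucleus_radius)
    return mesh


def select_gene_voxel(mesh: Mesh, r: float) -> int:
    """Pick the promoter voxel at radial depth ``r`` inside the nuclear membrane.

    ``r`` is measured inward from the nuclear membrane, so the voxel returned
    is the one whose centre radius is nearest ``nucleus_radius - r``; ties are
    broken by lowest voxel index.  ``r = nucleus_radius`` (the default model
    geometry) selects the voxel closest to the cell centre.
    """
    if not (0 <= r <= mesh.nucleus_radius):
        raise ConfigurationError(
            f"gene distance r={r} outside [0, nucleus_radius={mesh.nucleus_radius}]"
        )
    target = mesh.nucleus_radius - r
    radii = np.linalg.norm(mesh.voxel_centers, axis=1)
    nuclear = np.flatnonzero(mesh.nucleus_mask)
    best = nuclear[np.argmin(np.abs(radii[nuclear] - target))]  # argmin: first min wins
    return int(best)


@dataclass
class JumpRateTable:
    """Per-species diffusion jump rates on the mesh adjacency graph.

    ``edge_rates[s, e]`` is the rate constant (min⁻¹) for a molecule of
    species ``s`` in voxel ``i`` to hop across CSR edge ``e`` (an ordered
    pair ``i -> adjacency_indices[e]``).  On the uniform Cartesian mesh every
    edge of a diffusible species carries ``D / h**2``; non-diffusible species
    (the promoter states) carry zero everywhere.
    """

    species: list
    edge_rates: np.ndarray  # (S, E)
    diffusion_coefficients: dict = field(default_factory=dict)  # m^2 min^-1

    def rate(self, species_index: int, edge: int) -> float:
        return float(self.edge_rates[species_index, edge])

    def outflow_totals(self, mesh: Mesh) -> np.ndarray:
        """(S, V) total outbound rate constant per molecule per voxel."""
        S = self.edge_rates.shape[0]
        out = np.zeros((S, mesh.n_voxels))
        for v in range(mesh.n_voxels):
            sl = slice(mesh.adjacency_indptr[v], mesh.adjacency_indptr[v + 1])
            out[:, v] = self.edge_rates[:, sl].sum(axis=1)
        return out


def compute_jump_rates(
    mesh: Mesh,
    D_by_species: Mapping[str, float],
    non_diffusible: tuple = ("P_f", "P_o"),
) -> JumpRateTable:
    """Convert diffusion coefficients (m² min⁻¹) into per-face jump rates.

    For Cartesian voxels of edge ``h`` the per-face rate is ``D / h**2`` with
    ``D`` in μm² min⁻¹.  Promoter species are pinned to the gene voxel: any
    diffusion coefficient supplied for them is ignored with a warning and
    their jump rates are identically zero.
    """
    species = list(D_by_species)
    E = len(mesh.adjacency_indices)
    edge_rates = np.zeros((len(species), E))
    h2 = mesh.voxel_edge**2
    for s, name in enumerate(species):
        D = float(D_by_species[name])
        if D < 0:
            raise ConfigurationError(f"negative diffusion coefficient for {name}")
        if name in non_diffusible:
            if D > 0:
                warnings.warn(
                    f"promoter species {name} does not diffuse; ignoring D={D}",
                    stacklevel=2,
                )
            continue
        edge_rates[s, :] = D * M2_PER_MIN_TO_UM2_PER_MIN / h2
    return JumpRateTable(
        species=species,
        edge_rates=edge_rates,
        diffusion_coefficients=dict(D_by_species),
    )
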