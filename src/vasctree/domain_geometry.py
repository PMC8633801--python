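"""Perfusion domains: membership tests, uniform sampling and axis-aligned partitions.

A perfusion domain is the 3-D region to be vascularized.  Two concrete
representations are supported:

* :class:`BoxDomain` -- an axis-aligned parallelepiped, with exact membership
  and volume.
* :class:`MeshDomain` -- a watertight triangulated surface, with ray-crossing
  membership and divergence-theorem volume.

Domains can be decomposed into disjoint axis-aligned cells
(:func:`partition_axis_aligned`); the labelling of a point to a cell is a
function (half-open cells, last cell per axis closed) so that no point belongs
to two subdomains.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "PerfusionDomain",
    "BoxDomain",
    "MeshDomain",
    "TriangleMesh",
    "SubdomainCell",
    "DomainPartition",
    "partition_axis_aligned",
    "allometric_inlet_scaling",
    "icosphere",
    "DegenerateDomainError",
    "MeshError",
]

#: rejection-sampling draw cap before a domain is declared degenerate
MAX_REJECTION_DRAWS = 10**6


class DegenerateDomainError(RuntimeError):
    """Rejection sampling failed to hit the domain within the draw cap."""


class MeshError(ValueError):
    """Surface mesh is unusable (non-watertight, empty, inconsistent)."""


class PerfusionDomain:
    """Abstract perfusion region with an inside test and a uniform sampler."""

    seed: int | None = None

    @property
    def volume(self) -> float:
        raise NotImplementedError

    @property
    def l_char(self) -> float:
        """Characteristic length, cube root of the volume."""
        return float(self.volume) ** (1.0 / 3.0)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners of the axis-aligned bounding box."""
        raise NotImplementedError

    def contains(self, point) -> bool:
        point = np.asarray(point, dtype=float)
        if not np.all(np.isfinite(point)):
            raise ValueError("point has non-finite coordinates")
        return bool(self.contains_many(point[None, :])[0])

    def contains_many(self, points: np.ndarray) -> np.ndarray:
        """Vectorized inside test for an (n, 3) array of points."""
        raise NotImplementedError

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sample_point(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform point inside the region via rejection from the bounding box.

        Consumes the generator state deterministically (64 draws per batch,
        scanned in order), so equal seeds give equal sample streams.
        """
        lo, hi = self.bounds
        if self.volume <= 0:
            raise DegenerateDomainError("domain has non-positive volume")
        drawn = 0
        while drawn < MAX_REJECTION_DRAWS:
            batch = rng.uniform(lo, hi, size=(64, 3))
            drawn += 64
            inside = self.contains_many(batch)
            if inside.any():
                return batch[int(np.argmax(inside))].copy()
        raise DegenerateDomainError(
            f"no interior point found after {MAX_REJECTION_DRAWS} draws"
        )


@dataclasses.dataclass(frozen=True)
class BoxDomain(PerfusionDomain):
    """Axis-aligned box [lo, hi] in cm; membership and volume are exact."""

    lo: np.ndarray
    hi: np.ndarray
    seed: int | None = None

    def __init__(self, lo, hi, seed: int | None = None):
        lo = np.asarray(lo, dtype=float).copy()
        hi = np.asarray(hi, dtype=float).copy()
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("box corners must be 3-vectors")
        if not np.all(hi > lo):
            raise ValueError("box must have positive extent on every axis")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        object.__setattr__(self, "seed", seed)

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    @property
    def bounds(self):
        return self.lo, self.hi

    def contains_many(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return np.all((points >= self.lo) & (points <= self.hi), axis=1)


class TriangleMesh:
    """Minimal watertight triangle surface (vertices (n,3), faces (m,3) int).

    Watertightness is enforced at construction: every undirected edge must be
    shared by exactly two faces with opposite orientation.
    """

    def __init__(self, vertices, faces, check: bool = True):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (m, 3)")
        if len(self.faces) == 0:
            raise MeshError("mesh has no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")
        if check and not self.is_watertight():
            raise MeshError("mesh is not watertight (open or inconsistent edges)")

    def is_watertight(self) -> bool:
        # each directed edge must appear exactly once and its reverse exactly once
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        fwd = {tuple(e) for e in edges.tolist()}
        if len(fwd) != len(edges):
            return False
        return all((b, a) in fwd for a, b in fwd)

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def signed_volume(self) -> float:
        """Volume by the divergence theorem (positive for outward orientation)."""
        t = self.triangles
        return float(np.einsum("ij,ij->", np.cross(t[:, 0], t[:, 1]), t[:, 2]) / 6.0)

    @classmethod
    def load(cls, path) -> "TriangleMesh":
        path = Path(path)
        suffix = path.suffix.lower()
        if suffix == ".obj":
            verts, faces = _read_obj(path)
        elif suffix == ".stl":
            verts, faces = _read_stl_ascii(path)
        elif suffix == ".ply":
            verts, faces = _read_ply_ascii(path)
        else:
            raise MeshError(f"unsupported mesh format: {suffix}")
        return cls(verts, faces)

    def save_obj(self, path) -> None:
        with open(path, "w") as fh:
            for v in self.vertices:
                fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in self.faces + 1:
                fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def _read_obj(path):
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise MeshError("only triangular faces are supported")
                faces.append(idx)
    return np.array(verts), np.array(faces)


def _read_stl_ascii(path):
    verts, faces, cur = [], [], []
    index: dict[tuple, int] = {}
    with open(path, errors="replace") as fh:
        head = fh.read(5)
        if head.lower() != "solid":
            raise MeshError("only ASCII STL is supported")
        fh.seek(0)
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                v = tuple(float(x) for x in parts[1:4])
                if v not in index:
                    index[v] = len(verts)
                    verts.append(v)
                cur.append(index[v])
                if len(cur) == 3:
                    faces.append(cur)
                    cur = []
    return np.array(verts), np.array(faces)


def _read_ply_ascii(path):
    with open(path, errors="replace") as fh:
        if fh.readline().strip() != "ply":
            raise MeshError("not a PLY file")
        n_vert = n_face = 0
        while True:
            line = fh.readline()
            if not line:
                raise MeshError("unexpected end of PLY header")
            parts = line.split()
            if parts[:2] == ["format", "binary_little_endian"] or parts[:2] == [
                "format",
                "binary_big_endian",
            ]:
                raise MeshError("only ASCII PLY is supported")
            if parts[:2] == ["element", "vertex"]:
                n_vert = int(parts[2])
            elif parts[:2] == ["element", "face"]:
                n_face = int(parts[2])
            elif parts == ["end_header"]:
                break
        verts = [
            [float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)
        ]
        faces = []
        for _ in range(n_face):
            row = fh.readline().split()
            if int(row[0]) != 3:
                raise MeshError("only triangular faces are supported")
            faces.append([int(x) for x in row[1:4]])
    return np.array(verts), np.array(faces)


class MeshDomain(PerfusionDomain):
    """Region bounded by a watertight surface; volume via the divergence theorem."""

    def __init__(self, mesh: TriangleMesh, seed: int | None = None):
        self.mesh = mesh
        self.seed = seed
        vol = mesh.signed_volume()
        if vol < 0:  # inward-oriented surface; flip
            self.mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
            vol = -vol
        if vol <= 0:
            raise MeshError("mesh encloses no volume")
        self._volume = vol
        t = self.mesh.triangles
        self._v0 = t[:, 0]
        self._e1 = t[:, 1] - t[:, 0]
        self._e2 = t[:, 2] - t[:, 0]
        self._lo = self.mesh.vertices.min(axis=0)
        self._hi = self.mesh.vertices.max(axis=0)

    @classmethod
    def from_file(cls, path, seed: int | None = None) -> "MeshDomain":
        return cls(TriangleMesh.load(path), seed=seed)

    @property
    def volume(self) -> float:
        return self._volume

    @property
    def bounds(self):
        return self._lo, self._hi

    # fixed, slightly irrational ray direction dodges edge-on degeneracies
    _RAY = np.array([0.57735026918962584, 0.57735026962962584, 0.57735026873962584])

    def contains_many(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        out = np.zeros(len(points), dtype=bool)
        bbox = np.all((points >= self._lo) & (points <= self._hi), axis=1)
        for i in np.flatnonzero(bbox):
            out[i] = self._crossings(points[i]) % 2 == 1
        return out

    def _crossings(self, origin: np.ndarray) -> int:
        # Moller-Trumbore across all triangles at once
        d = self._RAY
        h = np.cross(d, self._e2)
        a = np.einsum("ij,ij->i", self._e1, h)
        ok = np.abs(a) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = origin - self._v0
        u = np.einsum("ij,ij->i", s, h) * inv
        q = np.cross(s, self._e1)
        v = (q @ d) * inv
        t = np.einsum("ij,ij->i", self._e2, q) * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        return int(np.count_nonzero(hit))


class SubdomainCell(PerfusionDomain):
    """One axis-aligned cell of a partition, intersected with the parent domain."""

    def __init__(self, parent: PerfusionDomain, lo, hi, index: int,
                 seed: int | None = None):
        self.parent = parent
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.index = index
        self.seed = seed
        self._volume: float | None = None

    @property
    def bounds(self):
        return self.lo, self.hi

    @property
    def volume(self) -> float:
        if self._volume is None:
            if isinstance(self.parent, BoxDomain):
                # cells tile the box exactly
                self._volume = float(np.prod(self.hi - self.lo))
            else:
                # deterministic Monte-Carlo estimate for mesh parents
                rng = np.random.default_rng(
                    0 if self.parent.seed is None else self.parent.seed + 7919 * (self.index + 1)
                )
                n = 20_000
                pts = rng.uniform(self.lo, self.hi, size=(n, 3))
                frac = float(np.count_nonzero(self.contains_many(pts))) / n
                self._volume = frac * float(np.prod(self.hi - self.lo))
        return self._volume

    def contains_many(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        inside = np.all((points >= self.lo) & (points <= self.hi), axis=1)
        if inside.any():
            inside = inside & self.parent.contains_many(points)
        return inside


class DomainPartition:
    """Disjoint decomposition of a domain into axis-aligned cells.

    ``label`` maps a point to exactly one cell index (half-open cell
    membership; the last cell along each axis is closed) or -1 for points
    outside the parent domain.
    """

    def __init__(self, parent: PerfusionDomain, counts: tuple[int, int, int]):
        counts = tuple(int(c) for c in counts)
        if any(c < 1 for c in counts):
            raise ValueError("partition counts must be positive on every axis")
        self.parent = parent
        self.counts = counts
        self.lo, self.hi = parent.bounds
        self.widths = (self.hi - self.lo) / np.array(counts, dtype=float)
        self.subdomains: list[SubdomainCell] = []
        base_seed = 0 if parent.seed is None else parent.seed
        idx = 0
        for ix in range(counts[0]):
            for iy in range(counts[1]):
                for iz in range(counts[2]):
                    cell_lo = self.lo + self.widths * np.array([ix, iy, iz])
                    cell_hi = cell_lo + self.widths
                    self.subdomains.append(
                        SubdomainCell(parent, cell_lo, cell_hi, idx,
                                      seed=base_seed * 100_003 + idx + 1)
                    )
                    idx += 1

    @property
    def n_part(self) -> int:
        return len(self.subdomains)

    def label(self, point) -> int:
        point = np.asarray(point, dtype=float)
        ijk = np.floor((point - self.lo) / self.widths).astype(int)
        counts = np.array(self.counts)
        # closed upper face of the last cell per axis
        ijk = np.where((ijk == counts) & (point == self.hi), counts - 1, ijk)
        if np.any(ijk < 0) or np.any(ijk >= counts):
            return -1
        if not self.parent.contains(point):
            return -1
        return int((ijk[0] * self.counts[1] + ijk[1]) * self.counts[2] + ijk[2])

    def label_many(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return np.array([self.label(p) for p in points], dtype=int)


def partition_axis_aligned(domain: PerfusionDomain,
                           counts: tuple[int, int, int]) -> DomainPartition:
    """Split ``domain`` into ``n_x * n_y * n_z`` disjoint axis-aligned cells."""
    return DomainPartition(domain, counts)


def allometric_inlet_scaling(V: float, Q_ref: float, r_ref: float,
                             V_ref: float) -> tuple[float, float]:
    """Scale inlet flow and root radius with perfusion volume.

    Flow scales linearly with volume and the root radius with the 3/8 power:
    ``Q = Q_ref * (V/V_ref)``, ``r0 = r_ref * (V/V_ref)**(3/8)``.
    """
    if V <= 0 or Q_ref <= 0 or r_ref <= 0 or V_ref <= 0:
        raise ValueError("allometric scaling requires positive arguments")
    ratio = V / V_ref
    return Q_ref * ratio, r_ref * ratio ** 0.375


def icosphere(subdivisions: int = 2, radius: float = 1.0) -> TriangleMesh:
    """Subdivided icosahedron with vertices projected onto a sphere."""
    phi = (1.0 + 5.0 ** 0.5) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v / np.linalg.norm(v)) for v in verts]
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = np.array(verts[i]) + np.array(verts[j])
            verts.append(tuple(m / np.linalg.norm(m)))
            cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdivisions):
        nxt = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            nxt += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = nxt
    return TriangleMesh(np.array(verts) * radius, np.array(faces))
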