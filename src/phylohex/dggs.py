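"""Icosahedral aperture-7 hexagonal discrete global grid.

This module implements the hexagonal hierarchical grid design popularized by
the H3 system: the sphere is partitioned into cells derived from triangular
lattices laid gnomonically on the 20 faces of an icosahedron.  Each coarser
cell splits into seven finer ones ("aperture 7"), giving

    cell_count(r) = 2 + 120 * 7**r

cells at resolution ``r`` (0 coarsest .. 15 finest), of which exactly 12 are
pentagons centred on the icosahedron vertices and the rest are hexagons.

Construction
------------
For face ``f`` with gnomonically projected corners ``A, B, C`` (an equilateral
triangle) the resolution-``r`` cell centres are the Eisenstein-integer lattice

    { A + (m + n*w) * u_r : m, n integers } , w = exp(i*pi/3),
    u_r = (B - A) / (2 * (1 + w) * (2 + w)**r)

restricted to the closed face triangle.  ``|2+w|^2 = 7`` gives the aperture-7
scaling and the 19.107 degree inter-resolution rotation; ``|2(1+w)|^2 = 12``
makes resolution 0 the 122-cell Goldberg grid.  Face edges carry lattice
points only at their endpoints (icosahedron vertices, the pentagons) and
midpoints, each owned by the lowest-indexed face containing them, so the
centre set is globally consistent and seam-free.

Cells are the spherical Voronoi regions of these centres.  All point
assignment and boundary computations are exact up to floating point: in-
triangle tests use integer arithmetic on Eisenstein pairs, Voronoi vertices
are circumcentres of centre triples on the sphere.

Cell ids pack (resolution, face, lattice m, lattice n) into 59 bits of an
unsigned 64-bit integer and are serialized as 16-character lowercase hex
strings in tabular outputs.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# Authalic Earth radius: the sphere with the same surface area as the WGS84
# ellipsoid.  Used for all cell areas and edge lengths.
EARTH_RADIUS_KM = 6371.0072

MAX_RES = 15
_ENUM_MAX_RES = 6  # exhaustive cell enumeration supported up to here

_OMEGA = complex(0.5, np.sqrt(3.0) / 2.0)  # sixth root of unity
_COORD_OFFSET = 1 << 24  # lattice coords stored with this offset (25 bits)

# ---------------------------------------------------------------------------
# Eisenstein-integer helpers.  A pair (a, b) represents a + b*w with
# w = exp(i*pi/3), so w**2 = w - 1.
# ---------------------------------------------------------------------------


def _emul(p: tuple[int, int], q: tuple[int, int]) -> tuple[int, int]:
    a, b = p
    c, d = q
    return (a * c - b * d, a * d + b * c + b * d)


@lru_cache(maxsize=None)
def _delta(res: int) -> tuple[int, int]:
    """Edge vector of the face triangle in lattice units: 2(1+w)(2+w)**res."""
    d = (2, 2)
    for _ in range(res):
        d = _emul(d, (2, 1))
    return d


@lru_cache(maxsize=None)
def _half_delta(res: int) -> tuple[int, int]:
    d = (1, 1)
    for _ in range(res):
        d = _emul(d, (2, 1))
    return d


@lru_cache(maxsize=None)
def _specials(res: int) -> dict[tuple[int, int], tuple[str, object]]:
    """Lattice coords of boundary centres: 3 corners and 3 edge midpoints."""
    d = _delta(res)
    h = _half_delta(res)
    corner = {0: (0, 0), 1: d, 2: _emul(d, (0, 1))}
    mid = {(0, 1): h, (0, 2): _emul(h, (0, 1)), (1, 2): _emul(h, (1, 1))}
    out: dict[tuple[int, int], tuple[str, object]] = {}
    for k, c in corner.items():
        out[c] = ("corner", k)
    for e, c in mid.items():
        out[c] = ("mid", e)
    return out


def _inside_closed(a, b, res: int):
    """Exact closed-triangle test for lattice point(s) (a, b) at ``res``.

    Works elementwise on integer numpy arrays.  The triangle has corners
    0, delta, delta*w (counter-clockwise); cross((a1,b1),(a2,b2)) has the
    sign of a1*b2 - a2*b1.
    """
    da, db = _delta(res)
    ea, eb = _emul((da, db), (0, 1))  # delta * w
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    s0 = da * b - a * db  # cross(delta, P)
    s1 = (ea - da) * (b - db) - (a - da) * (eb - db)  # cross(C-B, P-B)
    s2 = (-ea) * (b - eb) - (a - ea) * (-eb)  # cross(-C, P-C)
    return (s0 >= 0) & (s1 >= 0) & (s2 >= 0)


# ---------------------------------------------------------------------------
# Icosahedron geometry
# ---------------------------------------------------------------------------


def _build_icosahedron():
    lat_hi = np.arctan(0.5)
    verts = [np.array([0.0, 0.0, 1.0])]
    for k in range(5):
        lon = np.deg2rad(72.0 * k)
        verts.append(
            np.array(
                [np.cos(lat_hi) * np.cos(lon), np.cos(lat_hi) * np.sin(lon), np.sin(lat_hi)]
            )
        )
    for k in range(5):
        lon = np.deg2rad(36.0 + 72.0 * k)
        verts.append(
            np.array(
                [np.cos(lat_hi) * np.cos(lon), np.cos(lat_hi) * np.sin(lon), -np.sin(lat_hi)]
            )
        )
    verts.append(np.array([0.0, 0.0, -1.0]))
    verts = np.array(verts)

    faces = []
    for i in range(5):
        j = (i + 1) % 5
        faces.append((0, 1 + i, 1 + j))  # north cap
        faces.append((1 + i, 1 + j, 6 + i))  # upper middle
        faces.append((6 + i, 1 + j, 6 + j))  # lower middle
        faces.append((11, 6 + j, 6 + i))  # south cap
    # canonical order: sorted so face indexes are stable
    faces = [tuple(f) for f in faces]

    out = []
    for fv in faces:
        v = verts[list(fv)]
        if np.linalg.det(v) < 0:  # enforce counter-clockwise from outside
            fv = (fv[0], fv[2], fv[1])
            v = verts[list(fv)]
        out.append((fv, v))
    return verts, out


_ICO_VERTS, _ICO_FACES = _build_icosahedron()
N_FACES = len(_ICO_FACES)


class _Face:
    __slots__ = ("index", "vert_ids", "verts", "center", "e1", "e2", "corners2d")

    def __init__(self, index, vert_ids, verts):
        self.index = index
        self.vert_ids = vert_ids
        self.verts = verts
        c = verts.sum(axis=0)
        self.center = c / np.linalg.norm(c)
        e1 = verts[0] - np.dot(verts[0], self.center) * self.center
        self.e1 = e1 / np.linalg.norm(e1)
        self.e2 = np.cross(self.center, self.e1)
        self.corners2d = np.array([self._project_one(v) for v in verts])

    def _project_one(self, p):
        t = p / np.dot(p, self.center) - self.center
        return complex(np.dot(t, self.e1), np.dot(t, self.e2))

    def project(self, pts):
        """Gnomonic projection of unit vectors (N,3) to complex plane coords."""
        pts = np.atleast_2d(pts)
        denom = pts @ self.center
        t = pts / denom[:, None] - self.center
        return t @ self.e1 + 1j * (t @ self.e2)

    def unproject(self, z):
        """Inverse gnomonic: complex plane coords to unit vectors (N,3)."""
        z = np.atleast_1d(z)
        t = (
            self.center[None, :]
            + np.real(z)[:, None] * self.e1[None, :]
            + np.imag(z)[:, None] * self.e2[None, :]
        )
        return t / np.linalg.norm(t, axis=1, keepdims=True)


_FACES = [_Face(i, fv, v) for i, (fv, v) in enumerate(_ICO_FACES)]
_FACE_CENTERS = np.array([f.center for f in _FACES])

for _f in _FACES:
    _A, _B, _C = _f.corners2d
    assert abs((_C - _A) - (_B - _A) * _OMEGA) < 1e-12, "face corners not equilateral CCW"

# ownership of shared boundary points: lowest face index wins
_VERTEX_FACES: dict[int, list[tuple[int, int]]] = {}
_EDGE_FACES: dict[frozenset, list[tuple[int, tuple[int, int]]]] = {}
for _f in _FACES:
    for k, gv in enumerate(_f.vert_ids):
        _VERTEX_FACES.setdefault(gv, []).append((_f.index, k))
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        key = frozenset((_f.vert_ids[i], _f.vert_ids[j]))
        _EDGE_FACES.setdefault(key, []).append((_f.index, (i, j)))
for _v in _VERTEX_FACES.values():
    _v.sort()
for _e in _EDGE_FACES.values():
    _e.sort()

assert len(_VERTEX_FACES) == 12 and len(_EDGE_FACES) == 30


@lru_cache(maxsize=None)
def _lattice_u(face: int, res: int) -> complex:
    A, B, _ = _FACES[face].corners2d
    da, db = _delta(res)
    return (B - A) / (da + db * _OMEGA)


def _corner_coords(res: int, k: int) -> tuple[int, int]:
    d = _delta(res)
    return {0: (0, 0), 1: d, 2: _emul(d, (0, 1))}[k]


def _mid_coords(res: int, e: tuple[int, int]) -> tuple[int, int]:
    h = _half_delta(res)
    return {(0, 1): h, (0, 2): _emul(h, (0, 1)), (1, 2): _emul(h, (1, 1))}[tuple(sorted(e))]


def _canonical(res: int, face: int, coords: tuple[int, int]) -> tuple[int, tuple[int, int]]:
    """Map a boundary lattice point to its owning (face, coords)."""
    kind = _specials(res).get(coords)
    if kind is None:
        return face, coords
    tag, which = kind
    if tag == "corner":
        gv = _FACES[face].vert_ids[which]
        f0, k0 = _VERTEX_FACES[gv][0]
        return f0, _corner_coords(res, k0)
    gi, gj = which
    key = frozenset((_FACES[face].vert_ids[gi], _FACES[face].vert_ids[gj]))
    f0, e0 = _EDGE_FACES[key][0]
    return f0, _mid_coords(res, e0)


# ---------------------------------------------------------------------------
# Cell ids
# ---------------------------------------------------------------------------


def _pack(res: int, face: int, a: int, b: int) -> int:
    return (
        (res << 55)
        | (face << 50)
        | ((a + _COORD_OFFSET) << 25)
        | (b + _COORD_OFFSET)
    )


def _pack_vec(res: int, face: int, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    base = np.uint64((res << 55) | (face << 50))
    return (
        base
        | ((a + _COORD_OFFSET).astype(np.uint64) << np.uint64(25))
        | (b + _COORD_OFFSET).astype(np.uint64)
    )


def _unpack(cell: int) -> tuple[int, int, int, int]:
    res = (cell >> 55) & 0xF
    face = (cell >> 50) & 0x1F
    a = ((cell >> 25) & 0x1FFFFFF) - _COORD_OFFSET
    b = (cell & 0x1FFFFFF) - _COORD_OFFSET
    return res, face, a, b


def cell_to_str(cell) -> str:
    """Serialize a cell id as a 16-character lowercase hex string."""
    return format(int(cell), "016x")


def str_to_cell(s: str) -> int:
    return int(s, 16)


def cell_resolution(cell: int) -> int:
    return _unpack(int(cell))[0]


def is_valid_cell(cell: int) -> bool:
    try:
        res, face, a, b = _unpack(int(cell))
    except (TypeError, ValueError):
        return False
    if not (0 <= res <= MAX_RES and 0 <= face < N_FACES):
        return False
    if not bool(_inside_closed(a, b, res)):
        return False
    return (face, (a, b)) == _canonical(res, face, (a, b))


def is_pentagon(cell: int) -> bool:
    res, face, a, b = _unpack(int(cell))
    kind = _specials(res).get((a, b))
    return kind is not None and kind[0] == "corner"


# ---------------------------------------------------------------------------
# Coordinate conversions
# ---------------------------------------------------------------------------


def _latlon_to_xyz(lat, lon):
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


def _xyz_to_latlon(p):
    p = np.atleast_2d(p)
    lat = np.rad2deg(np.arcsin(np.clip(p[:, 2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(p[:, 1], p[:, 0]))
    return lat, lon


def _cell_center_xyz(cell: int):
    res, face, a, b = _unpack(int(cell))
    f = _FACES[face]
    z = f.corners2d[0] + (a + b * _OMEGA) * _lattice_u(face, res)
    return f.unproject(np.array([z]))[0]


def cell_to_latlon(cell: int) -> tuple[float, float]:
    """Centre of a cell as (lat, lon) in decimal degrees."""
    lat, lon = _xyz_to_latlon(_cell_center_xyz(cell))
    return float(lat[0]), float(lon[0])


_NBR_OFFSETS = np.array(
    [(da, db) for da in range(-2, 3) for db in range(-2, 3)], dtype=np.int64
)


def cells_from_xyz(pts: np.ndarray, res: int) -> np.ndarray:
    """Vectorized point-to-cell assignment for unit vectors (N, 3).

    A point belongs to the cell whose centre is nearest on the sphere
    (the cells are Voronoi regions of the centre set).  Candidate centres
    are gathered by lattice quantization on the three nearest faces.
    """
    if not 0 <= res <= MAX_RES:
        raise ValueError(f"resolution must be in [0, {MAX_RES}], got {res}")
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    n = pts.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.uint64)
    dots = pts @ _FACE_CENTERS.T
    top3 = np.argsort(-dots, axis=1)[:, :3]

    best_dot = np.full(n, -2.0)
    best_id = np.zeros(n, dtype=np.uint64)
    specials = _specials(res)
    tol = 1e-12

    for slot in range(3):
        fidx = top3[:, slot]
        for face in np.unique(fidx):
            sel = np.where(fidx == face)[0]
            f = _FACES[face]
            z = f.project(pts[sel])
            w = (z - f.corners2d[0]) / _lattice_u(face, res)
            b0 = np.round(np.imag(w) / _OMEGA.imag).astype(np.int64)
            a0 = np.round(np.real(w) - 0.5 * b0).astype(np.int64)
            for da, db in _NBR_OFFSETS:
                a = a0 + da
                b = b0 + db
                ok = _inside_closed(a, b, res)
                if not ok.any():
                    continue
                idx = sel[ok]
                aa, bb = a[ok], b[ok]
                zc = f.corners2d[0] + (aa + bb * _OMEGA) * _lattice_u(face, res)
                cen = f.unproject(zc)
                d = np.einsum("ij,ij->i", pts[idx], cen)
                # canonical ids (specials remapped to owning face)
                ids = np.empty(len(idx), dtype=np.uint64)
                plain = np.ones(len(idx), dtype=bool)
                for k in range(len(idx)):
                    co = (int(aa[k]), int(bb[k]))
                    if co in specials:
                        f0, c0 = _canonical(res, face, co)
                        ids[k] = _pack(res, f0, c0[0], c0[1])
                        plain[k] = False
                if plain.any():
                    ids[plain] = _pack_vec(res, int(face), aa[plain], bb[plain])
                better = d > best_dot[idx] + tol
                tie = (np.abs(d - best_dot[idx]) <= tol) & (ids < best_id[idx])
                upd = better | tie
                tgt = idx[upd]
                best_dot[tgt] = d[upd]
                best_id[tgt] = ids[upd]
    return best_id


def cells_from_latlon(lats, lons, res: int) -> np.ndarray:
    """Vectorized (lat, lon) arrays (degrees) to cell-id array."""
    return cells_from_xyz(_latlon_to_xyz(lats, lons), res)


def latlon_to_cell(lat: float, lon: float, res: int) -> int:
    """Cell id containing the point (lat, lon) at the given resolution."""
    return int(cells_from_latlon([lat], [lon], res)[0])


def cell_to_parent(cell: int, parent_res: int | None = None) -> int:
    """Containing cell at the next-coarser (or given) resolution."""
    res = cell_resolution(cell)
    if parent_res is None:
        parent_res = res - 1
    if not 0 <= parent_res < res:
        raise ValueError(f"parent resolution must be in [0, {res - 1}]")
    c = _cell_center_xyz(cell)
    return int(cells_from_xyz(c[None, :], parent_res)[0])


# ---------------------------------------------------------------------------
# Boundaries (spherical Voronoi cells)
# ---------------------------------------------------------------------------


def _gather_candidates(center: np.ndarray, res: int, rho_steps: float = 2.6):
    """All cell centres within ~rho_steps lattice steps of ``center``."""
    out = []
    seen = set()
    win = int(np.ceil(rho_steps)) + 1
    offs = np.array(
        [(da, db) for da in range(-win, win + 1) for db in range(-win, win + 1)],
        dtype=np.int64,
    )
    for f in _FACES:
        u = _lattice_u(f.index, res)
        rho = rho_steps * abs(u) * 1.5 + 0.05
        if np.dot(center, f.center) < np.cos(min(rho + 0.8, np.pi / 2)):
            continue
        if np.dot(center, f.center) <= 0.2:
            continue
        z = f.project(center[None, :])[0]
        w = (z - f.corners2d[0]) / u
        b0 = int(np.round(w.imag / _OMEGA.imag))
        a0 = int(np.round(w.real - 0.5 * b0))
        a = a0 + offs[:, 0]
        b = b0 + offs[:, 1]
        ok = _inside_closed(a, b, res)
        if not np.any(ok):
            continue
        zc = f.corners2d[0] + (a[ok] + b[ok] * _OMEGA) * u
        cen = f.unproject(zc)
        for k in range(cen.shape[0]):
            key = tuple(np.round(cen[k], 9))
            if key in seen:
                continue
            seen.add(key)
            out.append(cen[k])
    return np.array(out)


def _clip_halfplanes(center: np.ndarray, cand: np.ndarray, scale: float):
    """Voronoi cell of ``center`` vs candidates, via gnomonic half-planes.

    Returns 2-D polygon vertices (counter-clockwise) in the tangent frame,
    plus the frame basis, exploiting that spherical bisectors project to
    straight lines under the gnomonic projection at ``center``.
    """
    c = center
    e1 = np.cross(c, np.array([0.0, 0.0, 1.0]) if abs(c[2]) < 0.9 else np.array([1.0, 0.0, 0.0]))
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)

    L = 4.0 * scale
    poly = [np.array([-L, -L]), np.array([L, -L]), np.array([L, L]), np.array([-L, L])]

    dist = cand @ c
    order = np.argsort(-dist)  # clip with nearest candidates first
    for k in order:
        x = cand[k]
        nvec = c - x
        n2 = np.array([np.dot(nvec, e1), np.dot(nvec, e2)])
        rhs = np.dot(x, c) - 1.0  # keep side: n2 . v >= rhs
        nrm = np.linalg.norm(n2)
        if nrm < 1e-15:
            continue
        new_poly = []
        m = len(poly)
        if m == 0:
            break
        vals = [np.dot(n2, p) - rhs for p in poly]
        for i in range(m):
            j = (i + 1) % m
            pi, pj = poly[i], poly[j]
            vi, vj = vals[i], vals[j]
            if vi >= 0:
                new_poly.append(pi)
            if (vi > 0) != (vj > 0) and vi != vj:
                t = vi / (vi - vj)
                new_poly.append(pi + t * (pj - pi))
        poly = new_poly
    return poly, e1, e2


def _dedupe_ring(verts3d: np.ndarray, tol: float = 1e-9):
    keep = []
    m = verts3d.shape[0]
    for i in range(m):
        if np.linalg.norm(verts3d[i] - verts3d[(i - 1) % m]) > tol:
            keep.append(i)
    return verts3d[keep]


def cell_boundary_xyz(cell: int) -> np.ndarray:
    """Boundary vertices of a cell as unit vectors, counter-clockwise."""
    res, face, a, b = _unpack(int(cell))
    center = _cell_center_xyz(cell)
    cand = _gather_candidates(center, res)
    cand = cand[np.einsum("ij,j->i", cand, center) < 1.0 - 1e-15]  # drop self
    scale = abs(_lattice_u(face, res))
    poly2d, e1, e2 = _clip_halfplanes(center, cand, scale)
    if len(poly2d) < 3:
        raise RuntimeError(f"degenerate Voronoi cell for {cell_to_str(cell)}")
    v3 = np.array([center + p[0] * e1 + p[1] * e2 for p in poly2d])
    v3 /= np.linalg.norm(v3, axis=1, keepdims=True)
    return _dedupe_ring(v3, tol=1e-9 * scale)


def cell_boundary(cell: int) -> np.ndarray:
    """Boundary of a cell as an (k, 2) array of (lat, lon), counter-clockwise."""
    v3 = cell_boundary_xyz(cell)
    lat, lon = _xyz_to_latlon(v3)
    return np.column_stack([lat, lon])


# ---------------------------------------------------------------------------
# Areas and lengths
# ---------------------------------------------------------------------------


def _fan_excess(center, verts):
    """Spherical polygon area (steradians) as a fan of triangles from center."""
    m = verts.shape[0]
    total = 0.0
    for i in range(m):
        a, b2, c2 = center, verts[i], verts[(i + 1) % m]
        num = np.dot(a, np.cross(b2, c2))
        den = 1.0 + np.dot(a, b2) + np.dot(b2, c2) + np.dot(c2, a)
        total += 2.0 * np.arctan2(num, den)
    return total


def _arc_lengths(verts):
    m = verts.shape[0]
    nxt = np.roll(verts, -1, axis=0)
    cr = np.linalg.norm(np.cross(verts, nxt), axis=1)
    dt = np.einsum("ij,ij->i", verts, nxt)
    return np.arctan2(cr, dt)


def cell_area_km2(cell: int) -> float:
    """Spherical area of a cell on the authalic Earth sphere, km^2."""
    center = _cell_center_xyz(cell)
    verts = cell_boundary_xyz(cell)
    return float(_fan_excess(center, verts) * EARTH_RADIUS_KM**2)


def cell_count(res: int) -> int:
    """Closed-form number of cells at a resolution: 2 + 120 * 7**res."""
    if not 0 <= res <= MAX_RES:
        raise ValueError(f"resolution must be in [0, {MAX_RES}], got {res}")
    return 2 + 120 * 7**res


def mean_cell_area_km2(res: int) -> float:
    """Mean cell area from the closed-form cell count (any resolution)."""
    return 4.0 * np.pi * EARTH_RADIUS_KM**2 / cell_count(res)


def grid_cells(res: int) -> np.ndarray:
    """All cell ids at a resolution (exhaustive; res <= 6)."""
    if not 0 <= res <= _ENUM_MAX_RES:
        raise ValueError(
            f"exhaustive enumeration supported for resolution <= {_ENUM_MAX_RES}; "
            "use cell_count() / mean_cell_area_km2() closed forms instead"
        )
    ids = []
    specials = _specials(res)
    for f in _FACES:
        a, b = _interior_lattice(f.index, res)
        ids.append(_pack_vec(res, f.index, a, b))
        owned = []
        for co, (tag, which) in specials.items():
            if _canonical(res, f.index, co) == (f.index, co):
                owned.append(_pack(res, f.index, co[0], co[1]))
        ids.append(np.array(sorted(owned), dtype=np.uint64))
    out = np.concatenate(ids)
    assert out.size == cell_count(res)
    return out


@lru_cache(maxsize=32)
def _interior_lattice(face: int, res: int):
    """Integer (a, b) arrays of strictly interior lattice points of a face."""
    da, db = _delta(res)
    ea, eb = _emul((da, db), (0, 1))
    amin, amax = min(0, da, ea), max(0, da, ea)
    bmin, bmax = min(0, db, eb), max(0, db, eb)
    a = np.arange(amin, amax + 1, dtype=np.int64)
    b = np.arange(bmin, bmax + 1, dtype=np.int64)
    A, B = np.meshgrid(a, b, indexing="ij")
    A = A.ravel()
    B = B.ravel()
    ok = _inside_closed(A, B, res)
    A, B = A[ok], B[ok]
    sp = np.zeros(A.shape, dtype=bool)
    for (ca, cb) in _specials(res):
        sp |= (A == ca) & (B == cb)
    A, B = A[~sp], B[~sp]
    assert A.size == 6 * 7**res - 2, (face, res, A.size)
    return A, B


def _deep_mask(a, b, res):
    """Cells whose 2-ring lies entirely inside the closed face triangle."""
    ok = np.ones(a.shape, dtype=bool)
    for da in range(-2, 3):
        for db in range(-2, 3):
            if max(abs(da), abs(db), abs(da + db)) > 2:
                continue
            ok &= _inside_closed(a + da, b + db, res)
    return ok


_RING1 = np.array([(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)], dtype=np.int64)


def grid_stats(res: int) -> dict:
    """Grid summary at a resolution (exhaustive enumeration, res <= 6).

    Returns cell_count, pentagon_count, mean_hexagon_area_km2 (pentagons
    excluded, matching the convention of published H3 tables),
    mean_pentagon_area_km2, mean_edge_length_km (over hexagon edges) and
    total_area_km2 (which must equal the sphere).
    """
    if not 0 <= res <= _ENUM_MAX_RES:
        raise ValueError(
            f"exhaustive grid_stats supported for resolution <= {_ENUM_MAX_RES}; "
            f"cell_count({res}) = 2 + 120*7**{res} and mean_cell_area_km2({res}) "
            "are available in closed form"
        )
    R2 = EARTH_RADIUS_KM**2
    hex_area_sum = 0.0
    hex_count = 0
    edge_len_sum = 0.0
    edge_count = 0
    pent_area_sum = 0.0
    total_area = 0.0

    for f in _FACES:
        a, b = _interior_lattice(f.index, res)
        deep = _deep_mask(a, b, res)
        u = _lattice_u(f.index, res)
        # vectorized fast path: interior cells with perfect 1-ring
        ad, bd = a[deep], b[deep]
        if ad.size:
            zc = f.corners2d[0] + (ad + bd * _OMEGA) * u
            cen = f.unproject(zc)  # (K,3)
            ring = np.empty((ad.size, 6, 3))
            for k, (da, db) in enumerate(_RING1):
                ring[:, k, :] = f.unproject(
                    f.corners2d[0] + ((ad + da) + (bd + db) * _OMEGA) * u
                )
            # Voronoi vertices: circumcentres of (c, n_k, n_{k+1})
            verts = np.cross(ring - cen[:, None, :], np.roll(ring, -1, axis=1) - cen[:, None, :])
            verts /= np.linalg.norm(verts, axis=2, keepdims=True)
            sign = np.sign(np.einsum("kij,ki->kj", verts.transpose(0, 2, 1), cen))
            verts *= sign[:, :, None]
            # fan areas
            nxt = np.roll(verts, -1, axis=1)
            num = np.einsum("ki,kji->kj", cen, np.cross(verts, nxt))
            den = (
                1.0
                + np.einsum("ki,kji->kj", cen, verts)
                + np.einsum("kji,kji->kj", verts, nxt)
                + np.einsum("kji,ki->kj", nxt, cen)
            )
            areas = (2.0 * np.arctan2(num, den)).sum(axis=1) * R2
            cr = np.linalg.norm(np.cross(verts, nxt), axis=2)
            dt = np.einsum("kji,kji->kj", verts, nxt)
            elens = np.arctan2(cr, dt) * EARTH_RADIUS_KM
            hex_area_sum += areas.sum()
            hex_count += ad.size
            edge_len_sum += elens.sum()
            edge_count += elens.size
            total_area += areas.sum()
        # slow path: shallow interior cells
        for aa, bb in zip(a[~deep], b[~deep]):
            cell = _pack(res, f.index, int(aa), int(bb))
            cen1 = _cell_center_xyz(cell)
            verts1 = cell_boundary_xyz(cell)
            area = _fan_excess(cen1, verts1) * R2
            el = _arc_lengths(verts1) * EARTH_RADIUS_KM
            hex_area_sum += area
            hex_count += 1
            edge_len_sum += el.sum()
            edge_count += el.size
            total_area += area
        # owned boundary specials
        for co, (tag, which) in _specials(res).items():
            if _canonical(res, f.index, co) != (f.index, co):
                continue
            cell = _pack(res, f.index, co[0], co[1])
            cen1 = _cell_center_xyz(cell)
            verts1 = cell_boundary_xyz(cell)
            area = _fan_excess(cen1, verts1) * R2
            el = _arc_lengths(verts1) * EARTH_RADIUS_KM
            total_area += area
            if tag == "corner":
                pent_area_sum += area
            else:
                hex_area_sum += area
                hex_count += 1
                edge_len_sum += el.sum()
                edge_count += el.size

    return {
        "resolution": res,
        "cell_count": hex_count + 12,
        "pentagon_count": 12,
        "mean_hexagon_area_km2": hex_area_sum / hex_count,
        "mean_pentagon_area_km2": pent_area_sum / 12.0,
        "mean_edge_length_km": edge_len_sum / edge_count,
        "total_area_km2": total_area,
    }
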