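"""Deterministic synthetic dental-arch generator with full ground truth.

Clinical scans cannot ship with the package, so every end-to-end test runs
on arches built here: a gingival base slab following a quadratic jawline,
carrying parametric teeth (rounded-box crowns with 1-5 spherical-cap cusps)
separated by gaps, with a sharpened implicit-union radius at the tooth-base
contact so the concave crease the partition stage depends on is guaranteed
to exist.  The implicit field is surfaced by marching cubes; optional
Gaussian vertex noise emulates scanner roughness.  Everything is
deterministic given the seed, and the generator records per-tooth region
masks, cusp apexes with buccal/lingual labels, intended occlusal
displacements, and the true vertical/anterior directions.

Conventions: +z is vertical (crowns up for a mandibular-style arch), +y is
anterior, patient-right is +x.  The jawline is y = -k x^2 with its apex at
the incisors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Polygon
from skimage.measure import marching_cubes

from .errors import ConfigError
from .mesh_core import TriangleMesh, make_mesh
from .tooth_assignment import ToothType

# per-position (mesiodistal, buccolingual, crown height, cusp count), mm
PERMANENT_DIMS = {
    1: (8.5, 6.2, 8.6, 1),
    2: (6.5, 6.0, 8.2, 1),
    3: (7.5, 7.8, 9.2, 1),
    4: (7.0, 9.6, 8.6, 2),
    5: (7.0, 9.6, 8.6, 2),
    6: (10.5, 11.0, 7.5, 4),
    7: (10.5, 11.0, 7.0, 4),
    8: (10.5, 10.5, 6.5, 4),
}
DECIDUOUS_SCALE = 0.8
DECIDUOUS_DIMS = {
    1: (8.5 * DECIDUOUS_SCALE, 5.6, 7.2, 1),
    2: (6.5 * DECIDUOUS_SCALE, 5.2, 6.8, 1),
    3: (7.5 * DECIDUOUS_SCALE, 6.4, 8.0, 1),
    4: (10.5 * DECIDUOUS_SCALE, 8.8, 6.0, 4),
    5: (10.5 * DECIDUOUS_SCALE, 8.8, 5.6, 4),
}

TOOTH_GAP_MM = 0.9          # clearance between neighbouring crowns
MIDLINE_GAP_MM = 1.8        # diastema between the central incisors
BASE_HALFWIDTH_MM = 9.5
BASE_DEPTH_MM = 10.0        # base slab extends from z=0 down to -BASE_DEPTH
CROWN_EMBED_MM = 1.5        # crown sinks this far into the base
CUSP_RADIUS_MM = 2.3
CUSP_SMOOTH_MM = 0.8        # smooth-union radius cusp <-> crown
JUNCTION_SMOOTH_MM = 0.2    # sharpened radius tooth <-> base (keeps the crease)
NECK_INSET_MM = 1.7         # horizontal overhang of the crown above its neck
OCCLUSION_GAP_MM = 2.0


@dataclass
class ArchSpec:
    """Parameters of one synthetic arch."""

    jaw: str = "L"                       # 'U' | 'L'
    dentition: str = "permanent"
    arch_k: float = 0.045                # jawline y = -k x^2
    present: dict = field(default_factory=dict)        # code -> bool
    size_scale: dict = field(default_factory=dict)     # code -> float
    transverse_offset: dict = field(default_factory=dict)  # code -> mm (+buccal)
    height_offset: dict = field(default_factory=dict)      # code -> mm
    noise_sigma: float = 0.05            # mm
    resolution: float = 0.4              # marching-cubes cell, mm
    seed: int = 0
    crown_down: bool = False             # maxillary arch mirrored for occlusion
    z_shift: float = 0.0

    def __post_init__(self):
        if not 0.15 <= self.resolution <= 0.6:
            raise ConfigError("resolution must be within [0.15, 0.6] mm")
        if not 0.0 <= self.noise_sigma < 0.3:
            raise ConfigError("noise sigma must be < 0.3 mm")
        if self.jaw not in ("U", "L"):
            raise ConfigError("jaw must be 'U' or 'L'")
        if self.dentition not in ("permanent", "deciduous"):
            raise ConfigError("dentition must be permanent or deciduous")

    @property
    def dims(self) -> dict:
        return PERMANENT_DIMS if self.dentition == "permanent" else DECIDUOUS_DIMS

    def tooth_codes(self) -> list:
        npos = len(self.dims)
        decid = self.dentition == "deciduous"
        codes = []
        for side in ("R", "L"):
            for p in range(1, npos + 1):
                codes.append(ToothType(self.jaw + side, p, decid))
        return codes


@dataclass
class CuspApex:
    position: np.ndarray      # (3,) mm
    label: str                # 'buccal' | 'lingual' | 'apex'


@dataclass
class ToothTruth:
    tooth: ToothType
    face_mask: np.ndarray     # face indices of the tooth region
    apexes: list              # list[CuspApex]
    centre: np.ndarray        # (3,) crown centre, mm
    dims: tuple               # (md, bl, height) as generated, mm

    @property
    def top_apex(self) -> CuspApex:
        return max(self.apexes, key=lambda a: a.position[2])


@dataclass
class GroundTruth:
    teeth: dict               # ToothType -> ToothTruth
    vertical: np.ndarray      # unit, out of the crowns
    anterior: np.ndarray
    intended_displacement: dict = field(default_factory=dict)  # ToothType -> mm

    def tooth(self, code: str):
        from .tooth_assignment import parse_tooth_type

        return self.teeth[parse_tooth_type(code)]


# ---------------------------------------------------------------------------
# implicit-field helpers


def _smin(a, b, r):
    """Polynomial smooth minimum with blending radius r."""
    h = np.clip(0.5 + 0.5 * (b - a) / r, 0.0, 1.0)
    return b * (1.0 - h) + a * h - r * h * (1.0 - h)


def _arc_length(k: float, t: float) -> float:
    """Arc length of y=-k x^2 from 0 to t."""
    if k < 1e-9:
        return t
    u = 2.0 * k * t
    return (u * np.sqrt(1 + u * u) + np.arcsinh(u)) / (4.0 * k)


def _t_for_arc(k: float, s: float) -> float:
    hi = max(s, 1.0)
    while _arc_length(k, hi) < s:
        hi *= 2.0
    return brentq(lambda t: _arc_length(k, t) - s, 0.0, hi, xtol=1e-10)


def _footprint_polygon_at(k: float, t: float, md: float, bl: float) -> Polygon:
    """Rotated rectangle of a crown footprint on the jawline at T=t."""
    c = np.array([t, -k * t * t])
    slope = -2.0 * k * t
    tan = np.array([1.0, slope]) / np.sqrt(1.0 + slope * slope)
    nrm = np.array([-tan[1], tan[0]])
    hu, hv = md / 2.0, bl / 2.0
    corners = [c + su * hu * tan + sv * hv * nrm
               for su, sv in ((-1, -1), (1, -1), (1, 1), (-1, 1))]
    return Polygon(corners)


@dataclass
class _ToothGeom:
    tooth: ToothType
    centre2d: np.ndarray      # (x, y) crown centre
    tangent2d: np.ndarray     # unit, along the arch
    buccal2d: np.ndarray      # unit, horizontal, away from the concave side
    md: float
    bl: float
    height: float
    cusps: list               # list[(offset3d, apex_z, label)]


def _layout(spec: ArchSpec) -> list:
    """Place tooth geometries round the jawline; raises on overlap."""
    k = spec.arch_k
    geoms = []
    for code in spec.tooth_codes():
        scale = spec.size_scale.get(str(code), 1.0) * spec.size_scale.get("*", 1.0)
        md, bl, height, ncusp = spec.dims[code.position]
        md, bl, height = md * scale, bl * scale, height * scale
        height += spec.height_offset.get(str(code), 0.0)
        geoms.append((code, md, bl, height, ncusp))

    # patient-right sits at +x for a crowns-up mandibular arch; a maxillary
    # arch is seen mirror-image when its crowns point up, and mirroring it
    # crown-down (occlusion pose) flips the side again
    right_sign = (1.0 if spec.jaw == "L" else -1.0) * (-1.0 if spec.crown_down else 1.0)
    placed = []
    for side_sign in (+1.0, -1.0):
        side = "R" if side_sign == right_sign else "L"
        midline = LineString([(0.0, -80.0), (0.0, 30.0)])
        prev_poly = None
        s = 0.0
        for code, md, bl, height, ncusp in geoms:
            if code.side != side:
                continue
            # advance along the arch until the rotated crown footprint
            # clears the previous one: on the tightly curved anterior arch
            # neighbouring crowns rotate tens of degrees relative to each
            # other and plain arc spacing would make them collide lingually
            s_centre = s + (TOOTH_GAP_MM if prev_poly is not None else 0.0) + md / 2.0
            while True:
                t_c = side_sign * _t_for_arc(k, s_centre)
                poly = _footprint_polygon_at(k, t_c, md, bl)
                if poly.distance(midline) < MIDLINE_GAP_MM / 2.0:
                    s_centre += 0.1
                    continue
                if prev_poly is not None and poly.distance(prev_poly) < TOOTH_GAP_MM:
                    s_centre += 0.1
                    continue
                break
            prev_poly = poly
            s = s_centre + md / 2.0
            if not spec.present.get(str(code), True):
                continue
            t = side_sign * _t_for_arc(k, s_centre)
            slope = -2.0 * k * t
            tangent = np.array([1.0, slope])
            tangent /= np.linalg.norm(tangent)
            buccal = np.array([-tangent[1], tangent[0]])
            if buccal[1] < 0:  # away from concave (posterior) side => +y component
                buccal = -buccal
            centre = np.array([t, -k * t * t])
            centre = centre + spec.transverse_offset.get(str(code), 0.0) * buccal
            mesial2d = -tangent * side_sign  # toward the midline

            cusps = []
            if ncusp == 1:
                cusps.append((np.zeros(2), height, "apex"))
            elif ncusp == 2:
                cusps.append((+0.26 * bl * buccal, height + 0.4, "buccal"))
                cusps.append((-0.26 * bl * buccal, height - 0.4, "lingual"))
            else:  # 4-cusp molar
                for mes_sign, dz_m in ((+1, 0.25), (-1, -0.25)):
                    for buc_sign, dz_b, lab in ((+1, 0.4, "buccal"), (-1, -0.4, "lingual")):
                        off = mes_sign * 0.22 * md * mesial2d + buc_sign * 0.26 * bl * buccal
                        cusps.append((off, height + dz_b + dz_m, lab))
            placed.append(
                _ToothGeom(code, centre, tangent, buccal, md, bl, height, cusps)
            )

    for i, g1 in enumerate(placed):
        for g2 in placed[i + 1:]:
            min_sep = 0.45 * (g1.md + g2.md)
            if np.linalg.norm(g1.centre2d - g2.centre2d) < min_sep - 0.5:
                raise ConfigError(
                    f"teeth {g1.tooth} and {g2.tooth} overlap beyond tolerance"
                )
    return placed


def _tooth_field(g: _ToothGeom, x, y, z):
    """Implicit field (negative inside) of one tooth on grid arrays."""
    u = (x - g.centre2d[0]) * g.tangent2d[0] + (y - g.centre2d[1]) * g.tangent2d[1]
    v = (x - g.centre2d[0]) * g.buccal2d[0] + (y - g.centre2d[1]) * g.buccal2d[1]
    w = z

    rc = CUSP_RADIUS_MM * min(1.0, g.md / 8.0)
    box_top = g.height - rc - 0.8
    w_eq = 0.45 * g.height
    # absolute neck inset: every tooth overhangs its junction by the same
    # horizontal amount, so small incisors get as sharp a crease as molars
    inset = NECK_INSET_MM * np.clip((w_eq - w) / (w_eq + CROWN_EMBED_MM), 0.0, 1.0)
    re = 1.2  # edge rounding of the crown box
    hu = g.md / 2.0 - re
    hv = g.bl / 2.0 - re
    du = np.abs(u) - (hu - inset)
    dv = np.abs(v) - (hv - inset)
    dw = np.maximum(-CROWN_EMBED_MM - w, w - box_top)
    dmax = np.maximum(np.maximum(du, dv), dw)
    dpos = np.sqrt(
        np.maximum(du, 0.0) ** 2 + np.maximum(dv, 0.0) ** 2 + np.maximum(dw, 0.0) ** 2
    )
    crown = np.where(dmax < 0, dmax, dpos) - re

    f = crown
    for off, apex_z, _lab in g.cusps:
        cx = g.centre2d + off
        cz = apex_z - rc
        sphere = (
            np.sqrt((x - cx[0]) ** 2 + (y - cx[1]) ** 2 + (z - cz) ** 2) - rc
        )
        f = _smin(f, sphere, CUSP_SMOOTH_MM)
    return f


def _base_field(spec: ArchSpec, x2d, y2d, z):
    """Implicit field of the gingival base: a flat-topped slab following the
    jawline (top at z=0, depth BASE_DEPTH_MM, rounded outer edges)."""
    k = spec.arch_k
    t_end = _t_for_arc(k, _quadrant_arc(spec)) + BASE_HALFWIDTH_MM * 0.5
    ts = np.linspace(-t_end, t_end, max(int(4 * t_end), 64))
    poly = np.column_stack([ts, -k * ts * ts])
    tree = cKDTree(poly)
    d2d, _ = tree.query(np.column_stack([x2d.ravel(), y2d.ravel()]), workers=-1)
    d2d = d2d.reshape(x2d.shape) - BASE_HALFWIDTH_MM

    half = BASE_DEPTH_MM / 2.0
    dz = np.abs(z + half) - half  # slab from -BASE_DEPTH to 0
    rr = 1.0
    a = d2d[:, :, None] + rr
    b = dz[None, None, :] + rr
    dmax = np.maximum(a, b)
    dpos = np.sqrt(np.maximum(a, 0.0) ** 2 + np.maximum(b, 0.0) ** 2)
    return np.where(dmax < 0, dmax, dpos) - rr


def _quadrant_arc(spec: ArchSpec) -> float:
    dims = spec.dims
    total = 0.0
    for p in range(1, len(dims) + 1):
        md = dims[p][0]
        total += md + TOOTH_GAP_MM
    return total


def generate_arch(spec: ArchSpec):
    """Generate one arch: (TriangleMesh, GroundTruth).  Deterministic."""
    geoms = _layout(spec)
    res = spec.resolution

    xs_min = min(g.centre2d[0] for g in geoms) - 12.0
    xs_max = max(g.centre2d[0] for g in geoms) + 12.0
    ys_min = min(g.centre2d[1] for g in geoms) - 12.0
    ys_max = max(g.centre2d[1] for g in geoms) + BASE_HALFWIDTH_MM + 6.0
    zs_min = -BASE_DEPTH_MM - 2.0
    zs_max = max(g.height for g in geoms) + 2.0

    gx = np.arange(xs_min, xs_max + res, res)
    gy = np.arange(ys_min, ys_max + res, res)
    gz = np.arange(zs_min, zs_max + res, res)
    x2d, y2d = np.meshgrid(gx, gy, indexing="ij")

    fld = _base_field(spec, x2d, y2d, gz)
    for g in geoms:
        sl = _subgrid(gx, gy, gz, g)
        if sl is None:
            continue
        ix, iy, iz = sl
        xx = gx[ix][:, None, None]
        yy = gy[iy][None, :, None]
        zz = gz[iz][None, None, :]
        tf = _tooth_field(g, xx, yy, zz)
        region = fld[np.ix_(ix, iy, iz)]
        fld[np.ix_(ix, iy, iz)] = _smin(region, tf, JUNCTION_SMOOTH_MM)

    verts, faces, _, _ = marching_cubes(fld, level=0.0, spacing=(res, res, res))
    verts = verts + np.array([gx[0], gy[0], gz[0]])
    # marching_cubes ('descent') already winds faces outward for a
    # negative-inside field; verified by the signed-volume check in tests.

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        tm = make_mesh(verts, faces)
        vnormals = _vertex_normals(tm)
        # scanner noise is smooth at the sub-millimetre scale: draw iid
        # amplitudes, diffuse them over the vertex graph (correlation length
        # ~1 mm), rescale to sigma, and displace along vertex normals.
        amp = rng.normal(0.0, 1.0, size=len(tm.vertices))
        amp = _graph_smooth(tm, amp, passes=3)
        std = amp.std()
        if std > 0:
            amp *= spec.noise_sigma / std
        verts = tm.vertices + vnormals * amp[:, None]
        faces = tm.faces
    mesh = make_mesh(verts, faces)

    if spec.crown_down:
        flipped = mesh.vertices.copy()
        flipped[:, 2] = -flipped[:, 2] + spec.z_shift
        mesh = TriangleMesh(flipped, mesh.faces[:, ::-1].copy())

    truth = _ground_truth(spec, mesh, geoms)
    return mesh, truth


def _subgrid(gx, gy, gz, g: _ToothGeom):
    pad = max(g.md, g.bl) / 2.0 + 4.0
    ix = np.nonzero((gx >= g.centre2d[0] - pad) & (gx <= g.centre2d[0] + pad))[0]
    iy = np.nonzero((gy >= g.centre2d[1] - pad) & (gy <= g.centre2d[1] + pad))[0]
    iz = np.nonzero((gz >= -CROWN_EMBED_MM - 2.0) & (gz <= g.height + 2.5))[0]
    if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
        return None
    return ix, iy, iz


def _graph_smooth(mesh: TriangleMesh, values: np.ndarray, passes: int) -> np.ndarray:
    """Average a per-vertex scalar over the 1-ring, ``passes`` times."""
    edges = np.unique(
        np.sort(
            np.concatenate(
                [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
            ),
            axis=1,
        ),
        axis=0,
    )
    n = len(mesh.vertices)
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)
    deg[deg == 0] = 1.0
    out = values
    for _ in range(passes):
        acc = np.zeros(n)
        np.add.at(acc, edges[:, 0], out[edges[:, 1]])
        np.add.at(acc, edges[:, 1], out[edges[:, 0]])
        out = 0.5 * (out + acc / deg)
    return out


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    n = np.zeros_like(mesh.vertices)
    fn = mesh.face_normals * mesh.face_areas[:, None]
    for i in range(3):
        np.add.at(n, mesh.faces[:, i], fn)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return n / norms


def _ground_truth(spec: ArchSpec, mesh: TriangleMesh, geoms) -> GroundTruth:
    vertical = np.array([0.0, 0.0, -1.0 if spec.crown_down else 1.0])
    anterior = np.array([0.0, 1.0, 0.0])

    cz = mesh.face_centroids.copy()
    if spec.crown_down:
        cz = cz.copy()
        cz[:, 2] = -(cz[:, 2] - spec.z_shift)

    nf = len(mesh.faces)
    best = np.full(nf, np.inf)
    owner = np.full(nf, -1)
    above = cz[:, 2] > 1.0  # exposed crown above the gingival apron
    for i, g in enumerate(geoms):
        near = (
            (np.abs(cz[:, 0] - g.centre2d[0]) < g.md / 2 + 4)
            & (np.abs(cz[:, 1] - g.centre2d[1]) < g.bl / 2 + 4)
            & above
        )
        idx = np.nonzero(near)[0]
        if len(idx) == 0:
            continue
        tf = _tooth_field(
            g, cz[idx, 0], cz[idx, 1], cz[idx, 2]
        )
        close = np.abs(tf) < 0.3
        sel = idx[close]
        better = tf[close] < best[sel]
        owner[sel[better]] = i
        best[sel[better]] = tf[close][better]

    teeth = {}
    for i, g in enumerate(geoms):
        mask = np.nonzero(owner == i)[0]
        apexes = []
        for off, apex_z, lab in g.cusps:
            p = np.array([g.centre2d[0] + off[0], g.centre2d[1] + off[1], apex_z])
            if spec.crown_down:
                p = p.copy()
                p[2] = -p[2] + spec.z_shift
            apexes.append(CuspApex(position=p, label=lab))
        centre3d = np.array([g.centre2d[0], g.centre2d[1], g.height / 2.0])
        if spec.crown_down:
            centre3d[2] = -centre3d[2] + spec.z_shift
        teeth[g.tooth] = ToothTruth(
            tooth=g.tooth,
            face_mask=mask,
            apexes=apexes,
            centre=centre3d,
            dims=(g.md, g.bl, g.height),
        )
    return GroundTruth(
        teeth=teeth,
        vertical=vertical,
        anterior=anterior,
        intended_displacement={
            t: spec.transverse_offset.get(str(t), 0.0) for t in teeth
        },
    )


# ---------------------------------------------------------------------------
# occluded pairs


def generate_occluded_pair(spec_max: ArchSpec, spec_mand: ArchSpec):
    """Generate a maxillary/mandibular pair registered in occlusion.

    Both arches share the jawline; the maxillary arch is mirrored crown-down
    above the mandibular one with a fixed tip-to-tip vertical gap.  Intended
    transverse displacements are the maxillary per-tooth offsets relative to
    the (unoffset) mandibular arch.
    """
    if abs(spec_max.arch_k - spec_mand.arch_k) > 1e-9:
        raise ConfigError("occluded arches need matching arch coefficients")
    if spec_max.jaw != "U" or spec_mand.jaw != "L":
        raise ConfigError("pass a maxillary (U) and a mandibular (L) spec")

    mand_mesh, mand_truth = generate_arch(spec_mand)
    top_mand = float(
        max(t.top_apex.position[2] for t in mand_truth.teeth.values())
    )
    max_height = max(
        spec_max.dims[p][2] for p in range(1, len(spec_max.dims) + 1)
    )
    z_shift = top_mand + OCCLUSION_GAP_MM + max_height + 1.0
    spec_max = replace(spec_max, crown_down=True, z_shift=z_shift)
    max_mesh, max_truth = generate_arch(spec_max)

    combined = GroundTruth(
        teeth={**mand_truth.teeth, **max_truth.teeth},
        vertical=mand_truth.vertical,
        anterior=mand_truth.anterior,
        intended_displacement=dict(max_truth.intended_displacement),
    )
    return max_mesh, mand_mesh, combined


# ---------------------------------------------------------------------------
# training-set derivation


def default_training_specs(n: int = 12, dentition: str = "permanent",
                           base_seed: int = 1000) -> list:
    """Specs spanning plausible size variation for training-set generation.

    Alternates jaws; a global size jitter of ~6% and per-arch seed emulate
    the spread of a hand-labelled example database.
    """
    rng = np.random.default_rng(base_seed)
    specs = []
    for i in range(n):
        scale = float(np.clip(rng.normal(1.0, 0.06), 0.85, 1.15))
        specs.append(
            ArchSpec(
                jaw="L" if i % 2 else "U",
                dentition=dentition,
                size_scale={"*": scale},
                noise_sigma=0.05,
                seed=base_seed + i,
            )
        )
    return specs


def generate_training_set(specs):
    """Build a TrainingSet from generated arches using ground-truth masks.

    Each present tooth's truth region becomes a blob (member peaks = detected
    peak points inside the region); molars additionally contribute their
    mesial and distal halves, split at the crown centre along the arch
    tangent, so half-molar types are trainable.
    """
    from .mesh_core import build_adjacency
    from .orientation import ArchFrame
    from .peak_detection import find_peaks
    from .tooth_assignment import TrainingSet, compute_features
    from .tooth_partition import Blob, fit_jawline

    if len(specs) < 2:
        raise ConfigError("need at least 2 specs for a training set")

    samples: dict = {}
    for spec in specs:
        mesh, truth = generate_arch(spec)
        frame = ArchFrame(
            mesh.centroid,
            np.cross(truth.anterior, truth.vertical),
            truth.anterior,
            truth.vertical,
        )
        adj = build_adjacency(mesh)
        peaks = find_peaks(mesh, adj, frame)
        jawline = fit_jawline(peaks, frame)

        # face -> owning truth tooth
        face_owner: dict = {}
        for t, tt in truth.teeth.items():
            for f in tt.face_mask:
                face_owner[int(f)] = t
        peak_owner: dict = {}
        for p in peaks:
            for f in adj.vertex_faces(p.vertex_index):
                owner = face_owner.get(int(f))
                if owner is not None:
                    peak_owner.setdefault(owner, []).append(p)
                    break

        for t, tt in truth.teeth.items():
            if len(tt.face_mask) == 0:
                continue
            own_peaks = peak_owner.get(t, [])
            if not own_peaks:
                continue
            blob = Blob(faces=frozenset(int(f) for f in tt.face_mask), peaks=own_peaks)
            feats = compute_features(mesh, blob, frame, jawline)
            samples.setdefault(t.training_key, []).append(feats.vector())
            if t.is_molar:
                _add_half_samples(
                    mesh, t, tt, own_peaks, frame, jawline, samples
                )

    template_keys = _template_keys(specs[0].dentition)
    short = [k for k in template_keys if len(samples.get(k, [])) < 2]
    if short:
        raise ConfigError(f"training types with <2 samples: {short}")
    return TrainingSet(samples)


def _add_half_samples(mesh, tooth, tt, own_peaks, frame, jawline, samples):
    from .tooth_assignment import compute_features
    from .tooth_partition import Blob

    local_c = frame.to_local(tt.centre)[0]
    tan = jawline.tangent(local_c[0])
    centroids = frame.to_local(mesh.face_centroids[tt.face_mask])
    along = (centroids[:, :2] - local_c[:2]) @ tan
    # mesial = toward the midline: smaller |arc| side
    mesial_sign = -np.sign(jawline.arc_length(local_c[0]) or 1.0) * np.sign(tan @ tan)
    s_centre = jawline.arc_length(local_c[0])
    toward_midline = -np.sign(s_centre) if s_centre != 0 else 1.0
    for half, sign in ((0, toward_midline), (1, -toward_midline)):
        sel = tt.face_mask[np.nonzero(along * sign >= 0)[0]]
        if len(sel) < 3:
            continue
        half_faces = frozenset(int(f) for f in sel)
        half_peaks = [
            p
            for p in own_peaks
            if (frame.to_local(p.position)[0, :2] - local_c[:2]) @ tan * sign >= 0
        ] or own_peaks[:1]
        blob = Blob(faces=half_faces, peaks=half_peaks)
        feats = compute_features(mesh, blob, frame, jawline)
        samples.setdefault(
            tooth.with_half(half).training_key, []
        ).append(feats.vector())


def _template_keys(dentition: str) -> list:
    from .tooth_assignment import build_template

    keys = []
    for jaw in ("U", "L"):
        for slot in build_template(jaw, dentition).slots:
            if slot.training_key not in keys:
                keys.append(slot.training_key)
    return keys
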