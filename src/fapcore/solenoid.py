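"""Idealized beta-solenoid backbone models of amyloid fiber cores.

Each sequence repeat forms one rung of a cross-beta solenoid: its strands run
as flat, pleated beta-strands in the cross-sectional (xy) plane, rungs stack
along the fibril axis (+z) at the cross-beta spacing, and short arcs turn the
chain between strands.  A two-sided arrangement places two antiparallel-
running, in-register parallel sheets facing each other across the core; a
three-sided arrangement places three strands on a triangular cross-section.
Inter-repeat linkers are rendered as coarse excursion loops outside the core
and flagged non-core.

The model is a Calpha trace with pseudo-Cbeta atoms; geometry constants are
textbook cross-beta values (3.8 A Calpha step, 3.45 A per-residue strand
projection, 4.75 A rung rise, 10 A sheet separation).  Arcs are traced as
shallow circular turns in the cross-sectional plane with a small outward
sagitta (default 2 A) so the idealized core stays compact; see the methods
documentation for the rationale.  No Ramachandran realism is claimed for arcs
or loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .repeats import RoleMap


@dataclass(frozen=True)
class GeometryParams:
    """Cross-beta geometry constants, in Angstrom.

    ca_step: consecutive in-strand Calpha distance.
    axial_projection: per-residue translation along the strand direction
        (smaller than ca_step because of the pleat).
    rung_rise: cross-beta stacking distance along the fibril axis.
    sheet_separation: Calpha-Calpha distance between opposing sheets.
    cb_offset: pseudo-Cbeta displacement off the Calpha, alternating
        into/out of the core with residue parity.
    arc_bulge: outward sagitta of the arc turns in the cross-section.
    corner_margin: strand setback from the triangle vertices (three-sided).
    loop_standoff: clearance between linker excursion loops and the core.
    """

    ca_step: float = 3.8
    axial_projection: float = 3.45
    rung_rise: float = 4.75
    sheet_separation: float = 10.0
    cb_offset: float = 1.5
    arc_bulge: float = 2.0
    corner_margin: float = 8.0
    loop_standoff: float = 6.0

    def __post_init__(self):
        for name in ("ca_step", "axial_projection", "rung_rise",
                     "sheet_separation", "cb_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.axial_projection >= self.ca_step:
            raise ValueError("axial_projection must be smaller than ca_step")

    @property
    def pleat_amplitude(self) -> float:
        """Half the pleat zigzag so consecutive Calpha are ca_step apart."""
        return 0.5 * math.sqrt(self.ca_step ** 2 - self.axial_projection ** 2)


class BuildError(ValueError):
    """Raised when a role map cannot be realised with the given geometry."""


@dataclass
class SolenoidModel:
    """Calpha / pseudo-Cbeta coordinates with rung, role and chain bookkeeping.

    Atom arrays are parallel: ``res_id`` (1-based sequence position),
    ``atom_name`` ("CA"/"CB"), ``monomer`` (0-based copy index) and ``coords``
    (n x 3, Angstrom, fibril axis +z).
    """

    res_id: np.ndarray
    atom_name: np.ndarray
    monomer: np.ndarray
    coords: np.ndarray
    rung_of: dict[int, int]
    role_of: dict[int, str]
    arrangement: str
    n_monomers: int
    params: GeometryParams
    sequence: str | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.res_id)

    @property
    def n_rungs(self) -> int:
        return (max(self.rung_of.values()) + 1) if self.rung_of else 0

    def atom_coords(self, res: int, atom: str = "CA") -> np.ndarray:
        """Coordinates of one residue's atom across all monomer copies."""
        sel = (self.res_id == res) & (self.atom_name == atom)
        return self.coords[sel]

    def select(self, atom: str | None = None, monomer: int | None = None,
               roles: set[str] | None = None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom is not None:
            mask &= self.atom_name == atom
        if monomer is not None:
            mask &= self.monomer == monomer
        if roles is not None:
            mask &= np.array([self.role_of[r] in roles for r in self.res_id])
        return mask


# ---------------------------------------------------------------------------
# arc and loop traces
# ---------------------------------------------------------------------------

def _shallow_arc(p_from: np.ndarray, p_to: np.ndarray, n_atoms: int,
                 outward: np.ndarray, s: float) -> np.ndarray:
    """Evenly spaced points on a circular arc of arclength ``s`` between two
    anchors, bulging along ``outward`` (orthogonalized against the chord)."""
    chord = p_to - p_from
    c = float(np.linalg.norm(chord))
    chat = chord / c
    o = outward - np.dot(outward, chat) * chat
    norm_o = np.linalg.norm(o)
    o = o / norm_o if norm_o > 1e-9 else _any_perpendicular(chat)
    ts = np.arange(1, n_atoms + 1) / (n_atoms + 1)
    if s <= c * (1 + 1e-9):
        return p_from + np.outer(ts, chord)
    # solve sin(u)/u = c/s for the half-angle u of the circular arc
    u = brentq(lambda x: math.sin(x) / x - c / s, 1e-9, math.pi - 1e-9)
    r = s / (2 * u)
    mid = 0.5 * (p_from + p_to)
    center = mid - r * math.cos(u) * o
    thetas = -u + 2 * u * ts
    return (center[None, :]
            + r * np.cos(thetas)[:, None] * o[None, :]
            + r * np.sin(thetas)[:, None] * chat[None, :])


def _arc_sagitta(c: float, s: float) -> float:
    """Sagitta of a circular arc with chord ``c`` and arclength ``s``."""
    if s <= c * (1 + 1e-9):
        return 0.0
    u = brentq(lambda x: math.sin(x) / x - c / s, 1e-9, math.pi - 1e-9)
    r = s / (2 * u)
    return r * (1 - math.cos(u))


def _arc_points(p_from: np.ndarray, p_to: np.ndarray, n_atoms: int,
                out_from: np.ndarray, out_to: np.ndarray,
                params: GeometryParams, max_bulge: float | None = None) -> np.ndarray:
    """Place ``n_atoms`` arc residues on an idealized turn between anchors.

    Short, roomy turns use a shallow circular arc (sagitta at most
    ``max_bulge``, default ``arc_bulge``) in the plane of the chord and the
    outward direction.  Crowded turns — more chain than the gap can hold at
    beta spacing — switch to a waypoint trace: the chain escapes each
    junction with a full-length step directed outward and out of the rung
    plane (perpendicular to the sheet normal, clearing the strand-end
    pseudo-Cbeta), and the remaining residues bridge the two escape points.
    Slack is absorbed along the fibril axis, keeping the cross-section
    compact.
    """
    chord = p_to - p_from
    c = float(np.linalg.norm(chord))
    if c < 1e-9:
        raise BuildError("arc endpoints coincide")
    s_avail = (n_atoms + 1) * params.ca_step
    if s_avail < c - 1e-9:
        raise BuildError(
            f"infeasible arc closure: {n_atoms} arc residues span at most "
            f"{s_avail:.2f} A but the sheet gap requires {c:.2f} A"
        )
    # preferred: a circular turn at full bond spacing (a petal for short
    # chords); used whenever its sagitta fits the bulge budget
    b_full = _arc_sagitta(c, s_avail)
    if max_bulge is None or b_full <= max_bulge:
        return _shallow_arc(p_from, p_to, n_atoms, out_from + out_to, s_avail)

    # shallow mode when even beta-like spacing fits within the bulge budget
    b0 = min(max_bulge, 0.5 * c)
    r0 = (c * c / 4 + b0 * b0) / (2 * b0) if b0 > 1e-9 else float("inf")
    if math.isfinite(r0):
        u0 = math.asin(min(1.0, c / (2 * r0)))
        s_shallow = min(s_avail, 2 * r0 * u0)
    else:
        s_shallow = min(s_avail, c)
    if s_shallow / (n_atoms + 1) >= 2.95 or n_atoms <= 2:
        return _shallow_arc(p_from, p_to, n_atoms, out_from + out_to, s_shallow)

    # waypoint mode: junction escape steps, then bridge.  The escape lifts
    # the chain to the inter-rung midplane (rise/2), equidistant from the
    # strand ends of both neighboring rungs, and pushes modestly outward.
    z_esc = 0.5 * params.rung_rise
    xy_esc = min(2.1, math.sqrt(max(params.ca_step ** 2 - z_esc ** 2, 0.25)))
    dz = p_to[2] - p_from[2]
    s_from, s_to = 1.0, (1.0 if abs(dz) <= 1e-6 else -1.0)

    def escape(anchor, out_xy, zsign):
        o = np.array([out_xy[0], out_xy[1], 0.0])
        n = np.linalg.norm(o)
        o = o / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
        return anchor + xy_esc * o + zsign * z_esc * np.array([0.0, 0.0, 1.0])

    E = escape(p_from, out_from, s_from)
    F = escape(p_to, out_to, s_to)
    if n_atoms == 2:
        return np.stack([E, F])
    # the 2% extra arclength bows the bridge slightly outward, clearing
    # inward-pointing strand-end pseudo-CB at short strand extents
    interior = _shallow_arc(E, F, n_atoms - 2,
                            0.5 * (out_from + out_to),
                            max(float(np.linalg.norm(F - E)), 1e-6) * 1.02)
    return np.vstack([E[None, :], interior, F[None, :]])


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(v, ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _loop_points(anchor: np.ndarray, n_atoms: int, outward_xy: np.ndarray,
                 params: GeometryParams) -> np.ndarray:
    """Coarse excursion loop for linker residues, outside the core.

    A near-closed circle in the cross-sectional plane, stood off from the
    core by ``loop_standoff``, whose circumference matches the chain length.
    """
    s = (n_atoms + 1) * params.ca_step
    r = s / (2 * math.pi)
    o = np.array([outward_xy[0], outward_xy[1], 0.0])
    n = np.linalg.norm(o)
    o = o / n if n > 1e-9 else np.array([-1.0, 0.0, 0.0])
    center = anchor + (r + params.loop_standoff) * o
    phi0 = math.atan2(*( (anchor - center)[[1, 0]] ))  # angle of anchor direction
    t = np.arange(1, n_atoms + 1) / (n_atoms + 1)
    phis = phi0 + 2 * math.pi * t
    pts = np.stack([
        center[0] + r * np.cos(phis),
        center[1] + r * np.sin(phis),
        np.full(n_atoms, anchor[2]),
    ], axis=1)
    return pts


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

def _rung_layout(runs, params: GeometryParams, arrangement: str):
    """In-plane strand anchors for one rung.

    Returns per-strand (start_xy, direction_xy, inward_normal_xy, n_res).
    """
    strands = [(role, s, e) for role, s, e in runs if role.startswith("strand")]
    proj = params.axial_projection
    lengths = [e - s + 1 for _, s, e in strands]
    exts = [(n - 1) * proj for n in lengths]
    if arrangement == "two_sided":
        sep = params.sheet_separation
        # strand1 +x at y=0; strand2 -x at y=sep, centered on strand1's extent
        x2_start = 0.5 * (exts[0] + exts[1])
        return [
            (np.array([0.0, 0.0]), np.array([1.0, 0.0]), np.array([0.0, 1.0]), lengths[0]),
            (np.array([x2_start, sep]), np.array([-1.0, 0.0]), np.array([0.0, -1.0]), lengths[1]),
        ]
    # three_sided: strands along the sides of an equilateral triangle
    m = params.corner_margin
    side = max(exts) + 2 * m
    dirs = [np.array([math.cos(a), math.sin(a)])
            for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)]
    verts = [np.array([0.0, 0.0])]
    for k in range(2):
        verts.append(verts[-1] + side * dirs[k])
    # inward normal: rotate direction by +90 degrees (counterclockwise traversal)
    normals = [np.array([-d[1], d[0]]) for d in dirs]
    return [
        (verts[k] + m * dirs[k], dirs[k], normals[k], lengths[k])
        for k in range(3)
    ]


def build_solenoid(rolemap: RoleMap, params: GeometryParams | None = None) -> SolenoidModel:
    """Build idealized Calpha / pseudo-Cbeta coordinates from a role map.

    One rung per repeat, stacked at ``rung_rise`` along +z; strands are
    pleated in-plane traces, arcs shallow circular turns, linkers non-core
    excursion loops.  Pseudo-Cbeta atoms sit ``cb_offset`` along the local
    cross-section normal, alternating into/out of the core with residue
    parity (the pleat uses the same alternation, keeping equivalent residues
    of successive rungs exactly ``rung_rise`` apart).
    """
    params = params or GeometryParams()
    if not rolemap.rungs:
        raise BuildError("role map contains no complete rung")
    n_sides = 2 if rolemap.arrangement == "two_sided" else 3
    rise = params.rung_rise
    amp = params.pleat_amplitude

    # residue -> (base position, normal) assembled rung by rung
    ca_base: dict[int, np.ndarray] = {}
    normal: dict[int, np.ndarray] = {}
    role_of: dict[int, str] = {}
    rung_of: dict[int, int] = {}
    rung_first: dict[int, int] = {}  # residue -> first residue of its rung

    layouts = []
    for r, runs in enumerate(rolemap.rungs):
        layout = _rung_layout(runs, params, rolemap.arrangement)
        layouts.append(layout)
        z = r * rise
        strands = [(role, s, e) for role, s, e in runs if role.startswith("strand")]
        centroid_pts = []
        for (start_xy, dir_xy, nrm_xy, n_res), (_role, s, e) in zip(layout, strands):
            for k in range(n_res):
                res = s + k
                xy = start_xy + k * params.axial_projection * dir_xy
                ca_base[res] = np.array([xy[0], xy[1], z])
                normal[res] = np.array([nrm_xy[0], nrm_xy[1], 0.0])
                centroid_pts.append(xy)
        centroid = np.mean(centroid_pts, axis=0)
        first = runs[0][1]
        for role, s, e in runs:
            for res in range(s, e + 1):
                role_of[res] = role
                rung_of[res] = r
                rung_first[res] = first

    # pleated strand Calphas.  The pleat phase is anchored at each rung's
    # first residue (not global sequence parity) so that equivalent residues
    # of successive rungs are exact translates even for odd repeat lengths.
    def parity_sign(res: int) -> float:
        return 1.0 if (res - rung_first.get(res, res)) % 2 == 0 else -1.0

    ca: dict[int, np.ndarray] = {}
    for res, base in ca_base.items():
        ca[res] = base + parity_sign(res) * amp * normal[res]

    # arcs: connect strand k end -> strand k+1 start within the rung; the
    # trailing arc closes onto the next rung's first strand start (+rise in z)
    for r, runs in enumerate(rolemap.rungs):
        layout = layouts[r]
        strands = [(role, s, e) for role, s, e in runs if role.startswith("strand")]
        arcs = [(role, s, e) for role, s, e in runs if role == "arc"]
        centroid_xy = np.mean([ca_base[s][:2] for _, s, _ in strands]
                              + [ca_base[e][:2] for _, _, e in strands], axis=0)
        for k, (_role, a_s, a_e) in enumerate(arcs):
            prev_end_res = strands[k][2]
            p_from = ca[prev_end_res]
            if k + 1 < len(strands):
                p_to = ca[strands[k + 1][1]]
            else:
                # virtual/actual start of the next rung's first strand
                next_first = None
                if r + 1 < len(rolemap.rungs):
                    nxt = rolemap.rungs[r + 1]
                    next_first = [x for x in nxt if x[0] == "strand1"][0][1]
                if next_first is not None and next_first in ca:
                    p_to = ca[next_first]
                else:
                    start_xy, _d, nrm_xy, _n = layouts[min(r + 1, len(layouts) - 1)][0]
                    virt = strands[0][1] + 0  # parity of this rung's first residue
                    p_to = (np.array([start_xy[0], start_xy[1], (r + 1) * rise])
                            + parity_sign(virt) * amp
                            * np.array([nrm_xy[0], nrm_xy[1], 0.0]))
            # escape tangentially: continue along the incoming strand axis,
            # and approach the outgoing strand from behind its start
            d_in = layout[k][1]
            d_out = layout[(k + 1) % len(strands)][1]
            out_from = np.array([d_in[0], d_in[1], 0.0])
            out_to = np.array([-d_out[0], -d_out[1], 0.0])
            n_arc = a_e - a_s + 1
            # two-sided cross-sections are width-constrained; triangular
            # corners have open space outside, so in-plane petal turns are
            # free there.  Rung-closing turns climb the rise and use the
            # waypoint trace instead of a tilted petal.
            closing = k + 1 >= len(strands)
            max_bulge = params.arc_bulge if (n_sides == 2 or closing) else None
            pts = _arc_points(p_from, p_to, n_arc, out_from, out_to,
                              params, max_bulge=max_bulge)
            for k2, res in enumerate(range(a_s, a_e + 1)):
                ca[res] = pts[k2]
                d = pts[k2][:2] - centroid_xy
                nd = np.linalg.norm(d)
                normal[res] = (np.array([d[0], d[1], 0.0]) / nd if nd > 1e-9
                               else np.array([1.0, 0.0, 0.0]))

    # linker excursion loops (between consecutive repeats only)
    if rolemap.rungs:
        seq_len = len(rolemap.roles)
        linker_runs = _contiguous_runs(rolemap.roles, "linker")
        for (l_s, l_e) in linker_runs:
            # the rung that follows this linker anchors the loop
            nxt_rung = None
            for r, runs in enumerate(rolemap.rungs):
                if runs[0][1] > l_e:
                    nxt_rung = r
                    break
            if nxt_rung is None:
                continue
            first_res = rolemap.rungs[nxt_rung][0][1]
            anchor = ca_base[first_res]
            strands0 = layouts[nxt_rung]
            centroid_xy = np.mean([p for p, _d, _n, _l in strands0], axis=0)
            out_xy = anchor[:2] - centroid_xy
            pts = _loop_points(anchor, l_e - l_s + 1, out_xy, params)
            for k2, res in enumerate(range(l_s, l_s + (l_e - l_s + 1))):
                ca[res] = pts[k2]
                d = pts[k2][:2] - centroid_xy
                nd = np.linalg.norm(d)
                normal[res] = (np.array([d[0], d[1], 0.0]) / nd if nd > 1e-9
                               else np.array([-1.0, 0.0, 0.0]))
                role_of[res] = "linker"
                rung_of[res] = nxt_rung

    # assemble atom arrays (residue order), CB after CA.  Strand CBs
    # alternate into/out of the core with the pleat; turn and loop CBs all
    # point outward (radially away from the core axis).
    res_ids, names, coords = [], [], []
    for res in sorted(ca):
        res_ids.append(res)
        names.append("CA")
        coords.append(ca[res])
        cb_sign = parity_sign(res) if role_of[res].startswith("strand") else 1.0
        cb = ca[res] + cb_sign * params.cb_offset * normal[res]
        res_ids.append(res)
        names.append("CB")
        coords.append(cb)
    return SolenoidModel(
        res_id=np.array(res_ids, dtype=int),
        atom_name=np.array(names),
        monomer=np.zeros(len(res_ids), dtype=int),
        coords=np.array(coords, dtype=float),
        rung_of=rung_of,
        role_of=role_of,
        arrangement=rolemap.arrangement,
        n_monomers=1,
        params=params,
        sequence=rolemap.sequence,
    )


def _contiguous_runs(roles: list[str], which: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for k, role in enumerate(roles, start=1):
        if role == which and start is None:
            start = k
        elif role != which and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, len(roles)))
    return runs


# ---------------------------------------------------------------------------
# stacking, measurement, checks
# ---------------------------------------------------------------------------

def stack_monomers(model: SolenoidModel, n: int = 3) -> SolenoidModel:
    """Stack ``n`` translated copies continuing the rung lattice along +z."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return model
    if model.n_monomers != 1:
        raise ValueError("stack_monomers expects a single-monomer model")
    rise = model.params.rung_rise
    offset = model.n_rungs * rise
    res_id = np.concatenate([model.res_id] * n)
    names = np.concatenate([model.atom_name] * n)
    monomer = np.concatenate([np.full(model.n_atoms, k, dtype=int) for k in range(n)])
    coords = np.concatenate([
        model.coords + np.array([0.0, 0.0, k * offset]) for k in range(n)
    ])
    return replace(model, res_id=res_id, atom_name=names, monomer=monomer,
                   coords=coords, n_monomers=n)


def measure_core_width(model: SolenoidModel, rung: int = 0) -> float:
    """Cross-sectional core width in nm.

    Maximum pairwise Calpha distance within one rung, projected onto the
    cross-sectional (xy) plane; linker/loop residues are excluded.
    """
    if not model.rung_of:
        raise ValueError("model has no rungs")
    sel = model.select(atom="CA", monomer=0,
                       roles={"strand1", "strand2", "strand3", "arc"})
    sel &= np.array([model.rung_of[r] == rung for r in model.res_id])
    xy = model.coords[sel][:, :2]
    if len(xy) < 2:
        return 0.0
    return float(pdist(xy).max()) / 10.0


@dataclass
class ClashReport:
    """Non-bonded atom pairs closer than the clash threshold."""

    pairs: list[tuple[tuple[int, str, int], tuple[int, str, int], float]]
    count: int
    min_dist: float


def clash_check(model: SolenoidModel, min_dist: float = 3.0) -> ClashReport:
    """All non-bonded atom pairs (|residue gap| >= 2 within a chain, any pair
    across chains) closer than ``min_dist`` Angstrom."""
    if model.n_atoms == 0:
        return ClashReport(pairs=[], count=0, min_dist=min_dist)
    tree = cKDTree(model.coords)
    close = tree.query_pairs(min_dist, output_type="ndarray")
    out = []
    for a, b in close:
        same_chain = model.monomer[a] == model.monomer[b]
        gap = abs(int(model.res_id[a]) - int(model.res_id[b]))
        if same_chain and gap < 2:
            continue  # bonded or same residue
        d = float(np.linalg.norm(model.coords[a] - model.coords[b]))
        out.append((
            (int(model.res_id[a]), str(model.atom_name[a]), int(model.monomer[a])),
            (int(model.res_id[b]), str(model.atom_name[b]), int(model.monomer[b])),
            d,
        ))
    return ClashReport(pairs=out, count=len(out), min_dist=min_dist)


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

_CHAINS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_pdb(model: SolenoidModel, stream) -> None:
    """Write the model as PDB: one chain per monomer, CA/CB ATOM records.

    The fibril axis is +z (stated in a REMARK).  Round-trip through a PDB
    reader reproduces coordinates to the format's 1e-3 A precision.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if model.n_atoms == 0:
        raise ValueError("cannot write an empty model")
    if model.n_atoms > 99999:
        raise ValueError("more than 99,999 atoms: PDB cannot hold this model; "
                         "use a smaller stack (mmCIF output is not provided)")
    if model.n_monomers > len(_CHAINS):
        raise ValueError("too many monomers for single-character chain IDs")

    atoms = struc.AtomArray(model.n_atoms)
    atoms.coord = model.coords.astype(np.float32)
    atoms.chain_id = np.array([_CHAINS[m] for m in model.monomer])
    atoms.res_id = model.res_id
    atoms.atom_name = model.atom_name
    if model.sequence:
        atoms.res_name = np.array(
            [_AA3.get(model.sequence[r - 1].upper(), "ALA") if r <= len(model.sequence)
             else "ALA" for r in model.res_id])
    else:
        atoms.res_name = np.full(model.n_atoms, "ALA")
    atoms.element = np.full(model.n_atoms, "C")
    atoms.hetero = np.zeros(model.n_atoms, dtype=bool)
    atoms.set_annotation("occupancy", np.ones(model.n_atoms, dtype=np.float32))
    atoms.set_annotation("b_factor", np.zeros(model.n_atoms, dtype=np.float32))

    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.lines = [
        "REMARK 999 IDEALIZED CROSS-BETA SOLENOID MODEL; FIBRIL AXIS = +Z",
        "REMARK 999 CROSS-SECTION = XY PLANE; CA/PSEUDO-CB TRACE ONLY",
    ] + pdb.lines
    if hasattr(stream, "write"):
        text = "\n".join(pdb.lines) + "\n"
        stream.write(text)
    else:
        with open(stream, "w") as fh:
            fh.write("\n".join(pdb.lines) + "\n")


def read_pdb_model(stream, params: GeometryParams | None = None) -> SolenoidModel:
    """Read a CA/CB model written by :func:`write_pdb` back into a
    :class:`SolenoidModel` (roles/rungs unknown: all residues become core
    strand residues of a single rung unless annotated otherwise)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if hasattr(stream, "read"):
        pdb = PDBFile.read(stream)
    else:
        with open(stream) as fh:
            pdb = PDBFile.read(fh)
    atoms = pdb.get_structure(model=1)
    chains = sorted(set(atoms.chain_id))
    chain_index = {c: k for k, c in enumerate(chains)}
    res_id = atoms.res_id.astype(int)
    monomer = np.array([chain_index[c] for c in atoms.chain_id])
    role_of = {int(r): "strand1" for r in set(res_id)}
    rung_of = {int(r): 0 for r in set(res_id)}
    return SolenoidModel(
        res_id=res_id,
        atom_name=atoms.atom_name.astype("U4"),
        monomer=monomer,
        coords=atoms.coord.astype(float),
        rung_of=rung_of,
        role_of=role_of,
        arrangement="unknown",
        n_monomers=len(chains),
        params=params or GeometryParams(),
    )
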