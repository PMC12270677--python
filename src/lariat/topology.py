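"""Lariat decomposition, linking numbers, threading and loop handedness.

A disulfide bond closes a covalent loop through the backbone: the Cα trace
between the bonded cysteines plus the Sγ–Sγ bridge.  Together with the chain
segments outside the loop (the tails) this forms a *lariat*.  Two lariats
whose tails mutually thread each other's loops form a double-lariat knot
(DLK), the topology characteristic of the stacked-lariat granulin scaffold.

Threading is quantified by the Gauss linking number between a closed loop and
a tail closed far from the system ("lasso" closure): each tail endpoint is
extended radially away from the loop centroid to a large sphere and the two
ray ends are joined by a great-circle arc.  Two independent linking-number
routes are provided: signed crossings in a generic planar projection (the
fast primary) and the numeric Gauss double integral at fine discretization
(the oracle).

Loop handedness (right/left turn) is the sign of the summed virtual torsion
angles of consecutive Cα quadruples along the loop — a chirality-odd scalar
that flips under mirror reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import DisulfideConnectivity
from .structures import StructureEnsemble

__all__ = [
    "Lariat",
    "TopologyReport",
    "decompose_lariats",
    "close_curve",
    "curve_separation",
    "linking_number",
    "gauss_linking_number",
    "classify_dlk",
    "loop_handedness",
    "analyze_topology",
]


@dataclass
class Lariat:
    """One disulfide-closed loop plus the chain outside it.

    ``tail_paths`` are the flank polylines anchored at the bounding cysteine
    Cα (they share that single point with the loop).  ``thread_pieces`` are
    the maximal chain pieces strictly outside the loop span — the curves
    whose linking with the loop defines threading; they carry their residue
    span so a piece can be attributed to another lariat.
    """

    bond: tuple[int, int]                     # cysteine positions (a < b)
    loop_residues: tuple[int, int]            # residue span of the loop
    loop_path: np.ndarray                     # closed polyline (first == last)
    tail_paths: list = field(default_factory=list)   # open polylines
    thread_pieces: list = field(default_factory=list)  # ((lo, hi), polyline)

    @property
    def has_tails(self) -> bool:
        return len(self.tail_paths) > 0


@dataclass
class TopologyReport:
    lariats: list
    linking_matrix: np.ndarray        # |Lk(loop_i, closed tail of j)| max over tails
    threading_pairs: list             # (i, j): a tail of lariat j threads loop i
    dlk: bool
    handedness: list                  # per-lariat 'right'/'left'/'indeterminate'


def decompose_lariats(
    structure: StructureEnsemble,
    conn: DisulfideConnectivity,
    model: int = 0,
) -> list[Lariat]:
    """One lariat per disulfide: covalent loop plus N-/C-terminal tails.

    The loop polyline runs Cα(a)…Cα(b), crosses to Sγ(b), bridges to Sγ(a)
    and closes back at Cα(a).  Tails are the Cα segments of residues outside
    [a, b], each anchored at the bounding cysteine Cα so they connect to the
    loop region.
    """
    residues = structure.residues
    lariats = []
    for a, b in conn.pairs:
        loop_res = [int(r) for r in residues if a <= r <= b]
        if not loop_res:
            raise ValueError(f"no residues in loop span {a}-{b}")
        try:
            pts = [structure.coords[model, structure.atom_index(r, "CA")]
                   for r in loop_res]
            sg_b = structure.coords[model, structure.atom_index(b, "SG")]
            sg_a = structure.coords[model, structure.atom_index(a, "SG")]
        except KeyError as exc:
            raise ValueError(f"missing atom for lariat {a}-{b}: {exc}") from None
        loop = np.vstack(pts + [sg_b, sg_a, pts[0]])

        def ca_path(res_list):
            return np.vstack([
                structure.coords[model, structure.atom_index(r, "CA")]
                for r in res_list
            ])

        tails = []
        n_side = [int(r) for r in residues if r <= a]
        c_side = [int(r) for r in residues if r >= b]
        if len(n_side) > 1:
            tails.append(ca_path(n_side))
        if len(c_side) > 1:
            tails.append(ca_path(c_side))
        pieces = []
        for run in (_runs([int(r) for r in residues if r < a]),
                    _runs([int(r) for r in residues if r > b])):
            for lo, hi, rr in run:
                if len(rr) >= 2:
                    pieces.append(((lo, hi), ca_path(rr)))
        lariats.append(Lariat(bond=(a, b), loop_residues=(a, b),
                              loop_path=loop, tail_paths=tails,
                              thread_pieces=pieces))
    return lariats


def _runs(res_list):
    """Maximal runs of consecutive residue numbers: (lo, hi, members)."""
    runs = []
    for r in res_list:
        if runs and r == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], r, runs[-1][2] + [r])
        else:
            runs.append((r, r, [r]))
    return runs


# ---------------------------------------------------------------------------
# curve closure

def close_curve(open_path: np.ndarray, reference: np.ndarray,
                radius_factor: float = 10.0) -> np.ndarray:
    """Close an open polyline far from a reference loop ("lasso" closure).

    Both endpoints are extended radially away from the reference centroid to
    a sphere of ``radius_factor`` × system diameter, then joined by a
    great-circle arc on that sphere.  For well-separated geometry the
    resulting linking number is insensitive to the closure details.
    """
    open_path = np.asarray(open_path, dtype=float)
    if np.allclose(open_path[0], open_path[-1]):
        return open_path
    centroid = np.asarray(reference, dtype=float).mean(axis=0)
    allpts = np.vstack([open_path, reference])
    diameter = float(np.max(np.linalg.norm(allpts - centroid, axis=1))) * 2.0
    R = max(radius_factor * diameter, 10.0)

    def to_sphere(p):
        v = p - centroid
        nrm = np.linalg.norm(v)
        if nrm < 1e-9:
            v, nrm = np.array([1.0, 0.0, 0.0]), 1.0
        return centroid + v / nrm * R

    s0, s1 = to_sphere(open_path[0]), to_sphere(open_path[-1])
    # great-circle arc on the sphere from the end-ray back to the start-ray
    u_end, u_start = (s1 - centroid) / R, (s0 - centroid) / R
    dot = float(np.clip(u_end @ u_start, -1.0, 1.0))
    if np.pi - np.arccos(dot) < 1e-6:
        # antipodal rays: route through an orthogonal waypoint
        w = np.array([1.0, 0.0, 0.0])
        if abs(u_end @ w) > 0.9:
            w = np.array([0.0, 1.0, 0.0])
        w = w - (w @ u_end) * u_end
        w /= np.linalg.norm(w)
        arc = np.vstack([_slerp(u_end, w, centroid, R),
                         _slerp(w, u_start, centroid, R)])
    else:
        arc = _slerp(u_end, u_start, centroid, R)
    closed = np.vstack([open_path, s1, arc, s0, open_path[0]])
    keep = np.ones(len(closed), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(closed, axis=0), axis=1) > 1e-9
    return closed[keep]


def _slerp(u0, u1, centroid, R, n: int = 16) -> np.ndarray:
    dot = float(np.clip(u0 @ u1, -1.0, 1.0))
    omega = np.arccos(dot)
    ts = np.linspace(0.0, 1.0, n + 1)[1:]
    if omega < 1e-8:
        return centroid + np.outer(np.ones_like(ts), u1) * R
    pts = (np.sin((1 - ts)[:, None] * omega) * u0
           + np.sin(ts[:, None] * omega) * u1) / np.sin(omega)
    return centroid + pts * R


# ---------------------------------------------------------------------------
# linking numbers

def gauss_linking_number(curve_a: np.ndarray, curve_b: np.ndarray,
                         subdivide: int = 4) -> float:
    """Numeric Gauss double integral over two closed polylines.

    Midpoint rule over segments subdivided ``subdivide``-fold; converges to
    the integer linking number for disjoint closed curves.  Used as the
    independent oracle for :func:`linking_number`.
    """
    a = _subdivided(np.asarray(curve_a, float), subdivide)
    b = _subdivided(np.asarray(curve_b, float), subdivide)
    da = np.diff(a, axis=0)
    db = np.diff(b, axis=0)
    ma = a[:-1] + da / 2.0
    mb = b[:-1] + db / 2.0
    r = ma[:, None, :] - mb[None, :, :]
    cross = np.cross(da[:, None, :], db[None, :, :])
    norm3 = np.linalg.norm(r, axis=-1) ** 3
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.einsum("ijk,ijk->ij", r, cross) / norm3
    return float(np.nansum(integrand) / (4.0 * np.pi))


def _subdivided(curve: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return curve
    out = [curve[:1]]
    for p, q in zip(curve[:-1], curve[1:]):
        ts = np.linspace(0.0, 1.0, k + 1)[1:]
        out.append(p + np.outer(ts, q - p))
    return np.vstack(out)


def linking_number(
    closed_a: np.ndarray,
    curve_b: np.ndarray,
    closure: str = "sphere",
    min_separation: float = 1e-6,
    return_residual: bool = False,
):
    """Integer Gauss linking number of a closed curve with a second curve.

    ``curve_b`` may be open, in which case it is closed by the scheme named
    in ``closure`` (``sphere``: radial lasso closure relative to
    ``closed_a``).  Computed from signed crossings in a generic planar
    projection; the result is rounded to the nearest integer and, with
    ``return_residual``, reported with the distance to that integer from the
    Gauss-integral cross-check to flag ill-conditioned geometry.

    Raises ``ValueError`` when the curves pass within ``min_separation`` of
    each other (perturb and retry).
    """
    a = _ensure_closed(np.asarray(closed_a, float))
    b = np.asarray(curve_b, float)
    if not np.allclose(b[0], b[-1]):
        if closure != "sphere":
            raise ValueError(f"unknown closure scheme {closure!r}")
        b = close_curve(b, a)
    b = _ensure_closed(b)
    if _min_distance(a, b) < min_separation:
        raise ValueError(
            "curves touch within tolerance; perturb the geometry and retry"
        )
    raw = _crossing_sign_link(a, b)
    lk = int(round(raw))
    residual = abs(raw - lk)
    if residual > 0.25:
        # projection hit a degenerate direction: fall back on the Gauss sum
        raw = gauss_linking_number(a, b, subdivide=2)
        lk = int(round(raw))
        residual = abs(raw - lk)
    if return_residual:
        return lk, residual
    return lk


def curve_separation(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Minimum distance between two polylines (endpoint-to-segment bound).

    Both the crossing-sign computation and the numeric Gauss integral are
    only trustworthy when this is comfortably larger than the discretization
    scale.
    """
    return _min_distance(_ensure_closed(np.asarray(curve_a, float)),
                         _ensure_closed(np.asarray(curve_b, float)))


def _ensure_closed(curve: np.ndarray) -> np.ndarray:
    if np.allclose(curve[0], curve[-1]):
        return curve
    return np.vstack([curve, curve[0]])


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    # conservative point-to-segment distance both ways
    return min(_pts_to_segs(a, b), _pts_to_segs(b, a))


def _pts_to_segs(pts: np.ndarray, poly: np.ndarray) -> float:
    p0, p1 = poly[:-1], poly[1:]
    d = p1 - p0
    L2 = np.maximum(np.einsum("ij,ij->i", d, d), 1e-12)
    w = pts[:, None, :] - p0[None, :, :]
    t = np.clip(np.einsum("ijk,jk->ij", w, d) / L2[None, :], 0.0, 1.0)
    proj = p0[None] + t[..., None] * d[None]
    return float(np.min(np.linalg.norm(pts[:, None, :] - proj, axis=-1)))


def _crossing_sign_link(a: np.ndarray, b: np.ndarray, max_tries: int = 8) -> float:
    """Sum of signed crossings between projections of two closed polylines / 2.

    The projection direction starts at +z and is re-drawn deterministically
    whenever a crossing is nearly degenerate (parallel segments or a crossing
    at a segment endpoint).
    """
    rng = np.random.default_rng(20240901)
    rot = np.eye(3)
    for _ in range(max_tries):
        ok, total = _count_crossings(a @ rot.T, b @ rot.T)
        if ok:
            return total / 2.0
        # deterministic random re-orientation
        q = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(q)
    raise ValueError("no generic projection found; curves may be degenerate")


def _seg2d_distance(p0, p1, q0, q1) -> float:
    def pt_seg(p, a, b):
        d = b - a
        L2 = max(float(d @ d), 1e-12)
        t = np.clip((p - a) @ d / L2, 0.0, 1.0)
        return float(np.linalg.norm(p - (a + t * d)))

    return min(pt_seg(p0, q0, q1), pt_seg(p1, q0, q1),
               pt_seg(q0, p0, p1), pt_seg(q1, p0, p1))


def _count_crossings(a: np.ndarray, b: np.ndarray, eps: float = 1e-9):
    pa, qa = a[:-1], a[1:]
    pb, qb = b[:-1], b[1:]
    da = qa - pa
    db = qb - pb
    # 2D intersection of all segment pairs (x,y components)
    denom = (da[:, None, 0] * db[None, :, 1] - da[:, None, 1] * db[None, :, 0])
    diff = pb[None, :, :2] - pa[:, None, :2]
    s_num = diff[..., 0] * db[None, :, 1] - diff[..., 1] * db[None, :, 0]
    t_num = diff[..., 0] * da[:, None, 1] - diff[..., 1] * da[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = s_num / denom
        t = t_num / denom
    margin = 1e-6
    nonpar = np.abs(denom) > eps
    inside = nonpar & (s > margin) & (s < 1 - margin) & (t > margin) & (t < 1 - margin)
    # a crossing on or near a segment endpoint makes the count ambiguous
    wide = nonpar & (s > -margin) & (s < 1 + margin) & (t > -margin) & (t < 1 + margin)
    if np.any(wide & ~inside):
        return False, 0.0
    # near-parallel pairs are degenerate only if the projected segments touch
    for i, j in zip(*np.nonzero(~nonpar)):
        if _seg2d_distance(pa[i, :2], qa[i, :2], pb[j, :2], qb[j, :2]) < 1e-6:
            return False, 0.0
    cand = inside
    ii, jj = np.nonzero(cand)
    total = 0.0
    for i, j in zip(ii, jj):
        za = a[i, 2] + s[i, j] * da[i, 2]
        zb = b[j, 2] + t[i, j] * db[j, 2]
        if abs(za - zb) < 1e-9:
            return False, 0.0
        # positive crossing: (t_over × t_under)·ẑ > 0 with the over strand first
        if za > zb:
            over, under = da[i, :2], db[j, :2]
        else:
            over, under = db[j, :2], da[i, :2]
        total += np.sign(over[0] * under[1] - over[1] * under[0])
    return True, total


# ---------------------------------------------------------------------------
# DLK classification and handedness

def classify_dlk(lariats: list[Lariat]) -> tuple[bool, list, np.ndarray]:
    """Mutual-threading test over all lariat pairs.

    Loop i is *threaded by lariat j* when some maximal chain piece outside
    loop i's residue span links loop i (lasso closure) and that piece
    overlaps lariat j's span — for covalently disjoint lariats this is
    exactly the linking of loop i with the closed tail of j, and it stays
    well defined when lariat spans nest or overlap (where the raw tail of j
    would coincide with part of loop i's own backbone).  Entry (i, j) of the
    returned matrix is the largest such |linking number|; a DLK requires two
    distinct lariats that thread each other.
    """
    n = len(lariats)
    M = np.zeros((n, n), dtype=int)
    for i, la in enumerate(lariats):
        for (lo, hi), piece in la.thread_pieces:
            try:
                lk = linking_number(la.loop_path, piece)
            except ValueError:
                continue
            if lk == 0:
                continue
            for j, lb in enumerate(lariats):
                if j == i:
                    continue
                a, b = lb.loop_residues
                if lo <= b and hi >= a:   # piece overlaps lariat j's span
                    M[i, j] = max(M[i, j], abs(lk))
    pairs = [(i, j) for i in range(n) for j in range(n)
             if i != j and M[i, j] >= 1]
    dlk = any(M[i, j] >= 1 and M[j, i] >= 1
              for i in range(n) for j in range(i + 1, n))
    return dlk, pairs, M


def loop_handedness(loop_path: np.ndarray, theta_min: float = 30.0) -> str:
    """Right/left turn sense of a closed loop from summed virtual torsions.

    The signed dihedral angle of every consecutive point quadruple along the
    (cyclically extended) loop is summed; ``right`` if the sum exceeds
    +``theta_min`` degrees, ``left`` below −``theta_min``, else
    ``indeterminate``.  Planar or collinear loops give zero torsion.
    """
    pts = np.asarray(loop_path, float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    n = len(pts)
    if n < 4:
        raise ValueError("need at least 4 points for handedness")
    total = 0.0
    for k in range(n):
        p = [pts[(k + m) % n] for m in range(4)]
        tor = _torsion(*p)
        if tor is not None:
            total += tor
    if total > theta_min:
        return "right"
    if total < -theta_min:
        return "left"
    return "indeterminate"


def _torsion(p0, p1, p2, p3):
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None   # collinear triple: torsion undefined
    nb1 = np.linalg.norm(b1)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b1 / nb1))
    return float(np.degrees(np.arctan2(y, x)))


def analyze_topology(
    structure: StructureEnsemble,
    conn: DisulfideConnectivity,
    model: int = 0,
    theta_min: float = 30.0,
) -> TopologyReport:
    """Full topology report: lariats, threading matrix, DLK flag, handedness."""
    lariats = decompose_lariats(structure, conn, model=model)
    dlk, pairs, M = classify_dlk(lariats)
    hands = [loop_handedness(la.loop_path, theta_min=theta_min)
             for la in lariats]
    return TopologyReport(lariats=lariats, linking_matrix=M,
                          threading_pairs=pairs, dlk=dlk, handedness=hands)
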