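"""Ground-truth generators for every analysis stage.

Emulates, at coarse (Cα/Sγ) resolution, the inputs of a disulfide-rich
peptide study: compact self-avoiding chains with a planted disulfide
matching, NOE-like upper-bound distance restraints derived from a reference
structure plus multiplicative noise, αH shift profiles with β-strand
offsets, mirror images for chirality tests, and threaded/unthreaded lariat
toys for the topology machinery.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .connectivity import GRANULIN_PAIRS, DisulfideConnectivity
from .embedding import (
    CA_SG_TETHER,
    CLASH_DIST,
    SS_BOND,
    PairEnergy,
    coarse_topology,
    steric_pairs,
)
from .restraints import CA_CA_TRANS, DistanceRestraint, RestraintSet
from .sequence_mass import GRN_P4A, PeptideSequence, parse_sequence
from .shifts import RANDOM_COIL_HA, ShiftTable
from .structures import StructureEnsemble, residue_name

__all__ = [
    "GeneratorConfig",
    "build_structure",
    "make_restraints",
    "make_shifts",
    "mirror",
    "make_threaded_lariats",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic pipeline.

    Defaults emulate the 24-residue, six-cysteine granulin-derived peptide:
    granulin planted matching, 5 Å NOE-like restraint cutoff with 10%
    one-sided bound noise, and the two β-strand runs seen in its shift
    profile.
    """

    n_residues: int = 24
    cys_positions: tuple = (1, 8, 14, 15, 23, 24)
    connectivity: tuple = GRANULIN_PAIRS
    restraint_cutoff: float = 5.0      # Å
    bound_noise: float = 0.10          # fractional, one-sided
    decoy_restraint_fraction: float = 0.0
    strand_segments: tuple = ((11, 15), (19, 24))
    strand_offset: float = 0.3         # ppm added on strand residues
    coil_offset: float = -0.1          # ppm elsewhere
    shift_noise: float = 0.0           # ppm, Gaussian
    proline_cb_cg: float | dict = 3.0  # planted Cβ−Cγ difference(s), ppm
    sequence: str | None = None        # defaults to the granulin peptide
    seed: int = 0

    def __post_init__(self):
        for f in (self.bound_noise, self.decoy_restraint_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fractions must lie in [0,1], got {f}")
        for c in self.cys_positions:
            if not 1 <= c <= self.n_residues:
                raise ValueError(f"cysteine position {c} outside chain")

    def resolved_sequence(self) -> PeptideSequence:
        if self.sequence is not None:
            seq = parse_sequence(self.sequence)
        elif (self.n_residues == 24
              and tuple(self.cys_positions) == (1, 8, 14, 15, 23, 24)):
            seq = parse_sequence(GRN_P4A)
        else:
            letters = ["A"] * self.n_residues
            for c in self.cys_positions:
                letters[c - 1] = "C"
            seq = parse_sequence("".join(letters))
        if seq.cys_positions != tuple(self.cys_positions):
            raise ValueError("sequence cysteines disagree with cys_positions")
        return seq


# ---------------------------------------------------------------------------
# reference structures

def build_structure(config: GeneratorConfig, max_retries: int = 20) -> StructureEnsemble:
    """A compact self-avoiding Cα/Sγ chain with the planted disulfides.

    Random coordinates are relaxed under virtual-bond (3.8 ± 0.01 Å),
    Cα–Sγ tether (2.5 Å), planted Sγ–Sγ (2.05 ± 0.05 Å), excluded-volume
    (≥ 2.0 Å nonbonded) and spherical-confinement penalties; configurations
    failing the geometric checks are retried with a fresh sub-seed.
    """
    seq = config.resolved_sequence()
    conn = DisulfideConnectivity(config.connectivity)
    if not conn.is_perfect_on(seq.cys_positions):
        raise ValueError("connectivity is not a perfect matching on the cysteines")
    topo = coarse_topology(seq)

    for attempt in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 17, attempt)))
        x = _self_avoiding_walk(topo, rng)
        if x is None:
            continue
        # fold: close the planted disulfides and pack the coil to globular
        # density (wall radius ≈ 2.95·n^⅓ Å gives the Rg ≈ 6–7 Å and the
        # contact counts typical of folded disulfide-rich peptides of this
        # size), then tighten the covalent geometry
        confine_r = 2.95 * config.n_residues ** (1.0 / 3.0)
        for wb, wc, wconf in ((30.0, 5.0, 1.0), (400.0, 60.0, 5.0)):
            E = _chain_energy(topo, conn, bond_w=wb, clash_w=wc)
            fun = _with_confinement(E, confine_r, weight=wconf)
            res = minimize(fun, x.ravel(), jac=True, method="L-BFGS-B",
                           options=dict(maxiter=1500, maxcor=20))
            x = res.x.reshape(topo.n_atoms, 3)
            x -= x.mean(axis=0)
        if _geometry_ok(topo, conn, x):
            st = StructureEnsemble(
                res_num=topo.res_num, res_name=topo.res_name,
                atom_name=topo.atom_name, coords=x[None],
            )
            st.meta["connectivity"] = conn
            st.meta["sequence"] = seq.residues
            return st
    raise RuntimeError(
        f"could not realize connectivity {conn.pairs} after {max_retries} tries"
    )


def _self_avoiding_walk(topo, rng, max_step_tries: int = 60):
    """Random self-avoiding Cα walk (3.8 Å steps, 2.0 Å exclusion) with Sγ.

    Steps are drawn with a mild persistence bias so the walk resembles a
    polypeptide coil rather than a collapsed cluster; Sγ pseudo-atoms are
    placed 2.5 Å from their Cα in a clash-free random direction.  Returns
    None when the walk dead-ends (caller retries with a fresh sub-seed).
    """
    n = topo.n_res
    pts = [np.zeros(3)]
    prev_dir = None
    for _ in range(1, n):
        for _try in range(max_step_tries):
            d = rng.normal(size=3)
            if prev_dir is not None:
                d = d + 0.8 * prev_dir   # persistence
            d /= np.linalg.norm(d)
            cand = pts[-1] + CA_CA_TRANS * d
            if all(np.linalg.norm(cand - p) >= CLASH_DIST for p in pts[:-1]):
                break
        else:
            return None
        prev_dir = d
        pts.append(cand)
    ca = np.asarray(pts)
    xyz = np.zeros((topo.n_atoms, 3))
    xyz[:n] = ca
    for c in topo.cys_positions:
        base = ca[c - 1]
        for _try in range(max_step_tries):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = base + CA_SG_TETHER * d
            others = np.vstack([ca[np.arange(n) != c - 1]])
            if np.min(np.linalg.norm(others - cand, axis=1)) >= CLASH_DIST:
                break
        xyz[topo.atom_of[(c, "SG")]] = cand
    return xyz


def _chain_energy(topo, conn, bond_w, clash_w) -> PairEnergy:
    E = PairEnergy()
    for r in range(2, topo.n_res + 1):
        E.add_equality(topo.atom_of[(r - 1, "CA")], topo.atom_of[(r, "CA")],
                       CA_CA_TRANS, bond_w)
    for c in topo.cys_positions:
        E.add_equality(topo.atom_of[(c, "CA")], topo.atom_of[(c, "SG")],
                       CA_SG_TETHER, bond_w)
    for a, b in conn.pairs:
        E.add_equality(topo.atom_of[(a, "SG")], topo.atom_of[(b, "SG")],
                       SS_BOND, bond_w)
    for i, j, floor in steric_pairs(topo, conn):
        E.add_lower(i, j, floor, clash_w)
    return E.freeze(topo.n_atoms)


def _with_confinement(E: PairEnergy, radius: float, weight: float):
    def fun(x):
        e, g = E(x)
        xyz = x.reshape(-1, 3)
        r = np.linalg.norm(xyz, axis=1)
        excess = np.maximum(0.0, r - radius)
        e += weight * np.sum(excess ** 2)
        mask = excess > 0
        gg = g.reshape(-1, 3)
        gg[mask] += (2.0 * weight * excess[mask] / np.maximum(r[mask], 1e-9)
                     )[:, None] * xyz[mask]
        return e, gg.ravel()
    return fun


def _geometry_ok(topo, conn, xyz, bond_tol=0.01, ss_tol=0.05) -> bool:
    for r in range(2, topo.n_res + 1):
        d = np.linalg.norm(xyz[topo.atom_of[(r - 1, "CA")]]
                           - xyz[topo.atom_of[(r, "CA")]])
        if abs(d - CA_CA_TRANS) > bond_tol:
            return False
    for a, b in conn.pairs:
        d = np.linalg.norm(xyz[topo.atom_of[(a, "SG")]]
                           - xyz[topo.atom_of[(b, "SG")]])
        if abs(d - SS_BOND) > ss_tol:
            return False
    bonded = {(min(i, j), max(i, j)) for i, j in _bonded_pairs(topo, conn)}
    n = topo.n_atoms
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in bonded and d[i, j] < CLASH_DIST - 1e-3:
                return False
    return True


def _bonded_pairs(topo, conn):
    for r in range(2, topo.n_res + 1):
        yield topo.atom_of[(r - 1, "CA")], topo.atom_of[(r, "CA")]
    for c in topo.cys_positions:
        yield topo.atom_of[(c, "CA")], topo.atom_of[(c, "SG")]
    for a, b in conn.pairs:
        yield topo.atom_of[(a, "SG")], topo.atom_of[(b, "SG")]


# ---------------------------------------------------------------------------
# restraints

def make_restraints(structure: StructureEnsemble, config: GeneratorConfig) -> RestraintSet:
    """NOE-like upper bounds from a reference structure.

    Every Cα/Sγ pair with sequence separation ≥ 2 and distance ≤ cutoff gets
    an upper bound d·(1 + noise·u), u ~ U(0,1).  The Sγ–Sγ bounds that would
    define the planted disulfides are excluded — the connectivity engine must
    infer them.  With ``decoy_restraint_fraction`` f > 0, round(f·n) tight
    random far-pair bounds are added; at f = 1 the set is pure decoys of the
    same size (noise mode).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 29)))
    conn_pairs = {tuple(sorted(p)) for p in config.connectivity}
    xyz = structure.coords[0]
    n_at = structure.n_atoms
    real, far = [], []
    for i in range(n_at):
        for j in range(i + 1, n_at):
            ri, rj = int(structure.res_num[i]), int(structure.res_num[j])
            if abs(ri - rj) < 2:
                continue
            ai, aj = str(structure.atom_name[i]), str(structure.atom_name[j])
            if (ai == aj == "SG"
                    and tuple(sorted((ri, rj))) in conn_pairs):
                continue
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d <= config.restraint_cutoff:
                u = rng.uniform()
                real.append(DistanceRestraint(
                    ri, ai, rj, aj, d * (1.0 + config.bound_noise * u)))
            else:
                far.append((ri, ai, rj, aj))
    f = config.decoy_restraint_fraction
    decoys = []
    if f > 0 and far:
        n_decoy = len(real) if f >= 1.0 else int(round(f * len(real)))
        picks = rng.choice(len(far), size=min(n_decoy, len(far)), replace=False)
        for k in picks:
            ri, ai, rj, aj = far[int(k)]
            decoys.append(DistanceRestraint(
                ri, ai, rj, aj, float(rng.uniform(3.0, 4.5))))
    distance = decoys if f >= 1.0 else real + decoys
    return RestraintSet(distance=distance)


# ---------------------------------------------------------------------------
# chemical shifts

def make_shifts(config: GeneratorConfig) -> ShiftTable:
    """A synthetic αH shift table with planted strand offsets.

    αH = random coil + ``strand_offset`` on strand residues, ``coil_offset``
    elsewhere, plus Gaussian noise; prolines also get Cβ/Cγ shifts realizing
    the configured Cβ−Cγ difference.
    """
    seq = config.resolved_sequence()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 43)))
    in_strand = set()
    for lo, hi in config.strand_segments:
        if not (1 <= lo <= hi <= config.n_residues):
            raise ValueError(f"strand segment ({lo},{hi}) outside chain")
        in_strand.update(range(lo, hi + 1))
    table = ShiftTable()
    for res in seq.numbering:
        aa = seq[res]
        base = RANDOM_COIL_HA[aa]
        offset = config.strand_offset if res in in_strand else config.coil_offset
        value = base + offset + rng.normal(scale=config.shift_noise)
        name = residue_name(aa)
        if aa == "G":
            table.set(res, name, "HA2", value)
            table.set(res, name, "HA3", value)
        else:
            table.set(res, name, "HA", value)
        if aa == "P":
            delta = (config.proline_cb_cg.get(res, 3.0)
                     if isinstance(config.proline_cb_cg, dict)
                     else config.proline_cb_cg)
            table.set(res, name, "CB", 32.0)
            table.set(res, name, "CG", 32.0 - delta)
    return table


# ---------------------------------------------------------------------------
# geometry toys

def mirror(structure: StructureEnsemble) -> StructureEnsemble:
    """Mirror image: reflect every model through the x = 0 plane."""
    coords = structure.coords.copy()
    coords[..., 0] *= -1.0
    out = structure.with_coords(coords)
    out.meta["mirrored"] = not structure.meta.get("mirrored", False)
    return out


def make_threaded_lariats(threaded: bool, seed: int = 0) -> tuple[StructureEnsemble, dict]:
    """A two-lariat toy chain, Hopf-threaded or separated.

    One chain carries two disulfide-closed loops (circles of ~4.8 Å radius
    discretized at virtual-bond spacing).  ``threaded=True`` places the
    loops as a Hopf pair (each loop passes through the other), the geometry
    of mutually threading lariats; ``False`` places them far apart.  Returns
    the structure and a ground-truth dict with the connectivity and the
    expected DLK flag.  Coordinates get a deterministic 0.01 Å jitter per
    seed so repeated builds are reproducible but distinct across seeds.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 57)))
    r = 4.8
    # loop A: circle in the z=0 plane, closure gap at 180° so the segment
    # crossing loop B's disc (near 0°) is real backbone, not the S-S bridge
    ang_a = np.radians(np.linspace(197.0, 163.0 + 360.0, 8))
    # loop B: circle in the y=0 plane with its gap at 0° (away from loop A)
    ang_b = np.radians(np.linspace(17.0, 343.0, 8))
    center_b = np.array([r, 0.0, 0.0]) if threaded else np.array([3.0 * r, 0.0, 0.0])

    loop_a = np.stack([r * np.cos(ang_a), r * np.sin(ang_a),
                       np.zeros_like(ang_a)], axis=1)
    loop_b = center_b + np.stack([r * np.cos(ang_b), np.zeros_like(ang_b),
                                  r * np.sin(ang_b)], axis=1)

    # N tail: radially outward from loop A, out of both loop planes
    dir_a = loop_a[0] / np.linalg.norm(loop_a[0])
    tail_n = [loop_a[0] + dir_a * 7.6 + np.array([0, 0, 3.0]),
              loop_a[0] + dir_a * 3.8 + np.array([0, 0, 1.5])]
    # connector from loop A end to loop B start, routed out of plane
    w1 = loop_a[-1] + np.array([0.0, -3.0, 3.5])
    w2 = loop_b[0] + np.array([0.0, -3.0, 3.5])
    # C tail: radially outward from loop B center, +z side
    dir_b = (loop_b[-1] - center_b) / np.linalg.norm(loop_b[-1] - center_b)
    tail_c = [loop_b[-1] + dir_b * 3.8 + np.array([0, 3.0, 0.0]),
              loop_b[-1] + dir_b * 7.6 + np.array([0, 4.5, 0.0])]

    ca = np.vstack(tail_n + [loop_a, w1[None], w2[None], loop_b] + tail_c)
    ca = ca + rng.normal(scale=0.01, size=ca.shape)
    n_res = len(ca)
    na = len(ang_a)
    cys = (3, 3 + na - 1, 3 + na + 2, 3 + na + len(ang_b) + 1)
    conn = DisulfideConnectivity(((cys[0], cys[1]), (cys[2], cys[3])))

    res_num, res_name, atom_name, coords = [], [], [], []
    for i, p in enumerate(ca, start=1):
        res_num.append(i)
        res_name.append("CYS" if i in cys else "GLY")
        atom_name.append("CA")
        coords.append(p)
    # Sγ midway between the bonded Cα pair ends so the bridge closes cleanly
    for a, b in conn.pairs:
        pa, pb = ca[a - 1], ca[b - 1]
        mid = 0.5 * (pa + pb)
        for cpos, p in ((a, pa), (b, pb)):
            res_num.append(cpos)
            res_name.append("CYS")
            atom_name.append("SG")
            coords.append(p + 0.45 * (mid - p))
    structure = StructureEnsemble(
        res_num=np.asarray(res_num), res_name=np.asarray(res_name),
        atom_name=np.asarray(atom_name), coords=np.asarray(coords)[None],
    )
    truth = dict(connectivity=conn, dlk=threaded, n_residues=n_res,
                 threaded=threaded)
    structure.meta.update(truth)
    return structure, truth
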