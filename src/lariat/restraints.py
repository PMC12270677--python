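"""Experimental-style restraints and target-function scoring.

Distance upper bounds (NOE-like, optionally flagged as hydrogen bonds) and
dihedral-angle ranges are held in a :class:`RestraintSet`.  The target
function follows the squared-excess family used by NMR structure-calculation
programs:

    TF = Σ max(0, d − upper)²  +  w · Σ (angle excess, rad)²

Violations are counted only where the excess exceeds a reporting cutoff
(default 0.2 Å for distances, 2.5° for angles), matching the convention of
restraint-violation plots.

File dialects: CYANA-style ``.upl`` (upper-limit distance) and ``.aco``
(angle constraint) columns, plus an equivalent TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .sequence_mass import PeptideSequence
from .structures import StructureEnsemble

__all__ = [
    "DistanceRestraint",
    "DihedralRestraint",
    "RestraintSet",
    "ScoreReport",
    "score_structure",
    "project_restraints",
    "proline_omega_toggle",
    "read_upl",
    "write_upl",
    "read_aco",
    "write_aco",
    "read_restraints_tsv",
    "write_restraints_tsv",
]

COARSE_ATOMS = ("CA", "SG")
#: Extra slack added when a non-coarse atom reference is projected onto Cα.
PROJECTION_PAD = 1.5
#: Cα(i−1)–Cα(i) virtual bond length across a trans / cis peptide bond (Å).
CA_CA_TRANS = 3.80
CA_CA_CIS = 2.90


@dataclass(frozen=True)
class DistanceRestraint:
    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    upper: float          # Å
    hbond: bool = False

    def __post_init__(self):
        if self.upper <= 0:
            raise ValueError(f"upper bound must be positive, got {self.upper}")


@dataclass(frozen=True)
class DihedralRestraint:
    res: int
    angle: str            # phi | psi | omega | chi1
    lower: float          # degrees in (-180, 180], wraparound allowed
    upper: float

    _ANGLES = ("phi", "psi", "omega", "chi1")

    def __post_init__(self):
        if self.angle not in self._ANGLES:
            raise ValueError(f"unknown angle {self.angle!r}")
        for v in (self.lower, self.upper):
            if not -180.0 < v <= 180.0:
                raise ValueError(f"angle bound {v} outside (-180, 180]")


@dataclass
class RestraintSet:
    distance: list[DistanceRestraint] = field(default_factory=list)
    dihedral: list[DihedralRestraint] = field(default_factory=list)

    def __len__(self):
        return len(self.distance) + len(self.dihedral)


@dataclass
class ScoreReport:
    """Target function and violation counts of one structure/connectivity."""

    connectivity: object | None
    target_function: float
    n_distance_violations: int
    n_angle_violations: int
    best_seed: int | None = None
    max_distance_excess: float = 0.0
    converged: bool = True

    @property
    def n_violations(self) -> int:
        return self.n_distance_violations + self.n_angle_violations


# ---------------------------------------------------------------------------
# geometry helpers

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


_DIHEDRAL_ATOMS = {
    # angle -> ((residue offset, atom name) x 4)
    "phi": ((-1, "C"), (0, "N"), (0, "CA"), (0, "C")),
    "psi": ((0, "N"), (0, "CA"), (0, "C"), (1, "N")),
    "omega": ((-1, "CA"), (-1, "C"), (0, "N"), (0, "CA")),
    "chi1": ((0, "N"), (0, "CA"), (0, "CB"), (0, "SG")),
}


def _angle_excess_deg(value: float, lower: float, upper: float) -> float:
    """Shortest angular distance (deg) from ``value`` to the arc [lower, upper].

    The allowed arc runs counterclockwise from lower to upper (wraparound
    allowed); zero if inside.
    """
    width = (upper - lower) % 360.0
    rel = (value - lower) % 360.0
    if rel <= width:
        return 0.0
    # outside: distance to nearer boundary along the circle
    return min(rel - width, 360.0 - rel)


# ---------------------------------------------------------------------------
# scoring

def score_structure(
    structure: StructureEnsemble,
    restraints: RestraintSet,
    model: int = 0,
    dist_cutoff: float = 0.2,
    angle_cutoff: float = 2.5,
    angle_weight: float = 1.0,
    connectivity=None,
) -> ScoreReport:
    """Target function and violation counts for one model.

    Every restraint must resolve to atoms present in the structure; for an
    omega restraint on a Cα-only structure the cis/trans state is evaluated
    through the Cα(i−1)–Cα(i) virtual-bond proxy (3.8 Å trans, 2.9 Å cis,
    ±0.1 Å slack).
    """
    xyz = structure.coords[model]
    tf = 0.0
    n_dviol = 0
    n_aviol = 0
    max_excess = 0.0
    for r in restraints.distance:
        try:
            i = structure.atom_index(r.res_i, r.atom_i)
            j = structure.atom_index(r.res_j, r.atom_j)
        except KeyError as exc:
            raise ValueError(f"unresolvable restraint {r}: {exc}") from None
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        excess = max(0.0, d - r.upper)
        tf += excess * excess
        max_excess = max(max_excess, excess)
        if excess > dist_cutoff:
            n_dviol += 1
    for r in restraints.dihedral:
        value = _resolve_dihedral(structure, xyz, r)
        if value is None:
            # Cα-level omega proxy: distance deviation scored like a distance
            i = structure.atom_index(r.res - 1, "CA")
            j = structure.atom_index(r.res, "CA")
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            target = CA_CA_CIS if _is_cis_range(r) else CA_CA_TRANS
            excess = max(0.0, abs(d - target) - 0.1)
            tf += excess * excess
            if excess > dist_cutoff:
                n_dviol += 1
            continue
        excess = _angle_excess_deg(value, r.lower, r.upper)
        tf += angle_weight * np.radians(excess) ** 2
        if excess > angle_cutoff:
            n_aviol += 1
    return ScoreReport(
        connectivity=connectivity,
        target_function=tf,
        n_distance_violations=n_dviol,
        n_angle_violations=n_aviol,
        max_distance_excess=max_excess,
    )


def _is_cis_range(r: DihedralRestraint) -> bool:
    """True if an omega range is centred nearer 0° than 180°."""
    width = (r.upper - r.lower) % 360.0
    centre = (r.lower + width / 2.0 + 180.0) % 360.0 - 180.0
    return abs(centre) < 90.0


def _resolve_dihedral(structure, xyz, r: DihedralRestraint):
    pts = []
    for off, name in _DIHEDRAL_ATOMS[r.angle]:
        try:
            pts.append(xyz[structure.atom_index(r.res + off, name)])
        except KeyError:
            if r.angle == "omega" and _has_only_coarse(structure):
                return None
            raise ValueError(
                f"unresolvable dihedral restraint {r}: atom {name} "
                f"of residue {r.res + off} missing"
            ) from None
    return dihedral_angle(*pts)


def _has_only_coarse(structure) -> bool:
    return bool(np.all(np.isin(structure.atom_name, COARSE_ATOMS)))


# ---------------------------------------------------------------------------
# projection to the coarse Cα/Sγ representation

def project_restraints(restraints: RestraintSet, seq: PeptideSequence) -> RestraintSet:
    """Project restraints onto the Cα/Sγ coarse representation.

    Distance references to atoms other than Cα/Sγ are moved to the residue's
    Cα with a +1.5 Å pad on the bound.  Omega dihedral restraints become
    Cα(i−1)–Cα(i) virtual-bond information handled by the embedder; phi/psi/
    chi1 restraints carry no Cα-level signal and are dropped.
    """
    out = RestraintSet()
    for r in restraints.distance:
        ai, aj, pad = r.atom_i, r.atom_j, 0.0
        if ai not in COARSE_ATOMS:
            ai, pad = "CA", pad + PROJECTION_PAD
        if aj not in COARSE_ATOMS:
            aj, pad = "CA", pad + PROJECTION_PAD
        if r.res_i == r.res_j and ai == aj:
            continue  # collapsed intra-residue restraint carries no signal
        out.distance.append(
            DistanceRestraint(r.res_i, ai, r.res_j, aj, r.upper + pad, r.hbond)
        )
    for r in restraints.dihedral:
        if r.angle == "omega":
            out.dihedral.append(r)
    return out


def proline_omega_toggle(
    restraints: RestraintSet,
    residue: int,
    form: str,
    seq: PeptideSequence | None = None,
    tol: float = 10.0,
) -> RestraintSet:
    """Return a copy with the omega restraint of a proline set to cis or trans.

    trans: ω in [180−tol, −180+tol] (wrapping through 180°); cis: ω in
    [−tol, +tol].  Any existing omega restraint on that residue is replaced.
    """
    if form not in ("cis", "trans"):
        raise ValueError(f"form must be 'cis' or 'trans', got {form!r}")
    if seq is not None and seq[residue] != "P":
        raise ValueError(f"residue {residue} is {seq[residue]}, not proline")
    if form == "trans":
        lower, upper = 180.0 - tol, -180.0 + tol  # wraps through ±180°
    else:
        lower, upper = -tol, tol
    new = RestraintSet(
        distance=list(restraints.distance),
        dihedral=[d for d in restraints.dihedral
                  if not (d.res == residue and d.angle == "omega")],
    )
    new.dihedral.append(DihedralRestraint(residue, "omega", lower, upper))
    return new


# ---------------------------------------------------------------------------
# file I/O (CYANA-style dialects and TSV)

def read_upl(path) -> list[DistanceRestraint]:
    """Read a CYANA-style .upl file: resnum resname atom resnum resname atom upper."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(tok)}")
            out.append(
                DistanceRestraint(
                    res_i=int(tok[0]), atom_i=tok[2],
                    res_j=int(tok[3]), atom_j=tok[5],
                    upper=float(tok[6]),
                )
            )
    return out


def write_upl(restraints: Iterable[DistanceRestraint], path, seq: PeptideSequence | None = None):
    from .structures import residue_name

    def rname(res):
        return residue_name(seq[res]) if seq is not None else "UNK"

    with open(path, "w") as fh:
        for r in restraints:
            fh.write(
                f"{r.res_i:4d} {rname(r.res_i):>4s} {r.atom_i:<4s} "
                f"{r.res_j:4d} {rname(r.res_j):>4s} {r.atom_j:<4s} "
                f"{r.upper:8.2f}\n"
            )


def read_aco(path) -> list[DihedralRestraint]:
    """Read a CYANA-style .aco file: resnum resname angle lower upper."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(tok)}")
            out.append(
                DihedralRestraint(
                    res=int(tok[0]), angle=tok[2].lower(),
                    lower=float(tok[3]), upper=float(tok[4]),
                )
            )
    return out


def write_aco(restraints: Iterable[DihedralRestraint], path, seq: PeptideSequence | None = None):
    from .structures import residue_name

    def rname(res):
        return residue_name(seq[res]) if seq is not None else "UNK"

    with open(path, "w") as fh:
        for r in restraints:
            fh.write(
                f"{r.res:4d} {rname(r.res):>4s} {r.angle.upper():<6s} "
                f"{r.lower:8.1f} {r.upper:8.1f}\n"
            )


def read_restraints_tsv(path) -> RestraintSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    rset = RestraintSet()
    for _, row in df.iterrows():
        if row["kind"] == "distance":
            rset.distance.append(
                DistanceRestraint(
                    int(row["res_i"]), str(row["atom_i"]),
                    int(row["res_j"]), str(row["atom_j"]),
                    float(row["upper"]), bool(row.get("hbond", False)),
                )
            )
        elif row["kind"] == "dihedral":
            rset.dihedral.append(
                DihedralRestraint(
                    int(row["res_i"]), str(row["atom_i"]).lower(),
                    float(row["lower"]), float(row["upper"]),
                )
            )
        else:
            raise ValueError(f"unknown restraint kind {row['kind']!r}")
    return rset


def write_restraints_tsv(rset: RestraintSet, path):
    import pandas as pd

    rows = []
    for r in rset.distance:
        rows.append(dict(kind="distance", res_i=r.res_i, atom_i=r.atom_i,
                         res_j=r.res_j, atom_j=r.atom_j,
                         lower=np.nan, upper=r.upper, hbond=r.hbond))
    for r in rset.dihedral:
        rows.append(dict(kind="dihedral", res_i=r.res, atom_i=r.angle,
                         res_j=np.nan, atom_j="", lower=r.lower,
                         upper=r.upper, hbond=False))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
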