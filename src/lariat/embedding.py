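"""Coarse-grained restraint embedding and disulfide-connectivity ranking.

This is a desk-scale analogue of the structure-calculation step used to infer
disulfide connectivity by exhaustion: each candidate perfect matching of the
cysteines is imposed as Sγ–Sγ bond constraints on a Cα/Sγ chain model, the
chain is embedded under the experimental-style distance restraints by penalty
minimization, and candidates are ranked by the resulting target function and
violation counts.  The true connectivity is the one that can satisfy the
restraints; wrong matchings force incompatible Sγ contacts and score high.

Representation: one Cα pseudo-atom per residue (virtual bond 3.8 Å) plus one
Sγ pseudo-atom per cysteine tethered 2.5 Å from its Cα; disulfides are
Sγ–Sγ = 2.05 Å constraints.  Minimization is multi-start: the first start is
a distance-geometry (shortest-path metric MDS) embedding, the rest are random
coils; each start is polished with L-BFGS using analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import DisulfideConnectivity, enumerate_connectivities
from .restraints import (
    CA_CA_CIS,
    CA_CA_TRANS,
    RestraintSet,
    ScoreReport,
    _is_cis_range,
    project_restraints,
    score_structure,
)
from .sequence_mass import PeptideSequence
from .structures import StructureEnsemble, residue_name

__all__ = ["ScoringConfig", "ConnectivityCall", "embed", "rank_connectivities",
           "coarse_topology", "PairEnergy"]

SS_BOND = 2.05
CA_SG_TETHER = 2.5
#: hard lower bound on any nonbonded pair (chain self-avoidance guarantee)
CLASH_DIST = 2.0
#: soft van-der-Waals-like contact floors of the coarse model: Cα beads carry
#: side-chain volume (nonbonded Cα–Cα in folded proteins stays ≳ 4 Å); Sγ is
#: a bare sulfur
STERIC_CA_CA = 4.0
STERIC_SG = 3.0


@dataclass
class ScoringConfig:
    """Tunable knobs of the embedding/ranking engine."""

    n_seeds: int = 20
    seed: int = 0
    dist_cutoff: float = 0.2       # Å, violation reporting
    angle_cutoff: float = 2.5      # degrees
    angle_weight: float = 1.0      # rad⁻² Å² weight of angle TF term
    ratio_threshold: float = 3.0   # winner-vs-runner-up TF factor to assign
    tf_floor: float = 1e-3         # Å², below this TF values are "zero"
    tf_ceiling: float = 100.0      # Å², above this an embed is unconverged
    maxiter: int = 400
    bond_weight: float = 30.0
    clash_weight: float = 5.0


@dataclass
class ConnectivityCall:
    """Outcome of the exhaustive connectivity ranking."""

    verdict: str                           # 'assigned' | 'undetermined'
    winner: DisulfideConnectivity | None
    ratio_to_runner_up: float


# ---------------------------------------------------------------------------
# chain topology and the penalty function

@dataclass
class CoarseTopology:
    """Atom layout of the Cα/Sγ model and its fixed interaction lists."""

    n_res: int
    cys_positions: tuple[int, ...]
    atom_of: dict = field(default_factory=dict)   # (res, name) -> index
    res_num: np.ndarray = None
    res_name: np.ndarray = None
    atom_name: np.ndarray = None

    @property
    def n_atoms(self) -> int:
        return self.n_res + len(self.cys_positions)


def coarse_topology(seq: PeptideSequence) -> CoarseTopology:
    n = len(seq)
    cys = seq.cys_positions
    topo = CoarseTopology(n_res=n, cys_positions=cys)
    res_num, res_name, atom_name = [], [], []
    for r in range(1, n + 1):
        topo.atom_of[(r, "CA")] = len(res_num)
        res_num.append(r)
        res_name.append(residue_name(seq[r]))
        atom_name.append("CA")
    for c in cys:
        topo.atom_of[(c, "SG")] = len(res_num)
        res_num.append(c)
        res_name.append("CYS")
        atom_name.append("SG")
    topo.res_num = np.asarray(res_num)
    topo.res_name = np.asarray(res_name)
    topo.atom_name = np.asarray(atom_name)
    return topo


class PairEnergy:
    """Vectorized pairwise penalty: harmonic bonds, upper bounds, clashes.

    Terms:
      * equality  w·(d − d0)²        (virtual bonds, tethers, S–S)
      * upper     w·max(0, d − u)²   (restraints)
      * lower     w·max(0, l − d)²   (excluded volume)
    """

    def __init__(self):
        self._eq = []     # (i, j, d0, w)
        self._up = []     # (i, j, u, w)
        self._lo = []     # (i, j, l, w)

    def add_equality(self, i, j, d0, w):
        self._eq.append((i, j, d0, w))

    def add_upper(self, i, j, u, w=1.0):
        self._up.append((i, j, u, w))

    def add_lower(self, i, j, l, w):
        self._lo.append((i, j, l, w))

    def freeze(self, n_atoms: int):
        self.n_atoms = n_atoms

        def pack(rows):
            if not rows:
                return (np.zeros(0, int), np.zeros(0, int),
                        np.zeros(0), np.zeros(0))
            a = np.asarray(rows, dtype=float)
            return (a[:, 0].astype(int), a[:, 1].astype(int), a[:, 2], a[:, 3])

        self.eq_i, self.eq_j, self.eq_d0, self.eq_w = pack(self._eq)
        self.up_i, self.up_j, self.up_u, self.up_w = pack(self._up)
        self.lo_i, self.lo_j, self.lo_l, self.lo_w = pack(self._lo)
        self.all_i = np.concatenate([self.eq_i, self.up_i, self.lo_i])
        self.all_j = np.concatenate([self.eq_j, self.up_j, self.lo_j])
        return self

    def __call__(self, x: np.ndarray):
        """Energy and gradient; ``x`` is flat (n_atoms*3,)."""
        xyz = x.reshape(self.n_atoms, 3)
        dvec = xyz[self.all_i] - xyz[self.all_j]
        d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        d = np.maximum(d, 1e-8)
        ne, nu = len(self.eq_i), len(self.up_i)
        de, du, dl = d[:ne], d[ne:ne + nu], d[ne + nu:]
        exc_e = de - self.eq_d0
        exc_u = np.maximum(0.0, du - self.up_u)
        exc_l = np.maximum(0.0, self.lo_l - dl)
        energy = (np.sum(self.eq_w * exc_e**2)
                  + np.sum(self.up_w * exc_u**2)
                  + np.sum(self.lo_w * exc_l**2))
        # dE/dd for each pair
        dEdd = np.concatenate([
            2.0 * self.eq_w * exc_e,
            2.0 * self.up_w * exc_u,
            -2.0 * self.lo_w * exc_l,
        ])
        f = (dEdd / d)[:, None] * dvec
        grad = np.zeros_like(xyz)
        np.add.at(grad, self.all_i, f)
        np.add.at(grad, self.all_j, -f)
        return energy, grad.ravel()


def _build_energy(
    topo: CoarseTopology,
    projected: RestraintSet,
    connectivity: DisulfideConnectivity | None,
    config: ScoringConfig,
) -> PairEnergy:
    E = PairEnergy()
    wb = config.bond_weight
    # virtual Cα–Cα bonds; an omega restraint overrides the bond length
    bond_len = {r: CA_CA_TRANS for r in range(2, topo.n_res + 1)}
    for dr in projected.dihedral:
        if dr.angle == "omega" and 2 <= dr.res <= topo.n_res:
            bond_len[dr.res] = CA_CA_CIS if _is_cis_range(dr) else CA_CA_TRANS
    for r in range(2, topo.n_res + 1):
        i, j = topo.atom_of[(r - 1, "CA")], topo.atom_of[(r, "CA")]
        E.add_equality(i, j, bond_len[r], wb)
    for c in topo.cys_positions:
        i, j = topo.atom_of[(c, "CA")], topo.atom_of[(c, "SG")]
        E.add_equality(i, j, CA_SG_TETHER, wb)
    if connectivity is not None:
        for a, b in connectivity.pairs:
            i, j = topo.atom_of[(a, "SG")], topo.atom_of[(b, "SG")]
            E.add_equality(i, j, SS_BOND, wb)
    for dr in projected.distance:
        i = topo.atom_of.get((dr.res_i, dr.atom_i))
        j = topo.atom_of.get((dr.res_j, dr.atom_j))
        if i is None or j is None:
            raise ValueError(f"restraint {dr} not resolvable at Cα/Sγ level")
        E.add_upper(i, j, dr.upper, 1.0)
    for i, j, floor in steric_pairs(topo, connectivity):
        E.add_lower(i, j, floor, config.clash_weight)
    return E.freeze(topo.n_atoms)


def steric_pairs(topo: CoarseTopology, connectivity=None):
    """Soft excluded-volume pairs ``(i, j, contact floor Å)`` of the model.

    Covalently linked pairs (chain neighbours, tethers, and all four atoms
    of an imposed disulfide unit) are excluded; everything else gets the
    Cα–Cα or Sγ contact floor.
    """
    excluded = set()

    def exclude(i, j):
        excluded.add((min(i, j), max(i, j)))

    for r in range(2, topo.n_res + 1):
        exclude(topo.atom_of[(r - 1, "CA")], topo.atom_of[(r, "CA")])
    for c in topo.cys_positions:
        exclude(topo.atom_of[(c, "CA")], topo.atom_of[(c, "SG")])
    if connectivity is not None:
        for a, b in connectivity.pairs:
            for p, q in (("SG", "SG"), ("CA", "SG"), ("SG", "CA")):
                exclude(topo.atom_of[(a, p)], topo.atom_of[(b, q)])
    is_sg = topo.atom_name == "SG"
    n = topo.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            floor = STERIC_SG if (is_sg[i] or is_sg[j]) else STERIC_CA_CA
            yield i, j, floor


def _mds_init(topo: CoarseTopology, E: PairEnergy, rng) -> np.ndarray:
    """Distance-geometry start: metric MDS on shortest-path distances."""
    n = topo.n_atoms
    rows = np.concatenate([E.eq_i, E.up_i])
    cols = np.concatenate([E.eq_j, E.up_j])
    vals = np.concatenate([E.eq_d0, E.up_u])
    g = csr_matrix((vals, (rows, cols)), shape=(n, n))
    D = shortest_path(g, directed=False)
    D[~np.isfinite(D)] = np.nanmax(D[np.isfinite(D)]) if np.isfinite(D).any() else 10.0
    # classical MDS
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:3]
    lam = np.clip(w[idx], 0.0, None)
    x = v[:, idx] * np.sqrt(lam)
    return (x + rng.normal(scale=0.3, size=x.shape)).ravel()


def _random_init(topo: CoarseTopology, rng) -> np.ndarray:
    radius = 3.0 * topo.n_res ** (1.0 / 3.0)
    return rng.normal(scale=radius / 2.0, size=(topo.n_atoms, 3)).ravel()


def _to_structure(topo: CoarseTopology, models: np.ndarray) -> StructureEnsemble:
    return StructureEnsemble(
        res_num=topo.res_num,
        res_name=topo.res_name,
        atom_name=topo.atom_name,
        coords=models,
    )


def embed(
    restraints: RestraintSet,
    connectivity: DisulfideConnectivity | None,
    seq: PeptideSequence,
    config: ScoringConfig | None = None,
) -> tuple[StructureEnsemble, ScoreReport]:
    """Embed the chain under restraints with a candidate connectivity imposed.

    Runs ``config.n_seeds`` starts (one distance-geometry, the rest random
    coils), minimizes the penalty with L-BFGS, and returns the models sorted
    by target function together with the best model's :class:`ScoreReport`.
    Stops early once a start reaches an (unimprovable) zero target function.
    """
    config = config or ScoringConfig()
    projected = project_restraints(restraints, seq)
    topo = coarse_topology(seq)
    E = _build_energy(topo, projected, connectivity, config)
    # the steric-free pre-stage lets the chain pass through itself (no
    # topological traps); the full potential then resolves clashes
    E_soft = _build_energy(topo, projected, connectivity,
                           replace(config, clash_weight=0.0))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    models, tfs, reports = [], [], []
    best_x = None
    for s in range(max(1, config.n_seeds)):
        # start portfolio: distance-geometry first, then alternate fresh
        # random coils with basin-hopping perturbations of the best so far
        if s == 0:
            x = _mds_init(topo, E, rng)
        elif s % 2 == 1 or best_x is None:
            x = _random_init(topo, rng)
        else:
            x = best_x + rng.normal(scale=1.5, size=best_x.shape)
        x = minimize(E_soft, x, jac=True, method="L-BFGS-B",
                     options=dict(maxiter=config.maxiter // 2, maxcor=20)).x
        x = minimize(E, x, jac=True, method="L-BFGS-B",
                     options=dict(maxiter=config.maxiter, maxcor=20)).x
        xyz = x.reshape(topo.n_atoms, 3)
        st = _to_structure(topo, xyz[None])
        rep = score_structure(
            st, projected,
            dist_cutoff=config.dist_cutoff,
            angle_cutoff=config.angle_cutoff,
            angle_weight=config.angle_weight,
            connectivity=connectivity,
        )
        rep.best_seed = s
        models.append(xyz)
        tfs.append(rep.target_function)
        reports.append(rep)
        if best_x is None or rep.target_function <= min(tfs):
            best_x = x
        if rep.target_function < config.tf_floor and rep.n_violations == 0:
            break
    order = np.argsort(tfs, kind="stable")
    best = reports[order[0]]
    best.converged = best.target_function <= config.tf_ceiling
    ensemble = _to_structure(topo, np.stack([models[k] for k in order]))
    return ensemble, best


def rank_connectivities(
    restraints: RestraintSet,
    seq: PeptideSequence,
    config: ScoringConfig | None = None,
) -> tuple[list[ScoreReport], ConnectivityCall]:
    """Score every disulfide connectivity and call the assignment.

    Reports are sorted by ascending target function (ties: fewer violations,
    then canonical pair order).  The verdict is ``assigned`` only if the
    winner has zero violations and its target function is lower than the
    runner-up's by at least ``config.ratio_threshold``; otherwise
    ``undetermined`` (which also covers the no-information case where every
    candidate scores an effectively zero target function).
    """
    config = config or ScoringConfig()
    cys = seq.cys_positions
    reports = []
    for conn in enumerate_connectivities(cys):
        _, rep = embed(restraints, conn, seq, config)
        reports.append(rep)
    reports.sort(key=lambda r: (r.target_function, r.n_violations,
                                r.connectivity.pairs))
    winner, runner = reports[0], reports[1]
    ratio = runner.target_function / max(winner.target_function, config.tf_floor)
    assigned = (winner.n_violations == 0
                and ratio >= config.ratio_threshold)
    call = ConnectivityCall(
        verdict="assigned" if assigned else "undetermined",
        winner=winner.connectivity if assigned else None,
        ratio_to_runner_up=ratio,
    )
    return reports, call
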