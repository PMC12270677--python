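"""Rigid-body superposition (Kabsch), subset RMSD, ensemble RMSF/RMSD.

The rotation is always proper (determinant +1); reflections are forbidden so
that superposition can never silently flip chirality, which matters for the
loop-handedness analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import StructureEnsemble

__all__ = [
    "AtomSelection",
    "SuperpositionResult",
    "kabsch",
    "subset_rmsd",
    "ensemble_rmsf",
    "ensemble_rmsd_trace",
]


@dataclass(frozen=True)
class AtomSelection:
    """Residue ranges plus an atom-name filter (e.g. backbone N/CA/C).

    ``residues`` is an iterable of residue numbers (or None for all);
    ``atoms`` an iterable of atom names (or None for all).
    """

    residues: tuple | None = None
    atoms: tuple | None = ("N", "CA", "C")

    @staticmethod
    def backbone(start: int, end: int) -> "AtomSelection":
        return AtomSelection(residues=tuple(range(start, end + 1)),
                             atoms=("N", "CA", "C"))

    @staticmethod
    def ca_range(start: int, end: int) -> "AtomSelection":
        return AtomSelection(residues=tuple(range(start, end + 1)),
                             atoms=("CA",))

    def resolve(self, structure: StructureEnsemble) -> np.ndarray:
        idx = structure.select(residues=self.residues, atoms=self.atoms)
        if idx.size == 0:
            raise ValueError(f"selection {self} matches no atoms")
        return idx


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3×3, det +1
    translation: np.ndarray   # 3-vector, Å
    rmsd: float               # Å over the fitted atoms
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates with the fitted transform (x → R·x + t)."""
        return coords @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns the proper rotation R and translation t minimizing
    ‖a − (R·b + t)‖ and the resulting RMSD.  Requires ≥ 3 matched points
    spanning at least a plane (collinear/degenerate input raises).
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape:
        raise ValueError(f"point counts differ: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[0] < 3 or A.shape[1] != 3:
        raise ValueError("need matched (n≥3, 3) coordinate arrays")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise ValueError("rank-deficient (collinear) input; rotation undefined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((A - moved) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=A.shape[0])


def subset_rmsd(
    structure_a: StructureEnsemble,
    structure_b: StructureEnsemble,
    fit_selection: AtomSelection,
    report_selection: AtomSelection | None = None,
    model_a: int = 0,
    model_b: int = 0,
) -> float:
    """Superpose on ``fit_selection`` atoms, report RMSD over ``report_selection``.

    With ``report_selection=None`` the fit selection is reported (fit-on-self),
    the convention used for loop-to-loop comparisons.
    """
    report_selection = report_selection or fit_selection
    ia, ib = fit_selection.resolve(structure_a), fit_selection.resolve(structure_b)
    if ia.size != ib.size:
        raise ValueError("fit selection sizes differ between structures")
    fit = kabsch(structure_a.coords[model_a, ia], structure_b.coords[model_b, ib])
    ra, rb = report_selection.resolve(structure_a), report_selection.resolve(structure_b)
    if ra.size != rb.size:
        raise ValueError("report selection sizes differ between structures")
    moved = fit.apply(structure_b.coords[model_b, rb])
    diff = structure_a.coords[model_a, ra] - moved
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def _superposed_stack(
    models: StructureEnsemble,
    selection: AtomSelection | None,
    reference,
    n_iter: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """All models superposed onto the reference over the selection.

    ``reference`` is a model index or ``"mean"`` (iteratively refined mean
    structure).  Returns (aligned coords (n_models, n_atoms, 3), fit indices).
    """
    if models.n_models < 2:
        raise ValueError("need at least two models")
    sel = selection.resolve(models) if selection is not None else np.arange(models.n_atoms)
    X = models.coords.copy()
    if reference == "mean":
        ref = X[0, sel]
        for _ in range(n_iter):
            aligned = np.empty_like(X)
            for m in range(X.shape[0]):
                fit = kabsch(ref, X[m, sel])
                aligned[m] = fit.apply(X[m])
            ref = aligned[:, sel].mean(axis=0)
            X = aligned
        return X, sel
    ref = X[int(reference), sel]
    aligned = np.empty_like(X)
    for m in range(X.shape[0]):
        fit = kabsch(ref, X[m, sel])
        aligned[m] = fit.apply(X[m])
    return aligned, sel


def ensemble_rmsf(
    models: StructureEnsemble,
    selection: AtomSelection | None = None,
    reference="mean",
) -> np.ndarray:
    """Per-atom RMSF (Å) about the ensemble mean after superposition.

    RMSF_i = sqrt(mean_m |x_mi − x̄_i|²) over the atoms of ``selection``
    (default: Cα of all residues).
    """
    selection = selection or AtomSelection(atoms=("CA",))
    aligned, sel = _superposed_stack(models, selection, reference)
    sub = aligned[:, sel]
    mean = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))


def ensemble_rmsd_trace(
    models: StructureEnsemble,
    selection: AtomSelection | None = None,
    reference=0,
) -> np.ndarray:
    """RMSD of each model to the reference after per-model superposition."""
    selection = selection or AtomSelection(atoms=("CA",))
    aligned, sel = _superposed_stack(models, selection, reference)
    if reference == "mean":
        ref = aligned[:, sel].mean(axis=0)
    else:
        ref = aligned[int(reference), sel]
    diff = aligned[:, sel] - ref
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))
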