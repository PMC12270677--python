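"""Peptide sequence bookkeeping and theoretical masses.

Covers the small amount of mass spectrometry arithmetic the structural
analysis relies on: parsing one-letter sequences with cysteine-position
bookkeeping, theoretical reduced/oxidized masses (each disulfide removes two
hydrogens), and mass-accuracy errors in parts per million.

Residue masses are loaded from ``data/residue_masses.tsv`` (standard IUPAC
monoisotopic and average tables; provenance in the file header).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "PeptideSequence",
    "MassReport",
    "parse_sequence",
    "theoretical_mass",
    "ppm_error",
    "GRN_P4A",
    "GRN_L1M",
]

#: Sequences of the engineered granulin-derived peptide and its Pro2→Gly mutant.
GRN_P4A = "CPDAVYTCRPGQTCCRGLHGYGCC"
GRN_L1M = "CGDAVYTCRPGQTCCRGLHGYGCC"

WATER_MONO = 18.0105646863
WATER_AVG = 18.01528
HYDROGEN_MONO = 1.0078250319
HYDROGEN_AVG = 1.00794
PROTON = 1.007276466879


def _load_mass_table() -> tuple[dict, dict]:
    with resources.files("lariat.data").joinpath("residue_masses.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    mono = dict(zip(df["aa"], df["monoisotopic"]))
    avg = dict(zip(df["aa"], df["average"]))
    return mono, avg


RESIDUE_MASS_MONO, RESIDUE_MASS_AVG = _load_mass_table()


@dataclass(frozen=True)
class PeptideSequence:
    """A validated one-letter peptide sequence (1-based numbering)."""

    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in RESIDUE_MASS_MONO:
                raise ValueError(f"unknown residue code {aa!r} at position {i}")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]

    @property
    def cys_positions(self) -> tuple[int, ...]:
        """1-based positions of cysteines, strictly increasing."""
        return tuple(i for i, aa in enumerate(self.residues, 1) if aa == "C")

    @property
    def numbering(self) -> range:
        return range(1, len(self.residues) + 1)


def parse_sequence(text: str) -> PeptideSequence:
    """Parse a one-letter sequence string, ignoring surrounding whitespace.

    Raises ``ValueError`` naming the offending position for any code outside
    the 20-residue standard alphabet.
    """
    return PeptideSequence("".join(text.split()).upper())


@dataclass(frozen=True)
class MassReport:
    """Theoretical masses (Da) of a peptide in reduced and oxidized form."""

    monoisotopic_reduced: float
    average_reduced: float
    monoisotopic_oxidized: float
    average_oxidized: float
    n_disulfides: int

    @property
    def mh_plus_average(self) -> float:
        """[M+H]+ of the oxidized form, average masses."""
        return self.average_oxidized + PROTON

    @property
    def mh_plus_monoisotopic(self) -> float:
        return self.monoisotopic_oxidized + PROTON


def theoretical_mass(seq: PeptideSequence, n_disulfides: int = 0) -> MassReport:
    """Theoretical peptide masses; each disulfide bond removes two hydrogens.

    ``n_disulfides`` may not exceed half the number of cysteines.
    """
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be non-negative")
    if 2 * n_disulfides > len(seq.cys_positions):
        raise ValueError(
            f"{n_disulfides} disulfides need {2 * n_disulfides} cysteines, "
            f"sequence has {len(seq.cys_positions)}"
        )
    mono = sum(RESIDUE_MASS_MONO[aa] for aa in seq.residues) + WATER_MONO
    avg = sum(RESIDUE_MASS_AVG[aa] for aa in seq.residues) + WATER_AVG
    return MassReport(
        monoisotopic_reduced=mono,
        average_reduced=avg,
        monoisotopic_oxidized=mono - 2 * HYDROGEN_MONO * n_disulfides,
        average_oxidized=avg - 2 * HYDROGEN_AVG * n_disulfides,
        n_disulfides=n_disulfides,
    )


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Mass accuracy |theoretical − observed| / theoretical × 1e6.

    The theoretical value is the denominator; display convention is one
    decimal place.
    """
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return abs(theoretical_mz - observed_mz) / theoretical_mz * 1e6
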