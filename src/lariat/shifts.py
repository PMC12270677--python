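"""Chemical-shift analyses: secondary αH shifts, β-strand runs, proline forms.

Secondary shifts are observed αH shifts minus random-coil reference values
(Wishart 1995 table shipped in ``data/random_coil_ha.tsv``); runs of
consecutive positive secondary shifts flag β-strand.  Proline cis/trans
state is classified from the Cβ−Cγ shift difference using the published
calibration intervals (0–4.8 ppm fully trans, 9.15–14.4 ppm fully cis,
the gap in between ambiguous), with sequential αδ/αα NOE peaks as
independent evidence.

Shift tables read/write a TSV dialect and a minimal NMR-STAR v3
``_Atom_chem_shift`` loop (the BMRB export subset).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ShiftTable",
    "SecondaryShiftProfile",
    "RANDOM_COIL_HA",
    "TRANS_RANGE",
    "CIS_RANGE",
    "secondary_shifts",
    "detect_strand_runs",
    "classify_proline_shift",
    "proline_noe_evidence",
    "read_shifts",
    "write_shifts",
]

#: Cβ−Cγ difference intervals (ppm) predicting 100% trans / 100% cis.
TRANS_RANGE = (0.0, 4.8)
CIS_RANGE = (9.15, 14.4)

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _load_random_coil() -> dict[str, float]:
    with resources.files("lariat.data").joinpath("random_coil_ha.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(df["aa"], df["ha"]))


RANDOM_COIL_HA = _load_random_coil()


@dataclass
class ShiftTable:
    """Chemical shifts keyed by (residue number, atom name)."""

    shifts: dict = field(default_factory=dict)     # (res, atom) -> ppm
    res_name: dict = field(default_factory=dict)   # res -> one-letter code

    def set(self, res: int, res_name: str, atom: str, value: float) -> None:
        if not math.isfinite(value):
            raise ValueError(f"non-finite shift for residue {res} atom {atom}")
        code = _ONE_LETTER.get(res_name.upper(), res_name.upper())
        self.res_name[res] = code
        self.shifts[(res, atom.upper())] = float(value)

    def get(self, res: int, atom: str, default=None):
        return self.shifts.get((res, atom.upper()), default)

    @property
    def residues(self) -> list[int]:
        return sorted({r for r, _ in self.shifts})

    def alpha_h(self, res: int):
        """The αH shift of a residue; glycine averages HA2/HA3 when both exist."""
        ha = self.get(res, "HA")
        if ha is not None:
            return ha
        ha2, ha3 = self.get(res, "HA2"), self.get(res, "HA3")
        present = [v for v in (ha2, ha3) if v is not None]
        return float(np.mean(present)) if present else None

    def proline_cb_cg(self, res: int):
        """Cβ − Cγ shift difference (ppm) for a proline residue."""
        if self.res_name.get(res) != "P":
            raise ValueError(f"residue {res} is not proline")
        cb, cg = self.get(res, "CB"), self.get(res, "CG")
        if cb is None or cg is None:
            return None
        return cb - cg


@dataclass
class SecondaryShiftProfile:
    """Per-residue Δδ(αH) with sign counts and β-strand segments."""

    residues: np.ndarray            # residue numbers where Δδ defined
    delta: np.ndarray               # ppm, same length
    n_positive: int
    n_negative: int
    strand_segments: list = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.delta, index=self.residues, name="delta_ha")


def secondary_shifts(
    shifts: ShiftTable,
    reference: dict[str, float] | None = None,
    min_run: int = 4,
) -> SecondaryShiftProfile:
    """Δδ(αH) = observed − random coil, per residue.

    Residues lacking an αH shift or absent from the reference table are
    skipped (the latter with a warning).  Positive means strictly > 0.
    ``strand_segments`` are filled by :func:`detect_strand_runs`.
    """
    reference = RANDOM_COIL_HA if reference is None else reference
    res_list, deltas = [], []
    for res in sorted(shifts.res_name):
        obs = shifts.alpha_h(res)
        if obs is None:
            continue
        code = shifts.res_name[res]
        if code not in reference:
            warnings.warn(f"residue {res} ({code}) absent from reference table; "
                          "skipped", stacklevel=2)
            continue
        res_list.append(res)
        deltas.append(obs - reference[code])
    if not res_list:
        raise ValueError("no αH shifts available")
    delta = np.asarray(deltas)
    profile = SecondaryShiftProfile(
        residues=np.asarray(res_list),
        delta=delta,
        n_positive=int(np.sum(delta > 0)),
        n_negative=int(np.sum(delta < 0)),
    )
    profile.strand_segments = detect_strand_runs(profile, min_run=min_run)
    return profile


def detect_strand_runs(profile: SecondaryShiftProfile, min_run: int = 4) -> list:
    """Maximal runs of consecutive residues with positive Δδ, length ≥ min_run.

    Consecutive means consecutive residue numbers; a gap in the data breaks
    a run.  Returns ``[(start_res, end_res), ...]``, disjoint and maximal.
    """
    segments = []
    start = prev = None
    for res, d in zip(profile.residues, profile.delta):
        positive = d > 0
        contiguous = prev is not None and res == prev + 1
        if positive and start is not None and contiguous:
            prev = res
        elif positive:
            if start is not None and prev - start + 1 >= min_run:
                segments.append((int(start), int(prev)))
            start = prev = res
        else:
            if start is not None and prev - start + 1 >= min_run:
                segments.append((int(start), int(prev)))
            start = prev = None
    if start is not None and prev - start + 1 >= min_run:
        segments.append((int(start), int(prev)))
    return segments


def classify_proline_shift(delta_cb_cg: float) -> str:
    """Cis/trans category from the proline Cβ−Cγ shift difference (ppm).

    Closed calibration intervals: [0, 4.8] → ``trans``; [9.15, 14.4] →
    ``cis``; the open gap (4.8, 9.15) → ``ambiguous``; anything else →
    ``outside_calibration``.
    """
    if not math.isfinite(delta_cb_cg):
        raise ValueError("shift difference must be finite")
    lo_t, hi_t = TRANS_RANGE
    lo_c, hi_c = CIS_RANGE
    if lo_t <= delta_cb_cg <= hi_t:
        return "trans"
    if lo_c <= delta_cb_cg <= hi_c:
        return "cis"
    if hi_t < delta_cb_cg < lo_c:
        return "ambiguous"
    return "outside_calibration"


def proline_noe_evidence(noe_peaks, residue: int, res_name: str = "P") -> str:
    """Sequential NOE evidence for the cis/trans state of a proline.

    An Hα(i−1)↔Hδ(i) peak indicates trans (``alpha_delta_trans``); if both
    that and an Hα(i−1)↔Hα(i) peak are present the evidence is ``conflict``;
    otherwise ``none``.  Peaks are (res_i, atom_i, res_j, atom_j) tuples in
    either atom order.
    """
    if _ONE_LETTER.get(res_name.upper(), res_name.upper()) != "P":
        raise ValueError(f"residue {residue} ({res_name}) is not proline")

    def is_ha(atom):
        return atom.upper() in ("HA", "HA2", "HA3")

    def is_hd(atom):
        return atom.upper() in ("HD", "HD2", "HD3")

    saw_ad = saw_aa = False
    for ri, ai, rj, aj in noe_peaks:
        for (r1, a1, r2, a2) in ((ri, ai, rj, aj), (rj, aj, ri, ai)):
            if r1 == residue - 1 and is_ha(a1) and r2 == residue:
                if is_hd(a2):
                    saw_ad = True
                elif is_ha(a2):
                    saw_aa = True
    if saw_ad and saw_aa:
        return "conflict"
    if saw_ad:
        return "alpha_delta_trans"
    return "none"


# ---------------------------------------------------------------------------
# I/O

def read_shifts(path, format: str = None) -> ShiftTable:
    """Read a shift table from TSV or a minimal NMR-STAR v3 file.

    Format is inferred from the extension (``.str`` → nmrstar) unless given.
    """
    fmt = format or ("nmrstar" if str(path).endswith(".str") else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        table = ShiftTable()
        for _, row in df.iterrows():
            table.set(int(row["res_num"]), str(row["res_name"]),
                      str(row["atom"]), float(row["shift"]))
        return table
    if fmt == "nmrstar":
        return _read_nmrstar(path)
    raise ValueError(f"unknown format {format!r}")


def write_shifts(table: ShiftTable, path, format: str = None) -> None:
    fmt = format or ("nmrstar" if str(path).endswith(".str") else "tsv")
    rows = [
        dict(res_num=res, res_name=table.res_name[res], atom=atom,
             shift=value)
        for (res, atom), value in sorted(table.shifts.items())
    ]
    if fmt == "tsv":
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return
    if fmt != "nmrstar":
        raise ValueError(f"unknown format {format!r}")
    back = {v: k for k, v in _ONE_LETTER.items()}
    with open(path, "w") as fh:
        fh.write("data_shifts\n\nsave_assigned_chemical_shifts\n"
                 "   loop_\n"
                 "      _Atom_chem_shift.ID\n"
                 "      _Atom_chem_shift.Comp_index_ID\n"
                 "      _Atom_chem_shift.Comp_ID\n"
                 "      _Atom_chem_shift.Atom_ID\n"
                 "      _Atom_chem_shift.Val\n\n")
        for k, row in enumerate(rows, 1):
            name = back.get(row["res_name"], row["res_name"])
            fh.write(f"      {k} {row['res_num']} {name} {row['atom']} "
                     f"{row['shift']:.3f}\n")
        fh.write("   stop_\nsave_\n")


def plot_profile(profile: SecondaryShiftProfile, path) -> None:
    """Write a per-residue Δδ(αH) bar plot (strand runs shaded)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 2.5))
    colors = ["#2166ac" if d > 0 else "#b2182b" for d in profile.delta]
    ax.bar(profile.residues, profile.delta, color=colors, width=0.8)
    for lo, hi in profile.strand_segments:
        ax.axvspan(lo - 0.5, hi + 0.5, color="0.85", zorder=0)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\Delta\delta(\alpha H)$ / ppm")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _read_nmrstar(path) -> ShiftTable:
    """Parse the ``_Atom_chem_shift`` loop of an NMR-STAR v3 file."""
    tags: list[str] = []
    table = ShiftTable()
    state = "scan"   # scan -> loop_tags -> rows
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.strip()
            if state == "scan":
                if tok == "loop_":
                    state, tags = "loop_tags", []
            elif state == "loop_tags":
                if tok.startswith("_"):
                    tags.append(tok.split()[0])
                elif tok == "" and not tags:
                    continue
                elif any(t.startswith("_Atom_chem_shift.") for t in tags):
                    state = "rows"
                else:
                    state = "scan"   # some other loop; skip its rows
                if state != "rows" or tok == "":
                    continue
                # fall through: current line is the first data row
                _parse_star_row(tok, tags, table, path, lineno)
            elif state == "rows":
                if tok in ("stop_", ""):
                    if tok == "stop_":
                        break
                    continue
                _parse_star_row(tok, tags, table, path, lineno)
    if not table.shifts:
        raise ValueError(f"no _Atom_chem_shift loop found in {path}")
    return table


def _parse_star_row(tok, tags, table, path, lineno):
    fields = tok.split()
    if len(fields) != len(tags):
        raise ValueError(
            f"{path}:{lineno}: row has {len(fields)} fields, loop declares "
            f"{len(tags)} tags"
        )
    row = dict(zip(tags, fields))
    try:
        table.set(
            int(row["_Atom_chem_shift.Comp_index_ID"]),
            row["_Atom_chem_shift.Comp_ID"],
            row["_Atom_chem_shift.Atom_ID"],
            float(row["_Atom_chem_shift.Val"]),
        )
    except KeyError as exc:
        raise ValueError(f"{path}:{lineno}: missing tag {exc}") from None
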