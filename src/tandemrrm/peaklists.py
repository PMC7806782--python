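"""Assigned HSQC peak lists and ligand-titration series.

Peak lists are Sparky-style whitespace tables: an assignment token such as
``G142N-H`` followed by two chemical shifts (default column order w1 = 15N,
w2 = 1H).  Peaks are matched across titration points by their assignment
(residue number), never by spectral proximity: the lists are assumed to be
assigned, so no peak-tracking heuristic exists here.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "AssignedPeak",
    "PeakList",
    "TitrationSeries",
    "read_peaklist",
    "write_peaklist",
    "assemble_titration",
    "write_table",
]

# e.g. "G142N-H": one-letter residue name, residue number, 15N-1H moiety
_ASSIGNMENT_RE = re.compile(r"^([A-Za-z])(\d+)N-H$")

# plausibility windows for amide shifts, used when validation is on
_H_RANGE = (5.0, 13.0)
_N_RANGE = (100.0, 140.0)


@dataclass(frozen=True)
class AssignedPeak:
    """One assigned amide cross peak: residue identity plus (1H, 15N) ppm."""

    residue_number: int
    residue_name: str
    w_H: float
    w_N: float

    def validate(self) -> None:
        if self.residue_number < 1:
            raise ValidationError(f"residue_number must be >= 1, got {self.residue_number}")
        if not (_H_RANGE[0] <= self.w_H <= _H_RANGE[1]):
            raise ValidationError(
                f"1H shift {self.w_H} ppm outside {_H_RANGE} for residue {self.residue_number}"
            )
        if not (_N_RANGE[0] <= self.w_N <= _N_RANGE[1]):
            raise ValidationError(
                f"15N shift {self.w_N} ppm outside {_N_RANGE} for residue {self.residue_number}"
            )


@dataclass
class PeakList:
    """A labelled collection of assigned peaks (one titration condition)."""

    label: str
    peaks: tuple[AssignedPeak, ...] = ()
    _index: dict[int, AssignedPeak] = field(init=False, repr=False)

    def __post_init__(self):
        self.peaks = tuple(self.peaks)
        index: dict[int, AssignedPeak] = {}
        for p in self.peaks:
            if p.residue_number in index:
                raise ValidationError(
                    f"duplicate residue {p.residue_number} in peak list '{self.label}'"
                )
            index[p.residue_number] = p
        self._index = index

    def __len__(self) -> int:
        return len(self.peaks)

    def __contains__(self, residue_number: int) -> bool:
        return residue_number in self._index

    def get(self, residue_number: int) -> AssignedPeak:
        return self._index[residue_number]

    @property
    def residue_numbers(self) -> set[int]:
        return set(self._index)


@dataclass
class TitrationSeries:
    """Peak lists across a ligand titration, plus [P] and the [L] ladder (mM).

    The first concentration must be 0 (the ligand-free reference spectrum).
    Residues missing from a later list are *not* dropped: downstream CSD
    profiling reports them as disappeared.
    """

    protein_conc: float
    ligand_concs: tuple[float, ...]
    peaklists: tuple[PeakList, ...]

    def __post_init__(self):
        self.ligand_concs = tuple(float(c) for c in self.ligand_concs)
        self.peaklists = tuple(self.peaklists)
        if self.protein_conc <= 0:
            raise ValidationError(f"protein_conc must be > 0 mM, got {self.protein_conc}")
        if len(self.ligand_concs) != len(self.peaklists):
            raise ValidationError(
                f"{len(self.ligand_concs)} concentrations but {len(self.peaklists)} peak lists"
            )
        if not self.ligand_concs or self.ligand_concs[0] != 0.0:
            raise ValidationError("first ligand concentration must be 0 (reference)")
        for lo, hi in zip(self.ligand_concs, self.ligand_concs[1:]):
            if hi <= lo:
                raise ValidationError(
                    f"ligand concentrations must be strictly increasing ({lo} -> {hi})"
                )

    @property
    def reference(self) -> PeakList:
        return self.peaklists[0]

    def at(self, ligand_conc: float) -> PeakList:
        for c, pl in zip(self.ligand_concs, self.peaklists):
            if c == ligand_conc:
                return pl
        raise ValidationError(f"ligand concentration {ligand_conc} mM not in series")


def _parse_row(token: str, w1: str, w2: str, flip_columns: bool):
    m = _ASSIGNMENT_RE.match(token)
    if m is None:
        raise ValueError(f"malformed assignment token {token!r}")
    name, number = m.group(1).upper(), int(m.group(2))
    a, b = float(w1), float(w2)
    w_N, w_H = (b, a) if flip_columns else (a, b)
    return AssignedPeak(residue_number=number, residue_name=name, w_H=w_H, w_N=w_N)


def read_peaklist(
    path,
    dialect: str = "sparky",
    label: str | None = None,
    flip_columns: bool = False,
    validate: bool = True,
) -> PeakList:
    """Read a Sparky-style ``.list`` file.

    One optional header line is tolerated; any later unparsable row raises
    :class:`ParseError` naming the line number.  ``flip_columns`` flips the
    w1/w2 convention for the opposite dialect (default w1 = 15N, w2 = 1H).
    """
    if dialect != "sparky":
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    path = Path(path)
    peaks: list[AssignedPeak] = []
    seen_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 3:
                if not seen_data and lineno == 1:
                    continue  # header
                raise ParseError(
                    f"expected 'Assignment w1 w2', got {line.rstrip()!r}",
                    path=path,
                    line_number=lineno,
                )
            try:
                peak = _parse_row(*fields, flip_columns=flip_columns)
            except ValueError as exc:
                if not seen_data and lineno == 1:
                    continue  # header row with three columns
                raise ParseError(str(exc), path=path, line_number=lineno) from exc
            if validate:
                peak.validate()
            peaks.append(peak)
            seen_data = True
    return PeakList(label=label if label is not None else path.stem, peaks=tuple(peaks))


def write_peaklist(peaklist: PeakList, path, flip_columns: bool = False) -> None:
    """Serialise to the same Sparky dialect (ppm to 3 decimals, w1 = 15N)."""
    with open(path, "w") as fh:
        fh.write("Assignment         w1         w2\n")
        for p in peaklist.peaks:
            a, b = (p.w_H, p.w_N) if flip_columns else (p.w_N, p.w_H)
            fh.write(f"{p.residue_name}{p.residue_number}N-H {a:10.3f} {b:10.3f}\n")


def assemble_titration(
    peaklists: Sequence[PeakList],
    ligand_concs: Sequence[float],
    protein_conc: float,
) -> TitrationSeries:
    """Bundle per-condition peak lists into a validated titration series."""
    if len(peaklists) != len(ligand_concs):
        raise ValidationError(
            f"{len(peaklists)} peak lists but {len(ligand_concs)} concentrations"
        )
    return TitrationSeries(
        protein_conc=float(protein_conc),
        ligand_concs=tuple(ligand_concs),
        peaklists=tuple(peaklists),
    )


def write_table(records, path) -> None:
    """Write tabular results as CSV with a header and deterministic columns.

    ``records`` may be a DataFrame or an iterable of dicts; it must be
    non-empty.  Floats are written to 6 decimals.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise ValidationError("refusing to write an empty table")
    df.to_csv(path, index=False, float_format="%.6f")
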