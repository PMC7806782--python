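"""Calpha superposition of tethered vs isolated domain structures.

Reads PDB coordinate files through Bio.PDB, pairs residues by identical
residue number (optionally after a fixed offset) within a named domain
range, and reports the least-squares RMSD after optimal proper rotation.
NMR ensembles default to model 1; ``model_index`` selects others.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser

from ._geometry import kabsch_rmsd
from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "StructureModel",
    "DomainDefinition",
    "SuperpositionResult",
    "read_structure",
    "common_range",
    "kabsch_superpose",
    "domain_rmsd_report",
]


@dataclass
class StructureModel:
    """Ordered Calpha trace of one model/chain: (resnum, resname, xyz in A)."""

    model_index: int
    chain_id: str
    residues: tuple[tuple[int, str, tuple[float, float, float]], ...]

    def __post_init__(self):
        nums = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValidationError("residue numbers must be strictly increasing")
        coords = np.array([r[2] for r in self.residues], dtype=float)
        if coords.size and not np.isfinite(coords).all():
            raise ValidationError("non-finite coordinates")

    @property
    def residue_numbers(self) -> list[int]:
        return [r[0] for r in self.residues]

    def coords(self) -> np.ndarray:
        return np.array([r[2] for r in self.residues], dtype=float)


@dataclass(frozen=True)
class DomainDefinition:
    """Inclusive residue range of one domain in construct numbering."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"domain {self.name}: start must be < end")

    def __contains__(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end


@dataclass
class SuperpositionResult:
    rmsd: float
    n_atoms: int
    rotation: np.ndarray
    translation: np.ndarray


def read_structure(path, model_index: int = 1, chain_id: str | None = None) -> StructureModel:
    """Parse one model/chain's Calpha atoms from a PDB file.

    ``model_index`` is 1-based over MODEL blocks in file order.  The first
    alternate location of a disordered CA is kept.  ``chain_id=None`` takes
    the first chain.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Bio.PDB is chatty about nonstandard records
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    models = list(structure)
    if not 1 <= model_index <= len(models):
        raise ValidationError(
            f"model {model_index} requested but file has {len(models)} model(s)"
        )
    model = models[model_index - 1]
    chains = {c.id: c for c in model}
    if chain_id is None:
        chain = next(iter(model))
    elif chain_id in chains:
        chain = chains[chain_id]
    else:
        raise ValidationError(f"chain {chain_id!r} not found (have {sorted(chains)})")
    rows = []
    for residue in chain:
        if "CA" not in residue:
            continue
        ca = residue["CA"]
        if ca.is_disordered():
            ca = sorted(ca.disordered_get_list(), key=lambda a: a.get_altloc())[0]
        rows.append((residue.id[1], residue.get_resname(), tuple(map(float, ca.coord))))
    if not rows:
        raise ValidationError(f"no CA atoms in model {model_index} chain {chain.id!r}")
    rows.sort(key=lambda r: r[0])
    return StructureModel(model_index=model_index, chain_id=chain.id, residues=tuple(rows))


def common_range(
    a: StructureModel,
    b: StructureModel,
    domain: DomainDefinition,
    offset_b: int = 0,
):
    """Paired coordinate arrays over the shared residue numbers in a domain.

    ``offset_b`` is added to b's residue numbers before matching (fixed
    renumbering between constructs); no sequence alignment is attempted.
    """
    a_map = {r[0]: r[2] for r in a.residues if r[0] in domain}
    b_map = {r[0] + offset_b: r[2] for r in b.residues if (r[0] + offset_b) in domain}
    shared = sorted(set(a_map) & set(b_map))
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared residues in {domain.name} "
            f"[{domain.start}-{domain.end}]; need >= 3"
        )
    coords_a = np.array([a_map[r] for r in shared], dtype=float)
    coords_b = np.array([b_map[r] for r in shared], dtype=float)
    return coords_a, coords_b, shared


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal proper superposition of b onto a; RMSD over all pairs."""
    rmsd, rot, trans = kabsch_rmsd(coords_a, coords_b)
    return SuperpositionResult(
        rmsd=rmsd, n_atoms=int(np.asarray(coords_a).shape[0]), rotation=rot, translation=trans
    )


def domain_rmsd_report(
    tethered: StructureModel,
    isolated: StructureModel,
    domain: DomainDefinition,
    offset_b: int = 0,
) -> SuperpositionResult:
    """Calpha RMSD between two forms over one domain's structured range."""
    ca, cb, _ = common_range(tethered, isolated, domain, offset_b=offset_b)
    return kabsch_superpose(ca, cb)
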