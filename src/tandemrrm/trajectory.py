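"""Replica trajectory analyses: RMSD time series, RMSF, and dRMSF rules.

A :class:`TrajectoryEnsemble` holds independent replicas of frames x atoms
coordinates with a shared (residue_number, atom_name) topology — exactly the
shape of several parallel MD runs of one construct.  RMSD is computed per
replica against that replica's first frame (or its mean structure) after
optimal superposition over the selection; the quoted mean +/- SD pools all
frames of all replicas.  RMSF uses the mean structure of each replica as the
fluctuation reference and averages the per-replica profiles.

The tethered-vs-isolated comparison reduces each residue to
delta = RMSF_tethered - RMSF_isolated and flags residues with
delta > mean + one sample SD, the same significance convention used for
chemical-shift perturbations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._geometry import fit_frames_to_reference, superpose_batch
from .errors import ParseError, ValidationError
from .structures import DomainDefinition

__all__ = [
    "TrajectoryEnsemble",
    "RmsdSeries",
    "RmsfProfile",
    "DeltaRmsfResult",
    "rmsd_series",
    "domain_overlay_rmsd",
    "rmsf_profile",
    "delta_rmsf",
    "read_trajectory_pdb",
    "write_trajectory_pdb",
]


@dataclass
class TrajectoryEnsemble:
    """replicas: list of (frames, atoms, 3) arrays sharing one topology."""

    replicas: list[np.ndarray]
    topology: tuple[tuple[int, str], ...]  # atom -> (residue_number, atom_name)
    frame_spacing: float = 0.1  # ns between stored frames

    def __post_init__(self):
        self.topology = tuple((int(r), str(n)) for r, n in self.topology)
        if not self.replicas:
            raise ValidationError("at least one replica required")
        n_atoms = len(self.topology)
        for i, rep in enumerate(self.replicas):
            rep = np.asarray(rep, dtype=float)
            self.replicas[i] = rep
            if rep.ndim != 3 or rep.shape[1] != n_atoms or rep.shape[2] != 3:
                raise ValidationError(
                    f"replica {i}: expected (frames, {n_atoms}, 3), got {rep.shape}"
                )
            if rep.shape[0] < 2:
                raise ValidationError(f"replica {i}: need >= 2 frames")
            if not np.isfinite(rep).all():
                raise ValidationError(f"replica {i}: non-finite coordinates")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def residue_numbers(self) -> list[int]:
        seen: list[int] = []
        for r, _ in self.topology:
            if r not in seen:
                seen.append(r)
        return seen

    def atom_indices(
        self,
        residue_range: tuple[int, int] | None = None,
        atom_name: str | None = "CA",
    ) -> np.ndarray:
        idx = []
        for i, (resnum, name) in enumerate(self.topology):
            if atom_name is not None and name != atom_name:
                continue
            if residue_range is not None and not (residue_range[0] <= resnum <= residue_range[1]):
                continue
            idx.append(i)
        return np.array(idx, dtype=int)


@dataclass
class RmsdSeries:
    per_replica: list[np.ndarray]  # frame-indexed RMSD, A
    mean: float
    sd: float
    selection: str

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.per_replica)


@dataclass
class RmsfProfile:
    values: dict[int, float]  # residue -> replica-averaged RMSF, A
    per_replica: list[dict[int, float]] = field(default_factory=list)
    selection: str = "CA"


@dataclass
class DeltaRmsfResult:
    delta: dict[int, float]
    mean: float
    sd: float
    threshold: float
    selected: set[int]
    outside_domains: dict[int, float] = field(default_factory=dict)


def _selection_indices(ens, residue_range, atom_name):
    idx = ens.atom_indices(residue_range=residue_range, atom_name=atom_name)
    if idx.size == 0:
        raise ValidationError(
            f"empty selection (range={residue_range}, atom={atom_name})"
        )
    if idx.size < 3:
        raise ValidationError(f"selection has {idx.size} atoms; need >= 3")
    return idx


def rmsd_series(
    ens: TrajectoryEnsemble,
    residue_range: tuple[int, int] | None = None,
    atom_name: str = "CA",
    ref: str = "first",
) -> RmsdSeries:
    """Per-replica RMSD of every frame against the replica's reference.

    ``ref='first'`` uses frame 0, ``ref='mean'`` the mean structure after a
    first-frame pre-fit.  The headline mean/sd pool all frames of all
    replicas.
    """
    if ref not in ("first", "mean"):
        raise ValueError(f"ref must be 'first' or 'mean', got {ref!r}")
    idx = _selection_indices(ens, residue_range, atom_name)
    per_replica = []
    for rep in ens.replicas:
        sub = rep[:, idx, :]
        reference = sub[0]
        if ref == "mean":
            reference = fit_frames_to_reference(sub, sub[0]).mean(axis=0)
        per_replica.append(superpose_batch(sub, reference))
    pooled = np.concatenate(per_replica)
    sel = f"{atom_name or 'all'}"
    if residue_range is not None:
        sel += f" {residue_range[0]}-{residue_range[1]}"
    return RmsdSeries(
        per_replica=per_replica,
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        selection=sel,
    )


def domain_overlay_rmsd(ens: TrajectoryEnsemble, domain: DomainDefinition, **kw) -> RmsdSeries:
    """RMSD with superposition restricted to one domain's Calpha range,
    excluding unstructured termini/linker from both fit and measure."""
    return rmsd_series(ens, residue_range=(domain.start, domain.end), **kw)


def rmsf_profile(
    ens: TrajectoryEnsemble,
    residue_range: tuple[int, int] | None = None,
    atom_name: str = "CA",
) -> RmsfProfile:
    """Replica-averaged per-residue RMSF about the mean structure.

    Each replica is first superposed on its first frame, the mean structure
    is formed, frames are re-fitted onto that mean, and
    RMSF_i = sqrt(<|x_i - <x_i>|^2>) is averaged over replicas.
    """
    idx = _selection_indices(ens, residue_range, atom_name)
    resnums = [ens.topology[i][0] for i in idx]
    per_replica: list[dict[int, float]] = []
    for rep in ens.replicas:
        sub = rep[:, idx, :]
        fitted = fit_frames_to_reference(sub, sub[0])
        mean_structure = fitted.mean(axis=0)
        fitted = fit_frames_to_reference(sub, mean_structure)
        mean_structure = fitted.mean(axis=0)
        dev = fitted - mean_structure[None]
        rmsf = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
        rmsf[rmsf < 1e-8] = 0.0  # numerical floor: static input is exactly 0
        per_replica.append({r: float(v) for r, v in zip(resnums, rmsf)})
    avg = {
        r: float(np.mean([p[r] for p in per_replica])) for r in per_replica[0]
    }
    sel = f"{atom_name or 'all'}"
    if residue_range is not None:
        sel += f" {residue_range[0]}-{residue_range[1]}"
    return RmsfProfile(values=avg, per_replica=per_replica, selection=sel)


def delta_rmsf(
    tethered: RmsfProfile,
    isolated_rrm1: RmsfProfile,
    isolated_rrm2: RmsfProfile,
    domains: tuple[DomainDefinition, DomainDefinition],
) -> DeltaRmsfResult:
    """Tethered-minus-isolated RMSF with the mean + one SD selection rule.

    Each tethered residue inside a domain is compared against the isolated
    profile of that domain; linker/termini residues outside both domains are
    reported separately and excluded from the threshold and selection.
    """
    d1, d2 = domains
    delta: dict[int, float] = {}
    outside: dict[int, float] = {}
    for r, v in tethered.values.items():
        if r in d1:
            source = isolated_rrm1
        elif r in d2:
            source = isolated_rrm2
        else:
            outside[r] = v
            continue
        if r not in source.values:
            raise ValidationError(
                f"residue {r} inside domain but missing from the isolated profile"
            )
        delta[r] = v - source.values[r]
    if len(delta) < 2:
        raise ValidationError("need >= 2 in-domain residues for the significance rule")
    vals = np.array(list(delta.values()))
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    threshold = mean + sd
    selected = {r for r, v in delta.items() if v > threshold}
    return DeltaRmsfResult(
        delta=delta,
        mean=mean,
        sd=sd,
        threshold=threshold,
        selected=selected,
        outside_domains=outside,
    )


# ---------------------------------------------------------------------------
# multi-model PDB trajectory I/O (one MODEL per frame, one file per replica)

def write_trajectory_pdb(
    coords: np.ndarray,
    topology: Sequence[tuple[int, str]],
    path,
    resnames: Sequence[str] | None = None,
    chain_id: str = "A",
) -> None:
    """Write frames (F, n_atoms, 3) as a multi-model PDB file."""
    coords = np.asarray(coords, dtype=float)
    if resnames is None:
        resnames = ["ALA"] * len(topology)
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, ((resnum, name), resname) in enumerate(zip(topology, resnames)):
                x, y, z = coords[f, i]
                atom = name if len(name) == 4 else f" {name:<3s}"
                fh.write(
                    f"ATOM  {i + 1:5d} {atom}{'':1s}{resname:>3s} {chain_id}{resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_one_replica(path) -> tuple[np.ndarray, list[tuple[int, str]]]:
    frames: list[list[tuple[float, float, float]]] = []
    topo: list[tuple[int, str]] = []
    current: list[tuple[float, float, float]] | None = None
    first = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise ParseError("ENDMDL without MODEL", path=path, line_number=lineno)
                frames.append(current)
                if first:
                    first = False
                elif len(current) != len(topo):
                    raise ParseError(
                        f"frame {len(frames)} has {len(current)} atoms, expected {len(topo)}",
                        path=path,
                        line_number=lineno,
                    )
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:  # single-model file without MODEL records
                    current = []
                try:
                    name = line[12:16].strip()
                    resnum = int(line[22:26])
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except ValueError as exc:
                    raise ParseError(str(exc), path=path, line_number=lineno) from exc
                if first:
                    topo.append((resnum, name))
                current.append(xyz)
    if current:
        frames.append(current)
    if not frames:
        raise ParseError("no coordinate frames found", path=path)
    return np.array(frames, dtype=float), topo


def read_trajectory_pdb(paths: Sequence, frame_spacing: float = 0.1) -> TrajectoryEnsemble:
    """Read one replica per multi-model PDB file into an ensemble."""
    if not paths:
        raise ValidationError("no trajectory files given")
    replicas = []
    topo = None
    for p in paths:
        coords, this_topo = _read_one_replica(Path(p))
        if topo is None:
            topo = this_topo
        elif this_topo != topo:
            raise ValidationError(f"replica {p} topology differs from the first replica")
        replicas.append(coords)
    return TrajectoryEnsemble(replicas=replicas, topology=tuple(topo), frame_spacing=frame_spacing)
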