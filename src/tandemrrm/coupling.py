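"""Backbone-dihedral mutual information and inter-domain coupling maps.

Correlated residue motions are detected in internal coordinates: phi/psi
time series are extracted per replica, concatenated, binned on equal-width
circular bins over (-180, 180], and every torsion pair is scored with the
histogram mutual information MI = H(x) + H(y) - H(x, y) in nats.  A shuffle
null (mean MI of seeded permutations of one series) subtracts the finite-
sample bias.  Residue-pair scores sum the pairwise torsion MIs and are
normalised by the smaller of the two residues' summed marginal entropies,
giving values in [0, 1] so that a fixed coupling threshold (default 0.3) is
meaningful; normalising by the matrix maximum would pin the largest element
of pure noise at 1 and make any absolute threshold vacuous.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from MDAnalysis.lib.distances import calc_dihedrals

from .errors import ValidationError
from .structures import DomainDefinition
from .trajectory import TrajectoryEnsemble

__all__ = [
    "DihedralEnsemble",
    "MIMatrix",
    "CouplingReport",
    "compute_dihedrals",
    "mutual_information",
    "shuffle_null",
    "residue_mi_matrix",
    "coupling_report",
]


@dataclass
class DihedralEnsemble:
    """(residue, 'phi'|'psi') -> concatenated per-replica series, degrees."""

    angles: dict[tuple[int, str], np.ndarray]
    replica_boundaries: tuple[int, ...] = ()  # cumulative frame counts

    def __post_init__(self):
        for key, arr in self.angles.items():
            arr = np.asarray(arr, dtype=float)
            self.angles[key] = arr
            if arr.size and (arr.min() <= -180.0 - 1e-9 or arr.max() > 180.0 + 1e-9):
                raise ValidationError(f"{key}: angles outside (-180, 180]")

    @property
    def residues(self) -> list[int]:
        return sorted({r for r, _ in self.angles})

    def torsions_of(self, residue: int) -> list[tuple[int, str]]:
        return [k for k in self.angles if k[0] == residue]


@dataclass
class MIMatrix:
    residue_numbers: list[int]
    raw: np.ndarray  # symmetric, nats
    normalized: np.ndarray  # [0, 1]; diagonal = 1 by convention
    bin_count: int
    bias_corrected: bool


@dataclass
class CouplingReport:
    threshold: float
    pairs: list[tuple[int, int, float]]
    classes: dict[tuple[int, int], str]
    summary: dict[str, float]
    inter_intra_ratio: float | None  # None when undefined (flagged)


def compute_dihedrals(ens: TrajectoryEnsemble) -> DihedralEnsemble:
    """phi/psi time series from an N/CA/C backbone topology.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1); the
    torsions a terminal residue lacks are omitted.  IUPAC sign convention
    (as produced by MDAnalysis), degrees in (-180, 180].
    """
    atom_of: dict[tuple[int, str], int] = {}
    for i, key in enumerate(ens.topology):
        atom_of[key] = i
    residues = ens.residue_numbers
    for r in residues:
        for name in ("N", "CA", "C"):
            if (r, name) not in atom_of:
                raise ValidationError(f"residue {r} lacks backbone atom {name}")

    def series(quad):
        parts = []
        for rep in ens.replicas:
            a, b, c, d = (rep[:, atom_of[q], :] for q in quad)
            ang = calc_dihedrals(a, b, c, d)
            if not np.isfinite(ang).all():
                raise ValidationError(f"undefined torsion (collinear atoms) for {quad}")
            parts.append(np.degrees(ang))
        return np.concatenate(parts)

    angles: dict[tuple[int, str], np.ndarray] = {}
    for j, r in enumerate(residues):
        if j > 0:
            prev = residues[j - 1]
            angles[(r, "phi")] = series(((prev, "C"), (r, "N"), (r, "CA"), (r, "C")))
        if j < len(residues) - 1:
            nxt = residues[j + 1]
            angles[(r, "psi")] = series(((r, "N"), (r, "CA"), (r, "C"), (nxt, "N")))
    boundaries = tuple(np.cumsum([rep.shape[0] for rep in ens.replicas]).tolist())
    return DihedralEnsemble(angles=angles, replica_boundaries=boundaries)


def _bin_indices(angles: np.ndarray, bin_count: int) -> np.ndarray:
    width = 360.0 / bin_count
    idx = np.floor((np.asarray(angles, dtype=float) + 180.0) / width).astype(np.int64)
    return np.clip(idx, 0, bin_count - 1)


def _entropy_from_counts(counts: np.ndarray, n: int) -> float:
    nz = counts[counts > 0].astype(float)
    return float(np.log(n) - (nz * np.log(nz)).sum() / n)


def _mi_from_indices(xi, yi, bin_count) -> float:
    n = xi.size
    joint = np.bincount(xi * bin_count + yi, minlength=bin_count * bin_count)
    hx = _entropy_from_counts(np.bincount(xi, minlength=bin_count), n)
    hy = _entropy_from_counts(np.bincount(yi, minlength=bin_count), n)
    hxy = _entropy_from_counts(joint, n)
    return hx + hy - hxy


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    bin_count: int = 24,
    bias_correction: str = "none",
    n_shuffle: int = 10,
    seed: int = 0,
) -> float:
    """Histogram MI (nats) of two circular series on (-180, 180].

    ``bias_correction='shuffle'`` subtracts the mean MI of ``n_shuffle``
    seeded permutations of y (may leave a slightly negative value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D series")
    if bin_count < 2:
        raise ValidationError("bin_count must be >= 2")
    if x.size < 10 * bin_count:
        raise ValidationError(
            f"need >= 10 x bin_count = {10 * bin_count} samples, got {x.size}"
        )
    if bias_correction not in ("none", "shuffle"):
        raise ValueError(f"unknown bias_correction {bias_correction!r}")
    xi = _bin_indices(x, bin_count)
    yi = _bin_indices(y, bin_count)
    mi = _mi_from_indices(xi, yi, bin_count)
    if bias_correction == "shuffle":
        null_mean, _ = shuffle_null(x, y, bin_count, n_shuffle=n_shuffle, seed=seed)
        mi -= null_mean
    return mi


def shuffle_null(
    x: np.ndarray,
    y: np.ndarray,
    bin_count: int = 24,
    n_shuffle: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of the permutation-null MI distribution."""
    rng = np.random.default_rng(seed)
    xi = _bin_indices(x, bin_count)
    yi = _bin_indices(y, bin_count)
    vals = []
    for _ in range(n_shuffle):
        vals.append(_mi_from_indices(xi, rng.permutation(yi), bin_count))
    return float(np.mean(vals)), float(np.std(vals, ddof=1)) if n_shuffle > 1 else 0.0


def residue_mi_matrix(
    dih: DihedralEnsemble,
    bin_count: int = 24,
    bias_correction: str = "shuffle",
    n_shuffle: int = 10,
    seed: int = 0,
) -> MIMatrix:
    """Residue-pair MI matrix over concatenated replicas.

    raw(i, j) sums the pairwise torsion MIs between the residues' torsion
    sets (shuffle-corrected and floored at 0 when requested);
    normalized(i, j) = raw / min(H_i, H_j) with H_i the summed marginal
    entropy of residue i's torsions, clipped to [0, 1].  The normalized
    diagonal is 1 by convention; self-coupling is not a pair statistic.
    """
    residues = dih.residues
    if len(residues) < 2:
        raise ValidationError("need >= 2 residues with torsions")
    if bias_correction not in ("none", "shuffle"):
        raise ValueError(f"unknown bias_correction {bias_correction!r}")
    torsion_keys = sorted(dih.angles, key=lambda k: (k[0], k[1]))
    n = dih.angles[torsion_keys[0]].size
    idx = {k: _bin_indices(dih.angles[k], bin_count) for k in torsion_keys}
    marg_h = {
        k: _entropy_from_counts(np.bincount(idx[k], minlength=bin_count), n)
        for k in torsion_keys
    }
    # one permutation per shuffle round, shared across pairs: permuting the
    # second series of every pair with the same row permutation is a valid
    # independence null for cross pairs and costs one array shuffle per round
    rng = np.random.default_rng(seed)
    rounds = []
    if bias_correction == "shuffle":
        for _ in range(n_shuffle):
            perm = rng.permutation(n)
            rounds.append({k: idx[k][perm] for k in torsion_keys})

    h_res = {
        r: sum(marg_h[k] for k in dih.torsions_of(r)) for r in residues
    }
    m = len(residues)
    raw = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            total = 0.0
            for ka in dih.torsions_of(residues[a]):
                base = idx[ka] * bin_count
                ha = marg_h[ka]
                for kb in dih.torsions_of(residues[b]):
                    mi = ha + marg_h[kb] - _entropy_from_counts(
                        np.bincount(base + idx[kb], minlength=bin_count * bin_count), n
                    )
                    if rounds:
                        null = np.mean([
                            ha
                            + marg_h[kb]
                            - _entropy_from_counts(
                                np.bincount(
                                    base + rnd[kb], minlength=bin_count * bin_count
                                ),
                                n,
                            )
                            for rnd in rounds
                        ])
                        mi -= null
                    total += mi
            raw[a, b] = raw[b, a] = total
    floored = np.maximum(raw, 0.0)
    denom = np.minimum.outer(
        np.array([h_res[r] for r in residues]), np.array([h_res[r] for r in residues])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(denom > 0, floored / denom, 0.0)
    normalized = np.clip(normalized, 0.0, 1.0)
    np.fill_diagonal(normalized, 1.0)
    return MIMatrix(
        residue_numbers=list(residues),
        raw=raw,
        normalized=normalized,
        bin_count=bin_count,
        bias_corrected=bias_correction == "shuffle",
    )


def coupling_report(
    mi: MIMatrix,
    domains: tuple[DomainDefinition, DomainDefinition],
    threshold: float = 0.3,
) -> CouplingReport:
    """Threshold the normalized matrix and classify couplings by domain.

    Classes: intra-RRM1, intra-RRM2, inter-domain, linker-involving (a pair
    with a residue outside both domains).  The headline inter/intra ratio is
    the mean inter-domain strength over the mean intra-domain strength,
    flagged as undefined (None) when either class is empty.
    """
    d1, d2 = domains
    if max(d1.start, d2.start) <= min(d1.end, d2.end):
        raise ValidationError(f"domains {d1.name} and {d2.name} overlap")
    res = mi.residue_numbers
    pairs: list[tuple[int, int, float]] = []
    classes: dict[tuple[int, int], str] = {}
    for a in range(len(res)):
        for b in range(a + 1, len(res)):
            v = float(mi.normalized[a, b])
            if v <= threshold:
                continue
            ra, rb = res[a], res[b]
            if ra in d1 and rb in d1:
                cls = "intra-RRM1"
            elif ra in d2 and rb in d2:
                cls = "intra-RRM2"
            elif (ra in d1 and rb in d2) or (ra in d2 and rb in d1):
                cls = "inter-domain"
            else:
                cls = "linker-involving"
            pairs.append((ra, rb, v))
            classes[(ra, rb)] = cls
    summary: dict[str, float] = {}
    for cls in ("intra-RRM1", "intra-RRM2", "inter-domain", "linker-involving"):
        vals = [v for (ra, rb, v) in pairs if classes[(ra, rb)] == cls]
        if vals:
            summary[cls] = float(np.mean(vals))
    intra = [
        v
        for (ra, rb, v) in pairs
        if classes[(ra, rb)] in ("intra-RRM1", "intra-RRM2")
    ]
    inter = [v for (ra, rb, v) in pairs if classes[(ra, rb)] == "inter-domain"]
    ratio = float(np.mean(inter) / np.mean(intra)) if inter and intra else None
    return CouplingReport(
        threshold=float(threshold),
        pairs=sorted(pairs),
        classes=classes,
        summary=summary,
        inter_intra_ratio=ratio,
    )
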