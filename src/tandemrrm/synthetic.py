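"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its spec (seed included) and returns
the generated object together with a ground-truth record sufficient to
score the downstream estimator.

* Titrations: reference amide peaks drift along a fixed per-residue
  direction by the ligand-depletion model's predicted CSD, plus Gaussian
  ppm noise that is isotropic in the (d1H, d15N/2) metric, so the CSD noise
  scale is known exactly.  Peaks can disappear from a random concentration
  onward (exchange broadening), mirroring real titrations.
* Trajectories: an idealised N/CA/C backbone is rebuilt each frame from
  internal coordinates (fixed bond lengths/angles, per-frame phi/psi), so
  planted torsion statistics round-trip exactly through the dihedral
  extractor.  Optional ingredients: per-atom Cartesian jitter, a rigid
  inter-domain hinge rotation with an AR(1) angle series, and torsion pairs
  coupled through a Gaussian copula with known mutual information
  -0.5 ln(1 - rho^2).
* Melt curves: sums of two-state van 't Hoff transitions with linear
  baselines, optional post-transition signal decay (dye dissociation) and
  seeded noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import ndtr

from .csd import BindingModelParams, csd_model
from .errors import ValidationError
from .melt import MeltCurve
from .peaklists import AssignedPeak, PeakList, TitrationSeries
from .structures import DomainDefinition, StructureModel
from .trajectory import TrajectoryEnsemble

__all__ = [
    "PAPER_LIGAND_CONCS",
    "TitrationSpec",
    "TrajectorySpec",
    "MeltSpec",
    "gen_titration",
    "gen_trajectory",
    "gen_correlated_angles",
    "gen_meltcurve",
    "build_backbone",
    "structure_from_coords",
]

# the study's HSQC titration ladder (mM ATP) at 50 uM protein
PAPER_LIGAND_CONCS: tuple[float, ...] = (
    0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0
)

_AA_CODES = "ACDEFGHIKLMNQRSTVWY"  # prolines carry no amide peak


def wrap_angle(a):
    """Map angles (degrees) onto (-180, 180]."""
    w = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return w


# ---------------------------------------------------------------------------
# titrations

@dataclass
class TitrationSpec:
    n_residues: int = 40
    start_residue: int = 1
    true_kd: float | Mapping[int, float] = 7.7  # mM
    csd_max_range: tuple[float, float] = (0.2, 0.8)  # ppm
    noise_sd: float = 0.005  # ppm, per CSD-metric component
    disappear_prob: float = 0.0
    protein_conc: float = 0.05  # mM (50 uM)
    ligand_concs: tuple[float, ...] = PAPER_LIGAND_CONCS
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.disappear_prob <= 1.0:
            raise ValidationError("disappear_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_residues < 1:
            raise ValidationError("need at least one residue")


def _kd_of(spec: TitrationSpec, residue: int) -> float:
    if isinstance(spec.true_kd, Mapping):
        return float(spec.true_kd[residue])
    return float(spec.true_kd)


def gen_titration(spec: TitrationSpec):
    """Return (TitrationSeries, ground_truth).

    ground_truth maps residue -> dict(kd, csd_max, direction) where
    ``direction`` is the unit shift direction in the (d1H, d15N/2) metric,
    so the programmed CSD at [L] equals the depletion-model prediction.
    """
    rng = np.random.default_rng(spec.seed)
    residues = [spec.start_residue + i for i in range(spec.n_residues)]
    names = rng.choice(list(_AA_CODES), size=spec.n_residues)
    ref_h = rng.uniform(6.8, 9.6, size=spec.n_residues)
    ref_n = rng.uniform(105.0, 130.0, size=spec.n_residues)
    cmax = rng.uniform(*spec.csd_max_range, size=spec.n_residues)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_residues)

    n_conc = len(spec.ligand_concs)
    onset = np.full(spec.n_residues, n_conc, dtype=int)  # index from which peak is gone
    for i in range(spec.n_residues):
        if rng.random() < spec.disappear_prob:
            onset[i] = rng.integers(1, n_conc)

    truth = {}
    for i, r in enumerate(residues):
        truth[r] = {
            "kd": _kd_of(spec, r),
            "csd_max": float(cmax[i]),
            "direction": (float(np.cos(theta[i])), float(np.sin(theta[i]))),
            "disappears_at_index": int(onset[i]) if onset[i] < n_conc else None,
        }

    peaklists = []
    for ci, conc in enumerate(spec.ligand_concs):
        peaks = []
        for i, r in enumerate(residues):
            if ci >= onset[i]:
                continue
            params = BindingModelParams(kd=_kd_of(spec, r), csd_max=float(cmax[i]))
            shift = csd_model(params, spec.protein_conc, conc) if conc > 0 else 0.0
            dh = shift * np.cos(theta[i])
            dn2 = shift * np.sin(theta[i])  # component in the 15N/2 coordinate
            eh = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            en2 = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            peaks.append(
                AssignedPeak(
                    residue_number=r,
                    residue_name=str(names[i]),
                    w_H=float(ref_h[i] + dh + eh),
                    w_N=float(ref_n[i] + 2.0 * (dn2 + en2)),
                )
            )
        peaklists.append(PeakList(label=f"ATP_{conc:g}mM", peaks=tuple(peaks)))
    series = TitrationSeries(
        protein_conc=spec.protein_conc,
        ligand_concs=spec.ligand_concs,
        peaklists=tuple(peaklists),
    )
    return series, truth


# ---------------------------------------------------------------------------
# backbone construction from internal coordinates

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = np.radians(111.2)
_ANG_CA_C_N = np.radians(116.2)
_ANG_C_N_CA = np.radians(121.7)


def _place(a, b, c, bond, angle, torsion):
    """NeRF placement of the next atom; a, b, c are (..., 3) stacks."""
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = np.stack(
        [
            -bond * np.cos(angle) * np.ones_like(torsion),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ],
        axis=-1,
    )
    return c + d[..., :1] * bc + d[..., 1:2] * m + d[..., 2:3] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray, omega: float = 180.0) -> np.ndarray:
    """Build N/CA/C coordinates from per-frame torsions.

    ``phi`` and ``psi`` are (F, n_res) in degrees; phi[:, 0] and psi[:, -1]
    are ignored (undefined at the termini).  Returns (F, 3 * n_res, 3) in A
    with atoms ordered N, CA, C per residue.  Bond lengths/angles are ideal
    peptide values; omega is held fixed (trans by default).
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if phi.shape != psi.shape:
        raise ValidationError("phi and psi must have identical shapes")
    n_frames, n_res = phi.shape
    if n_res < 2:
        raise ValidationError("need >= 2 residues")
    phi_r, psi_r = np.radians(phi), np.radians(psi)
    omega_r = np.full(n_frames, np.radians(omega))

    coords = np.empty((n_frames, 3 * n_res, 3))
    n0 = np.zeros((n_frames, 3))
    ca0 = np.tile([_BOND_N_CA, 0.0, 0.0], (n_frames, 1))
    c0 = ca0 + _BOND_CA_C * np.array([-np.cos(_ANG_N_CA_C), np.sin(_ANG_N_CA_C), 0.0])
    coords[:, 0], coords[:, 1], coords[:, 2] = n0, ca0, c0
    for i in range(1, n_res):
        prev_n, prev_ca, prev_c = (coords[:, 3 * (i - 1) + k] for k in range(3))
        n_i = _place(prev_n, prev_ca, prev_c, _BOND_C_N, _ANG_CA_C_N, psi_r[:, i - 1])
        ca_i = _place(prev_ca, prev_c, n_i, _BOND_N_CA, _ANG_C_N_CA, omega_r)
        c_i = _place(prev_c, n_i, ca_i, _BOND_CA_C, _ANG_N_CA_C, phi_r[:, i])
        coords[:, 3 * i] = n_i
        coords[:, 3 * i + 1] = ca_i
        coords[:, 3 * i + 2] = c_i
    return coords


def structure_from_coords(
    coords: np.ndarray, residue_numbers: Sequence[int], atom_stride: int = 3
) -> StructureModel:
    """Calpha StructureModel from one frame of backbone coordinates."""
    rows = []
    for j, r in enumerate(residue_numbers):
        ca = coords[atom_stride * j + 1]
        rows.append((int(r), "ALA", (float(ca[0]), float(ca[1]), float(ca[2]))))
    return StructureModel(model_index=1, chain_id="A", residues=tuple(rows))


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class TrajectorySpec:
    n_residues: int = 168
    start_residue: int = 102
    domain1: tuple[int, int] = (105, 180)
    domain2: tuple[int, int] = (193, 261)
    n_replicas: int = 3
    n_frames: int = 500
    frame_spacing: float = 0.1  # ns
    jitter_sd: float | Mapping[int, float] = 0.1  # A per coordinate
    torsion_noise_sd: float = 12.0  # degrees of thermal phi/psi noise
    hinge_amplitude: float = 0.0  # degrees (SD of the hinge angle)
    hinge_correlation_time: float = 50.0  # frames
    coupled_residues: tuple[tuple[int, int], ...] = ()
    copula_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.hinge_amplitude < 0:
            raise ValidationError("hinge_amplitude must be >= 0")
        if not 0.0 <= self.copula_rho < 1.0:
            raise ValidationError("copula_rho must be in [0, 1)")
        if self.n_frames < 2:
            raise ValidationError("need >= 2 frames")
        last = self.start_residue + self.n_residues - 1
        for i, j in self.coupled_residues:
            for r in (i, j):
                if not (self.start_residue < r < last):
                    raise ValidationError(
                        f"coupled residue {r} must be interior (has both phi and psi)"
                    )

    @property
    def residue_numbers(self) -> list[int]:
        return [self.start_residue + i for i in range(self.n_residues)]

    @property
    def domains(self) -> tuple[DomainDefinition, DomainDefinition]:
        return (
            DomainDefinition("RRM1", *self.domain1),
            DomainDefinition("RRM2", *self.domain2),
        )


def _jitter_sd_array(spec: TrajectorySpec) -> np.ndarray:
    if isinstance(spec.jitter_sd, Mapping):
        return np.array([float(spec.jitter_sd.get(r, 0.0)) for r in spec.residue_numbers])
    return np.full(spec.n_residues, float(spec.jitter_sd))


def gen_trajectory(spec: TrajectorySpec):
    """Return (TrajectoryEnsemble, ground_truth).

    Base torsions are helical (phi -63, psi -42); thermal noise is wrapped
    Gaussian per frame.  Every torsion of a coupled pair (phi/psi of both
    residues) is driven by a shared one-factor Gaussian copula with pairwise
    latent correlation ``copula_rho`` and uniform circular marginals.  The
    hinge rotates residues past the linker midpoint about a fixed axis by an
    AR(1) angle series of SD ``hinge_amplitude``.
    """
    rng = np.random.default_rng(spec.seed)
    residues = spec.residue_numbers
    n_res, n_frames = spec.n_residues, spec.n_frames
    base_phi, base_psi = -63.0, -42.0
    coupled_slots = {}
    for pair in spec.coupled_residues:
        for r in pair:
            for tors in ("phi", "psi"):
                coupled_slots[(r, tors)] = pair

    jit = _jitter_sd_array(spec)
    d1, d2 = spec.domains
    hinge_res = (d1.end + d2.start) // 2
    hinge_atom_mask = np.repeat([r > hinge_res for r in residues], 3)
    hinge_pivot_index = 3 * residues.index(hinge_res) + 1 if hinge_res in residues else None

    replicas = []
    hinge_series_all = []
    for _rep in range(spec.n_replicas):
        phi = wrap_angle(base_phi + rng.normal(0.0, spec.torsion_noise_sd, (n_frames, n_res)))
        psi = wrap_angle(base_psi + rng.normal(0.0, spec.torsion_noise_sd, (n_frames, n_res)))
        # plant copula-coupled torsions (uniform marginals on (-180, 180])
        for pair in spec.coupled_residues:
            z = rng.normal(size=n_frames)
            a = np.sqrt(spec.copula_rho)
            for r in pair:
                for tors, arr in (("phi", phi), ("psi", psi)):
                    u = a * z + np.sqrt(1.0 - spec.copula_rho) * rng.normal(size=n_frames)
                    arr[:, residues.index(r)] = ndtr(u) * 360.0 - 180.0
        coords = build_backbone(phi, psi)

        if spec.hinge_amplitude > 0:
            tau = max(spec.hinge_correlation_time, 1.0)
            ar = np.exp(-1.0 / tau)
            eps = rng.normal(size=n_frames)
            theta = np.empty(n_frames)
            theta[0] = spec.hinge_amplitude * eps[0]
            for t in range(1, n_frames):
                theta[t] = ar * theta[t - 1] + spec.hinge_amplitude * np.sqrt(1 - ar**2) * eps[t]
            # fixed axis perpendicular to the chain direction of frame 0
            chain_vec = coords[0, -2] - coords[0, 1]
            axis = np.cross(chain_vec, [0.0, 0.0, 1.0])
            if np.linalg.norm(axis) < 1e-9:
                axis = np.array([1.0, 0.0, 0.0])
            axis /= np.linalg.norm(axis)
            rotmats = Rotation.from_rotvec(np.radians(theta)[:, None] * axis[None]).as_matrix()
            pivot = coords[:, hinge_pivot_index, :][:, None, :]
            moving = coords[:, hinge_atom_mask, :] - pivot
            coords[:, hinge_atom_mask, :] = (
                np.einsum("fij,fnj->fni", rotmats, moving) + pivot
            )
            hinge_series_all.append(theta)
        else:
            hinge_series_all.append(np.zeros(n_frames))

        if np.any(jit > 0):
            atom_sd = np.repeat(jit, 3)[None, :, None]
            coords = coords + rng.normal(0.0, 1.0, coords.shape) * atom_sd
        replicas.append(coords)

    topology = tuple(
        (r, name) for r in residues for name in ("N", "CA", "C")
    )
    ens = TrajectoryEnsemble(
        replicas=replicas, topology=topology, frame_spacing=spec.frame_spacing
    )
    truth = {
        "base_torsions": (base_phi, base_psi),
        "torsion_noise_sd": spec.torsion_noise_sd,
        "coupled_pairs": tuple(tuple(p) for p in spec.coupled_residues),
        "copula_rho": spec.copula_rho,
        "pair_mi_nats": (
            -0.5 * np.log(1.0 - spec.copula_rho**2) if spec.copula_rho > 0 else 0.0
        ),
        "jitter_sd": jit,
        "hinge_amplitude": spec.hinge_amplitude,
        "hinge_residue": hinge_res,
        "hinge_series": hinge_series_all,
        "domains": spec.domains,
    }
    return ens, truth


def gen_correlated_angles(n: int, rho: float, seed: int = 0):
    """Two uniform circular angle series with Gaussian-copula dependence.

    The latent correlation is exactly ``rho``; because the normal-CDF map is
    monotone, MI is preserved: MI = -0.5 ln(1 - rho^2) nats.
    """
    if not 0.0 <= rho < 1.0:
        raise ValidationError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.normal(size=n)
    x = ndtr(z1) * 360.0 - 180.0
    y = ndtr(z2) * 360.0 - 180.0
    return x, y


# ---------------------------------------------------------------------------
# melt curves

@dataclass
class MeltSpec:
    tm_values: tuple[float, ...] = (59.0,)  # degC
    van_t_hoff_dh: tuple[float, ...] = (800.0,)  # kJ/mol apparent, per transition
    amplitudes: tuple[float, ...] = (1.0,)
    baseline_intercept: float = 0.1
    baseline_slope: float = 0.0  # per degC
    decay_rate: float = 0.0  # per degC beyond each Tm (dye dissociation), off by default
    t_start: float = 30.0
    t_end: float = 90.0
    sampling_interval: float = 0.5  # degC between instrument reads
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        k = len(self.tm_values)
        if len(self.van_t_hoff_dh) != k or len(self.amplitudes) != k:
            raise ValidationError("tm_values, van_t_hoff_dh, amplitudes must align")
        for tm in self.tm_values:
            if not (self.t_start <= tm <= self.t_end):
                raise ValidationError(f"Tm {tm} outside the scanned range")


_R_KJ = 8.314462618e-3  # kJ/(mol K)


def gen_meltcurve(spec: MeltSpec):
    """Two-state transitions: unfolded fraction
    f(T) = 1 / (1 + exp((dH/R)(1/T - 1/Tm))) with T in kelvin, summed with
    amplitudes, plus a linear baseline, post-Tm exponential decay and noise.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.t_start, spec.t_end + 0.5 * spec.sampling_interval, spec.sampling_interval)
    tk = t + 273.15
    signal = spec.baseline_intercept + spec.baseline_slope * t
    for tm, dh, amp in zip(spec.tm_values, spec.van_t_hoff_dh, spec.amplitudes):
        tmk = tm + 273.15
        frac = 1.0 / (1.0 + np.exp((dh / _R_KJ) * (1.0 / tk - 1.0 / tmk)))
        decay = np.exp(-spec.decay_rate * np.maximum(0.0, t - tm))
        signal = signal + amp * frac * decay
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=t.size)
    curve = MeltCurve(temperature=t, signal=signal, label="synthetic")
    truth = {
        "tm_values": tuple(spec.tm_values),
        "amplitudes": tuple(spec.amplitudes),
        "sampling_interval": spec.sampling_interval,
    }
    return curve, truth
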