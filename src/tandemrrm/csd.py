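"""Chemical-shift perturbation (CSD) and residue-specific Kd fitting.

The combined shift index for an amide peak is

    CSD = sqrt( (d1H)^2 + (d15N)^2 / 4 )        [ppm]

with the nitrogen difference down-weighted by its ~4-fold larger ppm
dispersion.  Significant residues are those with CSD strictly above
mean + one sample standard deviation.

Binding is modelled with the one-site ligand-depletion isotherm: with total
protein [P] and total ligand [L] (both mM),

    CSD_obs = CSDmax * ( (P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L) ) / (2 P)

i.e. CSDmax times the bound fraction from the exact quadratic solution,
which matters here because the affinities are millimolar and the titration
spans [L] >> [P].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .peaklists import AssignedPeak, TitrationSeries

__all__ = [
    "CsdProfile",
    "SignificanceResult",
    "BindingModelParams",
    "ResidueFit",
    "BindingFitResult",
    "compute_csd",
    "csd_profile",
    "select_significant",
    "csd_model",
    "fit_kd_residue",
    "fit_kd_profile",
]


@dataclass
class CsdProfile:
    """Per-residue CSD of one condition against the 0 mM reference."""

    reference_label: str
    perturbed_label: str
    values: dict[int, float]
    disappeared: set[int] = field(default_factory=set)

    def __post_init__(self):
        if any(v < 0 for v in self.values.values()):
            raise ValidationError("CSD values must be non-negative")
        overlap = self.disappeared & set(self.values)
        if overlap:
            raise ValidationError(f"residues {sorted(overlap)} both valued and disappeared")


@dataclass
class SignificanceResult:
    """Mean + one sample SD rule; ``selected`` holds CSD > threshold."""

    mean: float
    sd: float
    threshold: float
    selected: set[int]


@dataclass
class BindingModelParams:
    kd: float  # mM
    csd_max: float  # ppm

    def __post_init__(self):
        if self.kd <= 0 or self.csd_max <= 0:
            raise ValidationError("kd and csd_max must be positive")


@dataclass
class ResidueFit:
    """Outcome of one residue's trace fit; never a silent default."""

    params: BindingModelParams | None
    kd_se: float
    csd_max_se: float
    rss: float
    converged: bool
    message: str = ""


@dataclass
class BindingFitResult:
    per_residue: dict[int, ResidueFit]
    aggregate_kd: float
    aggregate_kd_sd: float
    mode: str
    n_converged: int
    sd_defined: bool = True


def compute_csd(reference: AssignedPeak, perturbed: AssignedPeak) -> float:
    """Combined 1H/15N shift index between two assignments of one residue."""
    if reference.residue_number != perturbed.residue_number:
        raise ValidationError(
            f"residue mismatch: {reference.residue_number} vs {perturbed.residue_number}"
        )
    dh = perturbed.w_H - reference.w_H
    dn = perturbed.w_N - reference.w_N
    return math.sqrt(dh * dh + dn * dn / 4.0)


def csd_profile(series: TitrationSeries, at_conc: float) -> CsdProfile:
    """CSD of every residue at ``at_conc`` against the 0 mM reference.

    Residues present in the reference but missing at ``at_conc`` are recorded
    in ``disappeared`` (peak broadened/overlapped away), never dropped.
    """
    perturbed = series.at(at_conc)  # raises if at_conc not in series
    reference = series.reference
    values: dict[int, float] = {}
    gone: set[int] = set()
    for peak in reference.peaks:
        if peak.residue_number in perturbed:
            values[peak.residue_number] = compute_csd(peak, perturbed.get(peak.residue_number))
        else:
            gone.add(peak.residue_number)
    return CsdProfile(
        reference_label=reference.label,
        perturbed_label=perturbed.label,
        values=values,
        disappeared=gone,
    )


def select_significant(profile: CsdProfile) -> SignificanceResult:
    """Residues with CSD strictly above mean + one sample SD (n-1)."""
    vals = np.array(list(profile.values.values()), dtype=float)
    if vals.size < 2:
        raise ValidationError("need at least 2 residues with finite CSD")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    threshold = mean + sd
    selected = {r for r, v in profile.values.items() if v > threshold}
    return SignificanceResult(mean=mean, sd=sd, threshold=threshold, selected=selected)


def csd_model(params: BindingModelParams, protein_conc: float, ligand_conc) -> np.ndarray | float:
    """Ligand-depletion one-site prediction of the observed CSD (ppm).

    Vectorised over ``ligand_conc``; concentrations in mM.
    """
    if protein_conc <= 0:
        raise ValidationError(f"protein_conc must be > 0, got {protein_conc}")
    p = float(protein_conc)
    kd, cmax = params.kd, params.csd_max
    l = np.asarray(ligand_conc, dtype=float)
    s = p + l + kd
    disc = np.maximum(s * s - 4.0 * p * l, 0.0)
    bound_fraction = (s - np.sqrt(disc)) / (2.0 * p)
    out = cmax * bound_fraction
    return float(out) if out.ndim == 0 else out


def _residuals(theta, l, y, p):
    kd, cmax = theta
    s = p + l + kd
    disc = np.maximum(s * s - 4.0 * p * l, 0.0)
    return cmax * (s - np.sqrt(disc)) / (2.0 * p) - y


def fit_kd_residue(
    trace: Sequence[tuple[float, float]],
    protein_conc: float,
) -> ResidueFit:
    """Nonlinear least squares of the depletion model to one shift trace.

    ``trace`` is (ligand_conc, CSD) pairs; needs >= 4 finite points spanning
    at least a 4-fold concentration range.  Initialisation: Kd0 = median [L],
    CSDmax0 = 1.5 x max CSD, with a multi-start over {0.1x, 1x, 10x} Kd0.
    A flat or non-convergent trace yields ``converged=False``.
    """
    pts = [(float(l), float(y)) for l, y in trace if np.isfinite(l) and np.isfinite(y)]
    pts = [(l, y) for l, y in pts if l > 0]
    if len(pts) < 4:
        raise FitError(f"need >= 4 finite points with [L] > 0, got {len(pts)}")
    l = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if l.max() / l.min() < 4.0:
        raise FitError("ligand concentrations must span at least a 4-fold range")
    if protein_conc <= 0:
        raise ValidationError("protein_conc must be > 0")
    ymax = float(np.abs(y).max())
    if ymax < 1e-9:
        return ResidueFit(None, np.nan, np.nan, float((y**2).sum()), False, "flat trace")

    kd0 = float(np.median(l))
    cmax0 = 1.5 * ymax
    best = None
    for factor in (1.0, 0.1, 10.0):
        try:
            res = least_squares(
                _residuals,
                x0=[kd0 * factor, cmax0],
                bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                args=(l, y, float(protein_conc)),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return ResidueFit(None, np.nan, np.nan, np.nan, False, "no start converged")
    kd, cmax = best.x
    rss = float(2.0 * best.cost)
    dof = max(len(l) - 2, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        kd_se, cmax_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return ResidueFit(None, np.nan, np.nan, rss, False, "singular Jacobian")
    return ResidueFit(
        params=BindingModelParams(kd=float(kd), csd_max=float(cmax)),
        kd_se=kd_se,
        csd_max_se=cmax_se,
        rss=rss,
        converged=True,
    )


def residue_traces(
    series: TitrationSeries, residues: Iterable[int]
) -> dict[int, list[tuple[float, float]]]:
    """(ligand_conc, CSD) pairs per residue, skipping disappeared points."""
    residues = list(residues)
    traces: dict[int, list[tuple[float, float]]] = {r: [] for r in residues}
    for conc in series.ligand_concs[1:]:
        prof = csd_profile(series, conc)
        for r in residues:
            if r in prof.values:
                traces[r].append((conc, prof.values[r]))
    return traces


def fit_kd_profile(
    series: TitrationSeries,
    residues: Iterable[int],
    mode: str = "per_residue_mean",
) -> BindingFitResult:
    """Fit Kd over a residue set, aggregating per the requested convention.

    ``per_residue_mean``: each residue fitted independently; the aggregate is
    the mean of converged Kds with their sample SD.  ``global_shared_kd``: one
    shared Kd with per-residue CSDmax; the aggregate SD is the Kd standard
    error of that fit.  Disappeared titration points are excluded, never
    imputed.
    """
    residues = sorted(set(residues))
    if not residues:
        raise FitError("empty residue set")
    missing = [r for r in residues if r not in series.reference]
    if missing:
        raise ValidationError(f"residues {missing} absent from the reference list")
    if mode not in ("per_residue_mean", "global_shared_kd"):
        raise ValueError(f"unknown mode {mode!r}")

    traces = residue_traces(series, residues)

    if mode == "per_residue_mean":
        per_residue = {r: fit_kd_residue(traces[r], series.protein_conc) for r in residues}
        kds = [f.params.kd for f in per_residue.values() if f.converged]
        if not kds:
            raise FitError("all residue fits failed")
        sd_defined = len(kds) >= 2
        return BindingFitResult(
            per_residue=per_residue,
            aggregate_kd=float(np.mean(kds)),
            aggregate_kd_sd=float(np.std(kds, ddof=1)) if sd_defined else 0.0,
            mode=mode,
            n_converged=len(kds),
            sd_defined=sd_defined,
        )

    # global_shared_kd: parameters [Kd, CSDmax_1 .. CSDmax_m]
    p = float(series.protein_conc)
    ls = [np.array([pt[0] for pt in traces[r]]) for r in residues]
    ys = [np.array([pt[1] for pt in traces[r]]) for r in residues]
    for r, y in zip(residues, ys):
        if y.size < 4:
            raise FitError(f"residue {r}: fewer than 4 usable titration points")

    def global_resid(theta):
        kd = theta[0]
        out = []
        for i, (l, y) in enumerate(zip(ls, ys)):
            s = p + l + kd
            disc = np.maximum(s * s - 4.0 * p * l, 0.0)
            out.append(theta[1 + i] * (s - np.sqrt(disc)) / (2.0 * p) - y)
        return np.concatenate(out)

    kd0 = float(np.median(np.concatenate(ls)))
    x0 = [kd0] + [1.5 * max(float(np.abs(y).max()), 1e-6) for y in ys]
    best = None
    for factor in (1.0, 0.1, 10.0):
        start = list(x0)
        start[0] = kd0 * factor
        res = least_squares(
            global_resid,
            x0=start,
            bounds=([1e-9] * len(start), [np.inf] * len(start)),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("global fit did not converge from any start")
    rss = float(2.0 * best.cost)
    n_obs = sum(y.size for y in ys)
    dof = max(n_obs - len(best.x), 1)
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * rss / dof
        kd_se = float(np.sqrt(cov[0, 0]))
        cmax_ses = [float(np.sqrt(cov[i, i])) for i in range(1, len(best.x))]
    except np.linalg.LinAlgError:
        raise FitError("global fit covariance singular")
    kd = float(best.x[0])
    per_residue = {}
    for i, r in enumerate(residues):
        resid = global_resid(best.x)
        per_residue[r] = ResidueFit(
            params=BindingModelParams(kd=kd, csd_max=float(best.x[1 + i])),
            kd_se=kd_se,
            csd_max_se=cmax_ses[i],
            rss=rss,
            converged=True,
            message="shared-Kd fit",
        )
    return BindingFitResult(
        per_residue=per_residue,
        aggregate_kd=kd,
        aggregate_kd_sd=kd_se,
        mode=mode,
        n_converged=len(residues),
    )
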