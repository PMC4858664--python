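"""Ensemble-level analysis.

Combines the sequence-intrinsic aggregation profile with per-conformation
solvent exposure into structurally corrected profiles, averages them over
conformational ensembles, and provides the ensemble structure analytics:
per-strand beta populations, C-alpha fluctuations (RMSF), and free-energy
surfaces over collective-variable space.

The structural correction implements the protection idea: an
aggregation-prone residue only contributes to the aggregation propensity
of a conformation to the extent that it (and its spatial neighbourhood)
is solvent exposed.  With e_i the relative exposure of residue i and
K a Gaussian kernel over C-alpha distances,

    corrected_i = e_i * [sum_j K(d_ij) a_j e_j] / [sum_j K(d_ij) e_j]

where a_j is the intrinsic score.  A fully buried residue scores 0; with
everything exposed and a vanishing kernel width the corrected profile
reduces to the intrinsic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import superpose
from .errors import ConfigError, InputError
from .intrinsic import AggProfile, total_score
from .structfeat import (
    DihedralSet,
    SwitchingParams,
    backbone_and_chi1_dihedrals,
    compute_cvs,
    exposure_profile,
)
from .structio import Ensemble, Structure, extract_sequence

__all__ = [
    "KB_KJ_PER_MOL_K",
    "KernelParams",
    "CorrectedProfile",
    "EnsembleScores",
    "StrandPopulations",
    "FreeEnergySurface",
    "corrected_profile",
    "ensemble_average_profile",
    "strand_beta_populations",
    "rmsf_profile",
    "cv_table",
    "fes_from_samples",
    "marginalize_fes",
]

KB_KJ_PER_MOL_K = 0.0083145  # Boltzmann constant, kJ/mol/K


@dataclass(frozen=True)
class KernelParams:
    """Spatial smoothing kernel of the structural correction.

    Gaussian over C-alpha distances with width ``sigma_d`` (Angstrom),
    truncated at ``cutoff``; ``sasa_points`` and ``probe_radius``
    parameterize the underlying SASA call.
    """

    sigma_d: float = 5.0
    cutoff: float = 8.0
    probe_radius: float = 1.4
    sasa_points: int = 960
    max_sasa: str = "tien"  # "tien" (full side chains) or "united-gxg"

    def __post_init__(self) -> None:
        if self.sigma_d < 0:
            raise ConfigError("sigma_d must be >= 0")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be > 0")
        if self.max_sasa not in ("tien", "united-gxg"):
            raise ConfigError(
                f"max_sasa must be 'tien' or 'united-gxg', got {self.max_sasa!r}"
            )

    def max_sasa_table(self) -> dict[str, float] | None:
        from .structfeat import united_gxg_max_sasa

        if self.max_sasa == "united-gxg":
            return united_gxg_max_sasa(
                n_points=self.sasa_points, probe_radius=self.probe_radius
            )
        return None  # exposure_profile falls back to the Tien table


@dataclass
class CorrectedProfile:
    """Structurally corrected profile plus its provenance."""

    profile: AggProfile
    exposure: np.ndarray
    kernel: KernelParams
    provenance: str
    excluded_residues: tuple[int, ...] = ()  # 1-based, missing C-alpha

    @property
    def values(self) -> np.ndarray:
        return self.profile.values

    @property
    def total(self) -> float:
        return self.profile.total


@dataclass
class EnsembleScores:
    """Per-conformation total corrected scores and their ensemble mean."""

    per_conformation: np.ndarray
    weights: np.ndarray
    mean: float
    se: float
    single_conformation: bool = False

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InputError("standard error cannot be negative")


def corrected_profile(
    intrinsic: AggProfile,
    structure: Structure,
    kernel: KernelParams | None = None,
    exposure: np.ndarray | None = None,
) -> CorrectedProfile:
    """Exposure-gated, exposure-weighted spatial smoothing of the
    intrinsic profile on one conformation.

    ``exposure`` can be supplied to reuse a precomputed SASA; otherwise
    it is measured here.  Residues without a C-alpha are excluded (NaN)
    and reported in ``excluded_residues``.
    """
    kernel = kernel or KernelParams()
    seq = extract_sequence(structure)
    if seq.residues != intrinsic.sequence.residues:
        raise InputError(
            "structure sequence does not match the intrinsic profile sequence"
        )
    n = len(seq)
    if exposure is None:
        exposure = exposure_profile(
            structure,
            probe_radius=kernel.probe_radius,
            n_points=kernel.sasa_points,
            max_sasa_table=kernel.max_sasa_table(),
        ).relative
    e = np.asarray(exposure, dtype=float)
    if e.shape != (n,):
        raise InputError("exposure vector does not match sequence length")

    ca = structure.coords("CA")
    missing = np.any(np.isnan(ca), axis=1)
    values = np.full(n, np.nan)
    a = intrinsic.values
    sigma2 = max(kernel.sigma_d, 1e-12) ** 2
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    k = np.exp(-0.5 * d**2 / sigma2)
    k[d > kernel.cutoff] = 0.0
    k[:, missing] = 0.0
    for i in range(n):
        if missing[i]:
            continue
        if e[i] == 0.0:
            values[i] = 0.0
            continue
        w = k[i] * e
        denom = w.sum()
        values[i] = e[i] * float(w @ a) / denom if denom > 0 else 0.0
    prof = AggProfile(sequence=seq, values=values, kind="corrected")
    return CorrectedProfile(
        profile=prof,
        exposure=e,
        kernel=kernel,
        provenance=structure.id,
        excluded_residues=tuple(int(i) + 1 for i in np.where(missing)[0]),
    )


def ensemble_average_profile(
    ensemble: Ensemble,
    intrinsic: AggProfile,
    kernel: KernelParams | None = None,
) -> tuple[CorrectedProfile, EnsembleScores]:
    """Weighted ensemble average of per-conformation corrected profiles.

    Also returns the per-conformation total corrected scores with their
    weighted mean and standard error (sd / sqrt(N); with one
    conformation the SE is reported as 0 and flagged).  Because the
    total is the residue mean, the ensemble-mean total equals the total
    of the ensemble-mean profile exactly.
    """
    kernel = kernel or KernelParams()
    w = ensemble.weights
    profiles = [
        corrected_profile(intrinsic, conf, kernel) for conf in ensemble.conformations
    ]
    stack = np.vstack([p.values for p in profiles])
    mean_values = np.einsum("k,kn->n", w, stack)
    totals = np.array([p.total for p in profiles])
    mean = float(np.dot(w, totals))
    n = len(ensemble)
    if n == 1:
        se, single = 0.0, True
    else:
        var = float(np.dot(w, (totals - mean) ** 2))
        se, single = float(np.sqrt(var / n)), False
    avg = CorrectedProfile(
        profile=AggProfile(
            sequence=intrinsic.sequence, values=mean_values, kind="corrected"
        ),
        exposure=np.einsum("k,kn->n", w, np.vstack([p.exposure for p in profiles])),
        kernel=kernel,
        provenance="ensemble-average",
    )
    scores = EnsembleScores(
        per_conformation=totals, weights=w, mean=mean, se=se, single_conformation=single
    )
    return avg, scores


# ---------------------------------------------------------------------------
# Beta populations and fluctuations
# ---------------------------------------------------------------------------

@dataclass
class StrandPopulations:
    """Per-strand beta population: weighted fraction (over conformations
    and strand residues) of the Kabsch-Sander beta indicator."""

    labels: tuple[str, ...]
    ranges: tuple[tuple[int, int], ...]  # 1-based inclusive
    populations: np.ndarray


def strand_beta_populations(
    ensemble: Ensemble,
    strand_defs: list[tuple[str, int, int]],
) -> StrandPopulations:
    """Beta-structure populations over strand windows (1-based inclusive)."""
    from .structfeat import kabsch_sander_bridges

    n = len(ensemble.sequence)
    seen: set[int] = set()
    for label, start, end in strand_defs:
        if not (1 <= start <= end <= n):
            raise InputError(f"strand {label}: range ({start}, {end}) outside 1..{n}")
        span = set(range(start, end + 1))
        if span & seen:
            raise InputError(f"strand {label} overlaps a previous strand definition")
        seen |= span
    flags = np.vstack(
        [kabsch_sander_bridges(conf).beta for conf in ensemble.conformations]
    ).astype(float)
    pops = []
    for label, start, end in strand_defs:
        per_conf = flags[:, start - 1 : end].mean(axis=1)
        pops.append(float(np.dot(ensemble.weights, per_conf)))
    return StrandPopulations(
        labels=tuple(d[0] for d in strand_defs),
        ranges=tuple((d[1], d[2]) for d in strand_defs),
        populations=np.array(pops),
    )


def rmsf_profile(
    ensemble: Ensemble, max_iter: int = 30, tol: float = 1e-8
) -> np.ndarray:
    """Per-residue C-alpha root-mean-square fluctuation (Angstrom).

    Each conformation is rigid-body superposed (Kabsch) onto the
    weighted mean structure, iterating mean and superposition to
    convergence, so rigid motions of the whole chain contribute
    nothing.
    """
    if len(ensemble) < 2:
        raise InputError("RMSF needs at least 2 conformations")
    coords = np.stack([c.coords("CA") for c in ensemble.conformations])
    if np.any(np.isnan(coords)):
        raise InputError("RMSF requires a C-alpha in every residue")
    w = ensemble.weights
    ref = np.einsum("k,kij->ij", w, coords)
    for _ in range(max_iter):
        moved = np.stack([superpose(c, ref)[0] for c in coords])
        new_ref = np.einsum("k,kij->ij", w, moved)
        shift = float(np.max(np.abs(new_ref - ref)))
        ref = new_ref
        coords = moved
        if shift < tol:
            break
    dev2 = np.sum((coords - ref) ** 2, axis=-1)  # (K, N)
    return np.sqrt(np.einsum("k,kn->n", w, dev2))


def cv_table(
    ensemble: Ensemble,
    reference: DihedralSet | None = None,
    switching: SwitchingParams | None = None,
) -> pd.DataFrame:
    """Collective variables of every conformation, one row each.

    AlphaBeta references default to the first conformation's dihedrals.
    """
    ref = reference or backbone_and_chi1_dihedrals(ensemble.conformations[0])
    rows = []
    for conf in ensemble.conformations:
        cv = compute_cvs(conf, reference=ref, switching=switching)
        rows.append(
            {"conformation": conf.id, "beta": cv.beta, "pbeta": cv.pbeta,
             "ab": cv.ab, "bbab": cv.bbab}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """Free energy F = -kB T ln p on a regular grid over CV space.

    ``free_energy`` is shifted so the minimum over occupied bins is 0;
    empty bins are +inf.  ``n_outside`` counts samples falling outside
    the grid.
    """

    axes: tuple[str, ...]
    edges: tuple[np.ndarray, ...]
    free_energy: np.ndarray
    temperature: float
    n_outside: int = 0

    @property
    def probabilities(self) -> np.ndarray:
        """Normalized bin probabilities implied by the surface."""
        kt = KB_KJ_PER_MOL_K * self.temperature
        p = np.exp(-self.free_energy / kt)
        p[~np.isfinite(self.free_energy)] = 0.0
        return p / p.sum()


def fes_from_samples(
    cv_samples: np.ndarray,
    bin_edges: list[np.ndarray],
    weights: np.ndarray | None = None,
    temperature: float = 310.0,
    axes: tuple[str, ...] | None = None,
) -> FreeEnergySurface:
    """Weighted-histogram free-energy surface from CV samples.

    ``cv_samples`` is (N, D); bins are per-axis edge arrays.  The
    surface is invariant under uniform weight rescaling.  Samples
    outside the grid are dropped and counted in ``n_outside``.
    """
    samples = np.atleast_2d(np.asarray(cv_samples, dtype=float))
    if samples.ndim != 2:
        raise InputError("cv_samples must be (N, D)")
    n, d = samples.shape
    if not np.all(np.isfinite(samples)):
        raise InputError("cv_samples must be finite")
    if len(bin_edges) != d:
        raise InputError(f"need {d} edge arrays, got {len(bin_edges)}")
    if temperature <= 0:
        raise ConfigError("temperature must be positive")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise InputError("weights must match the number of samples")
    if np.any(w < 0):
        raise InputError("weights must be non-negative")
    hist, edges = np.histogramdd(samples, bins=bin_edges, weights=w)
    inside = hist.sum()
    unw, _ = np.histogramdd(samples, bins=bin_edges)
    n_outside = n - int(round(float(unw.sum())))
    if inside <= 0:
        raise InputError("no samples fall inside the grid")
    p = hist / inside
    kt = KB_KJ_PER_MOL_K * temperature
    with np.errstate(divide="ignore"):
        f = -kt * np.log(p)
    f -= f[np.isfinite(f)].min()
    return FreeEnergySurface(
        axes=axes or tuple(f"cv{i}" for i in range(d)),
        edges=tuple(np.asarray(e) for e in edges),
        free_energy=f,
        temperature=temperature,
        n_outside=n_outside,
    )


def marginalize_fes(
    surface: FreeEnergySurface, keep_axes: tuple[str, ...] | list[str]
) -> FreeEnergySurface:
    """Integrate out all axes not in ``keep_axes`` (probability space),
    re-convert to free energy and re-shift the minimum to 0.

    Axis order of the result follows the original surface, so keeping
    every axis is the identity.
    """
    keep = list(keep_axes)
    if not keep:
        raise InputError("keep_axes must not be empty")
    unknown = [a for a in keep if a not in surface.axes]
    if unknown:
        raise InputError(f"unknown axes {unknown}; surface has {surface.axes}")
    keep_idx = [i for i, a in enumerate(surface.axes) if a in keep]
    drop_idx = tuple(i for i, a in enumerate(surface.axes) if a not in keep)
    kt = KB_KJ_PER_MOL_K * surface.temperature
    p = np.exp(-surface.free_energy / kt)
    p[~np.isfinite(surface.free_energy)] = 0.0
    p_marg = p.sum(axis=drop_idx) if drop_idx else p
    p_marg = p_marg / p_marg.sum()
    with np.errstate(divide="ignore"):
        f = -kt * np.log(p_marg)
    f -= f[np.isfinite(f)].min()
    return FreeEnergySurface(
        axes=tuple(surface.axes[i] for i in keep_idx),
        edges=tuple(surface.edges[i] for i in keep_idx),
        free_energy=f,
        temperature=surface.temperature,
        n_outside=surface.n_outside,
    )
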