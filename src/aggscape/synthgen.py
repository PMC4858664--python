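"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here with a planted,
measurable signal: sequences containing hydrophobic aggregation hot
spots (optionally flanked by charged gatekeepers), idealized backbones
built from internal coordinates, a minimal antiparallel beta-hairpin,
and pairs of conformational ensembles in which the hot spot's mean
solvent exposure is shifted by a controlled amount between two variants
— the geometric analogue of one protein variant keeping its
aggregation-prone surface patch better protected, on average, than the
other.

Burial is implemented geometrically (flanking segments are packed
against the hot spot as occluding "lids") rather than by faking exposure
numbers, so the full SASA -> structural correction -> ensemble averaging
path is exercised end to end.  All randomness is driven by the spec's
seed; output is deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _build
from ._geom import place_atom
from .errors import ConfigError, InputError
from .structfeat import exposure_profile, united_gxg_max_sasa
from .structio import Atom, Ensemble, Residue, Sequence, Structure

__all__ = [
    "POLAR_BACKGROUND",
    "HOTSPOT_RESIDUES",
    "GATEKEEPER_RESIDUES",
    "SynthSpec",
    "make_sequence",
    "build_chain",
    "build_helix",
    "build_hairpin",
    "make_ensemble_pair",
]

#: small polar/neutral residues whose raw aggregation scores average to
#: about zero, so the background neither masks nor mimics the hot spot
POLAR_BACKGROUND = "STG"
HOTSPOT_RESIDUES = "VILF"
GATEKEEPER_RESIDUES = "DEKR"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic benchmark instance.

    ``hotspots`` are 1-based inclusive windows filled with hydrophobic
    residues; ``exposure_a``/``exposure_b`` are the target mean relative
    exposures of the (first) hot spot in the two generated ensembles, so
    ``exposure_a - exposure_b`` is the planted protection shift;
    ``noise`` is the per-atom Gaussian coordinate noise (Angstrom).
    """

    length: int = 40
    hotspots: tuple[tuple[int, int], ...] = ((15, 19),)
    gatekeepers: bool = False
    ensemble_size: int = 12
    exposure_a: float = 0.70
    exposure_b: float = 0.50
    noise: float = 0.3
    sasa_points: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ConfigError("length must be >= 10")
        spans = sorted(self.hotspots)
        for start, end in spans:
            if not (1 <= start <= end <= self.length):
                raise ConfigError(f"hot spot ({start}, {end}) outside 1..{self.length}")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1 + 1:  # +1: flanking gatekeeper slots must not collide
                raise ConfigError(f"hot spots ({s1},{e1}) and ({s2},{e2}) overlap")
        for name in ("exposure_a", "exposure_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.noise < 0:
            raise ConfigError("noise must be >= 0")
        if self.ensemble_size < 1:
            raise ConfigError("ensemble_size must be >= 1")


def make_sequence(spec: SynthSpec) -> Sequence:
    """Polar background with hydrophobic hot spots, optional gatekeepers.

    Background residues are drawn uniformly from S/T/N/Q/G, hot-spot
    residues from V/I/L/F; with ``gatekeepers`` one D/E/K/R is placed at
    each hot-spot flank.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    codes = list(rng.choice(list(POLAR_BACKGROUND), size=spec.length))
    for start, end in spec.hotspots:
        for i in range(start - 1, end):
            codes[i] = rng.choice(list(HOTSPOT_RESIDUES))
        if spec.gatekeepers:
            for flank in (start - 2, end):
                if 0 <= flank < spec.length:
                    codes[flank] = rng.choice(list(GATEKEEPER_RESIDUES))
    return Sequence(f"synth{spec.seed}", "".join(codes))


def build_chain(
    sequence: Sequence | str,
    phi_psi: tuple[float, float] | list[tuple[float, float]],
    structure_id: str = "built",
) -> Structure:
    """Idealized backbone (N/CA/C/O/CB) from per-residue dihedrals."""
    return _build.build_chain(sequence, phi_psi, structure_id=structure_id)


def build_helix(n_res: int = 12, codes: str | None = None) -> Structure:
    """Ideal alpha-helix at (phi, psi) = (-57, -47) degrees."""
    seq = codes if codes is not None else "A" * n_res
    return _build.build_chain(seq, _build.HELIX_PHI_PSI, structure_id="helix")


def build_hairpin(n_per_strand: int = 5) -> Structure:
    """Minimal antiparallel beta-hairpin.

    Two ideal strands with canonical inter-strand H-bond registry
    (O...H-N about 1.9-2.0 A), joined by a two-residue connector whose
    coordinates are interpolated between the strand termini (a synthetic
    linker, not a modelled turn — bridge detection and the beta-content
    CVs only see the strands).
    """
    if n_per_strand < 3:
        raise ConfigError("n_per_strand must be >= 3")
    a, b = _build.antiparallel_pair(n_per_strand)
    a, b = copy.deepcopy(a), copy.deepcopy(b)
    residues: list[Residue] = []
    for res in a.residues:
        residues.append(res)
    # synthetic two-residue linker between A's C-terminus and B's N-terminus
    c_end = a.residues[-1].atom("C").coords
    n_start = b.residues[0].atom("N").coords
    gap = n_start - c_end
    outward = np.array([1.0, 0.0, 0.0]) * 2.0
    for k, t in enumerate((1.0 / 3.0, 2.0 / 3.0), start=1):
        center = c_end + t * gap + outward * np.sin(np.pi * t)
        step = gap / np.linalg.norm(gap)
        atoms = [
            Atom("N", "N", center - 0.6 * step),
            Atom("CA", "C", center),
            Atom("C", "C", center + 0.6 * step),
            Atom("O", "O", center + 0.6 * step + np.array([0.0, 0.0, 1.23])),
        ]
        residues.append(Residue(index=0, code="G", atoms=atoms))
    for res in b.residues:
        residues.append(res)
    for i, res in enumerate(residues):
        res.index = i + 1
    return Structure(id=f"hairpin{n_per_strand}", residues=residues)


# ---------------------------------------------------------------------------
# Ensemble pairs with a planted protection shift
# ---------------------------------------------------------------------------

def _lid_segments(spec: SynthSpec) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    """(hotspot, four lid windows) as 0-based [start, end) windows.

    Two lid segments are carved from each flank (separated from the hot
    spot by a 2-residue gap) so that the hot spot can be occluded from
    above, below and both sides.
    """
    start, end = spec.hotspots[0]
    s0, e0 = start - 1, end  # half-open
    w = e0 - s0
    lids = [
        (s0 - 2 - w, s0 - 2),
        (s0 - 3 - 2 * w, s0 - 3 - w),
        (e0 + 2, e0 + 2 + w),
        (e0 + 3 + w, e0 + 3 + 2 * w),
    ]
    if min(l0 for l0, _ in lids) < 0 or max(l1 for _, l1 in lids) > spec.length:
        raise ConfigError(
            "hot spot too close to the termini to carve out packing lids; "
            f"need {2 * w + 3} residues on both sides"
        )
    return (s0, e0), lids


def _packed_conformation(
    base: Structure, spec: SynthSpec, lid_distance: float
) -> Structure:
    """Copy of ``base`` with both lid segments packed over/under the hot spot.

    Each lid adopts the hot-spot segment's geometry translated by
    +-``lid_distance`` along z, so occlusion of the hot spot increases
    smoothly as the distance shrinks.
    """
    (s0, e0), lids = _lid_segments(spec)
    struct = copy.deepcopy(base)
    hot = struct.residues[s0:e0]
    # above/below lids are staggered half a CA-CA step to plug lattice
    # gaps; the lateral lids close off the in-plane directions
    offsets = [
        np.array([1.9, 0.0, lid_distance]),
        np.array([-1.9, 0.0, -lid_distance]),
        np.array([0.0, lid_distance + 1.5, 0.0]),
        np.array([0.0, -(lid_distance + 1.5), 0.0]),
    ]
    for (l0, l1), offset in zip(lids, offsets):
        for k, res in enumerate(struct.residues[l0:l1]):
            template = hot[k]
            for atom in res.atoms:
                src = template.atom(atom.name) or template.atom("CA")
                atom.coords = src.coords + offset
    return struct


def _hotspot_exposure(struct: Structure, spec: SynthSpec) -> float:
    (s0, e0), _ = _lid_segments(spec)
    # exposures are calibrated against the united-atom Gly-X-Gly maxima
    # so the builder's fully exposed residues approach e = 1
    table = united_gxg_max_sasa(n_points=spec.sasa_points)
    prof = exposure_profile(struct, n_points=spec.sasa_points, max_sasa_table=table)
    return float(prof.relative[s0:e0].mean())


def _distance_for_exposure(
    base: Structure, spec: SynthSpec, target: float, max_iter: int = 40
) -> tuple[float, float]:
    """Bisect the lid distance until the hot spot's mean exposure hits
    ``target``; returns (distance, achieved).  Raises when the target is
    outside the geometrically reachable range."""
    lo, hi = 2.5, 30.0
    e_lo = _hotspot_exposure(_packed_conformation(base, spec, lo), spec)
    e_hi = _hotspot_exposure(_packed_conformation(base, spec, hi), spec)
    if not e_lo - 1e-6 <= target <= e_hi + 1e-6:
        raise InputError(
            f"target exposure {target:.3f} unreachable; achievable range "
            f"[{e_lo:.3f}, {e_hi:.3f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        e_mid = _hotspot_exposure(_packed_conformation(base, spec, mid), spec)
        if abs(e_mid - target) < 2e-3:
            return mid, e_mid
        if e_mid < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid, _hotspot_exposure(_packed_conformation(base, spec, mid), spec)


def _noisy_ensemble(
    packed: Structure, spec: SynthSpec, rng: np.random.Generator, label: str
) -> Ensemble:
    confs = []
    for k in range(spec.ensemble_size):
        conf = copy.deepcopy(packed)
        conf.id = f"{label}#{k + 1}"
        if spec.noise > 0:
            for res in conf.residues:
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(0.0, spec.noise, size=3)
        confs.append(conf)
    return Ensemble(conformations=confs)


def make_ensemble_pair(spec: SynthSpec) -> tuple[Ensemble, Ensemble, dict]:
    """Two ensembles of one sequence differing only in hot-spot burial.

    Variant A packs the flanking lids at the distance that realizes
    ``spec.exposure_a`` (mean relative exposure over the hot spot, on
    the noiseless conformation), variant B at the distance realizing
    ``spec.exposure_b``; every conformation then receives independent
    Gaussian coordinate noise.  Ground truth reports the calibrated lid
    distances and the exposure difference measured on the generated
    (noisy) ensembles.
    """
    if spec.ensemble_size < 10:
        raise ConfigError("ensemble pairs need ensemble_size >= 10")
    seq = make_sequence(spec)
    base = build_chain(seq, _build.STRAND_PHI_PSI, structure_id=seq.id)
    d_a, cal_a = _distance_for_exposure(base, spec, spec.exposure_a)
    if abs(spec.exposure_a - spec.exposure_b) < 1e-12:
        d_b, cal_b = d_a, cal_a
    else:
        d_b, cal_b = _distance_for_exposure(base, spec, spec.exposure_b)
    rng = np.random.default_rng(spec.seed)
    rng_a, rng_b = rng.spawn(2)
    ens_a = _noisy_ensemble(_packed_conformation(base, spec, d_a), spec, rng_a, "A")
    ens_b = _noisy_ensemble(_packed_conformation(base, spec, d_b), spec, rng_b, "B")

    def _measured(ens: Ensemble) -> float:
        return float(
            np.average(
                [_hotspot_exposure(c, spec) for c in ens.conformations],
                weights=ens.weights,
            )
        )

    e_a, e_b = _measured(ens_a), _measured(ens_b)
    ground_truth = {
        "sequence": seq.residues,
        "hotspot": spec.hotspots[0],
        "lid_distance_a": d_a,
        "lid_distance_b": d_b,
        "target_exposure_a": spec.exposure_a,
        "target_exposure_b": spec.exposure_b,
        "measured_exposure_a": e_a,
        "measured_exposure_b": e_b,
        "measured_delta_e": e_a - e_b,
        "planted_delta_e": spec.exposure_a - spec.exposure_b,
    }
    return ens_a, ens_b, ground_truth
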