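"""Rational mutation design.

Two-stage logic mirroring how exposure-shifted variants are engineered:
(1) select candidate sites that are both aggregation-prone in sequence
(intrinsic score above a threshold, default 1.0) and structurally
responsive (the ensemble-averaged corrected score changes by more than a
threshold, default 0.2, between two variant ensembles); (2) at each
candidate site, recompute the full intrinsic pipeline for all 19
substitutions and rank them by the change in total intrinsic score —
negative deltas are protective (solubilizing), positive ones promote
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .intrinsic import (
    AggProfile,
    ProfileParams,
    PropensityScales,
    intrinsic_profile,
)
from .structio import CANONICAL_AA, Sequence

__all__ = [
    "CandidateSite",
    "MutationScan",
    "BoxStats",
    "DesignReport",
    "candidate_sites",
    "scan_site",
    "rank_designs",
    "box_stats",
]


@dataclass(frozen=True)
class CandidateSite:
    """A residue passing both design filters."""

    index: int  # 1-based
    code: str
    intrinsic_value: float
    delta_corrected: float  # corrected_B - corrected_A at this residue


@dataclass
class MutationScan:
    """Delta total intrinsic score for the 19 substitutions at one site."""

    site: int
    wild_type: str
    deltas: dict[str, float]

    def __post_init__(self) -> None:
        if self.wild_type in self.deltas:
            raise InputError("self-substitution must not appear in a scan")
        if len(self.deltas) != 19:
            raise InputError(f"scan at site {self.site} has {len(self.deltas)} entries, expected 19")


@dataclass(frozen=True)
class BoxStats:
    """Box-plot summary: median, quartiles, 5th/95th percentiles."""

    median: float
    q1: float
    q3: float
    p5: float
    p95: float


@dataclass
class DesignReport:
    """Ranked single mutations across the scanned sites.

    ``ranking`` holds (site, wild-type, substitution, delta) tuples,
    most protective first (direction="protect") or most promoting first
    (direction="promote"); ties break deterministically by site index
    then substitution letter.
    """

    direction: str
    ranking: list[tuple[int, str, str, float]]

    @property
    def best(self) -> tuple[int, str, str, float]:
        return self.ranking[0]


def candidate_sites(
    intrinsic: AggProfile,
    corrected_avg_a: np.ndarray,
    corrected_avg_b: np.ndarray,
    intrinsic_threshold: float = 1.0,
    delta_threshold: float = 0.2,
) -> list[CandidateSite]:
    """Sites with intrinsic score > ``intrinsic_threshold`` whose
    ensemble-averaged corrected score differs by more than
    ``delta_threshold`` (absolute) between the two variants."""
    a = np.asarray(corrected_avg_a, dtype=float)
    b = np.asarray(corrected_avg_b, dtype=float)
    n = len(intrinsic.sequence)
    if a.shape != (n,) or b.shape != (n,):
        raise InputError("corrected profiles must match the intrinsic profile length")
    out = []
    delta = b - a
    for i in range(n):
        if intrinsic.values[i] > intrinsic_threshold and abs(delta[i]) > delta_threshold:
            out.append(
                CandidateSite(
                    index=i + 1,
                    code=intrinsic.sequence.residues[i],
                    intrinsic_value=float(intrinsic.values[i]),
                    delta_corrected=float(delta[i]),
                )
            )
    return out


def scan_site(
    sequence: Sequence,
    site: int,
    scales: PropensityScales | None = None,
    params: ProfileParams | None = None,
) -> MutationScan:
    """Recompute the full intrinsic pipeline for every substitution at
    ``site`` (1-based) and report delta total (mutant - reference)."""
    if not 1 <= site <= len(sequence):
        raise InputError(f"site {site} outside sequence of length {len(sequence)}")
    scales = scales or PropensityScales.default()
    params = params or ProfileParams()
    ref_total = intrinsic_profile(sequence, scales, params).total
    wt = sequence.residues[site - 1]
    deltas = {}
    for aa in CANONICAL_AA:
        if aa == wt:
            continue
        mutant = sequence.mutate(site, aa)
        deltas[aa] = intrinsic_profile(mutant, scales, params).total - ref_total
    return MutationScan(site=site, wild_type=wt, deltas=deltas)


def rank_designs(scans: list[MutationScan], direction: str) -> DesignReport:
    """Rank all scanned substitutions by delta total intrinsic score.

    direction="protect": ascending (most negative delta first);
    direction="promote": descending.  Deterministic tie-break by site
    index, then substitution letter.
    """
    if not scans:
        raise InputError("rank_designs needs at least one scan")
    if direction not in ("protect", "promote"):
        raise InputError(f"direction must be 'protect' or 'promote', got {direction!r}")
    entries = [
        (scan.site, scan.wild_type, aa, float(delta))
        for scan in scans
        for aa, delta in scan.deltas.items()
    ]
    sign = 1.0 if direction == "protect" else -1.0
    entries.sort(key=lambda t: (sign * t[3], t[0], t[2]))
    return DesignReport(direction=direction, ranking=entries)


def box_stats(score_set: np.ndarray) -> BoxStats:
    """Median, quartiles (linear interpolation) and 5th/95th percentiles."""
    values = np.asarray(score_set, dtype=float)
    if values.size == 0:
        raise InputError("box_stats needs at least one value")
    p5, q1, med, q3, p95 = np.percentile(values, [5, 25, 50, 75, 95])
    return BoxStats(median=float(med), q1=float(q1), q3=float(q3),
                    p5=float(p5), p95=float(p95))
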