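"""Sequence-based ("intrinsic") aggregation propensity profiles.

The intrinsic profile scores each residue's contribution to aggregation
from sequence alone: a linear combination of z-scored physico-chemical
propensities (hydrophobicity, beta-sheet and alpha-helix propensity,
side-chain charge), smoothed over a sliding window so that scores
describe aggregation-prone *regions* rather than isolated residues, and
reduced near charged "gatekeeper" residues (D/E/K/R), which are known to
suppress the aggregation of hydrophobic stretches they flank.

Sign convention: higher score = more aggregation-prone (the inverse of a
solubility score).  Values above ``aggregation_threshold`` (default 1.0)
mark aggregation-prone regions.

The per-residue combination is

    raw_i = w_hyd * z_hyd(aa_i) + w_beta * z_beta(aa_i)
            - w_alpha * z_alpha(aa_i) - w_chg * |charge(aa_i)|

where z_* denotes the scale z-scored over the 20-residue alphabet.  The
charge term uses the raw formal charge so that uncharged residues incur
exactly zero penalty.  The weights are an open calibration (the
published parameterizations in this family are proprietary); the
defaults here are fixed by the requirement that hydrophobic hot spots
score above +1 and gatekeepered flanks below it, and every constant is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .structio import CANONICAL_AA, Sequence

__all__ = [
    "PropensityScales",
    "ProfileParams",
    "AggProfile",
    "raw_residue_scores",
    "smooth_profile",
    "gatekeeper_correction",
    "total_score",
    "aggregation_prone_regions",
    "intrinsic_profile",
]

GATEKEEPERS = frozenset("DEKR")


def _zscore(scale: dict[str, float]) -> dict[str, float]:
    vals = np.array([scale[aa] for aa in CANONICAL_AA])
    mu, sd = vals.mean(), vals.std()
    return {aa: (scale[aa] - mu) / sd for aa in CANONICAL_AA}


@dataclass(frozen=True)
class PropensityScales:
    """The four per-amino-acid scales the raw score combines.

    ``hydrophobicity``, ``beta`` and ``alpha`` are arbitrary-unit
    propensities (z-scored internally before combination); ``charge`` is
    the formal side-chain charge at pH 7.4, fractional for histidine.
    """

    hydrophobicity: dict[str, float]
    beta: dict[str, float]
    alpha: dict[str, float]
    charge: dict[str, float]

    def __post_init__(self) -> None:
        for name in ("hydrophobicity", "beta", "alpha", "charge"):
            scale = getattr(self, name)
            missing = [aa for aa in CANONICAL_AA if aa not in scale]
            if missing:
                raise ConfigError(f"scale {name!r} missing residues {missing}")

    @classmethod
    def default(cls) -> "PropensityScales":
        """Load the packaged scale table (Kyte-Doolittle / Chou-Fasman)."""
        with resources.files("aggscape").joinpath("data/scales.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
        df = df.set_index("aa")
        return cls(
            hydrophobicity=df["hydrophobicity"].to_dict(),
            beta=df["beta"].to_dict(),
            alpha=df["alpha"].to_dict(),
            charge=df["charge"].to_dict(),
        )

    def znormed(self) -> tuple[dict, dict, dict]:
        """(z_hyd, z_beta, z_alpha) z-scored over the 20-letter alphabet."""
        return (
            _zscore(self.hydrophobicity),
            _zscore(self.beta),
            _zscore(self.alpha),
        )


@dataclass(frozen=True)
class ProfileParams:
    """Tunable constants of the intrinsic pipeline (all dimensionless).

    ``window`` is the sliding-average width (odd); ``gatekeeper_strength``
    (g) is the score reduction per charged residue within
    ``gatekeeper_reach`` (r_g) positions; scores above
    ``aggregation_threshold`` mark aggregation-prone regions.
    """

    w_hyd: float = 1.0
    w_beta: float = 0.4
    w_alpha: float = 0.2
    w_chg: float = 0.8
    window: int = 7
    gatekeeper_strength: float = 0.15
    gatekeeper_reach: int = 3
    aggregation_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError(f"window must be an odd integer >= 1, got {self.window}")
        if self.gatekeeper_strength < 0:
            raise ConfigError("gatekeeper_strength must be >= 0")
        if self.gatekeeper_reach < 0:
            raise ConfigError("gatekeeper_reach must be >= 0")
        if not np.isfinite(self.aggregation_threshold):
            raise ConfigError("aggregation_threshold must be finite")


@dataclass
class AggProfile:
    """Per-residue aggregation scores plus their scalar total.

    ``kind`` is ``"intrinsic"`` (sequence-only) or ``"corrected"``
    (exposure-modulated); ``total`` is the residue mean of ``values``.
    """

    sequence: Sequence
    values: np.ndarray
    kind: str = "intrinsic"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sequence),):
            raise InputError(
                f"profile has {self.values.shape} values for a "
                f"{len(self.sequence)}-residue sequence"
            )
        if self.kind not in ("intrinsic", "corrected"):
            raise ConfigError(f"unknown profile kind {self.kind!r}")

    @property
    def total(self) -> float:
        return total_score(self.values)

    def __len__(self) -> int:
        return len(self.values)


def raw_residue_scores(
    sequence: Sequence,
    scales: PropensityScales | None = None,
    params: ProfileParams | None = None,
) -> np.ndarray:
    """Unsmoothed per-residue aggregation scores (the linear combination)."""
    scales = scales or PropensityScales.default()
    params = params or ProfileParams()
    z_hyd, z_beta, z_alpha = scales.znormed()
    return np.array(
        [
            params.w_hyd * z_hyd[aa]
            + params.w_beta * z_beta[aa]
            - params.w_alpha * z_alpha[aa]
            - params.w_chg * abs(scales.charge[aa])
            for aa in sequence.residues
        ]
    )


def smooth_profile(raw_scores: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; truncated and renormalized at the termini."""
    raw_scores = np.asarray(raw_scores, dtype=float)
    n = raw_scores.shape[0]
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be an odd integer >= 1, got {window}")
    if window > n:
        raise ConfigError(f"window {window} exceeds sequence length {n}")
    kernel = np.ones(window)
    # 'same'-mode convolution of values and of ones gives truncated-window
    # sums and counts in one pass
    sums = np.convolve(raw_scores, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return sums / counts


def gatekeeper_correction(
    profile: np.ndarray,
    sequence: Sequence,
    g: float,
    r_g: int,
) -> np.ndarray:
    """Reduce each score by g per charged residue (D/E/K/R) within +-r_g.

    The correction only ever lowers values (g >= 0); a residue counts its
    charged neighbours, not itself.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (len(sequence),):
        raise InputError("profile and sequence lengths differ")
    if g < 0:
        raise ConfigError("gatekeeper strength must be >= 0")
    n = len(sequence)
    charged = np.array([aa in GATEKEEPERS for aa in sequence.residues], dtype=float)
    out = profile.copy()
    for i in range(n):
        lo, hi = max(0, i - r_g), min(n, i + r_g + 1)
        count = charged[lo:hi].sum() - charged[i]
        out[i] -= g * count
    return out


def total_score(values: np.ndarray) -> float:
    """Scalar aggregation score of a profile: the residue mean.

    The mean (rather than the sum) keeps totals comparable across
    sequence lengths.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("cannot total an empty profile")
    return float(values.mean())


def aggregation_prone_regions(
    profile: AggProfile | np.ndarray,
    threshold: float = 1.0,
) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive residues scoring above ``threshold``.

    Returns ``(start, end, peak)`` triples, 1-based inclusive.
    """
    values = profile.values if isinstance(profile, AggProfile) else np.asarray(profile, float)
    if not np.isfinite(threshold) and threshold > 0:
        raise ConfigError("threshold must be finite or -inf")
    above = values > threshold
    regions = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((start + 1, i, float(values[start:i].max())))
            start = None
    if start is not None:
        regions.append((start + 1, len(values), float(values[start:].max())))
    return regions


def intrinsic_profile(
    sequence: Sequence,
    scales: PropensityScales | None = None,
    params: ProfileParams | None = None,
) -> AggProfile:
    """Full intrinsic pipeline: raw combination -> smoothing -> gatekeepers.

    A pure function of (sequence, scales, params): identical inputs give
    byte-identical output.
    """
    scales = scales or PropensityScales.default()
    params = params or ProfileParams()
    raw = raw_residue_scores(sequence, scales, params)
    n = len(sequence)
    # window capped at (odd) sequence length for very short chains
    window = params.window if params.window <= n else (n if n % 2 else n - 1)
    smoothed = smooth_profile(raw, window)
    corrected = gatekeeper_correction(
        smoothed, sequence, params.gatekeeper_strength, params.gatekeeper_reach
    )
    return AggProfile(sequence=sequence, values=corrected, kind="intrinsic")
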