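# Methods

This note documents the models, parameter choices and numerical
conventions behind `aggscape`, and what the synthetic benchmark does and
does not establish.

## Intrinsic aggregation profile

The per-residue raw score is a linear combination of four
physico-chemical determinants:

    raw_i = w_hyd·z_hyd(aa_i) + w_β·z_β(aa_i) − w_α·z_α(aa_i) − w_chg·|q(aa_i)|

* Scales: Kyte–Doolittle hydrophobicity, Chou–Fasman β-sheet and
  α-helix propensities, formal side-chain charge at pH 7.4 (His counted
  as +0.1). Shipped as a versioned TSV resource
  (`aggscape/data/scales.tsv`).
* The three analogue scales are z-scored over the 20-letter alphabet so
  the weights are comparable; the charge term uses the *raw* |q|, not a
  z-score — a z-scored charge would shift the zero and penalize
  uncharged residues, destroying the property that charge-free
  sequences are untouched by charge terms.
* Defaults w = (1.0, 0.4, 0.2, 0.8). The published solubility-score
  parameterization this architecture follows is proprietary, so these
  weights are this package's own calibration, fixed once by two
  qualitative requirements: a 5-residue V/I/L/F hot spot in a polar
  background must exceed the aggregation threshold (+1), and placing
  D/E/K/R gatekeepers at its flanks must pull the flanks below it.
  Absolute scores are therefore not comparable to published solubility
  scores; orderings and threshold logic are the meaningful outputs.

Raw scores are smoothed by a centered moving average (window 7,
truncated and renormalized at the termini — window capped at the largest
odd number ≤ length for very short chains), then each residue is reduced
by g = 0.15 per charged D/E/K/R within ±3 positions (its own charge not
counted). The total score is the residue **mean**, not the sum, so
totals are comparable across lengths. All constants live in
`ProfileParams`.

A consequence of the window/reach geometry worth knowing: gatekeepers at
the flanks lower a hot spot's smoothed *peak* only if the peak position
is within gatekeeper reach or its smoothing window reaches the flanks.
For a 5-wide hot spot under the default window 7 / reach 3 both
mechanisms act; for a 7-wide hot spot the centre residue would be
untouched.

## Solvent exposure

SASA uses the Shrake–Rupley method with a deterministic golden-spiral
lattice (default 960 points, probe 1.4 Å) and Bondi-type radii (C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20 Å); hydrogens are excluded by default
since crystal structures lack them. An isolated atom's area is exact by
construction; agreement with an independent Monte-Carlo occlusion
estimator is within 1% on random clusters. Because the lattice is fixed
in space, rotation invariance is only approximate: ~1–2 Å² per residue
at 960 points on a 16-mer, shrinking with lattice density. Analyses that
compare SASA across conformations of the same chain are unaffected at
the exposure scales used here.

Relative exposure is e_i = clamp(SASA_i / maxSASA(aa_i), 0, 1). Two
maximum-SASA references are available (`KernelParams.max_sasa`):

* `"tien"` — theoretical Gly-X-Gly values of Tien et al. (2013), the
  right choice for real, full-side-chain structures (the default);
* `"united-gxg"` — each residue measured in an extended Gly-X-Gly
  tripeptide built with the package's own united-atom geometry
  (backbone + CB + one pseudo-γ atom). This is the matched reference
  for internally generated structures; against the Tien values their
  exposures would saturate near 0.5 simply because coarse side chains
  have less area. The pipeline switches to it automatically when it
  generated the structures itself.

## Structural correction and ensemble averaging

    corrected_i = e_i · [Σ_j K(d_ij)·raw'_j·e_j] / [Σ_j K(d_ij)·e_j]

with K Gaussian over Cα–Cα distances (σ_d = 5 Å, cutoff 8 Å, j includes
i). The form is this package's definition (the literature names the
concept but not the formula): exposure gates the residue itself, and the
exposure-weighted neighbourhood average lets buried neighbours shield a
residue's contribution. Fully buried residues (e_i = 0) score exactly 0;
with everything exposed and σ_d → 0 the corrected profile reduces to
the intrinsic one. Note the bound that actually holds is
|corrected_i| ≤ e_i·max_j|intrinsic_j| — a residue surrounded by
stronger neighbours can exceed its own intrinsic magnitude.

Ensemble averaging is a weighted mean (uniform weights by default; a
per-conformation weight file can supply externally computed weights,
e.g. from enhanced-sampling reweighting, which is out of scope here).
Since the total is a residue mean, the ensemble-mean total equals the
total of the ensemble-mean profile exactly (asserted to 1e-12). The
uncertainty reported is the weighted sd/√N without autocorrelation
correction — appropriate for independently generated conformations, an
underestimate for correlated trajectory frames.

## Secondary structure, CVs, free-energy surfaces

* **Kabsch–Sander bridges.** H-bond when
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol,
  with the amide H rebuilt 1.0 Å from N opposite the bisector of
  C(i−1)–N–CA; prolines and chain-initial residues never donate.
  Antiparallel/parallel bridges between residues ≥3 apart follow the
  standard patterns; the per-residue β indicator is "participates in ≥1
  bridge". Per-residue β populations use bridges (well-defined
  attribution); the segment CVs below are kept for free-energy axes.
* **β-content CVs.** Sum over disjoint 3-residue segment pairs
  (j ≥ i+3) of S(RMSD to an ideal two-strand template),
  S(r) = (1−(r/r0)^8)/(1−(r/r0)^12), r0 = 1 Å. Templates are built
  internally: a second ideal strand ((φ,ψ) = (−139°, 135°)) is rigidly
  placed by minimizing a least-squares ideal-H-bond objective
  (r_ON 2.9 Å, r_OH 1.95 Å at alternating rungs, the canonical ladder)
  with steric and strand-direction terms — the raw Kabsch–Sander energy
  is unbounded below and unusable as a placement objective. The
  template is the middle 3+3 residues of an optimized 5-residue pair.
  Absolute CV values depend on these internal templates and are not
  comparable to values from other implementations.
* **AlphaBeta CVs.** AB = Σ ½[1 + cos(θ − θ_ref)] over hydrophobic
  (A/V/L/I/M/F/W/C) χ1 angles, bbAB over all φ/ψ; undefined angles are
  excluded, reference angles default to an ensemble's first
  conformation.
* **FES.** p from a weighted histogram on per-axis bin edges;
  F = −k_B·T·ln p shifted so the occupied minimum is 0 (k_B = 0.0083145
  kJ/mol/K, default T = 310 K); empty bins +inf; marginalization sums
  probabilities over dropped axes and re-shifts, so keeping all axes is
  the identity and separable distributions marginalize exactly.

## Synthetic benchmark

The generator plants every signal the pipeline is meant to recover:

* Sequences: polar/neutral background drawn from S/T/G (their raw
  scores average ≈ 0, so the background neither masks nor mimics a hot
  spot), a 5-residue V/I/L/F hot spot at positions 15–19 of a 40-mer,
  optional gatekeepers at the flanks.
* Structures: backbones grown by NeRF from standard geometry
  (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231, CA–CB 1.521 Å;
  dihedral round trip exact to 1e-6 rad), plus one pseudo-γ atom per
  side chain at trans χ1 for coarse side-chain bulk.
* Protection shift: the base chain is extended; four flank-derived
  "lid" segments are rigidly packed around the hot spot (above/below
  staggered by half a CA–CA step, plus two lateral), and the lid
  distance is bisected until the noiseless hot-spot mean exposure hits
  the target (achievable range ≈ [0.10, 0.79] across seeds). Variant A
  targets e = 0.70, variant B 0.50 by default (δe = 0.2); every
  conformation then gets independent 0.3 Å Gaussian coordinate noise.
  Ensembles are 12 conformations (≥10 required), SASA at 256 lattice
  points — desk-scale sizes at which the planted δe = 0.2 ordering
  margin is ≈8 standard deviations across seeds.
* Ground truth reports the calibrated lid distances and the exposure
  shift measured on the generated (noisy) ensembles.

What passing does and does not show: the benchmark exercises the full
SASA → correction → averaging path on geometrically buried (not faked)
exposures, so it validates the mechanism and its statistics. It does not
emulate real side-chain packing, rotamers, correlated ensemble
structure, or metadynamics weights; recovering a planted shift here does
not certify quantitative accuracy on experimental ensembles, where the
correction constants (σ_d, cutoff) and the weight model matter.

## Design stage

Candidate sites: intrinsic > 1.0 **and** |Δ ensemble-corrected| > 0.2
(both thresholds strict, the Δ in absolute value since designs go in
both directions). Scans recompute the *full* intrinsic pipeline per
substitution — smoothing and gatekeeper effects of the mutation on its
neighbours are included, so Δtotal is not a per-site lookup.
Mutate-then-revert is exact to 1e-12. Ranking ties break by site index
then substitution letter; box statistics use linear-interpolation
(type-7) quantiles. Δ is computed on the intrinsic score; the corrected
profiles enter only site selection — mirroring the two-stage logic of
selecting structurally responsive sites, then designing on sequence.

## Determinism and error handling

Every stochastic step consumes a `numpy` `default_rng` seeded from the
configuration; fixture PDB output and full-run report bundles are
byte-identical under identical config+seed (no timestamps are written).
The CLI maps `InputError` → exit 2, `ConfigError` → exit 3,
`InternalError` → exit 4. Configurations reject unknown keys and
round-trip losslessly through YAML.

## Known limitations

* No pH-dependent titration, pattern terms beyond the gatekeeper
  correction, or cross-interaction (co-aggregation) scores.
* Single-chain analysis; mmCIF and binary trajectory formats are out of
  scope (ensembles travel as multi-MODEL PDB).
* The ensemble SE has no autocorrelation correction; supply externally
  computed weights for reweighted ensembles.
* Non-standard residues (MSE etc.) are rejected, not remapped.
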