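# aggscape

Structure- and ensemble-corrected protein aggregation propensity
profiling, with a rational mutation-design stage.

## The problem

Whether a folded protein aggregates is set only partly by its sequence.
Hydrophobic, β-prone stretches ("hot spots") drive aggregation, and
charged gatekeeper residues flanking them suppress it — but in the
native state many hot spots are buried, and what matters is how much of
the aggregation-prone surface is *exposed on average* over the
conformational ensemble. Two variants with near-identical sequences and
stabilities can differ sharply in aggregation because one keeps its hot
spots better protected. `aggscape` implements that analysis chain for
anyone studying amyloidogenic proteins (the motivating system is
β2-microglobulin and its aggregation-resistant variants) or engineering
solubility: per-residue aggregation scores from sequence, their
structural correction by solvent exposure, averaging over conformational
ensembles, ensemble structure analytics, and an in-silico saturation
mutagenesis stage that proposes protective or aggregation-promoting
single mutations.

## The model

**Intrinsic profile.** Each residue gets a raw aggregation score
(higher = more aggregation-prone; the sign-inverse of a solubility
score)

    raw_i = w_hyd·z_hyd(aa_i) + w_β·z_β(aa_i) − w_α·z_α(aa_i) − w_chg·|q(aa_i)|

from z-scored Kyte–Doolittle hydrophobicity and Chou–Fasman β/α
propensities plus a formal-charge penalty. The raw scores are smoothed
over a 7-residue window and reduced by g = 0.15 per charged gatekeeper
(D/E/K/R) within ±3 positions. Values above 1 mark aggregation-prone
regions; the scalar **total** is the residue mean.

**Structural correction.** With e_i the relative solvent exposure
(Shrake–Rupley SASA over a maximum-SASA reference, clamped to [0, 1])
and K a Gaussian kernel over Cα–Cα distances (σ = 5 Å, cutoff 8 Å),

    corrected_i = e_i · [Σ_j K(d_ij)·raw'_j·e_j] / [Σ_j K(d_ij)·e_j]

so a buried hot spot contributes nothing. Averaging the per-conformation
totals over an ensemble (uniform or supplied weights) gives the
**ensemble total structurally-corrected score**, the quantity that
separates aggregation-prone from protected variants.

**Ensemble analytics.** Kabsch–Sander H-bond bridges give per-residue β
indicators and per-strand β populations; Cα RMSF after iterative Kabsch
superposition quantifies fluctuations; antiparallel/parallel β-content
and AlphaBeta dihedral collective variables feed weighted-histogram
free-energy surfaces F = −k_B·T·ln p (310 K default) with exact
marginalization.

**Design.** Candidate sites must have intrinsic score > 1 *and* an
ensemble-corrected score change > 0.2 between two variant ensembles;
each candidate is scanned over all 19 substitutions by recomputing the
full intrinsic pipeline, and mutations are ranked by Δtotal (negative =
protective).

Because the published solubility-score parameterization is proprietary,
the linear-combination weights here are an open re-parameterization with
the same architecture; absolute scores are not comparable to published
ones, but orderings, thresholds and the design logic are.

## Worked example

`examples/02_structural_correction.py` generates two conformational
ensembles of one synthetic 40-mer whose hot-spot exposure differs by a
planted 0.2, and scores both:

```
sequence: GSSSTGTSTTGGGSIILLLTSTSSGTGGGTSTGGGGTTSS
planted exposure shift (A - B): 0.192
variant A (exposed)    total corrected score +0.1938 +- 0.0017 (hot-spot mean +0.544)
variant B (protected)  total corrected score +0.1663 +- 0.0010 (hot-spot mean +0.274)
```

Identical sequence, lower score for the protected variant: burial alone
changes predicted aggregation. `examples/04_mutation_design.py`
continues to the design stage:

```
candidate sites (intrinsic > 1, |delta corrected| > 0.2):
  L16: intrinsic +1.24, delta corrected -0.267
  F17: intrinsic +1.17, delta corrected -0.256
  V18: intrinsic +1.20, delta corrected -0.209
best protective mutation: V18E (delta total -0.1539)
best promoting mutation:  F17V (delta total +0.0222)
```

The top protective substitution at a hydrophobic hot spot is charged
(here V→E), which both removes hydrophobicity and gatekeeps the
neighbours; the promoting direction substitutes toward hydrophobic.
The remaining examples cover the intrinsic profile and gatekeepers
(01), bridges/CVs/free-energy surfaces (03), and the one-shot pipeline
(05). A thin CLI wraps the same stages
(`aggscape profile|features|ensemble-score|fes|design|fixtures|run`).

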