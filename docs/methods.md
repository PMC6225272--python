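# Methods

This note records the models implemented, the defaults chosen where the
classical workflow leaves them open, what the synthetic generators do and
do not emulate, and the numerical edge cases.

## Molecular-field descriptors

Molecules must arrive pre-aligned on a common scaffold; alignment is an
input contract, not an operation (a convenience rigid aligner is out of
the modelling surface). The lattice is the union bounding box of all atoms
expanded by a 4.0 Å margin per side and discretized at 2.0 Å, with a floor
of two planes per axis — the conventional defaults for this descriptor
family.

**Interaction fields.** At every lattice point the probe (sp³ carbon:
radius 1.7 Å, well depth 0.107 kcal/mol, charge +1 e) accumulates over
atoms a Lennard-Jones 6-12 energy `ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶]` with
arithmetic radius mixing and geometric well-depth mixing, and a Coulomb
energy `332.06 q_i q_p / r` with a distance-independent dielectric of 1.
Both are truncated to ±30 kcal/mol; the cap applies before any division
hazard, so a probe coincident with an atom simply reports +30. At points
where the steric energy reaches the cap the molecule's interior makes the
electrostatic value physically meaningless, so it is replaced by the mean
of the non-excluded molecules at that point (zero if every molecule is
excluded) — the classical treatment that keeps the column usable in
regression.

**Similarity fields.** Five Gaussian-attenuated property fields
`A_k(j) = −Σ_i w_ik exp(−0.3 r_ij²)` with unit probe weights: steric
weight = vdW radius³, electrostatic = PEOE partial charge, and
hydrophobic/donor/acceptor weights from a small rule-based atom-typing
table (carbons with no polar neighbour 1.0, halogens 0.5; N/O with an H
as donors; O and most neutral N as acceptors). These weights only need
relative magnitudes; the Gaussian form is smooth everywhere and needs no
cap.

**Charges.** Partial equalization of orbital electronegativity (PEOE)
with the Gasteiger–Marsili polynomial coefficients keyed on element and
hybridization, 6 iterations, damping 0.5, hydrogen cation
electronegativity 20.02. Total charge is conserved exactly by
construction. The aromatic (Hückel) π-charge correction is **not**
implemented — its parameters are not reproducible from the classical
descriptions — and this is a known limitation; against an independent
PEOE implementation (RDKit) per-atom agreement on small organics is
within 0.002 e.

**Column filtration.** Columns whose standard deviation across molecules
(population, ddof 0) falls below the threshold (default 2.0, energy units)
are dropped with their metadata retained. A threshold of zero is the
identity; dropping every column raises an error advising a lower
threshold.

## PLS model and statistics

NIPALS PLS1 on centered, unscaled data (unit scaling would distort the
energy-calibrated columns). Coefficients are `W(PᵀW)⁻¹q`; predictions add
back the training means. Degenerate inputs (zero centered variance, or a
vanishing residual covariance at some component) raise errors rather than
returning silent zeros.

* q² = 1 − PRESS/SS by exact leave-one-out refitting: each training
  compound is predicted by a model refit without it at the same component
  count. The covariance-shortcut (SAMPLS-style) LOO is mathematically the
  same quantity; the explicit loop is slower but transparent, and the
  test suite asserts bit-for-bit equality against an independent loop.
* SEE = √(RSS/(n−c−1)) and F = (r²/c)/((1−r²)/(n−c−1)), the denominators
  conventional in 3D-QSAR software. A perfect fit reports SEE 0 and
  F = +inf.
* The optimum component count is chosen from a LOO scan over
  1..max_components (default 10) as the smallest count whose q² is within
  a parsimony tolerance (0.005) of the scan maximum. After the planted or
  true dimensionality the q² curve plateaus and fluctuates at the 1e-4
  level; a strict argmax would chase that noise into needless extra
  components, so an added component must buy a material q² gain. The
  scan-and-select rule is applied uniformly, with no separately fixed
  component setting.
* Predictive r² = 1 − PRESS_test/Σ_test(y − ȳ_train)². A test set whose
  activities all equal the training mean makes the denominator zero; the
  statistic is then reported as −inf (flagged undefined) rather than
  raising.
* Field fractions: fraction_k = Σ_{j∈k}|β_j|sd_j / Σ_all|β_j|sd_j; they
  are non-negative and sum to one. Contour grids export sd_j·β_j per
  lattice point with favored/disfavored iso-levels at the 80th/20th
  percentiles of the nonzero values; rendering is out of scope.
* Train/test split: explicit flags when provided (the reference compound
  table carries 7 held-out compounds of 33); otherwise a seeded 3:1 split
  stratified by activity (one random member of each activity-sorted block
  of four is held out).

## Applicability domain

Leverages are the hat-matrix diagonal of the design [1 | latent scores]
(p = components + 1). The raw descriptor matrix has far more columns than
compounds and would make X(XᵀX)⁻¹Xᵀ rank-deficient; latent-score leverage
is the standard resolution in QSAR practice, and a rank-deficient design
raises an error that says so. Standardized residuals divide by the
residual standard deviation (ddof 1); an all-zero residual vector
standardizes to zeros, producing no outliers. Flags: outlier when
|std. residual| > 3, high leverage when h > h* = 3p/n.

## Network screening

Subgraph centrality is computed from the eigendecomposition of the
(unweighted) adjacency matrix — exactly the diagonal of the matrix
exponential; an isolated node scores e⁰ = 1. Betweenness is unnormalized
Brandes betweenness over unordered pairs, which matches exhaustive
shortest-path enumeration (asserted against an independent
Floyd–Warshall/path-count oracle in the tests); cross-component pairs
contribute nothing. Closeness defaults to the per-component standard form
(n_comp−1)/Σdist; the neighbour-count numerator (deg−1) that appears in
some applied write-ups is preserved as `variant="literal"` for
comparability, since it deviates from every standard source. Singleton
components score 0.

The screened subnetwork is the strict intersection of the three
per-measure top deciles (ceil(0.10·n) nodes, boundary ties all included —
inclusive ties favour recall of essential proteins). Whether "merged"
top-decile sets should mean a strict three-way intersection or a
two-of-three union is genuinely open; the strict form is the default and
`merge="pairwise"` exposes the alternative.

Cluster discovery itself (greedy cohesiveness growth) is not
reimplemented; the module evaluates and filters supplied candidate
clusters, which is the reproducible content of that stage: density
2m_in/(k(k−1)), quality w_in/(w_in+w_boundary), and a permutation
p-value — the +1-corrected tail probability that a uniformly random
same-size node set has density at least as high, over n_perm ≥ 99 seeded
draws. The acceptance filter keeps size ≥ 3, density ≥ 0.45,
quality ≥ 0.5 and p < 0.05, all configurable.

## Rank consistency (NDCG)

DCG_p = rel₁ + Σ_{i=2..p} rel_i/log₂ i — the standard
Järvelin–Kekäläinen discount. IDCG is the DCG of the relevance sorted
descending, NDCG = DCG/IDCG ∈ (0, 1] whenever some relevance is positive,
and equals 1 exactly for a descending-relevance ordering.

The graded relevance of a compound is not uniquely pinned down by the
classical description ("refers to pLD50"), so a brute-force oracle scores
three candidate schemes — raw pLD50, rank complement n−rank+1, and
exponential gain 2^pLD50 − 1 — against the reference consistency values
0.9122 (2V7O) and 0.8503 (2VZ6). **No scheme reproduces those values to 4
decimals from the printed integer ranks and pLD50 values alone** (the
full-list values are 0.9781/0.9275, 0.9671/0.9150 and 0.9653/0.8336
respectively; a wider sweep over discount conventions, ideal orientations
and list cutoffs also fails), which indicates the reference values were
computed from the raw docking fit scores, which were never deposited.
The selector therefore falls back to the scheme with the smallest total
absolute error — the exponential gain, which is also the standard graded
NDCG gain — and that scheme is the package default. Both receptor
orderings still rank 2V7O as the more consistent target, preserving the
qualitative conclusion. Ties in fit scores do not arise: the reference
ranks are already integer permutations, and user tables are validated as
such.

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)` and are
bit-reproducible; tests hash their output.

* `gen_latent_qstr` — X = TPᵀ + E with orthonormal loadings and
  standard-normal scores, y = Tq + f with ‖q‖ = 1, so the noiseless
  activity has unit variance and `noise_sd` is directly interpretable
  (0.5 ⇒ population R² = 0.8). Defaults: 32 molecules, 120 columns, 3
  components, activity noise 0.1, descriptor noise 0.05 — the scale of
  the compound set the pipeline targets. The planted truth is stored for
  recovery tests. It emulates the low-rank latent structure of field
  blocks, not their spatial column correlation or energy caps, so PLS
  recovery results here do not certify behaviour on pathological real
  alignments.
* `gen_point_molecules` — neutral random point-atom "molecules" in a
  shared frame with palette radii/well depths and random similarity
  weights. They exercise every field-engine invariant (capping,
  translation equivariance, smoothness) but carry no connectivity, so
  charge assignment is not applicable to them.
* `gen_ba_network` — preferential-attachment background (m = 1) with
  planted hubs wired to ≥ 30% of the graph. Hubs are picked outside the
  background's own top-degree decile and their edges go to a uniform
  sample of the remaining nodes, keeping the planted truth separable from
  the scale-free core the background necessarily grows; this emulates
  essential proteins whose interactions span the network rather than
  piggy-backing on one module. Real curated PPI networks have weighted,
  noisy, database-version-dependent edges that this generator does not
  model, so hub-recovery precision here bounds idealized, not curated,
  behaviour.
* `gen_ranking` — positive distinct relevance with a predicted ordering
  at an exact adjacent-swap (Kendall) distance from the ideal, for the
  monotone-concordance and extremal-NDCG properties.

## Problem sizes

The shipped analyses and tests run at the scale of the study itself:
33-compound tables, ~30-molecule synthetic QSTR sets with ~100-column
blocks, 100-node networks, and 999 permutation draws for cluster
p-values. These sizes are the study's own; every routine accepts larger
inputs.

## Known limitations

* No Hückel π correction in the charge model (see above).
* The exact interaction-field statistics of the commercial implementation
  (its q²/r² on the real compound set) are not reproducible because the
  lattice, probe, cap and dielectric of that workflow are unpublished;
  the property suite pins the implementable mathematics instead.
* Cluster discovery, docking, pharmacophore matching and molecular
  dynamics are consumed as inputs, never computed.
* The reference NDCG values are not reproducible from the printed ranks
  (see the rank-consistency section); the package reports what the
  selected scheme computes.
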