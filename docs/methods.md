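# Methods

## Elastic network model and response kernel

Structures are coarse-grained to Cα atoms. The anisotropic network Hessian
uses a distance-weighted spring for every pair within the cutoff: the
off-diagonal 3×3 superblock for a contact (i, j) is
−(γ/d²)(r_j−r_i)(r_j−r_i)ᵀ and diagonal superblocks enforce translation
invariance. The 1/d² weighting makes the model parameter-free beyond the
cutoff; γ only sets the overall scale and cancels out of all percentile
profiles. Defaults: cutoff 13 Å (captures second-shell Cα contacts),
γ = 1.

The response kernel is the Moore–Penrose pseudo-inverse computed by
eigendecomposition. Two null-space policies exist:

* `null_modes=6` (default) discards exactly the six rigid-body modes —
  deterministic for well-formed 3-D structures, and an *error* if the
  retained spectrum still contains a mode below 1e-10 of the largest
  eigenvalue (a planar, collinear, disconnected, or mechanism-bearing
  network);
* `null_modes=None` discards every mode below 1e-9 of the largest
  eigenvalue — for degenerate geometries such as the planar unit-square
  test fixture.

Covariance matrices from MD can be supplied instead of a structure
(`load_covariance`); they are symmetrized if within 1e-6 relative asymmetry
and used unchanged, since the Hessian pseudo-inverse is itself a covariance
up to temperature factors that cancel in the profiles.

## Perturbation response scanning and the direction average

The response of residue i to a unit force in direction d at residue j is
the norm of the corresponding 3-vector slice of K·F. Profiles average this
magnitude over force directions to mimic isotropic perturbation. The
default here is the *analytic* spherical average: for a 3×3 kernel block B
with singular values s₁,s₂,s₃, the mean of |B d| over the unit sphere is
the Carlson symmetric integral R_G(s₁², s₂², s₃²) (evaluated with
`scipy.special.elliprg`). Any finite direction set breaks rotational
symmetry at the 1e-3 level — enough to corrupt symmetry-based checks and to
make profiles depend on the arbitrary orientation of the input coordinates
— whereas the analytic average is exactly rotation invariant. Finite
direction sets (the 7-vector axes+diagonals set, or seeded random unit
vectors) remain available and are what the independent per-force
linear-solve oracle in the test suite exercises.

DFI is the row-normalized total response (Σ DFI = 1 by construction); DCI
is the ratio of mean response to functional-site forces over mean response
to forces anywhere. Percentile ranks use mid-rank ties:
rank = (#less + 0.5·#equal-others + 1)/N, so strictly increasing inputs map
to (1/N, …, 1) and duplicated values share a rank — this keeps threshold
behavior stable under ties. Hinge sites are flagged at %DFI < 0.2. Ranks
are computed over all residues; binding-site positions are excluded later,
by the classifier, so that rank values do not depend on which site set a
user supplies.

## Co-evolution scoring

The scorer is weighted mutual information with average-product correction:

* **Weights**: a sequence's weight is 1/(number of sequences at ≥ 80%
  pairwise identity to it, itself included); identity is computed over
  columns where both rows are non-gap. Duplicating every sequence k times
  therefore leaves all frequencies and scores unchanged.
* **Gaps**: pairwise-complete exclusion — rows gapped at either column of a
  pair are dropped for that pair. A 21-symbol alphabet would let shared
  gap stretches masquerade as covariation in sparse families. Pairs whose
  effective (weighted) row count falls below 5 are flagged invalid.
* **MI**: joint 20×20 weighted frequencies with a uniform additive
  pseudocount λ/400 per cell (λ = 0.5 by default), marginals from the
  joint, MI in bits.
* **APC**: corrected(a,b) = MI(a,b) − mean_a·mean_b/mean_all over valid
  pairs, removing the background signal that inflates every pair involving
  a high-entropy column.
* **Normalization**: corrected scores are percentile-ranked over valid
  upper-triangle pairs, giving a scale-free (0,1] score so the downstream
  0.6 threshold has a fixed meaning regardless of family size.

A position's coupling to the binding site is the maximum normalized score
between its column and any binding-site column (a single strong
co-evolutionary link suffices); a mean-over-columns mode is available.
Externally computed L×L score matrices (e.g. from direct-coupling or
deep-learning predictors, which this package deliberately does not
implement) can be ingested as drop-in replacements.

## Classification

dyn_bit = 1 iff %DFI ≤ 0.2 and %DCI ≥ 0.7; dyn_bit = 0 iff %DFI ≥ 0.7 and
%DCI < 0.7; all thresholds inclusive and configurable. Positions between
the rigid and flexible %DFI extremes, or with contradictory
rigidity/coupling, are left *unclassified* rather than forced into a bin —
forcing them would contaminate the category statistics the fitness module
computes. A `nearest` mode (splitting at the midpoint of the two %DFI
thresholds) exists for users who need every position binned. coevo_bit = 1
iff the binding-site coupling score is ≥ 0.6; positions with no mapped
alignment column score 0 (logged). Binding-site positions never appear in
the table.

Substitution proposal restricts the alignment to sequences whose
binding-site composition matches the reference at a configurable identity
(exact match by default; a conservative-class mode groups {ILVM}, {FYW},
{KR}, {DE}, {ST}, {NQ}), then reports, per candidate position, every
non-wild-type amino acid whose weighted frequency reaches 5%, with its
support count.

## Fitness stratification

Records are pooled one-per-substitution (a per-position-mean option
exists). The category comparison is a two-sided Mann–Whitney U — chosen
because mutational fitness distributions are heavy-tailed and the
hypothesis is distribution-free — exact enumeration for group sizes up to
20, tie-corrected normal approximation above; effect size is rank-biserial
2U/(n₁n₂) − 1. Because the hotspot category's signature is a *two-tailed*
widening (both enhancing and deleterious mutations), a dispersion contrast
is provided: the same test applied to absolute deviations from the neutral
band's midpoint. The neutral band defaults to [−0.1, 0.1] on a relative
fitness scale and is user-supplied in practice; "enhancing" fractions count
records strictly beyond the band edge in the better direction
(higher-is-better for fitness, lower-is-better for docking scores).

## Hydrogen-bond networks

Donors and acceptors come from residue-template tables (backbone N donates
except proline, backbone O/OXT accepts; side-chain sets follow standard
amino-acid chemistry, including S donors/acceptors for CYS/MET). An edge
exists when any donor heavy atom of one residue lies within 3.5 Å of an
acceptor of another; when the donor carries an explicit hydrogen, the
donor–H···acceptor angle must reach 120°. Backbone-adjacent pairs
(|Δresnum| ≤ 1, same chain) are excluded. Models of a multi-model PDB stand
in for MD snapshots; per-edge occupancy is the fraction of models
containing the edge. Pathways between two residues are all simple paths of
at most 6 edges over edges with occupancy ≥ 0.1, ranked by *support* — the
fraction of models in which every edge of the path co-occurs — then by
length, then lexicographically. Support ≤ bottleneck (the weakest edge's
occupancy) always; both are reported because "how often is the route
intact" and "where does it break" answer different questions.

## Synthetic data

The generators produce every input the pipeline consumes, at the scale the
tests and the acceptance script use:

* **Structures**: Cα traces at 3.8 Å spacing. `chain` is a jittered line;
  `ring` is a vertex-transitive crown (alternating ±0.25 Å out of plane,
  even sizes) rather than a flat polygon, because a strictly planar network
  has one spurious zero mode per residue; `square` is deliberately planar
  as a minimal degenerate test case; `dumbbell` is an hourglass — two lobes
  (6-residue face rings plus open helical tails) joined by a 2-residue
  neck on the axis. The neck is the most tightly coordinated part of the
  network and the displacement node of the soft inter-lobe modes, so at
  the default size (8 residues per lobe) the two neck residues attain the
  two lowest flexibility values by construction; large lobes grow long
  tails whose own soft bending modes can compete, so hinge dominance is
  only guaranteed for compact lobes.
* **Alignments**: per-column categorical draws at a stated conservation
  (default 0.5 — the mid-range of typical family columns), with planted
  covarying pairs: with probability *strength* the pair takes one of two
  symbol combinations, else independent draws over the same two symbols.
  At strength 1 each planted column is binary-uniform and the pair carries
  exactly 1 bit of MI in the large-sample limit. The reference row is the
  consensus. What this does *not* emulate: phylogenetic correlation
  between sequences, gap structure, or indirect (chained) couplings — so
  passing recovery tests shows the scorer works on clean signal, not that
  it untangles real-family confounders.
* **Fitness tables**: per-category Gaussians on a relative-fitness scale;
  defaults plant a strong two-tailed effect in (1,1) (|mean| 0.5, sd
  0.25), a weaker two-tailed effect in (0,1), a modest enhancing shift in
  (1,0), and near-zero noise in (0,0) (sd 0.05) — the qualitative pattern
  the classifier is meant to expose, with magnitudes chosen so the
  dispersion test at 100 records/category has comfortable but not trivial
  power.
* **H-bond ensembles**: residues on a wide circle, each with one backbone
  N (donor) and O (acceptor); a planted edge is realized in exactly
  round(occupancy·n_models) seeded models by extending the donor N to
  2.9 Å from the partner O, and parked at a ≥ 5 Å gap otherwise. One donor
  and one acceptor slot per residue means planted edge sets must decompose
  into simple paths or cycles; construction self-checks that detection
  recovers exactly the planted per-model edges.

All generators are pure functions of their arguments including the seed.

## Numerical choices and limitations

* Percentile thresholds (0.2/0.7/0.6) are inclusive ("or lower"/"or
  higher") and configurable; rank normalization makes the co-evolution
  threshold well-defined, but scores from external predictors on other
  scales must be rank-normalized before the threshold is meaningful.
* Problem sizes in the test suite and acceptance script (18–60 residue
  fixtures, 400×30 alignments, 10–20 seed repeats, 100 records/category)
  are chosen as the smallest scales at which the statistical properties
  under test are stable.
* The elastic-network route assumes a single well-defined native basin;
  supplied MD covariances relax that but inherit the trajectory's sampling
  quality.
* Hydrogen-bond detection is geometric only — no energetics, no
  water-mediated bridges — and trajectory formats must be converted to
  multi-model PDB upstream.
* Fitness stratification assumes position-level categories apply to every
  substitution at that position; substitution-level chemistry is outside
  the model.
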