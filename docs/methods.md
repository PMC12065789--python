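# Methods

This note documents the models and procedures implemented in `memscreen`,
the parameter choices that matter, what the synthetic-data generators
emulate, and the numerical decisions taken where the design was open.

## Yield quantification

Reporter fluorescence is converted to protein amount through a
four-parameter logistic, `y = L/(1+exp(-k(x-x0))) + b`, fit by
Levenberg–Marquardt least squares (`scipy.optimize.curve_fit`) with
initial guesses L = range(y), b = min(y), x0 = median(x), k = 4/range(x)
(the slope-matching heuristic for a logistic; the initialization is the
package's choice). L and k are constrained positive so the fitted curve
is monotone increasing and invertible. When the data do not bracket the
inflection (x0 outside the sampled amounts, or k·range(x) < 1) the fit is
returned with a `span_warning`: in that near-linear regime L, k, and b
trade off against each other and only the local slope is identified.

Fluorescence is inverted analytically; values outside the open range
(b, b+L) raise by default because inverting a sigmoid beyond its plateau
is unbounded — a clip-to-boundary mode exists for batch screening.
Amount → concentration is the exact unit identity
pmol × kDa / µL = µg/mL (so 1 pmol at 40 kDa in a 2 µL reaction is
20 µg/mL). Flow-cytometry events are gated on Cy5/SSC ∈ [0.5, 5] (the
liposome population) and normalized as log₁₀(GFP/Cy5); base 10 is the
package's choice of logarithm.

## Screening designs

The five factors (Mg, K, PEG, SecYE, lipid) are each discretized to
ordered levels and min-max scaled to [0, 1]; lipid types are ordered by
acyl-chain carbon count (DMPC 14 → 0, DPPC 16 → 0.5, DOPC 18 → 1) so the
factor is ordinal. The generalized subset design deals each factor's
levels round-robin into `reduction` interleaved groups and keeps runs
whose group-index sum ≡ r (mod reduction). In the divisible case every
subset has size full/reduction, perfect per-factor level balance, and the
`reduction` residue classes partition the full factorial — all verified
by brute-force enumeration in the tests. The shipped default grid has 3
levels per factor (243 runs, 81 after 3-fold reduction); level counts are
a required input when reproducing a specific screen, since they are a
property of that screen, not of the method.

## Success calling

A condition is a successful synthesis environment when the +liposome arm
beats its matched −liposome control by more than 1 pmol with a
significant two-sided Welch t-test. Welch (unequal variances) is used
because the two arms have different variance by construction; sample
SD (n−1) is used in all test statistics. Benjamini–Hochberg correction is
applied within each protein across its tested conditions (a global mode
exists); corrected mode gates on q < 0.05, screening mode on raw p.

Replicate outliers are removed first: a replicate is dropped when its
absolute deviation from the replicate median is at least twice the
replicate SD, where the SD is the population SD (n denominator) over all
replicates including the candidate. This choice is forced by arithmetic
at quadruplicate scale: with the sample SD a single gross outlier
inflates the SD to exactly half its own deviation, so the rule
asymptotically never fires, and a leave-one-out SD flags more than twice
the intended fraction on a 7.5%-contaminated screen; the population form
flags ≈ 7% with a ≈ 3.6% false-positive rate. Removal is single-pass,
worst-first, and never leaves fewer than three replicates.

Trimming extremes from quadruplicates shrinks the within-arm variance, so
the *raw* Welch p after outlier removal is mildly anti-conservative on
null data (measured ≈ 0.08–0.10 positive rate at α = 0.05). The
pipeline's operative decision is protected by the 1 pmol effect floor and
the BH correction: the false success-call rate on null screens is ≈ 0.
The acceptance suite asserts the decision-level control and the nominal
level of the untrimmed test, and this trade-off is stated here rather
than hidden.

Interaction analysis fits, per protein, an OLS model of z-scored yield on
the 5 scaled factors, their 10 pairwise products, and an intercept;
per-term p-values come from the standard OLS covariance. Preferred
compositions average each factor's encoding over the top-3 conditions by
mean Δyield (ties broken by smaller p, then input order). Trajectory
norms are √(ΔYield² + ΔConcentration²) per factor between the standard
and best conditions, on normalized scales.

## Ensemble active learning

The regressor ensemble crosses three feed-forward architectures
(128-64-32-16; 256-128-64-32-16; 512-…-16), three minibatch sizes
(10, 50, 200), and five 80:20 train/test splits in which all replicates
of a condition stay on one side — 45 members. Members are trained for a
fixed 100 epochs (no early stopping) with Adam at learning rate 10⁻³ on
the mean absolute error, on inputs of the 5 scaled factors plus a protein
descriptor block (one-hot identity, 2D embedding coordinates, or
nothing). Targets are per-protein z-scored yields so proteins with very
different absolute yields contribute comparably. The networks are
implemented directly on numpy (`memscreen._mlp`: He initialization, ReLU
hidden layers, linear output, standard Adam) so that per-member
architecture, batch size, epoch count, and seed are fully controlled and
the whole loop is deterministic under one master seed; member weight
seeds are derived from the spec seed by member index.

Candidate conditions are scored as mean + κ·SD over the member
predictions with κ = −1 by default: member disagreement is *penalized*,
selecting conditions that are consistently predicted high. κ = +1 (a
classical optimistic upper confidence bound) is available; the default
reflects the exploitation behaviour of a yield-maximizing campaign.
Already-tested conditions are excluded from acquisition, and rounds
retrain from scratch. The top k = 12 by score are acquired (ties broken
by higher mean, then input order).

## Response-profile embedding and transfer

Every (member, protein) pair predicts the full condition grid, giving a
profile matrix of members × proteins rows by grid-size columns, z-scored
per column, embedded to 2D by t-SNE (scikit-learn, perplexity 30, PCA
initialization, fixed seed; perplexity is auto-reduced with a warning
when the row count is too small). A protein is summarized by the centroid
of its member positions and their RMS dispersion.

Leave-one-protein-out transfer trains an ensemble without one protein and
predicts that protein's observed conditions, reporting R² on z-scored
values, for each descriptor mode. In embedding mode the held-out protein
needs coordinates without leaking its data into the model: the embedding
is built from an ensemble trained without it, and its coordinates are the
inverse-distance-weighted mean of the k = 3 nearest training proteins'
centroids, with distance measured between observed mean response profiles
over shared conditions. Embedding coordinates are min-max scaled (fit on
training proteins) before entering the network so the descriptor block
matches the [0, 1] factor scale.

## Structural featurization

Orientation assumes alternating TM topology: helix h contributes its
start terminus to membrane side A when h is even. The two side centers
(means of terminal-residue centroids) define the membrane normal; their
midpoint is translated to the origin and the A→B axis rotated onto +z.
Residue positions are heavy-atom centroids throughout. Single-helix
input is rejected — the rule cannot orient it.

QC fails a structure when < 75% of annotated TM residues lie within 20 Å
of the midplane or any annotated helix spans < 10 Å in z (a physically
impossible TM label). "Within the membrane" is judged on |z| (the slab),
not radial distance.

Layers partition residues by |z| with boundaries 6 / 15 / 20 / 30 Å:
inner hydrophobic (< 6), outer hydrophobic, interface, polar, and
water-exposed (> 30). Only the 6 and 30 Å ends are fixed by the slab
definition; the intermediate boundaries are defaults chosen to put the
membrane edge at 20 Å, consistent with the QC rule, and all four are
configurable.

The lipid-contact shell uses a 3D alpha shape of the residue centroids:
Delaunay tetrahedra with circumradius < α are kept and their
once-occurring faces form the bounding surface. α = 2.5 × the median
nearest-neighbor centroid distance, scaling the surface tightness with
protein size. Surface vertices outside the membrane slab are pushed far
away radially so only the intramembrane surface is reachable, then each
membrane-layer residue's exact distance to the triangle soup is computed
(`trimesh.triangles.closest_point`); < 4 Å means lipid-contacting,
otherwise interior. Polar/water residues are external. Degenerate cases
(< 4 membrane residues, empty alpha complex) mark everything contacting
with a warning.

Per-residue metrics: charge (+1 Arg/Lys/His, −1 Glu/Asp, 0 otherwise —
His is +1 by definition of the rule, physiological pKa notwithstanding);
hydrophobicity from the bundled Wimley–White whole-residue *interfacial*
scale (kcal/mol, positive = unfavorable transfer to the POPC interface);
depth = number of other residue centroids within 6 Å (symmetric by
construction); and a location-enrichment probability
freq(aa | layer, shell, depth bin) / freq(aa) with add-one smoothing over
a reference set (the working structure set by default), with depth
discretized into {0–2, 3–5, 6–8, ≥ 9}. The 8 location bins — 3 membrane
layers × {interior, contacting} plus polar and water × external — crossed
with the 4 metrics and averaged give the 32-feature default vector; an
expanded mode adds min/max/sum (128 features). Empty bins are zero with a
mask. Because orientation canonicalizes the frame and all metrics depend
only on z and pairwise geometry, the features are invariant to rigid-body
transforms of the input (verified to 10⁻⁶).

## Classification

Proteins are labeled successful when any condition passes the corrected
success call. Feature subsets (by default all combinations of 2–4 of the
8 location-bin families, capped and seeded) are z-scored, embedded to 2D
by t-SNE, and scored by an Ensemble Classifier: 50 RBF-kernel SVMs
(C = 100) trained on stratified 80:20 splits (the split fraction is the
package's choice), accuracy = mean member test accuracy. Embeddings above
0.77 accuracy are paired — each pair trains a new Ensemble Classifier on
the 4 embedding coordinates plus protein length (5 inputs) — and pairs
above 0.85 contribute all members to a comprehensive vote. Votes are hard
0/1 labels; per protein, mean > 0.7 with SD < 0.2 is *likely*
synthesizable, mean < 0.3 with SD < 0.15 *unlikely*, anything else
*uncertain*. The accuracy gates apply to ensemble-mean accuracy.

## Synthetic data: what it emulates, and what it does not

The landscape generator reproduces the *statistical* structure of a real
screen: per-protein quadratic response surfaces over the scaled factors
with planted optima, 1–3 signed pairwise interaction terms, matched
no-liposome baselines, i.i.d. normal replicate noise, and symmetric
outliers inflated to ≥ 4 noise SD at a 7.5% rate. Protein optima are a
smooth (linear + clip) function of a latent 2D coordinate, so
cross-protein structure exists for the profile embedding to discover.
Defaults — 4 replicates per arm, 0.5 pmol noise, 4 pmol effect scale,
0.5 pmol baseline — put planted effects at the scale of reported liposome
gains (a few pmol against a 1 pmol success floor) and give an irreducible
ensemble R² ceiling of ≈ 0.5–0.6 on the z scale, comparable to what a
real screen of this kind supports. The generator does not model CFPS
biochemistry, liposome physics, batch effects, or non-Gaussian noise;
passing tests show the *pipeline* behaves correctly under its stated
assumptions, not that real screens meet them.

The bundle generator produces ideal α-helices (1.5 Å rise, 100°/residue)
on a ring with alternating topology, a Cα plus one radially-displaced
sidechain pseudo-atom per residue (so centroids differ from Cα), and
amino-acid identities whose lipid-facing hydrophobic fraction is
0.5 + 0.5 × signal. Coordinates are rounded to PDB precision at
generation so files round-trip losslessly. Real predicted structures have
kinked helices, loops, and confidence artifacts none of which are
emulated. Test fixtures use 30–34-residue helices so the structure
extends past the 20 Å membrane edge, as real TM proteins do — otherwise
the alpha surface's top/bottom caps sit inside the slab and masquerade as
lipid.

## Problem sizes and verification

The test and acceptance workloads are sized for a single CPU: screens of
2–5 proteins over the 81-run GSD subset, reduced ensemble specs
(1 architecture × 1 batch size × 2 splits, 25–40 epochs) wherever the
member count itself is not the property under test, 20-seed repetitions
for the directional properties (acquisition vs random, embedding vs
one-hot transfer), and 40-bundle panels for the classifier properties.
The full 45-member cross is trained where its size is the point (once in
the tests, once in the acceptance script). The oracle for the
lipid-contact shell is an independent brute-force construction: per 6 Å
z-slab (one helical turn per helix, full azimuthal rim coverage), a
membrane residue contacts lipid iff it lies within 4 Å of the slab's 2D
convex-hull boundary; the alpha-shape shell agrees with it on ≥ 95% of
membrane residues across ring-bundle geometries.

## Known limitations

* The orientation rule requires ≥ 2 annotated TM helices and strict
  alternation; mis-annotated topologies fail QC rather than being fixed.
* β-barrels, re-entrant loops, and half-helices are out of scope.
* The probability metric defaults to the working set as its own
  reference; small panels make it noisy (smoothing keeps it finite).
* t-SNE embeddings are only reproducible for a fixed seed, scikit-learn
  version, and row order; centroids are stable, exact coordinates are
  not.
* The numpy MLP is CPU-only and single-threaded beyond BLAS; it is sized
  for screens of 10²–10⁴ rows, not larger.
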