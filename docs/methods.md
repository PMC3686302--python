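# Methods

## Functional-template model

A *functional template* for a target protein is a protein of known structure
that both superposes onto the target significantly and binds its molecular
partner the same way. Two independent labels are assigned per
(target, template, aspect) triple:

- **Location** — the template-to-target superposition has TM-score ≥ 0.4 and
  the superposed template partner lies within an aspect-specific distance of
  the target partner: 4 Å (ligand), 2 Å (metal), 3 Å (Fe–S cluster), 6 Å
  (protein), 6 Å (DNA). All thresholds are inclusive.
- **Features** — the binding chemistry/geometry is conserved: ligand
  Tanimoto coefficient ≥ 0.5 on 1024-bit fingerprints; identical metal
  element; same AT-rich/GC-rich DNA composition class; protein
  interface-similarity score ≥ 0.191.

The two labels are recorded independently (Features is not nested inside
Location): each has its own positives/negatives bookkeeping and its own
classifier.

### Superposition and TM-score

Rigid superpositions are Kabsch least-squares fits (SVD of the covariance
matrix, reflection branch forced to det = +1). The TM-score of an alignment
with target length L and per-pair distances d_i is

    TM = (1/L) Σ_i 1 / (1 + (d_i/d0)²),   d0 = 1.24 (L−15)^⅓ − 1.8,

normalized by the target length (the function-inference convention) with d0
floored at 0.5 Å, since the formula goes non-positive for L ≤ 21.

A full fragment-based structure-alignment search is out of scope; residue
correspondences are accepted as input (e.g. from an external aligner) and
otherwise come from a global Needleman–Wunsch sequence alignment (BLOSUM62,
gap open −11, extend −1, via Biopython's PairwiseAligner). Given
correspondences, the TM-score is maximized by iterative subset re-fitting:
starting from the all-pair Kabsch transform, pairs closer than a cutoff are
re-fit (schedule 3.5 Å plus two +1 Å expansions; minimum subset 4 pairs;
convergence when TM improves < 1e-6 or after 20 iterations), keeping the
best-scoring transform seen. The result never scores below the all-pair
fit. This rewards a well-fitting core over a few displaced segments, the
behaviour TM-score-optimal alignments exhibit, at bounded cost.

### Design choices in the labeling rules

- **Partner distance** is the minimum heavy-atom–to–heavy-atom distance
  between the superposed template partner and the target partner; for metal
  ions this reduces to the ion–ion distance, consistent with the tight 2 Å
  threshold. A center-of-mass definition would penalize size mismatches
  between otherwise co-located partners.
- **DNA composition tie**: a sequence with AT fraction exactly 0.5 is
  classed BALANCED and matches nothing — "AT-rich or GC-rich" names two
  strict classes.
- **Fe–S Features rule**: no printed criterion exists for inorganic
  clusters, so conservation is defined as equal cluster stoichiometry
  (Fe₂S₂ vs Fe₄S₄), read from the PDB component name where available and
  otherwise from the atom count.
- **Protein interfaces**: an externally computed interface-similarity
  (IS) score is used when supplied; otherwise a declared surrogate scores
  the fraction of target-interface residues whose superposition-mapped
  counterpart is interfacial on the template. Interfaces themselves are
  CA–CA contacts at 8 Å, the standard coarse definition when only CA traces
  are available. The IS ≥ 0.191 rule is applied as a Features-only
  criterion, in addition to (not instead of) the 6 Å Location rule.
- **Fingerprints are consumed, never computed**: fingerprint generation
  from chemical structures would pull in a cheminformatics stack the core
  does not need; fixtures and inputs supply bit vectors directly.
- **Dataset filters** (used when assembling benchmark sets): chains of
  50–600 residues; ligands of 7–60 heavy atoms, non-covalently bound (the
  covalency flag is an input, not detected); DNA of ≥ 10 nt; protein
  partners with ≥ 20 interfacial residues; metals in {Ca, Co, Cu, Fe, Mg,
  Mn, Zn}; Fe–S clusters with ≥ 2 Fe and ≥ 2 S.

## Score fusion

The classifier is a two-class Gaussian naive Bayes over up to ten
real-valued threading scores (CSI-BLAST, COMPASS, HHpred, HMMER, pfTools,
pGenThreader, SAM-T2K, SP3, SPARKS2, Threader; each method contributes one
score per template). Per class and per method, mean and SD are estimated
from the labeled training records where that score is present. Numerical
choices:

- **Missing scores**: the likelihood product runs over present features
  only — the standard NBC missing-data treatment; a method absent from an
  entire class is dropped from the model with a warning.
- **SD floor**: each SD is floored at 1e-6 × the pooled per-feature SD (or
  1e-6 when the pooled SD is zero) so zero-variance classes yield proper
  densities.
- **Log space**: posteriors are computed as a sigmoid of the accumulated
  log-odds, which is exact at the symmetry point and immune to underflow of
  ten small density products. Features are accumulated in a fixed registry
  order so serialization cannot perturb the float sum.
- **Priors** default to training class frequencies and can be overridden
  (positives/negatives ratios differ several-fold across binding aspects).

**Cross-validation** is twofold and grouped by target: all templates of a
target share a fold, so no model scores a template of a target it trained
on. Fold homogeneity per scoring method is checkable with a Pearson χ² test
on a 2 × k contingency of fold membership against pooled-quantile bins
(k = 10 by default; zero-expected bins are merged and df adjusted).

## Evaluation battery

- ROC curves sweep descending distinct scores with ties grouped (one vertex
  per distinct value), which makes the trapezoid area equal the
  Mann–Whitney pair-count AUC with half-tie credit — an identity the tests
  assert at 1e-12.
- Confidence bands: the band construction is not pinned down by convention,
  so a stratified bootstrap is used (resampling within class, n = 1000 by
  default), interpolating each curve onto a fixed 101-point FPR grid and
  taking pointwise two-sided percentile envelopes; deterministic per seed.
- The *optimal cutoff* is the Youden J = TPR − FPR maximizer, ties broken
  toward lower FPR.
- BEDROC follows the RIE-based closed form with α = 20 by default (the
  canonical early-recognition setting, exposed as a flag); positives are
  ranked by a stable descending-score sort.
- The Wilcoxon rank-sum Z uses midranks and the tie-corrected variance,
  without continuity correction.

## Site consensus

Partner centers of mass (computed with equal atomic masses — element masses
are irrelevant at the precision of an 8 Å cluster cutoff) are mapped into
the target frame and clustered by average-linkage agglomeration cut at 8 Å
(the algorithm is a convention choice; average linkage is deterministic and
standard for pocket consensus). Posteriors weight both the cluster centers
and the cluster ranking, separately switchable; entries below a posterior
floor (typically the Location model's optimal ROC cutoff) are discarded
first. Total retained posterior mass is conserved across clusters, and
ranking ties break on rounded center coordinates so input order never
matters.

## Synthetic fixtures: what they emulate, and what they do not

The score simulator draws labels from a Bernoulli prior and scores from
per-method class-conditional Gaussians, with optional missingness and an
optional shared latent factor that induces inter-method correlation.
Defaults are chosen to resemble a realistic benchmark: Δμ = 1 pooled SD per
method (per-method AUC ≈ 0.76, the range real single-threading programs
achieve), positive prior 0.2 (Location positives/negatives ratios run
roughly 0.1–0.9 across aspects), 10% missing scores, methods independent
given the class. Toy structures are ideal helices/strands/seeded coils with
canonical 3.8 Å CA spacing; template copies add Gaussian coordinate noise,
an optional partner displacement, and a known random rigid transform whose
inverse a correct superposition must recover.

What passing tests on these fixtures show: the estimators recover their
generating parameters, the metrics satisfy their exact identities, and the
decision rules implement their thresholds. What they cannot show: behaviour
on real threading scores (which are non-Gaussian, heavily correlated, and
missing non-randomly) or on real protein folds — the published benchmark
scale (thousands of PDB-derived proteins scored by ten external threading
programs) is far outside a self-contained build. Problem sizes used in the
test suite and acceptance script (10³–10⁴ simulated templates, 50–60-residue
toy structures) were chosen as the smallest at which the statistical checks
are stable.

## Known limitations

- The interface-overlap surrogate is coarser than a true interfacial
  alignment score; supplying externally computed IS-scores is preferred.
- Sequence-derived correspondences degrade for genuinely twilight-zone
  pairs; precomputed structure-alignment correspondences should be supplied
  where available.
- The PDB reader ingests the CA/HETATM subset it needs (longest protein
  chain as the target; other chains and het groups as partners); it is not
  a general-purpose structure parser, and mmCIF is not supported.
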