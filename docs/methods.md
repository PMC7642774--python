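# Methods

This note records the models, conventions and numerical choices behind
`mrprep`, and what its synthetic tests do and do not establish about real
data.

## Coarse-grained representation

A structure is an ordered list of residues, each carrying a Cα (mandatory),
a Cβ (absent for glycine) and a backbone carbonyl O, with per-atom B
factors. This three-site representation is what coarse-grained
structure-prediction simulations emit and what the whole pipeline operates
on; side chains, hydrogens and the remaining backbone atoms are neither
stored nor reconstructed, since no metric or preparation step here needs
them. Multi-model PDB files map to an `Ensemble` of frames sharing one
residue roster; a roster mismatch between MODEL blocks is an error rather
than a warning because every downstream operation (r.m.s.f., mutual Q)
assumes frame-to-frame residue correspondence.

Parsing policy: HETATM records are ignored (cofactors are not part of the
predicted model), altlocs other than ' '/'A' are skipped to obtain a
deterministic single conformer, residues with insertion codes are rejected,
and residues without a Cα are dropped with a warning — predicted models are
Cα-complete, crystal references occasionally are not. Multi-chain files
require an explicit chain selection; the pipeline treats one chain at a
time.

## Fluctuation analysis and trimming

For the trailing window of a trajectory (default `window_fraction = 0.25`,
the equilibrated tail of an annealing run), the r.m.s.f. of residue *k* is

    rmsf_k = sqrt( mean_f | x_k(f) − ⟨x_k⟩ |² )

over Cα positions. By default each window frame is first superposed
(Kabsch, all Cα) onto the window-mean structure, with the mean refreshed
once and the fit repeated — two passes are enough for the mean to
stabilise, and without superposition any rigid drift or tumbling of the
whole chain masquerades as per-residue flexibility. The raw (unsuperposed)
variant is exposed via `superpose=False`.

On pure-noise ensembles, superposition absorbs six rigid degrees of freedom
and therefore shrinks the estimate by a factor ≈ √(1 − 2/N) for N residues
(≈ 0.91 at N = 12, → 1 for long chains). Parameter-recovery tests
consequently run with `superpose=False`, where the estimator is unbiased
and the synthetic generator's analytic target √3·σ applies; the
superposed path is validated on its own null — a rigid structure under
random rigid motions must read as rmsf < 0.05 Å.

B factors follow the isotropic relation **B = (8π²/3)·rmsf²**, applied per
residue: every atom of a residue receives that residue's B, because the
fluctuation is estimated from the Cα trace alone. Trimming removes residues
with **rmsf strictly greater than the cutoff** (default 1.5 Å — the level
that delineates the most flexible coil); a residue exactly at the cutoff is
kept. Kept residues retain their original numbering. Trimmed-residue
secondary-structure stratification (helix/strand/coil/unstructured,
H/E/C/U) takes externally supplied labels; no secondary-structure
assignment is computed here.

## Similarity metrics

All metrics use Cα only, matching the coarse representation.

* **Kabsch superposition** — SVD of the covariance with a determinant
  correction so the rotation is always proper; returns the minimising
  rotation, translation and r.m.s.d.
* **Qw** — mean over residue pairs with sequence separation ≥ 3 of
  exp(−(r_ij − r′_ij)²/2σ_ij²) with σ_ij = (1+|i−j|)^0.15 Å. Normalising by
  the qualifying-pair count is identical to the textbook 2/((N−2)(N−3))
  prefactor for a contiguous chain, and keeps self-similarity exactly 1 on
  gapped (trimmed) rosters too.
* **Q_template** — the same functional form restricted to pairs of aligned
  residues, with sequence separation measured on the model side and pairs
  whose *template* distance is below 2 Å excluded from both the sum and the
  normalisation (a step-function guard against degenerate reference
  distances). With a full alignment and no excluded pairs it coincides with
  Qw, which is asserted in the tests.
* **GDT-TS** — mean over thresholds {1, 2, 4, 8} Å of the fraction of Cα
  within threshold after a single all-residue Kabsch superposition. This is
  deliberately not the LGA-style maximal-subset search used at CASP: one
  global superposition is cheaper, deterministic, and adequate for ranking
  ensemble members against a reference; scores can be slightly lower than
  LGA values for partially correct models.
* **Contact maps** — unordered pairs with Cα–Cα distance ≤ 9.5 Å and
  |i−j| ≥ 3; overlap reported as precision/recall/Jaccard with NaN for the
  undefined empty-set cases.

## Mutual-Q clustering

The pairwise Qw matrix over ensemble members is clustered agglomeratively
(average linkage) on the dissimilarity d = 1 − Q and cut at Q = 0.75 —
midway between the ~0.9 typical of runs sharing a basin and the ~0.5
observed between genuinely distinct folds. The pattern classifier then
reports:

* `single_dominant` — largest cluster ≥ half the frames (dominant-basin
  regime; more trials of the same protocol are worthwhile);
* `multi_cluster` — no dominant cluster, but ≥ 2 clusters of size ≥ 2 whose
  mean between-cluster Q stays above 0.5 (distinct but related folds; also
  worth more trials, one per cluster representative);
* `dispersed` — everything else: mostly singletons, or small clusters whose
  mutual Q has fallen to the ~0.5 level that marks targets the protocol
  cannot handle.

The between-cluster-Q condition is what separates `multi_cluster` from
`dispersed` when cluster sizes alone are ambiguous (e.g. many clusters of
two); both thresholds (`dominant_fraction`, `between_q_threshold`) are
exposed as parameters. Average linkage with a fixed input matrix makes the
clustering deterministic; the clustergram TSV is written in dendrogram leaf
order and is byte-identical across re-exports.

## MR triage

A trial record carries TFZ, LLG, R_free and map CC, any of which may be
absent. **Success is strictly R_free < 0.45** after rebuilding — R_free is
the only statistic that confirms a correct solution. TFZ ≥ 8 without a
confirming rebuild raises an advisory ("high TFZ without confirmed
rebuild"), never success: confidently scored placements can still be wrong.
Map-CC advisories use < 0.1 (likely failed) and > 0.25 (likely correct),
again advisory-only. Trials arrive as a TSV table rather than by parsing MR
program logs: log dialects vary across program versions, while a documented
five-column schema keeps triage deterministic and testable. The CLI can
emit a JSON stub of the recommended search settings (MR_AUTO mode, 1.5 Å
initial r.m.s. error estimate) for use when driving the MR programs
externally.

## Synthetic data

Fixtures are generated, never shipped. The ideal helix uses textbook Cα
geometry (1.5 Å rise, 100° twist, 2.3 Å radius → 3.83 Å virtual bonds,
(i, i+4) contacts inside 9.5 Å); the extended strand is a 3.3 Å-rise zigzag
with the same virtual bond length. Cβ sits 1.5 Å radially outward, O 1.2 Å
along the local chain direction — any self-consistent placement suffices
for the metrics, which read Cα only.

`perturb_ensemble` adds one independent isotropic Gaussian displacement per
residue per frame (shared by that residue's three atoms), optionally
composed with a random rigid motion per frame. This gives the analytically
known target rmsf = √3·σ_k used throughout the recovery tests. Real
trajectories are time-correlated, anisotropic and collective; passing these
tests therefore demonstrates correctness of the estimators and rules, not
performance of any prediction protocol on real crystallographic data.
Likewise the planted two-fold ensembles (helix vs strand halves, between-
fold Qw ≪ within-fold) validate partition recovery, not the behaviour of
real annealing runs. Trial tables draw success R_free from [0.22, 0.44]
and failure R_free from [0.46, 0.58], with failure TFZ extending above 8 so
the false-positive advisory path is exercised.

## Problem sizes and tolerances

The default test and acceptance runs use 4–30-residue fixtures, ensembles
of up to 4000 frames for fluctuation statistics, 20-member ensembles for
clustering, and 20 random seeds for the stochastic properties; the full
suite runs in a few seconds. Monte-Carlo recovery is asserted at 5%
relative (2000 frames), hand-enumerated metric oracles at 1e-6, the
numerical rotation-search oracle at 1e-4 Å, rigid-motion invariances at
1e-9, and PDB round trips at the format's own precision (0.001 Å
coordinates, 0.01 Å² B factors).

## Known limitations

* Single chain at a time; hetero-complex preparation is out of scope.
* No secondary-structure assignment, template search, model building or MR
  execution — those are the surrounding programs' jobs; this package
  prepares their inputs and triages their outputs.
* GDT-TS is the single-superposition variant (see above).
* The fluctuation model assumes the trajectory tail is equilibrated;
  `window_fraction` is a convention, not a convergence diagnostic.
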