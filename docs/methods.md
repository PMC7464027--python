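# Methods

## Scope and model

The package treats inhibitor design as a funnel over a combinatorially
enumerated chemical library. Its quantitative core is two families of
linear models and their validation arithmetic:

* **QSAR models.** pIC50 is modeled as a linear function of 2D
  descriptors, fitted by partial least squares (PLS). Four frozen
  equations ship as data (`data/qsar_models.yaml`): AT/AF for AChE (six
  terms) and BT/BF for BACE-1 (eleven terms). Prediction is the literal
  evaluation `intercept + Σ coefficient·descriptor` — no hidden scaling —
  so the coefficient files are the single source of truth and a test
  asserts them bitwise.
* **Screening statistics.** A pharmacophore (or any) screen summarized by
  (D, A, Ht, Ha) is scored by %yield = 100·Ha/Ht, %ratio = 100·Ha/A,
  EF = Ha·D/(Ht·A), and GH = [Ha(3A+Ht)/(4HtA)]·[1 − (Ht−Ha)/(D−A)].
  Given the count constraints (Ha ≤ min(A, Ht), Ht−Ha ≤ D−A, 0 < A < D)
  GH is provably in [0, 1]; the constraint Ht−Ha ≤ D−A (false positives
  cannot outnumber decoys) is enforced because GH leaves [0, 1] without
  it.

The pharmacophore search itself is out of scope: hits enter the pipeline
as an externally supplied id list, and the gate is pure set membership so
any tool can feed it. Docking is likewise out of scope; external scores
join the result table by id.

## Descriptor conventions

All descriptors are 2D (no conformers, no minimization). One aromaticity
model — RDKit's default perception — is used everywhere, since binned
descriptors are sensitive to it. Hydrogens are implicit; descriptors whose
definition includes hydrogen (a_ICM, Gasteiger charge totals, Crippen
additivity) query implicit-H counts explicitly.

* **Partial charges** are Gasteiger/PEOE charges as implemented in RDKit
  (deterministic; heavy-atom charges feed the bins, hydrogen charges can
  be folded in for charge-conservation checks). Elements without
  electronegativity parameters raise, naming the element.
* **Atomic logP / molar refractivity** are Wildman–Crippen contributions.
  Heavy-atom values (hydrogen types separate) feed the VSA bins — the
  convention the shipped bin tables assume; `include_h=True` folds
  hydrogen contributions into their heavy atom, making the columns sum
  exactly to molecular logP and MR.
* **Surface areas** are Labute's connectivity-based approximate accessible
  van der Waals areas (Å²), per heavy atom.
* **Binned VSA.** Bin tables live in `data/vsa_bins.yaml`. PEOE bins are
  signed half-open charge intervals of width 0.05 (`+k` ⇔ q ∈
  [0.05k, 0.05(k+1)), `-0` ⇔ [−0.05, 0), the outermost bins open-ended).
  SlogP bins use the classical 9-boundary table (−0.4 … 0.4). SMR bins
  use the 9-boundary subdivision on the Wildman–Crippen MR scale
  (1.29 … 4.0): the MOE manual's printed SMR boundaries (0.11–0.56) are on
  MOE's own MR parameterization and would collapse all Wildman–Crippen
  contributions into one bin, so the Crippen-scale table is the one that
  preserves the descriptor's discriminating power here. Every family
  partitions the real line, so bin sums conserve total VSA to 1e-6; a test
  also verifies exact agreement with RDKit's independent MOE-type VSA
  battery (whose partitions coincide, 1-indexed).
* **BCUT.** The Burden matrix carries the atomic property (Crippen logP
  or PEOE charge) on the diagonal; off-diagonals are 0.1×bond order
  (aromatic 1.5), +0.01 when either atom is terminal, and 0.001 for
  non-bonded pairs. Indices 0–3 pick the quartile positions
  round(i·(n−1)/3) of the ascending eigenvalue spectrum, so index 0/3 are
  the extreme eigenvalues. This is one of several BCUT conventions in
  circulation; it is isolated in one function and documented here because
  descriptor values (and hence absolute pIC50 predictions) depend on it.
* **petitjean** = (diameter − radius)/diameter over heavy-atom graph
  eccentricities; undefined (raises) for single atoms and disconnected
  graphs.
* **a_ICM** is the Shannon entropy of the element distribution including
  implicit hydrogens, in bits (log base 2, isolated behind one constant).
* **reactive** is 1 iff any SMARTS alert in `data/reactive.smarts`
  matches: metals, phospho groups, N/O/S–N/O/S single bonds, thiols, acyl
  halides, Michael acceptors, azides, esters. The patterns are data, not
  code; the het–het pattern deliberately excludes nitro and sulfonamide
  groups, which are ordinary substituents in this chemistry.
* **logS** is Delaney's ESOL linear estimate
  (0.16 − 0.63·clogP − 0.0062·MW + 0.066·RotB − 0.74·AromaticProportion).
  The originally fitted models used a different, undocumented solubility
  model; this substitution is a known comparability gap — rankings are
  expected to transfer, absolute coefficient×logS products only
  approximately.
* **Counts.** rings = SSSR count; chiral_u counts stereocenters with
  unassigned configuration; HBD/HBA use the classic N+O counting
  (OH/NH donors, N+O acceptors), shared with the Lipinski filter.

Because the original descriptor software is closed, exact numerical
equality with its output is not claimed anywhere; what the tests pin down
is internal consistency (partition conservation, renumbering invariance,
brute-force bin oracles) and agreement with RDKit's published
implementations of the same definitions.

## QSAR fitting and splitting

`fit_pls` centers X and y and runs NIPALS PLS (scikit-learn), then
collapses the latent model to `intercept + Xβ` — exact because the model
is linear. At full component count PLS equals ordinary least squares
(tested); on noiseless synthetic data it recovers the generating
coefficients to 1e-6. For refits on new data `fit_pls_auto` chooses the
component count by leave-one-out q² maximization and records the choice in
the model's provenance string, since the original component counts are
unstated.

`diverse_split` ranks rows by a greedy max–min Euclidean sweep (first pick
is the row farthest from the centroid, each next pick maximizes its
minimum distance to the picked set, ties to the lower index) and assigns
the top fraction to training — a deterministic stand-in for MOE's Diverse
Subset; `random` mode is a seeded uniform permutation.

## Validation metrics

Eqs for RMSE/R²/LOO metrics are direct summation; R²_LOO is anchored to
the full-sample observed mean. R²_pred scales the validation error by the
deviation of validation observations from the *training* mean; Q_F3²
scales the mean validation error by the training mean squared deviation —
the prediction-pair container therefore carries the training mean and MSD
(or the raw training observations, from which both are derived).

Roy's rm² family is implemented in its standard form
rm² = r²(1 − √(r² − r₀²)) with r² the squared Pearson correlation and r₀²
the through-origin determination coefficient (slope k = Σxy/Σx²), with
predicted on the y-axis vs observed for rm² and the axes swapped for
r′m². A flattened variant sometimes seen in print, r²(1 − r² − r₀²), is
provided as `rm2_as_printed` for comparability experiments only — the
standard thresholds (rm² ≥ 0.65, r̄m² ≥ 0.5, Δrm² ≤ 0.2) were derived for
the standard form, which is what the pass/fail decision uses. The
external-pass verdict requires all five threshold tests; if the training
context needed for Q_F3² is absent, the verdict is failed rather than
silently passed.

## Synthetic data: what it emulates and what it does not

* **Molecule fixtures** are single-substituted products of four stand-in
  cores (chalcone-, flavone-, curcumin- and chroman-like, each with
  explicit ports) with the 23 classical R-groups, plus eight hand-written
  audit molecules guaranteeing each reactive-alert category appears. The
  stand-ins are deliberately *not* any published scaffold set — the
  original cores exist only as figures — so descriptor and filter code
  paths are exercised on realistic chemistry, but library sizes and funnel
  counts of any specific campaign are not reproduced.
* **Regression scenarios** default to 150 training / 65 validation
  compounds over 11 predictors with noise σ = 0.4 pIC50 units — the scale
  of a mid-sized curated inhibitor series and of inter-laboratory IC50
  variability. They validate estimator correctness (recovery, PLS=OLS,
  LOO behavior), not any particular published fit: passing these tests
  shows the machinery is right, not that real descriptor matrices satisfy
  the linear model.
* **Screening scenarios** draw Ha ~ Bin(A, sensitivity) and
  FP ~ Bin(D−A, 1−specificity), defaulting to D=27024, A=655 with
  sensitivity 0.8 and specificity 0.985 — count scales matching a
  processed decoy-library screen. Real screens have property-matched
  decoys and correlated errors; the simulation only matches counts.

## Numerical choices and degenerate inputs

* Equality tolerances: 1e-6 for charge conservation and VSA partition,
  1e-10 for metric-oracle agreement, 1e-6 for noiseless PLS recovery.
* Comparisons against two-decimal table values use half-up (away from
  zero) rounding, the convention of printed tables (`round_half_up`).
* r², CCC, r₀² and GH raise informative errors on their degenerate inputs
  (zero variance, Ht = 0, A = 0, D ≤ A) instead of returning NaN.
* Enumeration order is fixed (scaffolds in input order, port subsets
  lexicographic, R-groups in input order), making every pipeline run
  byte-reproducible; deduplication keeps the first canonical occurrence.
* The filter bound tables are inclusive at the boundary (MW = 500 passes
  Lipinski), and each rule carries its own violation policy (Lipinski
  tolerates one violation by default, with a strict switch; the others
  none).

## Known limitations

* Absolute pIC50 predictions inherit every descriptor-convention gap
  (BCUT weighting, logS model, SMR bin scale) relative to the software the
  coefficients were fitted in; relative rankings within a library are the
  robust output.
* The Lipinski/Ghose/… filters all use Crippen SlogP as the single logP
  flavor; web tools that mix estimators can disagree on borderline
  molecules.
* `chiral_u` depends on stereo annotation in the input SMILES: a center
  written without configuration counts as unconstrained.
* The enumeration attaches R-groups only through single bonds at marked
  ports; fused-ring decoration or port-to-port R-groups are unsupported.
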