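# Methods

This note records the geometric model, statistical conventions,
synthetic-cohort design and numerical choices behind the package, and
what the passing tests do and do not establish.

## Measurement frame

Each record's seven midline landmarks (G′, Sn′, Pn′, Col, UL, LL, ACP)
are reduced to 2D sagittal coordinates before any measurement:

* **Plane.** Total-least-squares plane through the seven points
  (SVD of the centered 7×3 matrix; the normal is the least-variance
  direction).  All landmarks are nominally midline, so the plane is a
  proxy for the midsagittal plane; no bilateral landmarks are used.
* **Axes.** Superior = in-plane projection of Sn′→G′, normalized;
  anterior = in-plane orthogonal, signed so Pn′ is anterior-positive;
  lateral = anterior × superior (right-handed).  Origin at Sn′.  This
  is a natural-head-position proxy: "vertical" and "horizontal" refer
  to these axes, never to the scanner frame.
* **Invariance.** Because the frame is refit per record, every angle
  and distance is invariant (≈1e-9 relative) under rigid transforms of
  the input; the test suite checks 1e-6 absolute over random poses.
* **QC.** Chin asymmetry is screened as |lateral coordinate of ACP| in
  the fitted frame, with strict exclusion above 3 mm.  Failing
  subjects are removed whole (both timepoints) and logged.

Degenerate configurations (collinear landmarks, coincident anchor
pairs, G′ = Sn′) raise `GeometryError` rather than producing numbers.

## Chin construction

Line A runs G′→Sn′.  Line M is the ray from Sn′ making the target
convexity angle (default 170°, configurable, sex-independent) with the
ray Sn′→G′, rotated to the **posterior** side of line A; for angles in
(90°, 180°] it always points inferiorly, and at 180° it degenerates
gracefully to line A's inferior extension.  The MCP is the intersection
of the horizontal line through the ACP with line M; x = MCP_a − ACP_a
is kept signed (anterior-positive) and reported unsigned where a
distance is called for.

Numerical guards: the target angle must exceed 91° (within 1° of 90°
the horizontal intersection is ill-conditioned — the line M direction's
superior component passes through zero); line directions are
renormalized to unit length at 1e-9 tolerance.

Two properties define the construction and are enforced by tests:
convexity(G′, Sn′, MCP) equals the target angle to 1e-6°, always; and
MCP ≡ ACP exactly when the chin lies on the target ray.  Note the
second property lives on the *posterior rotation branch*: a chin
anterior to line A can realize the same interior convexity angle yet
is not on line M (it maps to a posterior MCP with x < 0).  The interior
angle does not encode the side; the signed offset does.

## Lip metrics

S line = Col → pogonion; E line = Pn′ → pogonion; both built twice per
record (pogonion = ACP and MCP; nose anchors shared).  Distances are
signed perpendicular point-to-line distances in the sagittal plane,
anterior-positive, with lines treated as infinite (standard
cephalometric practice).  A purely anteroposterior offset mode
(`distance_mode="horizontal"`) is provided for sensitivity analysis;
all defaults and reported numbers use perpendicular distances.  The
aesthetic flag marks |d| ≤ 2 mm (closed interval, configurable window).

## Statistics

* Descriptives: sample mean, SD (n−1), t-based 95% CI.
* Paired comparisons (ACP vs MCP per timepoint): two-sided paired t.
  Zero-variance convention: identical series give t = 0, p = 1;
  identical nonzero differences give t = ±∞, p = 0.
* Chin offsets (|x| at T0 vs T1): Wilcoxon signed-rank, zeros dropped,
  average ranks for ties; exact null distribution for n ≤ 25 nonzero
  differences via dynamic programming over doubled ranks (ties make
  scipy's exact path unavailable), normal approximation with
  continuity and tie corrections above.  The output label keeps the
  historical "Wilcoxon ranked sum" name used in the clinical
  literature; the statistic is the paired signed-rank test.
* Method agreement: ME = mean(ACP − MCP) and MAE = mean |ACP − MCP|
  with SD/min/max of the respective series.  MAE is non-negative by
  definition and bounds |ME| from above.
* Sex comparison: Welch's unequal-variance t (no variance-homogeneity
  assumption is defensible at n = 28 vs 40).
* Correlations: Pearson r with the t-transform p-value.
* Multiplicity: the default "paper" mode reproduces the published
  decision threshold p < 0.01 for α = 0.05 over 4 tests; "exact" mode
  returns α/n.  Both are reported, nothing is hidden in the tables.
* Shapiro–Wilk normality checks are computed per variable and logged;
  they do not switch tests automatically, since both parametric and
  rank tests are reported where they apply.

## Synthetic cohort

The generator emulates the *statistical structure* of a paired
pre/post-surgery cohort, not faces:

* **Layout.** Sn′ at the origin, G′ at a fixed 80 mm face height
  straight above, fixed nose geometry (Pn′ at (20, 10) mm, Col at
  (8, 2) mm — chosen so the S–E line gap at lip level comfortably
  spans the drawn offsets), chin drop h ~ N(55, 4²) mm per subject
  (shared across timepoints), truncated at 20 mm.
* **Chin.** A *directed* convexity angle θ = 180° − ε is drawn per
  timepoint (Gaussian, truncated to (120°, 240°)); ε > 0 is a chin
  posterior to line A, draws above 180° are anterior chins whose
  measured interior angle is 360° − θ.  The signed offset follows as
  x = h(tan ε − tan ε₀).
* **Defaults.** The default configuration back-solves the convexity
  Gaussians from the study's chin-offset distributions: pre-surgery
  from a folded-normal moment match of |x| = 8.53 ± 5.37 mm (signed
  x ≈ N(−7.9, 6.2²) — offsets negative: standardization pulls the
  chin back), post-surgery as zero-mean with σ = 3.87·√(π/2) ≈ 4.85 mm
  so mean |x| = 3.87 mm.  The symmetric post-surgery choice is forced
  by the near-zero post-surgery method bias: a one-sided fit would
  imply a mean ACP−MCP error of ≈1.5 mm, contradicting the reported
  agreement.  The mapping to angles uses a delta-method moment match
  through tan, discounting the chin-drop variance share.
* **Lips.** Four per-sex Gaussian targets (UL/LL × S/E, ACP-based,
  pre-surgery sex-pooled) per timepoint; each lip is placed at the
  unique intersection of its two offset constraints (2×2 linear
  solve).  Offsets are drawn with a within-timepoint correlation
  matrix (same-lip S vs E: 0.92; cross-lip: 0.50) — without it the
  implied lip heights are wildly unstable and a material fraction of
  draws is geometrically infeasible.  Draws whose solution falls
  below the chin or above the columella level are resampled (first
  preserving the subject-level effect, then unconditionally); under
  the defaults fewer than ~3% of draws are rejected and the induced
  mean bias is below 0.1 mm (the recovery experiment measures it).
* **Pairing.** T0 and T1 draws share a subject-level random effect
  with correlation 0.5 (convexity and lip offsets alike).
* **Noise and pose.** Isotropic landmark jitter (0.2 mm SD) plus extra
  lateral noise (0.5 mm SD), then a uniform random rigid pose per
  record, so the frame fit is always exercised.  Noiseless mode makes
  generator and measurer exact mutual inverses (tested to 1e-6).
* **Determinism.** One seeded generator per run; identical seed and
  configuration reproduce cohorts and result files byte-for-byte.

**What passing tests show, and what they do not.**  The generator
draws lip offsets *independently* of the chin geometry.  Real lips
co-vary with the jaw, and the modified chin point removes part of that
shared variance — which is why the real study sees *smaller* SDs for
MCP-based upper-lip measures, while this generator necessarily shows
larger ones (the offset between the two references adds, rather than
removes, variance).  Pipeline correctness, calibration of the CIs and
tests, and the pre→post chin-offset contraction are faithfully
exercised; the variance *ordering* between ACP- and MCP-based columns
is a feature of real anatomy the simulation does not reproduce.  The
generator also makes no claim to facial realism (fixed nose, no
soft-tissue response model, implied lip heights broader than anatomy).

## Calibration experiments

* **Recovery.** Replicate cohorts under the default configuration; for
  every (timepoint, sex, lip variable) the 95% CI of the sample mean
  must cover the configured mean at the nominal rate (3σ binomial band
  over 200 replicates in the acceptance test), and the signed chin
  offset is scored against per-subject ground truth (RMSE ≈ 0.4 mm at
  default noise).
* **Type-I error.** A null configuration draws chins around the target
  ray with a 0.5° spread — the landmark noise floor (0.5 mm at 55 mm
  chin depth).  The spread must sit at the noise floor because the
  ACP-vs-MCP lip difference is not an odd function of the chin offset;
  an anatomical-scale spread leaves a small second-order systematic
  residual (a real property of pivoted-line distances, measurable at
  ≈0.02 mm with 200×68 subjects), which would contaminate a type-I
  estimate.  At the noise floor the fraction of paired comparisons
  significant at the 0.01 threshold stays at the nominal rate within
  Monte-Carlo error.

Problem sizes used throughout (1000-configuration geometric sweeps,
200-replicate calibrations, 500-subject inversion checks) were chosen
so the full suite and the acceptance script each run in about a minute
on one CPU while keeping Monte-Carlo bands tight enough to be
informative.

## Known limitations

* Landmarks arrive as coordinates; no scan processing, landmark
  detection or mesh handling.
* The midsagittal plane is fit from midline landmarks only; true
  symmetry-plane estimation from bilateral anatomy is out of scope.
* The 170° target is applied to both sexes (the reported sex means
  differ by 0.2°); it is a config parameter, not a fitted quantity.
* Whether the original clinical software measured perpendicular or
  horizontal lip distances is unknown; both are implemented, the
  perpendicular convention is the default and the one all defaults
  were derived under.
* Reported unsigned chin-distance SD and the symmetric post-surgery
  offset model cannot both be matched exactly (see Defaults above);
  the symmetric model reproduces the median/IQR and the method-bias
  pattern and is the one implemented.
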