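# Methods

## Superimposition model

Two CBCT scans of the same maxilla, taken months apart, are related by
an unknown rigid motion plus true biological change.  Mini-screw
implants placed in inter-radicular bone are treated as rigid fiducials:
the four endpoints (head = mucosal end, tail = bone-deep end) of the two
implants on one side define a correspondence between scans, and the
least-squares proper rigid transform fitted to them maps every T1
landmark into the T2 frame.  The fit is the Kabsch solution — centroid
subtraction, SVD of the cross-covariance, determinant sign correction —
with no scaling, because superimposition of one rigid object must be an
isometry, and no reflection, even when the unconstrained least-squares
optimum would mirror.  The RMS residual after the fit (fiducial
registration error, FRE) is reported per side and flagged above a
configurable threshold (default 0.5 mm, roughly twice a CBCT voxel).
Each side is registered independently; tooth landmarks never enter the
transform, so tooth movement cannot bias the registration.

Before trusting the fiducials, their mutual rigidity is audited: the
head-to-head and tail-to-tail inter-implant distances are computed
inside each scan (hence pose-invariant) and the paired T1 − T2
differences are tested against zero.  The paired test's n is reported
explicitly; for digitisation noise with SD σ per coordinate the
differences are centred at zero with variance driven by 2σ² per
coordinate contribution.

## Reference frame and measures

All measures are expressed in an anatomical frame built on the T2 scan
only; T1 enters it through the registration.  The transverse plane
(plane 1) is the total-least-squares plane through the four crown points
U6C and U1C of both sides — the smallest-principal-direction solution,
minimising orthogonal residuals.  Its normal is oriented toward PNS so
that the X axis points superiorly and the intrusion sign convention
holds (the construction itself does not fix the sign).  PNS and ANS are
projected onto plane 1; the frame origin is PNS′, X = unit(PNS − PNS′),
Y = unit(ANS′ − PNS′) (in-plane, anterior), Z = X × Y.  The sagittal
plane (plane 2) passes through the origin with normal Z and contains
ANS, PNS and both projections by construction.

Per tooth, the sagittal axis angle drops the root tip onto plane 1,
projects crown, root and foot point onto the sagittal plane (discarding
the frame z coordinate), and measures the interior angle at the
projected root between the rays to the projected crown and foot point.
An auxiliary signed variant is positive when the projected crown lies
anterior to the vertical reference line; the default reported change
uses the unsigned angle, with the signed one available because an
unsigned change is ill-defined if an axis crosses the vertical.  The
angle constructed on U3 landmarks is the canine angle and on U6 the
molar angle (Tip3/Tip6); the incisor "torque" angles Tor2/Tor1 use the
identical construction on U2/U1 landmarks.

Changes are T1 − T2 throughout: negative Δx is intrusion, positive Δy
distal movement, positive ΔL root shortening, positive Δθ
crown-posterior tipping.  M is the full 3D Euclidean displacement of a
landmark (an in-plane variant would discard transverse motion; 3D was
chosen as the more conservative, information-preserving definition).
Left and right sides are integrated by component-wise averaging by
default (patient as unit of analysis); `per_side` keeps both records.
Because only x, y and unsigned angles are reported, left and right
records of mirror-symmetric movements are identical and no mirroring
step is needed.  Each central incisor is assigned to its anatomical side
and measured under that side's registration.

Key invariance properties (all enforced by tests): an arbitrary rigid
motion applied to either scan changes no reported measure by more than
1e-6 (the frame is rebuilt from T2 and T1 is re-registered); a simulated
sagittal rotation φ is recovered as Δθ = φ exactly at σ = 0 regardless
of rotation centre and concurrent translation, because both timepoint
angles are measured against the same vertical and the frame tilt cancels
in the difference.

## Statistics

Paired t-tests (t = mean(d)/(sd(d)/√n), df = n − 1) compare timepoints;
independent-samples t-tests compare groups, pooled-variance by default
with Welch co-reported (the variance assumption of the original SPSS
analysis is unknown, so both are surfaced).  Every test is also
available from (mean, SD, n) summaries, algebraically identical to the
raw-data form, so published tables can be re-analysed; the summary path
takes n explicitly because patient-level and side-level analyses differ.
All p-values are two-sided; significance is flagged at 0.05 and 0.01.
No multiple-testing correction is applied across the ~28 variables —
this mirrors common practice in the application area and is a documented
limitation, not an endorsement.

## Synthetic cohorts

The template arch is an invented but dimensionally realistic bilateral
maxillary dentition (molar-to-incisor arch depth ≈ 40 mm, root lengths
12–16 mm, axis inclinations 12–16°, implant separations 26.4 mm at head
and 18.3 mm at tail level), shipped as an editable CSV.  A patient is
generated by (1) rotating each moved tooth by φ about the transverse
axis through a configurable centre, (2) translating it, (3) shortening
the root apex toward the crown by the resorption amount, (4) mapping the
whole T1 set through the inverse of a random scanner pose, and (5)
adding iid N(0, σ²) noise to every coordinate of both scans
independently (noise after pose: two separate digitisation sessions).
Default σ = 0.25 mm, on the order of CBCT voxel size and landmark
replacement error; recovery studies use σ = 0.1 mm.  Per-patient RNG
substreams are derived from the cohort seed by counter, so cohorts are
reproducible and patients independent.

Cohort configurations draw per-patient movement parameters from normal
distributions.  The shipped G1/G2 presets are parameterised from the
root-apex linear-change, angle-change and root-length-change
distributions of a two-group (adolescent/adult) premolar-extraction
retraction study; preset tipping rotates about the root apex so the four
parameter families stay orthogonal (translation moves the apex, tipping
only the crown) and each is independently recoverable.  Resorption draws
are truncated at zero.  A closed-form `expected_movement` oracle
computes the implied record directly in the template frame; it equals
the pipeline output to 1e-9 at σ = 0 whenever the applied movements
leave the frame-defining landmarks (U6C, U1C, ANS, PNS) unmoved or
moving within the occlusal plane, and is approximate otherwise (moving
the frame landmarks tilts the fitted plane — a real property of the
measurement method, not an artefact).

What the simulator does not emulate: biomechanics (force systems, PDL
response), skeletal growth between timepoints (ANS/PNS drift), image
artefacts, or spatially correlated landmark error.  Passing recovery
tests therefore validates the geometry, registration and statistics of
the pipeline — not the clinical accuracy of landmark digitisation on
real scans.

## Numerical choices and degenerate inputs

Exact-geometry assertions use 1e-9 mm; degeneracy checks use 1e-6 mm.
Rigid and plane fits reject collinear or effectively duplicated point
sets (second singular value below tolerance).  The frame construction
rejects PNS on the occlusal plane and coincident ANS′/PNS′; the angle
construction rejects a vanishing projected ray (root on plane 1 or crown
on root).  Zero-variance paired differences and two zero-variance groups
raise degenerate-test errors rather than returning p-values; the
file-level pipeline logs and continues past degenerate patients or
groups.  CSV output stores full-precision floats (shortest round-trip
representation); display rounding to two decimals is a formatting
option only.

## Problem sizes

The default validation suite uses cohorts of 15–19 patients (matching
the emulated study design), 200-replicate recovery runs for the cohort
mean, 1000-cohort type-I-error runs for the stability test, and 10⁴
vectorised replicates for test-level error-rate checks — sizes chosen so
the whole suite completes in well under a minute while keeping
Monte-Carlo bands decisive.
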