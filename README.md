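# orthomove

Implant-superimposition analysis of 3D orthodontic tooth movement from
CBCT-derived landmark coordinates.

## The problem

When anterior teeth are retracted against mini-screw implant anchorage,
clinicians want to know how much each tooth actually moved in three
dimensions — crown and root apex separately — between the scan taken at
implant placement (T1) and the scan at the end of retraction (T2).  The
two scans are acquired in unrelated scanner coordinate frames, and in
growing patients no skeletal region can be assumed stable.  Mini-screw
implants, however, stay put, so the two scans can be superimposed by
rigidly registering the four endpoints (head and tail) of the two
implants on one side.

`orthomove` implements that workflow for anyone analysing landmark
tables exported from CBCT models:

1. **Registration** — least-squares proper rigid fit (Kabsch: centroid
   subtraction, cross-covariance SVD, determinant sign correction) of the
   four T1 implant endpoints onto the T2 endpoints, with the fiducial
   registration error (FRE) reported per side.
2. **Reference frame** — a transverse occlusal plane (plane 1) fitted by
   total least squares to the four molar/incisor crown points of the T2
   model; ANS and PNS are projected onto it, and a right-handed frame is
   built at PNS′ with X = unit(PNS − PNS′) (superior), Y = unit(ANS′ −
   PNS′) (anterior) and Z = X × Y (transverse).  The plane through PNS′
   with normal Z is the sagittal plane (plane 2).
3. **Measures** — per tooth (U6, U3, U2, U1, both sides): frame
   coordinates of crown and root landmarks; the sagittal long-axis angle
   θ = ∠(C′, R′, Rp′), where Rp is the root's foot point on plane 1 and
   primes denote sagittal-plane projections; root length ‖C − R‖.
   Changes are T1 − T2: Δx (negative = intrusion), Δy (positive = distal
   movement/retraction), M = 3D displacement, ΔL (positive = root
   resorption) and Δθ (positive = crown-posterior tipping; reported as
   Tip6/Tip3/Tor2/Tor1).
4. **Statistics** — paired t-tests within group, pooled or Welch
   independent-samples t-tests between groups, from raw records or
   directly from published (mean, SD, n) summaries.
5. **Synthetic cohorts** — a mirror-symmetric template arch is deformed
   by known per-tooth rigid movements, apex resorption, an arbitrary
   scanner pose and Gaussian digitisation noise, so the whole pipeline is
   validated by parameter recovery without any patient data.

Implant stability itself is auditable before superimposition: the
head-to-head and tail-to-tail inter-implant distances are pose-invariant
within each scan, and their paired T1 − T2 differences should be null.

## Worked example

Simulate the two study-condition cohorts (15 "adolescent" G1 patients,
19 "adult" G2 patients, σ = 0.25 mm noise), run the pipeline, and compare:

```python
import orthomove as om
from orthomove.simulate import default_template, group_preset_cohort, simulate_cohort

template = default_template()
g1 = simulate_cohort(template, group_preset_cohort("G1", sigma=0.25, seed=11))
g2 = simulate_cohort(template, group_preset_cohort("G2", sigma=0.25, seed=22))
v1 = om.cohort_variables(om.analyze_cohort(g1.patients))
v2 = om.cohort_variables(om.analyze_cohort(g2.patients))
tables = om.build_comparison_tables(v1, v2)
print(tables["between"].loc[["U3R_Y", "Tip6", "Tip3", "Tor1"],
                            ["g1_mean", "g1_sd", "g2_mean", "g2_sd", "t", "p", "sig"]].round(2))
```

```
          g1_mean  g1_sd  g2_mean  g2_sd     t     p sig
variable
U3R_Y        4.41   1.92     1.83   1.45  4.48  0.00  **
Tip6        -0.05   7.08     4.30   3.72 -2.31  0.03   *
Tip3         0.03   5.26     6.11   5.49 -3.26  0.00  **
Tor1         6.56   5.88     7.40   5.85 -0.41  0.68    
```

Reading the rows: the simulated adolescent cohort shows ~4.4 mm distal
canine-apex movement versus ~1.8 mm in adults (bodily versus tipping
retraction; p < 0.01), the molar tips mesially in adolescents but
distally in adults, and incisor torque change does not differ.  The
stability audit of the same G1 cohort,

```python
from orthomove.superimpose import stability_record, stability_table
records = [stability_record(t1, t2, s) for t1, t2 in g1.patients for s in ("L", "R")]
print(stability_table(records).round(3))
```

```
          t1_mean  t1_sd  t2_mean  t2_sd  diff_mean  diff_sd      t    df      p   n  significant_0.05
measure
ImplantH   26.433  0.384   26.417  0.322      0.016    0.503  0.170  29.0  0.866  30             False
ImplantT   18.196  0.324   18.305  0.365     -0.108    0.562 -1.055  29.0  0.300  30             False
```

confirms the implants are mutually stable (mean paired change ≈ 0, not
significant), which is what licenses them as registration fiducials.

The same steps are available from the shell:

```sh
orthomove simulate --preset G1 --sigma 0.25 --seed 11 --out g1/
orthomove measure --input g1/landmarks.csv --out g1_measured/
orthomove stability --input g1/landmarks.csv --out g1_stability.csv
orthomove compare --g1 g1_measured/variables.csv --g2 g2_measured/variables.csv --out between.csv
orthomove report --config run.yaml
```

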