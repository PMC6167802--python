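# perispace

Quantitative analysis of perirectal hydrogel spacer placement and its
effect on rectal dosimetry in prostate stereotactic body radiotherapy
(SBRT).

## The problem

Injecting an absorbable hydrogel spacer (e.g. SpaceOAR) between the
prostate and rectum enlarges the perirectal space and spares the rectum
during high-dose-per-fraction radiotherapy (36.25 Gy in 5 fractions).
But placement quality varies between operators and patients, and a
poorly placed gel — displaced laterally or craniocaudally from the
prostate midgland/midline — creates little space where it matters.
`perispace` implements a reproducible pipeline for scoring placement and
relating it to rectal dose, for medical physicists and radiation
oncology researchers working from contoured structure sets:

* **Perirectal space map** — the anterior–posterior gap between the
  posterior CTV surface and the anterior rectal wall, sampled on a
  4 × 4 cm coronal grid (1 cm steps, up to 25 distances) centered on the
  prostate midgland at midline, with pre/post difference maps and
  row/column/overall aggregates.
* **Placement angle θ** — the angle with vertex at the hydrogel center
  of mass G, subtended by the posterior-CTV point P at CTV center and
  the anterior rectal wall point R on the same central ray:
  θ = arccos⟨P−G, R−G⟩ / (‖P−G‖‖R−G‖). Perfect interposition gives
  θ = 180°; misplacement shrinks it.
* **Normalized θ·volume score** — (θ/180°)·(V/V_ref), with V_ref the
  largest gel volume in the cohort. This interaction metric captures
  that a large gel in the wrong place, or a tiny gel in the right place,
  both spare poorly.
* **Rectum DVH metrics** — rDmax 1/2/3 cc (minimum dose to the hottest
  N cc, by inverse-DVH lookup) and rV95/90/80 (volume receiving ≥ x% of
  the prescription), with table-driven constraint checks
  (default: 3 cc ≤ 3440 cGy).
* **Cohort statistics** — Pearson R², simple and multiple linear
  regression with standardized β, pooled two-sample t tests between
  symmetry groups, Shapiro–Wilk screening, assembled into the full
  placement-vs-dosimetry analysis grid.
* **Synthetic phantoms** — co-registered ellipsoidal CTV, tubular
  rectum, displaceable gel and an SBRT-like dose model with steep
  posterior falloff, each carrying planted ground truth, so the entire
  pipeline is testable without patient data.

## Worked example

```python
import perispace as ps

spec = ps.PhantomSpec(gel_volume_cc=10.3, gel_offset_mm=(8.0, 0.0, -5.0))
structures, dose, truth = ps.make_phantom(spec)

frame = ps.anatomic_frame(structures.ctv, structures.rectum)
metrics = ps.compute_placement_metrics(frame, structures.gel, reference_volume_cc=20.6)
sym = ps.symmetry_assessment(frame, structures.gel)
dvh = ps.compute_dvh_metrics(dose, structures.rectum)
pmap = ps.build_map(structures.ctv, structures.rectum)

print(f"gel volume      {metrics.gel_volume_cc:.1f} cc (planted {spec.gel_volume_cc})")
print(f"theta           {metrics.theta_deg:.1f} deg (planted {truth.theta_deg:.1f})")
print(f"theta*volume    {metrics.norm_theta_vol:.3f}")
print(f"symmetry        {sym.category.value}")
print(f"perirectal gap  {pmap.center:.1f} mm at CTV center")
print(f"rDmax 1cc       {dvh.rdmax_cgy[1.0]:.0f} cGy")
print(f"rV95            {dvh.rv_cc[95.0]:.2f} cc")
```

prints

```
gel volume      10.4 cc (planted 10.3)
theta           45.9 deg (planted 46.9)
theta*volume    0.129
symmetry        SYM1
perirectal gap  11.0 mm at CTV center
rDmax 1cc       2339 cGy
rV95            0.00 cc
```

The 10.3 cc gel was displaced 8 mm laterally and 5 mm inferiorly, so the
pipeline-measured θ of 45.9° (within 1° of the planted 46.9°) marks a
mediocre placement even though the gel still covers midline on all three
symmetry slices (SYM1) and opens an 11 mm central gap; the rectal hot
spot stays at 2339 cGy, well under the 3440 cGy 3 cc limit.

A command-line interface mirrors the library
(`perispace simulate | measure | metrics | dvh | analyze | run-all`);
`perispace run-all --n 20 --seed 0 --out out/` simulates a cohort,
measures every patient and writes the cohort CSV plus the full
regression report.

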