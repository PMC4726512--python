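# qma — quantitative morphometric analysis of intact joints

`qma` quantifies osteoarthritis-relevant morphology in *articulated*
(in-situ) small-animal knee joints imaged by microCT.  Most microCT
morphometry is done on disarticulated bones; keeping the joint intact
preserves the spatial relationship between femur and tibia, which is
where early degenerative change shows up.  The package is aimed at
preclinical imaging groups who already have segmented volumes (femur,
tibia, femoral/tibial cartilage) and want reproducible numbers for:

* **Cartilage morphometry** — thickness (Cg.Th, largest-inscribed-sphere
  definition), volume (Cg.V), surface (Cg.S) and Cg.S/Cg.V per
  lateral/medial compartment, plus 2D section thickness and mean
  greyscale (muGr) for histology comparison.
* **Direct bone morphometry** — Ct.Th, Ct.Po, BV, BS, BS/BV, BV/TV,
  Tb.Th, Tb.Sp, Tb.N, Conn.D = max(0, 1 − χ)/TV, and DA from the
  mean-intercept-length fabric ellipsoid.
* **Whole-joint measures** — condylar margin angles σ (which sharpen as
  marginal osteophytes grow) and ρ; joint space width JSW_L/JSW_M; the
  femur-to-tibia centre-of-mass vector (λ, α, β, γ with
  cos²α + cos²β + cos²γ = 1); the tibio-femoral twist angle τ; and
  virtual loading, where the femur is lowered onto the tibia in
  voxel steps to yield the contact-onset distance χ and the
  contact-area growth rate m [mm²/mm].
* **Reliability statistics** — ICC(A,1) with its F-based 95% CI,
  short-term precision errors PE(SD)/PE(%CV), Bland–Altman agreement
  with a proportional-bias test, and Pearson/linear regression.

Because real scan data of this kind is rarely shareable, the package
ships a phantom generator (`qma.phantom`) producing articulated joint,
plate, sphere and trabecular phantoms with *analytic* ground truth for
every metric — the basis of the test suite and the acceptance script.

See `docs/methods.md` for the estimator definitions, conventions
(Euler order for τ, sign of ρ, σ chord convention) and limitations.

## Worked example

```python
from qma import PhantomSpec, make_joint_phantom, compute_joint_metrics

spec = PhantomSpec(joint_gap_mm=1.0, cartilage_thickness_mm=(0.3, 0.3))
_, labels, truth = make_joint_phantom(spec)
record, _ = compute_joint_metrics(labels)

print(f"sigma_F.M = {record.sigma_fm_deg:6.2f} deg   (truth {truth['sigma_fm']:.2f})")
print(f"rho       = {record.rho_deg:6.2f} deg   (truth {truth['rho']:.2f})")
print(f"JSW_M     = {record.jsw_m_mm:6.3f} mm    (truth {truth['jsw_m']:.3f})")
print(f"chi_M     = {record.chi_m_mm:6.3f} mm    (truth {truth['chi_m']:.3f})")
print(f"m_M       = {record.m_m_mm2_per_mm:6.2f} mm^2/mm (truth {truth['m_m']:.2f})")
print(f"tau       = {record.tau_deg:6.3f} deg   (truth {truth['tau']:.3f})")
```

prints

```
sigma_F.M =  53.13 deg   (truth 53.13)
rho       =   0.00 deg   (truth 0.00)
JSW_M     =  1.000 mm    (truth 1.000)
chi_M     =  0.400 mm    (truth 0.400)
m_M       =   9.72 mm^2/mm (truth 9.74)
tau       =  0.000 deg   (truth 0.000)
```

The phantom has a 1.0 mm bone-to-bone gap and 0.3 mm cartilage on each
surface, so contact starts after χ = 1.0 − 0.3 − 0.3 = 0.4 mm of
virtual loading; the medial condylar chord from the notch gives
σ = atan(2.0/1.5) = 53.13°, and the symmetric condyles give ρ = 0 and
τ = 0.  The contact slope m matches the analytic sphere-on-plane
overlap area π(2Rd − d²) to within a fraction of a percent.

## Command line

```sh
qma phantom --preset suite --out phantoms/      # validation phantoms + truth manifests
qma run     --config run.yaml                   # full pipeline on a segmented volume
qma joint   --labels labels.nii.gz --laterality right --out metrics.json
qma repro   --table measures.csv --out repro.csv  # per-parameter ICC / PE report
```

Volumes are accepted as NIfTI, MetaImage or multi-page TIFF (spacing
supplied via config when the format lacks it).  Bone morphometry is
refused on volumes flagged as ionic-contrast (`hexabrix`) scans unless
forced, because such contrast perfuses bone tissue and corrupts
Ct.Th/BS/BV/Tb.Th.

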