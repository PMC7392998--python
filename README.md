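# dualkin

Voxel-wise dual kinetic analysis of simultaneous dynamic [18F]FDG PET and
DCE-MRI, as applied to non-small-cell lung cancer tumors imaged on an
integrated PET-MR scanner. The package computes parametric maps of the PET
and DCE microparameters on a common voxel grid, quantifies per-voxel fit
quality, and correlates every pair of parameters within a tumor — the
analysis that reveals regional decoupling between glucose metabolism and
microvascular perfusion (a hypoxia-like pattern: high phosphorylation where
perfusion and blood volume are low).

Because clinical dynamic PET-MRI datasets of this kind are generally not
shareable, the package ships a digital tumor phantom with known per-voxel
ground truth so that every stage — input-function extraction, model fitting,
fit-quality tables, correlation analysis — is validated end to end.

## Models

**PET — irreversible two-tissue compartment (Sokoloff) model.** With plasma
input C_p(t) and whole-blood activity C_wb(t):

    dC_f/dt = K1·C_p − (k2 + k3)·C_f
    dC_b/dt = k3·C_f
    C(t)    = (1 − v_b)(C_f + C_b) + v_b·C_wb

K1 (mL·min⁻¹·mL⁻¹) and k2 (min⁻¹) are the transport constants, k3 (min⁻¹)
the phosphorylation rate and v_b the fractional blood volume. Derived:
Ki = K1·k3/(k2 + k3) and MRGlu = Ki·glycaemia/LC with the lumped constant
LC = 1 (the oncology convention, making MRGlu a plain multiple of Ki). The
input function is image-derived from an aortic VOI.

**DCE-MRI — extended Tofts model.** The SPGR signal is converted to
gadolinium concentration by inverting the steady-state signal equation
(using the voxel's pre-contrast T10, the sequence TR and flip angle α, and
the contrast relaxivity r), with the arterial curve divided by (1 − Hct)
to yield a plasma concentration. Then

    C_t(t) = v_p·C_p(t) + Ktrans ∫₀ᵗ C_p(u)·e^(−Kep·(t−u)) du,  Kep = Ktrans/v_e.

**Statistics.** Per voxel, fit quality is the relative RMSE,
rRMSE = 100·‖measured − fitted‖₂/‖measured‖₂, summarized as median (IQR)
and binned at 20% / 45%. Per tumor, all 36 parameter pairs among PET
{K1, k2, k3, v_b, MRGlu} and DCE {Ktrans, v_e, Kep, v_p} are correlated
across voxels with Spearman's r_s after |z| > 3 outlier cleaning, with
seeded percentile-bootstrap 95% CIs (1000 resamples); |r_s| < 0.4 is low,
0.4–0.7 moderate, > 0.7 high.

## Worked example

`examples/` contains one short script per capability. Fitting a single
noisy PET voxel (`examples/02_pet_voxel_fit.py`) prints:

```
          truth    fitted
    K1    0.1500    0.1460
    k2    0.3000    0.2929
    k3    0.0500    0.0508
    vb    0.1000    0.1027
    Ki    0.0214    0.0216   (net influx constant, 1/min)
fit rRMSE 3.07% over 41 frames (3% added noise; converged=True)
```

The rates are recovered within a few percent under 3% noise, and the
derived influx constant Ki — the best-identified parameter combination —
within 1%. The full-pipeline example (`examples/06_full_pipeline.py`)
simulates the noisy default phantom, fits both modalities over all 520
tumor voxels and prints the parameter summaries, the fit-quality tables
and the hypoxia-pattern correlations, e.g.:

```
      k3-MRGlu (PET-PET): rs = +0.895 [+0.871, +0.914] high
     k3-Ktrans (PET-DCE): rs = -0.283 [-0.367, -0.177] low
```

— phosphorylation tracks the metabolic rate positively while varying
inversely with perfusion, the pattern built into the phantom's
hypoperfused, metabolically active core.

The same pipeline is scriptable from the shell:

```sh
dualkin simulate --out demo --seed 0           # write the phantom to disk
dualkin run-phantom --out results --seed 0     # simulate + analyze in one go
dualkin run-all --pet demo/pet_4d.nii.gz ...   # analyze files on disk
```

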