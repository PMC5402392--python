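# mpfkit

Fast single-point, synthetic-reference **macromolecular proton fraction
(MPF) mapping** for quantitative myelin MRI, together with everything needed
to validate it against histology on synthetic data: a digital mouse-brain
phantom with a full five-sequence acquisition simulator, Luxol-Fast-Blue
(LFB) optical-density quantification, and the statistical battery of an
MRI–histology validation study (MANOVA, effect sizes, regression/ANCOVA,
Bland–Altman repeatability).

## The problem and the method

MPF is the fraction *f* of proton magnetization residing in the semi-solid
macromolecular pool of the two-pool magnetization-transfer (MT) model. It
tracks myelin content in both white and gray matter, which makes it a
candidate imaging biomarker for demyelinating disease (e.g. the cuprizone
mouse model of multiple sclerosis, where myelin loss is diffuse rather than
focal).

The fast single-point method reconstructs a whole-brain MPF map from three
spoiled gradient-echo (SPGR) images plus two quick field-mapping scans:

- **MT-weighted SPGR** — TR 22 ms, 9° readout, preceded each TR by a 900°,
  10 ms Gaussian saturation pulse at +4.5 kHz off-resonance;
- **T1-/PD-weighted SPGR pair** (16°/3°, TR 16 ms) — a two-point
  variable-flip-angle (VFA/DESPOT1) fit yields the observed R1 = 1/T1 and
  proton density PD;
- **dual-TR AFI** (TR 13/65 ms, 60°) for the B1 scale, and a **dual-TE GRE
  phase pair** (TE 2.4/4.1 ms) for the B0 offset.

Instead of acquiring a no-saturation reference image, the method computes a
*synthetic reference* — the Ernst signal
S_ref = PD·sin α·(1−E1)/(1−E1·cos α), E1 = exp(−TR·R1) — at the MT
sequence's TR and (B1-corrected) flip angle. The measured ratio
S_MT/S_ref is then inverted voxelwise through the matrix pulsed-MT signal
model of the two-pool system (free pool F, bound pool B, cross-relaxation
rate constant R; saturation rates from the Lorentzian and super-Lorentzian
lineshapes), with the remaining two-pool parameters fixed at standard
constraint values (R = 19 s⁻¹, T2B = 10 µs, T2F·R1F = 0.022,
R1B = 1 s⁻¹). The model ratio is strictly decreasing in *f*, so a bracketed
root search recovers MPF uniquely.

Histological validation uses LFB-stained sections: myelin density is read
from the red channel as an optical density OD = 100·(1 − I_R/I_B), with
I_B a background factor from four off-tissue ROIs, averaged over three
adjacent sections per anatomical location.

## Worked example

Reconstructing the default 96×96×24 digital phantom (six labeled brain
structures with control-group MPF values, quadratic B0/B1 fields, Rician
noise at 1% of the white-matter MT-weighted signal):

```bash
python examples/03_phantom_reconstruction.py
```

```
structure              true MPF %  estimated %
corpus_callosum            13.150       13.147
anterior_commissure        11.930       11.925
internal_capsule           12.740       12.743
thalamus                   10.010       10.009
caudoputamen                8.540        8.544
cortex                      8.130        8.128
```

Each row compares the phantom's ground-truth structure-mean MPF with the
value recovered by the full pipeline (field-map estimation → VFA fit →
synthetic reference → single-point inversion); agreement is a few
thousandths of a percentage point at this noise level, and the white-matter
structures sit well above gray matter, as they should for a myelin
surrogate.

The validation statistics on the per-structure group summaries
(`python examples/05_validation_statistics.py`):

```
sample      r      r^2    slope  intercept   p
control    0.933  0.870  0.139      5.651  0.0066
cuprizone  0.963  0.927  0.135      5.996  0.0020
pooled     0.947  0.897  0.134      5.936  0.0000

Fisher r-to-z, control vs cuprizone: z = -0.37, p = 0.71
corpus callosum Cohen's d (MPF): 4.13
```

MPF is nearly proportional to the myelin stain (≈0.135 MPF% per OD%), the
control and demyelinated groups share one regression line, and cuprizone
demyelination of the corpus callosum is a >4-SD effect.

The other examples walk through the two-pool signal model, a single-voxel
inversion with B0/B1 errors, and histology rendering/quantification. The
same stages are available from the shell:

```bash
mpfkit simulate --seed 42 --out session/
mpfkit reconstruct --mt session/mt_w.nii --t1w session/t1_w.nii \
    --pdw session/pd_w.nii --out mpf.nii
mpfkit end-to-end --seed 1 --out study/
```

## Layout

- `src/mpfkit/mt_physics.py` — lineshapes, saturation rates, Ernst signal,
  two-pool steady state (vectorized closed form).
- `src/mpfkit/field_relaxometry.py` — AFI B1, dual-TE B0, VFA R1/PD,
  field-map filling/upsampling.
- `src/mpfkit/mpf_reconstruction.py` — synthetic reference, single-point
  constraint set, voxelwise/vectorized MPF inversion, map reconstruction.
- `src/mpfkit/phantom.py` — labeled digital phantom, acquisition simulator,
  synthetic LFB rendering.
- `src/mpfkit/histology.py` — red-channel OD quantification and
  aggregation into the tidy measurement table.
- `src/mpfkit/stats.py` — group comparison, regression, ANCOVA, factorial
  ANOVA, MANOVA/Wilks, repeatability.
- `src/mpfkit/pipeline.py`, `cli.py`, `config.py`, `io.py` — study glue,
  thin command line, configuration, NIfTI/PNG/CSV I/O.

See `docs/methods.md` for the model details, parameter choices and known
limitations.
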