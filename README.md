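# mrsquant

Absolute quantification of in-vivo **¹H/³¹P magnetic resonance spectra**
and the cohort statistics built on top of it.

The package is aimed at MRS methodologists and neuroimaging researchers
who need a fully scripted, inspectable version of the classical combined
proton/phosphorus workflow:

1. **Prior-knowledge time-domain fitting** (the AMARES role): the FID is
   modelled as a sum of Lorentzian-damped complex sinusoids,

   `s(t) = Σ_k A_k e^{iφ_k} Σ_m r_km exp[(−π d_k + 2πi f_km) t]`,

   with multiplet structure (doublet γ/α-ATP, 1:2:1 triplet β-ATP) and
   constraints — fixed values, bounds, amplitude-ratio and shift-offset
   links — built into the parameterisation.  Cramér–Rao lower bounds
   from the Fisher information of the constrained model provide the
   per-peak error estimates (`sd.amp.`), and the quality-control rules
   of the workflow (SNR > 3; %SD(Cr), %SD(Cho) < 20 %; per-peak relative
   error ≤ 1) are applied to the result.
2. **Absolute quantification** in mmol per kg of brain tissue:
   - proton channel via the internal tissue-water reference with the
     double-spin-echo relaxation factor
     `R_H = e^{−TE/T2} {1 − e^{−TR/T1} + 2e^{(TE/2−TR)/T1} − 2e^{(3TE/2−TR)/T1}}`,
     compartment water contents 0.78/0.65/0.97 (GM/WM/CSF) and the water
     molality 55 510 mmol/kg;
   - phosphorus channel via the phantom-replacement method (75 mmol/l
     KH₂PO₄ external reference) with the steady-state flip-angle factor
     `R_P = sin x (1 − E)/(1 − E cos x)`, `E = e^{−TR/T1}`, and a linear
     coil-loading correction from the transmitter reference amplitudes;
   - both followed by the CSF partial-volume correction `C/(1 − f_CSF)`.
3. **Chemical-shift physiology**: intracellular pH from the Pi–PCr shift
   difference δ, `pH = 6.75 + log₁₀[(3.27 − δ)/(δ − 5.63)]`, and free
   magnesium from the β-ATP–PCr difference δβ,
   `pMg = 4.24 − log₁₀[(δβ + 18.58)^0.42/(−15.74 − δβ)^0.84]`, with
   `[Mg²⁺] = 10^(−pMg)` mol/l, plus the PCr/Cr ratio with
   `[Cr] = [tCr] − [PCr]`.
4. **Cohort statistics**: relative group differences Δmf = (mN−fN)/fN,
   ΔCN = (mC−mN)/mN and hemispheric differences Δrl = (right−left)/left;
   one-way MANOVA per region with Wilks Λ = det(E)/det(E+H) and Rao's F;
   post hoc Scheffé contrasts; repeated-measures hemispheric tests as
   one-sample Hotelling T² on right-minus-left vectors with paired t
   tests per metabolite; Bonferroni thresholds 0.05/9 → 0.0056 and
   0.05/4 → 0.0125; and table-shaped reports.

A first-class synthetic-data module generates phosphorus/proton FIDs,
voxel tissue compositions and three-group cohort tables (fN n=21,
mN n=26, mC n=40 across nine volumes of interest) with published group
means as defaults, so the entire pipeline is testable without any data
download.

## Worked example

Simulate a standard phosphorus voxel at spectral SNR 15, fit it with the
standard prior knowledge, and derive pH:

```python
import mrsquant as mq
from mrsquant.validation import standard_prior_knowledge

acq = mq.phosphorus_acquisition()          # TR 1200 ms, 60°, 2 kHz, 1024 pts
truth = mq.default_phosphorus_model()      # PE..PCr, ATP multiplets, NAD, MM
sigma = mq.noise_sd_for_snr(truth, acq, 15.0)
fid = mq.simulate_fid(truth, acq, noise_sd=sigma, seed=42)

_, prior, constraints = standard_prior_knowledge()
fit = mq.SpectralFitModel(fid, prior, constraints).fit()
print(fit.summary())
pair = mq.shift_pair_from_fit(fit)
print("pH =", round(mq.ph_from_shift(pair.delta_pi), 3))
print("QC pass:", fit.qc("phosphorus").spectrum_ok)
```

which prints (abridged):

```
resonance    amplitude   sd.amp.  shift/ppm  damping/Hz  phase/deg  rel.err
PE              1.2853     0.105     6.7768       4.197      0.000   0.0815
...
PCr             3.6237     0.119    -0.0009       5.136      0.000   0.0329
gATP            2.6253     0.144    -2.5057       5.308      0.000   0.0549
...
pH = 7.005
QC pass: True
```

The PCr amplitude (true value 3.6) is recovered within its CRLB standard
deviation 0.119, the fitted Pi position gives an intracellular pH of
7.005, and the spectrum passes the SNR > 3 quality gate.  Weak peaks
(NAD, the macromolecular hump) carry large relative errors, which is
exactly what the per-peak QC rule screens.

The staged pipeline (simulate → fit → quantify → derive → stats) runs
from the command line and writes flat CSV/JSON/TSV artifacts plus a
structured log of every correction factor and QC decision:

```bash
mrsquant init-config --out mrsquant.yaml
mrsquant run --config mrsquant.yaml --stage all --seed 7 --out-dir out/
```

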