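# hpgluc

Simulation and quantification toolkit for hyperpolarized
δ-[1-¹³C]gluconolactone magnetic-resonance experiments probing
pentose-phosphate-pathway flux through 6-phosphogluconolactonase (PGLS).

## The problem

Dissolution dynamic nuclear polarization (DNP) boosts ¹³C polarization by
four to five orders of magnitude, making it possible to watch a single
enzymatic step in real time: δ-[1-¹³C]gluconolactone enters cells through
glucose transporters, is trapped by phosphorylation, and is hydrolyzed by
PGLS to [1-¹³C]6-phosphogluconate (6PG). The spectrum contains three lines —
6PG at 178.6 ppm, the γ anomer of the substrate at 177.0 ppm and the δ anomer
at 173.8 ppm — and the time-integrated product/substrate ratio

&nbsp;&nbsp;&nbsp;&nbsp;AUC(6PG) / AUC(δ-gluconolactone)&nbsp;&nbsp;(or / AUC(δ+γ))

is the flux surrogate that distinguishes tumor from normal brain and reports
on treatment response. Because hyperpolarized magnetization is non-renewable
— it relaxes with T1 and each radio-frequency pulse consumes a sin θ fraction
— every quantification step must account for the acquisition itself.

`hpgluc` implements that full pipeline, plus a physics-based synthetic-data
generator (multi-pool exchange/conversion dynamics, per-excitation RF
depletion, bolus input, complex Gaussian noise) so each stage can be
validated against closed-form oracles without any scanner data:

- `hpgluc.synth` — pool dynamics and spectrum/EPSI-grid rendering,
  thermal-equilibrium reference spectra, the reference phantom;
- `hpgluc.spectra` — apodization (5 Hz default), peak integration and
  detection, noise and SNR estimation;
- `hpgluc.kinetics` — AUC ratio metrics, flip-angle-corrected
  mono-exponential T1 fit, thermal polarization, polarization
  back-calculation to the time of dissolution;
- `hpgluc.epsi` — time-summed metabolite SNR grids, Lanczos-2 upsampling
  (8×8 → 256×256), ratio maps, ROI statistics, tumor volume from contours;
- `hpgluc.stats` — Welch unequal-variance t-tests and group summaries;
- `hpgluc.workflows` — the three study shapes (solution QC, cell treatment
  comparison, in vivo tumor / longitudinal studies) as seeded, deterministic
  pipelines; `hpgluc.io` — HDF5 containers and CSV peak tables.

## Worked example

`python examples/solution_qc.py` simulates a noiseless 11.7 T substrate
decay (TR 3 s, 13° flip), fits the flip-angle-corrected mono-exponential and
back-calculates polarization from a constructed thermal-reference pair:

```
fitted T1              : 15.70 s (rmse 7.67e-17)
polarization at t=0    : 14.7 %
SNR enhancement factor : 14571
```

The fit removes the per-pulse cos θ depletion before fitting the
exponential, so it recovers the generating T1 exactly; the back-calculation
divides the flip-angle- and average-corrected hyperpolarized/thermal signal
ratio by the thermal Boltzmann polarization (~1.0 × 10⁻⁵ at 11.7 T, 298 K)
after decay-correcting over the 20 s dissolution-to-acquisition delay.

`python examples/cell_treatment_study.py` compares a control arm with a
treated arm converting at 60% of the control rate (n = 3 each, noise
anchored at product SNR 50):

```
ratio_dgl: control 0.1104+-0.0094 vs treated 0.0706+-0.0062  t=6.14 p=0.0057 **
```

`python examples/invivo_mapping.py` maps one simulated EPSI acquisition:

```
         tumor: 6PG/substrate 1.367 +- 0.072 (4 voxels, 612 mm3)
 contralateral: 6PG/substrate 0.366 +- 0.038 (4 voxels, 612 mm3)
```

The elevated-conversion region lights up in the ratio map several-fold above
contralateral brain while the substrate remains distributed brain-wide.

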