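# sofiquant

Quantitative, threshold-free clustering analysis of membrane proteins from
super-resolution optical fluctuation imaging (SOFI).

Membrane proteins such as the T-cell co-receptor CD4 organize into
nanoscale high-density regions (HDRs) far below the diffraction limit.
Single-molecule localization microscopy struggles to count molecules in
densely packed regions, where overlapping emitters and multiple blinking
produce under-counting and artificial clusters.  `sofiquant` implements an
alternative route: a TIRF image sequence of stochastically blinking
fluorophores is converted into higher-order spatio-temporal cross-cumulant
images, the cumulant orders are combined into a molecular density map on a
4x super-resolved grid, and high-density regions are quantified by sweeping
a density threshold over the full range present in the sample — with the
working threshold chosen automatically, not by the examiner.

The package also contains the matching simulator (blinking photokinetics,
Gaussian PSF rendering, EMCCD camera noise, ground-truth HDR layouts) used
to validate the pipeline end to end.

## The model

For emitters blinking independently with on-time ratio ρ and per-pixel
brightness ε, the order-n cross-cumulant image of the mean-subtracted pixel
traces is

    g_n(r) = N(r) · μ_n · ε^n · κ_n(ρ),

where κ₂ = ρ(1−ρ), κ₃ = ρ(1−ρ)(1−2ρ), κ₄ = ρ(1−ρ)(1−6ρ+6ρ²), and
μ_n is the spatial integral of the order-n image PSF Uⁿ.  The cumulant
ratios

    K₁ = μ₂g₃ / (μ₃g₂) = ε(1−2ρ)
    K₂ = μ₂g₄ / (μ₄g₂) = ε²(1−6ρ+6ρ²)

close the system: ε = √(3K₁²−2K₂), ρ = (3K₁² − K₁ε − 2K₂)/(2(3K₁²−2K₂)),
and the molecular density is

    N(r) = (g₂(r)/μ₂) / (ε² ρ(1−ρ)).

Cross-cumulants of *distinct* neighbouring pixels are assigned to the pixel
centroid, which yields an n-fold finer virtual grid (26.25 nm at 4th order
for a 105 nm camera pitch; Nyquist-limited minimum HDR diameter 52.5 nm)
and removes shot-noise bias; the amplitude lost to pixel separation is
restored by the Gaussian distance factor exp(−Σᵢ|rᵢ−c|²/2σ²).

HDRs are the 8-connected components of {N/δ_avg ≥ t} for each threshold t
(δ_avg = mean density over the analyzed ROI).  The number of regions versus
threshold is modelled as a Gaussian bump (randomly scattered molecules) on
a floor (genuine clusters); the automatic threshold is the smallest grid
value at which the fitted Gaussian falls below one region per ROI.

## Worked example

Simulate one clustered scenario (10 HDRs of 180 nm diameter at
3000 molecules/µm², HDR-to-background contrast 100, 5000 frames) and
analyze it:

```bash
sofiquant simulate --out sim --frames 5000 --diameter-nm 180 \
    --density 3000 --contrast 100 --n-hdrs 10 --seed 2
python -c "from sofiquant import stack_io;
stack_io.write_config('config.yaml', stack_io.AcquisitionConfig())"
sofiquant analyze sim/scenario_0000_stack.tif --config config.yaml \
    --out analysis --no-drift
```

which prints

```
wrote 1 scenario(s) to sim
selected threshold: 4.60 x mean density; 10 HDRs
```

i.e. the automatic rule picked a density threshold of 4.6 times the ROI
mean, at which all 10 ground-truth high-density regions were segmented.
`analysis/`
contains the full per-threshold sweep (`sweep.csv`), the per-region table
at the selected threshold (`regions.csv`: area, equivalent diameter in nm,
centroid, mean relative density), the density map and bSOFI mask as
float TIFFs, a `summary.json` and a `manifest.json` echoing every
parameter of the run.

The same pipeline is available as a library:

```python
from sofiquant import AcquisitionConfig, analyze_sequence, simulator

optics = AcquisitionConfig()                      # 105 nm pitch, EM gain 300
gt = simulator.make_ground_truth(seed=2)          # 10 HDRs on 3x3 µm
seq = simulator.simulate_sequence(gt, 5000, simulator.PhotokineticsModel(),
                                  optics, seed=2)
res = analyze_sequence(seq, optics, correct_drift=False)
print(res.optimal_threshold, res.n_regions_at_optimum)
```

## Layout

| module | role |
| --- | --- |
| `stack_io` | TIFF stacks, acquisition configs, ROI selection |
| `drift_correction` | fiducial tracking and sub-pixel registration |
| `sofi_core` | cross-cumulant images of orders 2–4, bSOFI linearization |
| `density` | PSF moments, blinking inversion, density maps, masks |
| `hdr_cluster` | threshold sweep, automatic threshold, group summaries |
| `simulator` | photokinetics, PSF rendering, EMCCD noise, ground truth |
| `pipeline` / `cli` | the chained workflow and its command-line front end |

See `docs/methods.md` for the numerical and statistical choices.
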