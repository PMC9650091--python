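# vesifret

Analysis toolbox for detecting crowding-induced compaction of ~200 nm
lipid vesicles by FRET.  Large unilamellar vesicles carrying the DiI–DiD
donor–acceptor pair report conformational change through the apparent FRET
efficiency `E = I_A / (I_A + I_D)`: when a molecular crowder (sorbitol,
PEG, Ficoll) compacts a vesicle, the mean dye separation ⟨d⟩ shrinks and E
rises, following the Förster relation

    E = R0^6 / (R0^6 + R^6),      R0 = 5.3 nm for DiI–DiD.

The package implements the four quantitative readouts of such an assay as
one tested library, plus generators that produce every input modality with
known ground truth:

- **`photophysics`** — efficiency ↔ distance arithmetic.
- **`ensemble_spectra`** — bulk emission spectra across a crowder
  titration: band integration, background correction, E and ⟨d⟩ per
  concentration, quadratic trend fit.
- **`tcspc`** — fluorescence-lifetime fitting by iterative reconvolution
  of a multi-exponential decay with the instrument response (wrap-around
  over the laser repetition period), amplitude-weighted lifetime τ_av,
  parametric-bootstrap confidence intervals.
- **`dls`** — dynamic light scattering: `G(τ) = A[1 + B e^(-2Dq²τ)]`
  correlogram fits, Stokes–Einstein hydrodynamic diameters, log-normal
  size-distribution summaries for diameter tables.
- **`single_vesicle_imaging`** — dual-view TIRF movies of surface-tethered
  vesicles: channel registration, spot detection, background-corrected
  intensity traces, per-vesicle E, 0.01-bin population histograms with
  Gaussian peak fits, and before/after/wash reversibility classification.
- **`synthetic_data`** — seeded generators for all of the above.
- **`pipeline`** — YAML-configured end-to-end runs with consolidated
  reports.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Simulate a before/after/wash experiment in which a high-molecular-weight
crowder reversibly compacts the vesicles (E 0.40 → 0.60 → 0.40), then run
the full imaging pipeline on each movie:

```python
from vesifret import synthetic_data as sd, single_vesicle_imaging as svi

hists = []
for e in (0.40, 0.60, 0.40):   # before, +crowder, washed
    movie, truth = sd.generate_movie(
        n_frames=500, E_spec=("normal", e, 0.05), seed=101,
    )
    result = svi.analyze_movie(movie)
    hists.append(result["histogram"])

for name, h in zip(("before", "after", "wash"), hists):
    print(f"{name:7s} n={h.n_vesicles}  E peak={h.mean:.3f}  "
          f"<d>={h.mean_separation_nm:.2f} nm")
report = svi.compare_conditions(*hists, shift_threshold=0.03)
print("verdict:", report["verdict"])
```

Output:

```
before  n=193  E peak=0.393  <d>=5.70 nm
after   n=193  E peak=0.593  <d>=4.98 nm
wash    n=193  E peak=0.393  <d>=5.70 nm
verdict: reversible
```

193 vesicles are detected in the 25 × 50 µm field; the efficiency
histogram peak moves from ~0.40 (mean dye separation 5.70 nm) to ~0.59
(5.0 nm) on crowder addition and returns after washing, so the comparison
classifies the perturbation as reversible.  Per-vesicle total intensity
stays constant across conditions (the vesicles remain intact); an
irreversible crowder would leave the "wash" peak at the shifted position.

The same analyses are scriptable from the shell:

```sh
vesifret simulate decay --seed 2 --out demo/
vesifret fit-decay --decay demo/decay.csv --irf demo/irf.csv --n 2 --boot 100 --seed 7 --out demo/fit.csv
vesifret fit-dls --corr correlogram.csv --out fit.csv
vesifret run --config run.yaml
```

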