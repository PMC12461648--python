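# frapsr

Quantitative FRAP (fluorescence recovery after photobleaching) analysis
in the super-resolution regime, for nuclear condensates such as
53BP1-EGFP foci. At ~60 nm lateral resolution a single focus can be
resolved into *subcompartments* whose protein exchange rates differ;
`frapsr` provides the full measurement chain for that experiment plus a
ground-truth simulator, so every number the pipeline produces can be
validated without microscope data.

The package is aimed at microscopists and image analysts quantifying
condensate dynamics: it distinguishes *compact* foci (near-convex,
stationary contour, uniform single-compartment recovery) from
*amorphous* foci (irregular, shape-changing contour with multiple
kinetic subcompartments).

## The model

Recovery of a bleached compartment follows one-phase association

    y(t) = y₀ + (plateau − y₀)(1 − e^(−kt)),      t½ = ln 2 / k,

on curves double-normalized from raw ROI intensities:

    r = (Fc − Fb)/(Fc₀ − Fb)      photobleaching rate (control region)
    R = (Fi − Fb)/(Fi₀ − Fb)      recovery rate of the bleached ROI
    N = R / r                     normalized recovery

with Fi/Fc/Fb the bleach-ROI, control, and background means and
Fi₀/Fc₀ pre-bleach baselines. The immobile fraction is
1 − (plateau − y₀)/(1 − y₀). Morphometrics include the sphericity index
(convex-hull perimeter / boundary perimeter; 1 = convex, → 0 = spiky)
and centroid displacement between −5 s and +40 s. Subcompartments are
detected from the per-pixel time-to-half-recovery map and called
`multi` when per-region half-times have a coefficient of variation
above 0.3. A twin-bead assay classifies nanoruler pairs as resolved
("twin", two significant profile maxima) or not, realizing the
two-Gaussian dip criterion d > 2σ.

Modules: `phantom` (simulator), `segmentation`, `frap_kinetics`,
`subcompartments`, `resolution`, `io`/`config`/`pipeline`/`cli`.
See `docs/methods.md` for assumptions and parameter rationale.

## Worked example

Simulate an amorphous two-subcompartment focus at diSIM resolution and
run the full pipeline:

```python
from frapsr.phantom import (imaging_preset, preset_bleach, preset_scene,
                            simulate_frap_movie)
from frapsr.pipeline import run_pipeline

scene = preset_scene("untreated_amorphous")
imaging = imaging_preset("disim", seed=7, n_z=1)
movie, truth = simulate_frap_movie(scene, imaging, preset_bleach(scene))
bundle = run_pipeline(movie)
print(bundle["fits"][["focus_id", "k_per_s", "t_half_s", "plateau",
                      "immobile_fraction"]].round(4))
print(bundle["calls"].round(3))
print([round(f.t_half, 1) for f in bundle["call_objects"][0].fits])
```

prints

```
 focus_id  k_per_s  t_half_s  plateau  immobile_fraction
        0   0.0496   13.9781   0.8438             0.1706
 focus_id  n_subregions  heterogeneity_index  call contour_call
        0             2                0.628 multi    amorphous
[7.5, 32.8]
```

The whole-focus half-time (14.0 s) sits between the two subcompartment
half-times (7.5 s and 32.8 s; ground truth 7.8 s and 31.2 s), the focus
is correctly called `multi`-compartment with an `amorphous` contour, and
about 17% of the bleached signal never recovers (immobile fraction).

The same analyses are available from the shell:

```bash
frapsr simulate --preset untreated_amorphous --psf disim --seed 7 --out sim/
frapsr run --in sim/movie.tif --out results/
frapsr beads --in beads.tif --truth pairs.csv --pixel-size-nm 15 --out beads_out/
```

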