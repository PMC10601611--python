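# cyanofish

Quantification of mRNA-FISH and GFP fluorescence relative to the thylakoid
membrane in rod-shaped cyanobacteria.

Cyanobacteria hold two separate membrane systems — the photosynthetic
thylakoid shells near the cell periphery and the plasma membrane outside
them — and where an mRNA or a ribosome sits between them reports on where
membrane proteins are made. This package implements the image-quantification
pipeline behind that kind of study: cell segmentation from pigment
autofluorescence, short-axis radial profiling with a width-normalized radial
coordinate, Pearson colocalization at Costes' automatic threshold, per-cell
intensity statistics (patchiness, plasma-membrane band signal,
polar:equatorial ratio), rule-based FISH probe design, and statistical
reporting — together with a synthetic-micrograph generator with exact ground
truth used to validate every measurement.

## The core quantities

* **Normalized radial coordinate** *u*: an 8-pixel-wide line across a cell's
  short axis shows two thylakoid autofluorescence peaks; positions are
  expressed with the cell center at *u* = 0 and the peaks at ±0.5, so the
  peak-to-peak distance is the unit of length and cells of different widths
  are directly comparable. A FISH focus with |*u*| < 0.4 is central
  cytoplasm; |*u*| ≈ 0.5 overlaps the thylakoid zone; |*u*| > 0.6 lies
  beyond it, toward the plasma membrane.
* **Pearson correlation at Costes' threshold**: per cell, the
  product-moment correlation *r* of two channels' pixels (1 = perfect
  colocalization, −1 = perfect anti-correlation, 0 = uncorrelated), with
  background excluded by Costes' automatic threshold pair (T_A, T_B) — the
  highest thresholds at which the pixels below both are no longer positively
  correlated.
* **Patchiness**: per-cell SD of pixel intensities divided by total cell
  fluorescence — high for sharp puncta, low for diffuse signal; the readout
  of choice when a transcript's total signal is dwarfed by autofluorescence.
* **Membrane band**: fluorescence in a 0.2 µm-wide band drawn immediately
  outside the thresholded thylakoid region — the plasma-membrane zone.
* **Probe sets**: 20-nt oligos, GC ≈ 50 %, ≥ 2 nt between sites, at most 48
  per target, reported as synthesized (reverse complement, 3′ fluorophore).

## Worked example

Simulate an uninduced/induced pair of fields — in the induced field half the
FISH foci are drawn from a membrane model (|u| ≥ 0.5) — then run the
pipeline and test the radial shift:

```python
import numpy as np
from cyanofish import (SimConfig, simulate_condition_pair, preprocess,
                       segment_cells, extract_profile, localize_foci,
                       ttest_two_sample)
from cyanofish.simulate import FocusChannel, PigmentChannel

cfg = SimConfig(seed=11, n_cells=16, image_size=(768, 768),
                channels={"thylakoid": PigmentChannel(),
                          "fish": FocusChannel(n_foci=(3, 5))})
(img_a, _), (img_b, _) = simulate_condition_pair(cfg, shift=0.5)

def radial_positions(image):
    blurred = preprocess(image)
    cells = segment_cells(blurred)
    us = []
    for cell in cells:
        if cell.touches_border:
            continue
        profile = extract_profile(blurred, cell)
        us += [f.u for f in localize_foci(blurred, cell, profile, "fish")]
    return np.array(us)

u_a, u_b = radial_positions(img_a), radial_positions(img_b)
beyond = lambda u: (np.abs(u) >= 0.4).mean()
print(f"uninduced: n={len(u_a)} foci, beyond-central fraction {beyond(u_a):.2f}")
print(f"induced:   n={len(u_b)} foci, beyond-central fraction {beyond(u_b):.2f}")
res = ttest_two_sample(np.abs(u_a), np.abs(u_b))
print(f"t = {res.t_statistic:.2f}, p = {res.p_value:.2e} ({res.significance_label})")
```

Output:

```
uninduced: n=62 foci, beyond-central fraction 0.00
induced:   n=62 foci, beyond-central fraction 0.58
t = -7.79, p = 2.49e-12 (***)
```

The uninduced field keeps every detected focus in the central cytoplasm; in
the induced field 58 % of foci localize at or beyond the thylakoid zone, and
the two |u| distributions differ decisively — the pipeline recovers the
simulated redistribution.

The same stages are available from a shell:

```bash
cyanofish simulate --out run/ --seed 1
cyanofish segment  --in run/field.tif --out run/
cyanofish radial   --in run/field.tif --channel fish --out run/
cyanofish coloc    --in run/field.tif --ch1 fish --ch2 thylakoid --out run/
cyanofish metrics  --in run/field.tif --channels fish --out run/
cyanofish probes   --fasta target.fa --out probes/
cyanofish report   --metrics table.csv --pairs uninduced:induced --out run/
```

See `docs/methods.md` for the full description of each measurement, the
simulator's signal model, and the numerical choices.

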