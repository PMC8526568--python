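# lgt — local-GTP toolkit

Tools for asking whether a GTPase's activity tracks the *local* supply of
its substrate in live cells, plus a sequence-based method for predicting
how the supplying enzyme docks onto the GTPase.

Cells report GTP with a genetically encoded ratiometric sensor (GEVAL30,
half-maximal at Keff = 32.3 µM free GTP; its GTP-blind twin, GEVALNull,
is the negative control) while RAC1 activity is read out simultaneously
by a FRET biosensor. The question — do pixels with more free GTP show
more RAC1 activity? — is answered by a pixel-wise Pearson correlation
between the two index maps, frame by frame. Getting that number right
requires the whole unglamorous correction chain (dark current, shading,
channel registration, background, bleed-through, photobleaching), so the
package implements the chain end to end and ships a forward-model
microscope simulator with known ground truth to prove each stage inverts
what the optics did.

A second, independent arm predicts the IMPDH2–RAC1 style binding
interface from sequence alone: orthologs of two proteins are joined per
species into a concatenated alignment, inter-protein evolutionary
couplings are scored by direct-coupling analysis (mean-field or
pseudolikelihood), smoothed with a Gaussian convolution, and tested for
significance by shuffling one protein's species assignments.

## What it computes

**Imaging arm.** Per pixel and frame,

- FRET index (RAC1 activity): `R = (FRET − α·Donor − β·Acceptor) / Donor`,
  with bleed-through fractions α, β estimated from donor-only /
  acceptor-only control cells;
- GTP index: the ratio of GTP-sensor fluorescence excited at 409 nm vs
  494 nm, a saturating function `r_min + (r_max − r_min)·c/(Keff + c)` of
  free GTP `c`;
- per-frame Pearson `r` between the two indices over jointly valid
  pixels, summarized per cell (mean, median, quartiles) and compared
  between groups by Mann–Whitney; paired/unpaired two-tailed t-tests
  serve the cell-body vs cell-protrusion (CB/CP) ratio comparisons.

**Coevolution arm.** For column `i` of protein A and `j` of protein B,
the coupling score is the APC-corrected Frobenius norm of the 20×20
amino-acid coupling submatrix from DCA on the species-concatenated
alignment; the convolved inter-protein block is thresholded at the
minimum of its top 5%, and the species-shuffle randomization test
reports `p = exceedances / replicates` (e.g. 3 of 100 → p = 0.03).

## Worked example

Simulate three cells with a planted GTP–activity pixel correlation of
0.5, run the full correction + index + correlation pipeline, and compare
against the same scenes imaged with the GTP-blind Null sensor:

```python
from lgt.pipeline import ImagingRunConfig, run_imaging_pipeline, compare_sensor_groups
from lgt.synthetic import SceneConfig

res30 = run_imaging_pipeline(ImagingRunConfig(
    n_cells=3, scene=SceneConfig(rho=0.5), sensor="geval30", seed=1))
resnull = run_imaging_pipeline(ImagingRunConfig(
    n_cells=3, scene=SceneConfig(rho=0.5), sensor="null", seed=1))
for i, rec in enumerate(res30.records):
    print(f"GEVAL30 cell {i}: mean r = {rec.mean:+.3f} "
          f"(Q1 {rec.q1:+.3f}, median {rec.median:+.3f}, Q3 {rec.q3:+.3f})")
for i, rec in enumerate(resnull.records):
    print(f"Null    cell {i}: mean r = {rec.mean:+.3f}")
cmp_ = compare_sensor_groups(res30, resnull)
print(f"Mann-Whitney U = {cmp_.statistic:.1f}, two-sided p = {cmp_.p_value:.4f}")
```

prints

```
GEVAL30 cell 0: mean r = +0.480 (Q1 +0.459, median +0.488, Q3 +0.496)
GEVAL30 cell 1: mean r = +0.486 (Q1 +0.473, median +0.485, Q3 +0.496)
GEVAL30 cell 2: mean r = +0.482 (Q1 +0.469, median +0.482, Q3 +0.498)
Null    cell 0: mean r = -0.003
Null    cell 1: mean r = +0.003
Null    cell 2: mean r = +0.001
Mann-Whitney U = 9.0, two-sided p = 0.1000
```

The GTP-sensitive sensor recovers the planted correlation to within a
few hundredths (noise in the five channels attenuates Pearson r
slightly); the Null sensor's ratio carries no GTP information, so its
correlation with RAC1 activity sits at zero. With three cells per group
the exact Mann–Whitney p cannot go below 0.1 — complete separation of
larger groups does.

The same pipelines are scriptable from the shell:

```bash
lgt analyze-imaging --sensor geval30 --rho 0.5 --n-cells 3 --seed 1
lgt cbcp --n-cells 30 --offset 0.15 --test paired
lgt coevolve simulate --out msa/ --n-species 500 --pairs 5
lgt coevolve run --fasta-a msa/protein_a.fasta --fasta-b msa/protein_b.fasta
lgt coevolve randomize --fasta-a msa/protein_a.fasta --fasta-b msa/protein_b.fasta
```

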