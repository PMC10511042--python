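# spheromet

Quantitative image analysis of epithelial spheroid rounding.

When dispersed epithelial cells are seeded into a non-adhesive microwell,
the elongated cell mass gradually rounds into a spheroid. `spheromet`
implements the measurement pipelines used to characterize that process
from time-lapse microscopy, together with a ground-truthed synthetic-data
generator so every stage can be validated without external data. It is
aimed at cell biologists and image analysts quantifying 3D suspension
cultures: spheroid morphogenesis, collective nuclear motion, junction
maturation and spheroid fusion assays.

## What it computes

**Circularity kinetics** (`spheromet.morphometry`). The projected contour
of the cell mass is extracted at subpixel precision and its circularity
(the CellProfiler "form factor")

```
c = 4π · A / P²
```

is tracked over time (A = contour area, P = perimeter; c = 1 for a
circle). The curve is segmented into the *latent* phase (flat), *rising*
phase (increasing) and *static* phase (plateau), and discrete upward
jumps — the signature of two sub-masses fusing — are detected against a
local median-absolute-deviation noise floor.

**3D nuclei tracking** (`spheromet.tracking`). Nuclei in 3D+t stacks are
detected with an anisotropic Difference of Gaussians (σ = 1.9/3.8 px
laterally, 0.7/1.4 px axially by default), localized to subvoxel
precision by an iterative Gaussian-weighted centroid, and linked into
trajectories by gated greedy nearest-neighbor assignment (an optimal
assignment variant is a switch).

**Neighbor displacement correlation** (`spheromet.correlation`). For each
pair of neighboring cells and each frame, the direction correlation

```
r = (v_a · v_b) / (|v_a| |v_b|)
```

of the two displacement vectors is computed: +1 for cells moving in
parallel (coordinated sub-group motion), −1 for cells moving apart,
uniform on [−1, 1] for independent isotropic motion. The package builds
the per-pair table, the time-resolved r density, and the coordinated
fraction (share of pairs with r > 0.8 in a time window).

**Junction morphometrics** (`spheromet.junctions`). Punctum adherens (PA)
spots are segmented, kept only when attached to an F-actin bundle, and
sized by maximum Feret diameter; the ZO-1 tight-junction network is
enhanced, skeletonized to single-pixel width and its total length
reported per cell and per area.

**Fusion metrics** (`spheromet.fusion`). For spheroid-doublet fusion
assays: the doublet long-axis length (max Feret of the silhouette,
normalized to t = 0) and the contact length (minimum cross-section width
at the neck between the two lobes).

**Synthetic data** (`spheromet.synthetic`). Generators with exact ground
truth for all of the above: rounding mask movies from an analytic stadium
shape family, 3D+t nuclei stacks under coherent/independent/mixture
motion models, polygonal junction tessellations with PA spots, and
fusing-disc doublets. See `docs/methods.md` for the models and their
assumptions.

## Worked example

```python
from spheromet.synthetic import RoundingKinetics, generate_rounding_movie
from spheromet import morphometry as M

kin = RoundingKinetics(c_inf=0.95, t_latent=5.0, t_static=18.0,
                       jumps=[(10.0, 0.15)])
movie, truth = generate_rounding_movie(aspect_ratio=3.0, kinetics=kin,
                                       frames=25, seed=7)
series = M.circularity_timeseries(movie)
seg = M.segment_phases(series)
jumps = M.detect_jumps(series, min_step=0.08)

print(f"initial circularity (3:1 mass): {series.values[0]:.3f}")
print(f"plateau circularity:            {series.values[-1]:.3f}")
print(f"latent phase ends at            {seg.t_latent_end:.1f} h")
print(f"static phase starts at          {seg.t_static_start:.1f} h")
for t, d in jumps:
    print(f"fusion jump: +{d:.3f} circularity at {t:.1f} h")
```

prints

```
initial circularity (3:1 mass): 0.686
plateau circularity:            0.948
latent phase ends at            6.0 h
static phase starts at          17.0 h
fusion jump: +0.160 circularity at 10.0 h
```

The initial value 0.686 is the analytic circularity of a 3:1 rounded
rectangle; the measured series follows the programmed kinetics (latent
until 5 h, static from 18 h) within the stated tolerances, and the
programmed +0.15 fusion jump at 10 h is found at the right frame.

A command-line interface mirrors the library
(`spheromet simulate|circularity|track|correlate|junctions|fusion`, see
`spheromet --help`); it reads multi-page TIFF with a JSON calibration
sidecar and writes CSV/JSON.

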