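# ependypol

Quantification of planar cell polarity and near-wall flow in
multiciliated ependymal epithelia.

Ependymal cells line the brain ventricles and drive near-wall
cerebrospinal-fluid flow with bundles of motile cilia.  Each cilium is
anchored by a basal body (BB); the BBs of a cell cluster in a patch on
the apical surface, and both the placement of that patch within the cell
and the common orientation of the basal feet must be coordinated across
the tissue for flow to be directional.  Studies of hydrocephalus and
ciliopathies quantify this coordination from stained whole-mounts and
microsphere videos; `ependypol` packages those measurements — and a
ground-truthed synthetic-data generator for validating them — as a
tested Python library and command-line pipeline for researchers doing
ependymal or airway multiciliated-cell biology.

## What it computes

**Translational polarity.** For each cell with centroid *C* and BB-patch
centroid *BC*: the translational distance TD = |*C* − *BC*| (also
normalized by the cell's equivalent radius, TD/R_eq) and the BB patch
angle TA = direction of *C* → *BC*.

**Patch orientation.** The Feret (longest-caliper) diameter LD of the BB
point set and its axial Feret angle FA ∈ [0°, 180°).

**Rotational polarity.** Vectors from each basal-foot marker point to
its nearest BB point (greedy one-to-one, distance-gated); their circular
mean and resultant length *R* summarize how uniformly the cilia are
oriented.

**Circular statistics.** Circular mean and resultant length, the
Rayleigh uniformity test (Z = nR²), and Watson's two-sample U² test of
homogeneity,

U² = (nm/N²) [ Σₖ dₖ² − (Σₖ dₖ)²/N ],   dₖ = F̂ₐ(x₍ₖ₎) − F̂_b(x₍ₖ₎),

with a permutation p-value by default (asymptotic critical points
0.187/0.268 at α = 0.05/0.01 available for large samples).

**Flow analysis.** Microsphere videos → per-frame spot detection
(difference-of-Gaussians, sub-pixel refinement) → greedy gated
nearest-neighbor linking → one net-displacement direction per track →
Watson U² comparison between groups (coherent, wild-type-like flow vs
disorganized, mutant-like flow).

**Cohort arithmetic.** Minor allele frequency of a variant in a
sequenced cohort and the 2×2 χ² test of independence with Yates
continuity correction.

**Synthetic scenes.** A Voronoi epithelium of Poisson-disk seeds whose
per-cell patch offsets, elongation axes and basal-foot directions are
drawn from von Mises distributions around a global direction µ with
concentrations κ (κ = 0 is uniform), and microsphere videos advected by
a coherent or vortex flow field plus Brownian noise — every sampled
value recorded as ground truth.

## Worked example

```python
import ependypol as ep
from ependypol import synthetic_scene as ss, flow_tracking as ft

# a coordinated 200-cell epithelium: patches offset 35% of the cell
# radius toward 40 degrees, concentration kappa = 8
scene = ss.SceneConfig(n_cells=200, mu_global=40, kappa_trans=8,
                       offset_frac=0.35, seed=0)
labels, bb, feet, truth = ss.generate_mosaic(scene)
m = ep.measure_cells(ep.cells_from_label_image(labels), bb)
inner = m[~m.touches_border]
ta_mean, ta_R = ep.circular_mean_R(
    ep.AngleSample("TA", inner.TA.dropna().to_numpy()))
print(f"mean TD_norm: {inner.TD_norm.mean():.3f}")
print(f"TA mean, R:   {ta_mean:.1f} deg, {ta_R:.3f}")

# coherent vs disorganized flow, end to end
samples = []
for cfg, label in ((ss.FlowConfig(regime="coherent", mean_direction=45,
                                  seed=0), "WT"),
                   (ss.FlowConfig(regime="disorganized", seed=1), "mutant")):
    frames, _ = ss.generate_flow_video(cfg)
    tracks = ft.link_trajectories(ft.detect_stack(frames))
    samples.append(ft.direction_sample(tracks, label=label))
res = ft.compare_flow(samples[0], samples[1], seed=0)
print(f"Watson U2 = {res.u2:.3f}, permutation p = {res.p_value:.3f}")

print(f"cohort MAF = {ep.allele_frequency(1, 53):.4f}")
```

prints

```
mean TD_norm: 0.350
TA mean, R:   37.8 deg, 0.933
Watson U2 = 4.180, permutation p = 0.001
cohort MAF = 0.0094
```

The measured patch displacement (0.350) and direction (37.8°, resultant
length 0.933) recover the generative parameters (0.35, 40°); the
coherent and disorganized direction distributions differ at the
permutation floor p = 1/1000; one heterozygous carrier among 53 diploid
individuals gives an allele frequency of 0.0094.

The same analyses are available from the shell:

```sh
ependypol simulate --preset wt --seed 1 --flow --out out/wt
ependypol polarity --labels out/wt/labels.tif --points out/wt/points.csv --out out/pol
ependypol flow --input out/wt/flow.tif --input2 out/mut/flow.tif --out out/flow
ependypol cohort --table 1 105 3 201294 --maf 1 53
```

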