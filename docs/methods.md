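# Methods

This note records the models, conventions and numerical choices behind
`cortimap`, in the order the pipeline runs.

## Coordinate and voxel conventions

Volumes are `(z, y, x)` arrays with an isotropic voxel size in µm
(default 1.65 µm, the resolution of synchrotron CT of murine cortical
bone). `x` is the column index increasing rightward, `y` the row index
increasing downward; voxel *i* has its centre at `i × voxel size`. Voxel
size is explicit caller metadata — TIFF tags of synchrotron
reconstructions are too inconsistently populated to trust — so a mismatch
is detected only when two volumes are combined, and raises there.

## Segmentation

**Threshold.** Global iterative (isodata) thresholding: starting from the
global mean, `t ← (mean below t + mean at/above t)/2` until the update is
below 0.5 grey levels. Bone is `value ≥ t` (bright bone on dark
background). On a two-Gaussian image the fixed point sits between the
class means; a constant image has no fixed point and raises.

**Solid cortex.** The cortical compartment is rebuilt by a morphological
closing followed by 3D hole filling. Three numerical choices matter:

* The closing ball is a true Euclidean ball realised by two distance
  transforms (dilate: `dist-to-bone ≤ r`; erode: `dist-to-dilated-
  complement > r`). Iterated 6-connected dilations produce an L1 ball that
  only closes tubes of radius `r/√3`, which would silently break the
  "closing radius ≥ largest canal radius" contract. The default radius is
  8 voxels (13.2 µm at 1.65 µm), above any murine canal radius at this
  scale; it is a config parameter.
* The volume is padded before the closing — edge-replicated along z (the
  stack ends are artificial cuts through continuing bone, so canals
  intersecting them must still seal), zero-padded in-plane (genuine empty
  space). Without this, a dilation clipped at the canvas edge cannot be
  undone by the erosion and leaves spurious caps outside the cortex.
* The erosion runs half a voxel deeper than the dilation. A digitised
  concave surface (the endosteal circle) has staircase notches the
  continuum ball cannot enter; a symmetric threshold fills them with a
  one-voxel ring of spurious "porosity". Genuine bone removed by the
  deeper erosion is restored by union with the original bone mask, so the
  operation stays extensive and idempotent.

Hole filling is border-aware: background components connected to any
canvas face — including the open z faces, where the marrow cavity exits
the cropped stack — are preserved. Only fully enclosed cavities become
cortex. Porosity is then exactly `solid ∧ ¬bone`, which partitions the
solid cortex; the partition identity `|porosity| + |bone ∩ solid| =
|solid|` is asserted in tests on every run.

Morphology is 3D throughout (slice-wise closing fragments oblique canals);
a 2D mode is deliberately not offered.

## Regionalisation

The in-plane principal axis is the eigenvector of the larger eigenvalue of
the second-moment matrix of the z-projected cortical mask — the whole
cross-section turns as one rigid body, with the scan axis assumed along z.
The stack is rotated so this axis lies along +x, then by a further −45°,
and padded to an even square canvas. Rotations are nearest-neighbour so
masks stay binary and volume classes cannot drift; the foreground count is
checked to be conserved within 0.5 %. Angles follow the image frame
(y down): a content rotation by −45° takes a bar along +x to the 135°
diagonal. A degenerate (isotropic) moment tensor returns angle 0 by
tie-break. The 180° ambiguity of a principal axis is resolved on bilobed
projections by requiring the smaller lobe (the fibula) in the upper
half-canvas, with a `flip` override for atypical anatomy.

Quadrants are fixed pixel-coordinate blocks on the even square canvas:
upper-left → posterior, upper-right → lateral, lower-left → medial,
lower-right → anterior (on a 4000² canvas, each quadrant is 2000×2000).
The four masks tile the canvas exactly, so regional Ct.TV values sum to
the whole-volume Ct.TV identically.

Inputs already in the canonical orientation — generated phantoms in
particular — are analysed with `orient=False`, skipping both rotations.
This is deliberate: a nearest-neighbour −45° resampling can split a
~9-voxel lacuna in two, which would corrupt exact component counts for a
reason unrelated to the measurement method. Alignment itself is validated
separately (randomly rotated cross-sections re-align to below 1° residual).

## Pore classification and morphometry

Porosity components are labelled with 26-connectivity (matching common
particle-analyser behaviour; 6-connectivity is available) and classified
by volume: noise `[0, 25)` µm³, lacuna `[25, 2500]` µm³, canal
`(2500, ∞)` µm³. Both boundaries count as lacuna: the canal class is
defined strictly above 2500 µm³ and 25 µm³ is treated symmetrically.
Noise is excluded from all densities and porosity.

Ct.TV is the voxel count of the solid cortex (pores included) in mm³, so
Ct.Po is a true porosity fraction. Regional tables follow the
mask-then-analyse convention by default: porosity is clipped to each
quadrant before labelling, so a component straddling a boundary is cut and
its pieces classified from their clipped volumes (a warning is logged when
this changes the class census); a centroid-assignment mode is provided as
the alternative. Whole-volume counts always come from the unclipped
labelling, so voxel conservation holds in both modes.

## Distance mapping and the association filter

Two domains are mapped with the exact Euclidean distance transform
(distances in µm, voxel-centre to voxel-centre):

* **Ca.Incl**: solid cortex minus the canal mask — nearest vascular
  surface is an endosteal/periosteal boundary *or* a canal wall.
* **Ca.Excl**: the solid cortex itself — canals count as bone and
  distances pass through them.

Only the canal mask is subtracted: lacuna voxels stay in-domain, so a
lacuna never shields itself. Out-of-domain (surface) voxels carry
distance 0; an in-domain voxel face-adjacent to background therefore reads
one voxel width, not half — a configurable half-voxel offset is not
applied by default, and all reported distances share this convention.

Each lacuna's minimum lacunar distance is the minimum map value over its
voxels; Mm.Lc.D averages these with equal weight per lacuna. Bins are
`[0,25) [25,50) [50,75) [75,100) [100,∞)` µm; because the 75–100 µm
interval is often folded away in cumulative reports, the summary emits
both exclusive-bin percentages and cumulative "% within edge" columns.
The 100 µm ceiling is the conventional diffusion-survival limit for an
osteocyte.

The association filter compares the two minima: smaller under Ca.Incl
(beyond 10⁻⁶ µm, a float-representation guard only — both maps are
deterministic functions of their domains, so true ties are exact) →
canal-associated; equal → surface-associated. `Ca.Incl > Ca.Excl` violates
the dominance invariant and raises. Distance records carry
centroid-assigned regions (lacunae are small relative to a quadrant, so
clipping is immaterial at this step).

## The phantom generator

The phantom emulates a TFJ-like, purely cortical cross-section at desk
scale: an annulus of outer radius 195 µm and wall 85 µm on a 256×256×200
canvas at 1.65 µm voxels (the canvas bounds the geometry; an optional
posterior thickening factor emulates the thicker posterior cortex and is
used to give alignment tests an anisotropic target). Canals are straight
z tubes spanning the stack — real canals are irregular, but tube topology
exercises every operation, keeps the analytic volume `π r² L` exact, and
leaves the marrow and canal lumens open at the cut faces as in real
cropped stacks. Lacunae are randomly oriented ellipsoids (axis ratios up
to 1.8) with log-normal volumes (median 330 µm³, σ_log 0.35) truncated to
[40, 2000] µm³ so that voxelisation error cannot cross the 25/2500 µm³
class boundaries; any rasterisation that still lands outside [25, 2500]
µm³ is redrawn. Noise specks are 1–3 voxel clusters (< 25 µm³).

Objects are placed by rejection sampling (default cap 10 000 attempts per
object, error naming the stratum on exhaustion) in a fixed order — canals,
then lacunae region by region, then noise — from a single seeded
generator, so a spec plus seed reproduces volumes and truth tables
bit-exactly. The minimum inter-surface gap is 4 µm, wider than one voxel
diagonal (2.86 µm), so rasterised objects can never touch even
corner-to-corner and component counts are exactly recoverable. Planted
counts per region are `round(density × region cortex volume)` rather than
Poisson draws, keeping the scenario contrast deterministic in expectation.

Scenario presets are calibrated to the qualitative regional statistics of
healthy and VEGF-deficient murine cortex rather than to any single scan:
the WT-like preset plants canals at 500 mm⁻³ posterior vs 170 mm⁻³
elsewhere (the ~3:1 regional contrast of healthy bone, scaled to the
desk-size wall so each quadrant still receives canals) and places 30 % of
posterior lacunae (15 % elsewhere) as a peri-canal stratum within 12 µm of
a canal wall with a ×2 volume multiplier in the posterior only; the
KO-like preset plants 600 mm⁻³ uniformly with multiplier 1 everywhere.
Peri-canal lacunae are canal-associated *by construction*: a candidate is
accepted only if every voxel is at least 4 µm nearer a canal wall than the
endosteal/periosteal surface, so the planted truth itself realises the
configured volume coupling. The measured posterior canal-/surface-
associated mean-volume ratio is nevertheless below the raw multiplier
(≈ 1.5–1.7 rather than 2.0) because baseline-stratum lacunae that happen
to fall in a canal's association basin dilute the canal-associated pool —
the same dilution a real cortex would show.

Ground truth records, per object: centroid, analytic volume, region
(quadrant convention applied to the centroid), and for lacunae the minimum
over its voxel centres of the analytic distance to the nearest canal wall
(`|p − axis| − r`) and to the annulus surfaces (`min(ρ − r_in, r_out −
ρ)`), plus the implied association class. With a thickened posterior the
surface distance falls back to a distance transform of the clean
(pore-free) wall. These truths are independent of the measurement path,
which works from the rendered noisy greyscale (bone N(200, 10), pore
N(50, 10), clipped to 8 bits).

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: partial-volume boundary voxels, beam-hardening
and ring artefacts, curved or branching canals, the canalicular network,
anatomically realistic (non-annular) cross-sections, and spatially
correlated noise. The phantom validates the measurement machinery
(segmentation, labelling, classification, distance mapping, association),
not the biology of any particular scan.

## Problem sizes and expected accuracy

Recovery and contrast checks run on 256×256×200-voxel phantoms (≈ 13 M
voxels, ~420 µm field of view), three samples per scenario group; unit
tests use a 128×128×80 phantom with proportionally raised canal densities.
At these sizes: planted canal/lacuna/noise counts are recovered exactly;
the mean recovered lacuna volume sits within a fraction of a percent of
the planted analytic mean; association accuracy is 100 % for lacunae whose
analytic canal/surface margin exceeds two voxels; and Mm.Lc.D is recovered
within ~0.5 µm of the analytic truth (the residual is the voxel-centre
discretisation of the surface, bounded by about one voxel diagonal).
Distance-transform output is validated exactly — as integer squared voxel
distances — against a KD-tree brute-force nearest-background search on
random domains.

## Known limitations

* Alignment is in-plane only (one angle); a specimen tilted against the
  scan axis needs external reorientation first.
* The −45° rotation sign and the posterior/lateral naming presume the
  standard mounting orientation; the automatic fibula-based flip handles
  180° ambiguity but not arbitrary mountings.
* Straddle-split regional classification can demote a clipped canal
  fragment to the lacuna class near quadrant boundaries; this mirrors the
  mask-then-analyse convention and is logged, but regional component
  counts are convention-dependent.
* Distances are Euclidean through bone, not geodesic; no diffusion or
  canalicular-path modelling is attempted.
* Group summaries are descriptive (mean ± s.d., n−1 denominator);
  significance testing is left to external statistics tooling.
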