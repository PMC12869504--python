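# cortimap

Regional quantification of cortical bone porosity and 3D lacunar distance
mapping for high-resolution (synchrotron-class) CT image stacks of murine
long bones, with a fully ground-truthed synthetic phantom generator.

## The problem

Cortical bone is perforated by two pore populations: **intracortical
canals** (vascular channels, > 2500 µm³) and **osteocyte lacunae**
(25–2500 µm³ cavities housing osteocytes). Their abundance and spatial
arrangement vary systematically around the cortex — in the murine
tibiofibular junction (TFJ) the posterior region carries the highest canal
density and the largest lacunae — and this regional structure degrades in
vascular pathology. `cortimap` automates the measurement workflow:

1. **Segmentation** — global iterative (isodata) thresholding of the 8-bit
   greyscale stack; the solid cortical compartment is rebuilt by
   morphological closing plus border-aware 3D hole filling, and cortical
   porosity is `solid ∧ ¬bone`.
2. **Regionalisation** — the cross-section is aligned by the principal axis
   of its z-projection, rotated −45°, padded to an even square canvas and
   split into pixel-coordinate quadrants: upper-left → posterior,
   upper-right → lateral, lower-left → medial, lower-right → anterior.
3. **Pore classification** — 26-connected component labelling and a volume
   filter: noise `[0, 25)` µm³ (discarded), lacunae `[25, 2500]` µm³,
   canals `(2500, ∞)` µm³. Standard morphometry per scope: Ct.TV, Ct.Po (%),
   N.Ca/Ct.TV and N.Lc/Ct.TV (mm⁻³), Ca.V/Ct.TV and Lc.V/Ct.TV (%), mean
   Ca.V and Lc.V (µm³).
4. **Distance mapping** — exact Euclidean distance maps over the cortex with
   canals included (**Ca.Incl**) and excluded (**Ca.Excl**) as vascular
   surfaces; each lacuna's minimum map value is its *minimum lacunar
   distance*, averaged into **Mm.Lc.D** and binned (25/50/75/100 µm) into
   the lacunar percentage distance distribution (**%Lc.D.D**). The
   **association filter** classes a lacuna as *canal-associated* when canal
   inclusion shortens its minimum distance, else *surface-associated*.
5. **Reporting** — per-sample tables, manifests with checksums, and
   group-level mean ± s.d. summaries.

Because real synchrotron scans are rarely shareable, the `phantom` module
generates annular cortical phantoms with planted canals (z-axis tubes),
randomly oriented ellipsoidal lacunae and sub-25 µm³ noise specks, each
with analytic ground truth (volumes, regions, distances, association
class). Every pipeline stage is validated against these truths; a WT-like
preset encodes posterior-dominant canal density with enlarged peri-canal
lacunae, a KO-like preset the uniform, hyper-vascularised cortex of a
bone-specific VEGF knockout.

## Worked example

```python
import cortimap as cm

result = cm.run_pipeline(
    cm.RunConfig(phantom_preset="wt", seed=1, orient=False)
)
m = result.morphometry.set_index("scope")
print(f"whole Ct.Po      {m.loc['whole', 'ct_po_pct']:.2f} %")
print(f"posterior N.Ca   {m.loc['posterior', 'n_ca_per_mm3']:.0f} mm^-3")
s = result.distance_summary.set_index("scope")
print(f"Mm.Lc.D Ca.Incl  {s.loc['whole', 'mm_lc_d_ca_incl_um']:.1f} um")
print(f"Mm.Lc.D Ca.Excl  {s.loc['whole', 'mm_lc_d_ca_excl_um']:.1f} um")
print(f"posterior canal-associated  {s.loc['posterior', 'pct_canal_associated']:.0f} %")
```

prints, for this seed:

```
whole Ct.Po      1.29 %
posterior N.Ca   447 mm^-3
Mm.Lc.D Ca.Incl  17.0 um
Mm.Lc.D Ca.Excl  22.2 um
posterior canal-associated  51 %
```

Read: ~1.3 % of the cortical compartment is pore space; canals concentrate
in the posterior quadrant; removing canals from the vascular surface set
pushes the mean minimum lacunar distance from 17.0 to 22.2 µm, i.e. many
lacunae are nearer a canal than to the endosteal/periosteal surfaces (the
phantom wall is thinner than a real cortex, so these distances are smaller
than in vivo values). The same workflow runs on a real stack via
`cm.RunConfig(input_path="stack.tif", voxel_size_um=1.65)` or the CLI:

```bash
cortimap phantom --preset wt --seed 1 --out sample1/
cortimap run --phantom-preset wt --seed 1 --out out1/
cortimap summarise out1 out2 out3 --groups wt,wt,wt --out groups.csv
```

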