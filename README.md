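# gwcparc

Individual-subject whole-brain parcellation from resting-state fMRI, by
simultaneous graph learning and partitioning.

Constructing subject-level brain networks requires dividing the brain into
spatially contiguous, functionally homogeneous, reproducible parcels.
`gwcparc` implements a two-stage pipeline for volumetric BOLD data:

1. **SLIC supervoxels on time series** — local k-means in the unified
   distance `||v_i − v_j||²/m² + ||u_i − u_j||²/S²` over z-scored voxel
   time courses v and voxel coordinates u, producing ~1000 small connected
   building blocks.
2. **Graph-without-cut (GWC)** — learns a sparse affinity graph
   S ∈ R^{N×N} over the supervoxels together with feature weights α by
   minimizing

   ```
   Σ_ij ||x_i−x_j||² s_ij + λ Σ_m α_m Σ_ij ||y_i^(m)−y_j^(m)||² s_ij
     + μ Σ_ij ||z_i−z_j||² s_ij + β||S||_F² + βγ||α||²
   s.t.  s_i ≥ 0, s_i'1 = 1;  α ≥ 0, α'1 = 1;  Z'Z = I, Z ∈ R^{N×K}
   ```

   The μ-term constrains the graph Laplacian to K zero eigenvalues, so the
   converged graph has exactly K connected components — graph construction
   and partitioning happen in one optimization instead of cut-after-build.
   Features are the supervoxel mean time course, a 12-bin intensity
   histogram, and a 10-bin rotation-invariant 6-neighbor 3D LBP histogram;
   everything enters as max-normalized squared distance graphs.

The package also provides the three standard evaluation criteria (spatial
discontiguity index, functional homogeneity, adjacency-Dice
reproducibility), two competing baselines (voxel-level normalized cut with
spatially constrained correlation weights or dense Gaussian weights, and
SLIC-as-atlas), the randomized null variants of all three approaches, and
a synthetic phantom generator with planted contiguous parcels so the whole
pipeline is testable without any data download. See `docs/methods.md` for
the full model description and parameter guidance.

## Worked example

`examples/02_parcellate.py` generates a 20×20×12 phantom (4800 voxels, 8
planted parcels, T = 60, snr = 8) and runs the full pipeline:

```
$ python examples/02_parcellate.py
supervoxels: 144, iterations: 9
graph components at convergence: 8 (K = 8)
final feature weights alpha: [0.765 0.235 0.   ]
K_actual = 8, ARI vs planted parcels = 0.807
```

The learned graph decomposed into exactly the requested K = 8 components
(the rank constraint did the clustering), α concentrated on the mean
time-course feature (the only informative one on this phantom), and the
voxel-level atlas agrees with the planted parcels at ARI 0.81.
`examples/04_null_models.py` reruns each approach on randomized data:

```
graph-without-cut: homogeneity 0.918 vs null 0.581
normalized cut (Gaussian weights): homogeneity 0.931 vs null 0.221
SLIC supervoxels (m = 10): homogeneity 0.678 vs null 0.462
```

Each approach clearly beats its null, i.e. none of them is merely encoding
spatial geometry.

## Command line

```
gwc simulate   --shape 20 20 12 --k-true 8 --t 60 --snr 8 --seed 0 --out-dir phantom/
gwc parcellate --bold phantom/bold.nii.gz --mask phantom/mask.nii.gz \
               --k-clusters 8 --n-supervoxels 120 --k-neighbors 9 \
               --out atlas.nii.gz
gwc baseline   --method ncut23 --bold ... --mask ... --k-clusters 8 --out b.nii.gz
gwc evaluate   --atlas atlas.nii.gz --atlas-b phantom/truth.nii.gz \
               --bold phantom/bold.nii.gz --mask phantom/mask.nii.gz
```

Every run writes a JSON report (effective parameters, derived seeds, α and
objective trajectories, component counts, metric values). A YAML config
file can supply any `parcellate` option; explicit flags win.

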