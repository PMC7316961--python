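# footmech

Internal foot mechanics from serial CT acquisitions of a loaded foot.

When a cadaveric or in-vivo foot is scanned under a series of static load
cases, only the first (unloaded) scan is segmented bone by bone; every
later scan is just thresholded, leaving a single *skeleton* mask of all
bones interconnected at the joints.  `footmech` turns such a series into
quantitative biomechanics:

* **Hierarchical rigid registration** places each of the 30 bones (28 foot
  bones + tibia + fibula) in every loaded configuration by minimizing the
  mean squared nearest-point distance

  *C(R, T) = (1/N_p) Σᵢ ‖xᵢ − (R pᵢ + T)‖²*

  with SLSQP, coarse-to-fine over anatomical segments (whole foot → ankle
  → rays → individual bones) to avoid the local minima created by
  interconnected joints, with skeleton point subtraction in the final
  bone-by-bone pass.
* **Generic-to-patient mesh morphing** deforms a generic bone model onto
  each patient bone — similarity alignment, iterative normal projection
  with weight ramp *w(t) = min(a(1+t), w₁)* and windowed-sinc smoothing,
  then five iterations of landmark-driven radial-basis-function morphing
  with the inverse-multiquadric kernel *k(d) = (d² + d·c)^(−β)*,
  *β = min(b·d, k₁)* — and transfers ligament attachment points through
  the resulting displacement field.
* **Biomechanical measures**: bone translation/rotation amplitudes
  relative to tibia or calcaneus, projected joint angles
  (tibia–talus–calcaneus, calcaneus–talus–medial sesamoid) in the
  anatomical planes, and engineering strains of straight-line ligament
  fibres.
* **Paired statistics**: Wilcoxon signed-rank comparison of bare vs shod
  measures at α = 0.05.

A fully synthetic foot phantom (perturbed-superellipsoid bones voxelized
at CT resolution, with known transforms, attachments and deformation maps)
makes every stage testable without any imaging data.  See
`docs/methods.md` for the model details and assumptions.

## Worked example

Run the whole pipeline on a synthetic study (a few minutes per
configuration on one CPU):

```
$ footmech run --seed 42 --out study/
...
INFO footmech: registered N_0.1_bare: cloud residual 0.301 mm
INFO footmech: registered N_0.1_shod: cloud residual 0.281 mm
...
pipeline complete -> study/
```

or drive the stages individually:

```
$ footmech phantom --seed 42 --out phantom_dir/
phantom study written to phantom_dir

$ footmech register --bones phantom_dir/bones \
    --skeleton phantom_dir/skeleton_N_1.0_bare.nii.gz \
    --out transforms_N_1.0_bare.json
mean surface distance 0.175 mm -> transforms_N_1.0_bare.json
```

The reported number is the mean distance between each registered bone
surface and the skeleton surface: 0.175 mm here, i.e. well below the
voxel size (0.66 × 0.66 × 1.0 mm) — the registration is resolving bone
placement beyond grid resolution.  The per-bone transforms, residuals and
convergence flags are in the JSON output.

Morphing a generic bone onto a patient bone from Python:

```python
import footmech.phantom as ph
import footmech.morphing as mo

pair = ph.generate_bone_pairs(n=1, seed=42)[0]   # calcaneus-scale pair
result = mo.morph(pair["source"], pair["target"])
print({k: round(v, 4) for k, v in result.hrmsd_trace.items()})
```

```
{'aligned': 0.7098, 'projected': 0.1731, 'rbf_1': 0.1658,
 'rbf_2': 0.1064, 'rbf_3': 0.0512, 'rbf_4': 0.015, 'rbf_5': 0.0098}
```

The trace is the Hausdorff RMS distance (mm) after each protocol stage:
alignment leaves 0.71 mm of shape mismatch, normal projection reduces it
to 0.17 mm, and the five RBF iterations finish below 0.01 mm — the morphed
generic bone is geometrically indistinguishable from the patient bone, so
its ligament attachment points can be carried over
(`mo.transfer_attachments`).

Statistics on the measures table produced by the pipeline:

```
$ footmech compare --measures study/measures.csv --metric rotation_deg \
    --out wilcoxon.csv
rotation_deg: 20% of entities significant at alpha=0.05 -> wilcoxon.csv
```

The phantom's shod configurations are generated with stiffer relative
bone motion (the per-bone component halved), a sub-millimetre effect.
Run on the *registered* transforms, only a fifth of the bones reach
significance — the ~0.4 mm registration noise masks the rest — while the
same comparison on the ground-truth transforms flags essentially every
bone.  That gap is the method's noise floor made visible, and the reason
small-structure strains deserve caution on real data too.

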