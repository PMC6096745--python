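# lusplan

Pre-operative acquisition planning and global registration of laparoscopic
ultrasound (LUS) vessel data to a CT vascular model of the liver.

## The problem

During laparoscopic liver resection, a tracked LUS probe images vessels in a
very small field of view.  Registering those vessels to the pre-operative CT
would give the surgeon image guidance, but a small vessel snippet can fit
the CT vascular tree in many places: the registration is only trustworthy
where the captured vasculature is *geometrically unique*.  `lusplan` answers
the planning question this raises — **how much vessel data must be acquired
at each liver location for a globally unique rigid alignment?** — and
provides the registration machinery to act on the answer:

* **Feature assessment** — a simulation study comparing rigid registration
  on bifurcation landmarks (point-based, known pairing) against
  iterative-closest-point (ICP) on vessel centrelines, under Gaussian
  displacement models, scored by the RMS target registration error (TRE)
  over all bifurcations and by the *working radius* (the distance around the
  acquisition centre within which all bifurcations stay under a 5 mm
  clinical error).
* **Uniqueness planning** — for probe contact positions sampled evenly over
  the visible liver surface, expanding capture spheres select centreline
  points of the CT tree; a globally optimal ICP (GO-ICP, branch and bound
  over SE(3)) run with a 2.4 mm mean-distance acceptance threshold decides
  whether the captured subset re-registers only onto itself.  The smallest
  such radius is the uniqueness radius R_U; interpolated over the surface it
  forms the acquisition-planning map.
* **Sweep registration** — tracked 2D LUS frames (binary vessel masks +
  poses + calibration) are reduced to 3D centreline points via
  vessel-section centroids, smoothed against the digitised surface path, and
  registered to the CT tree with the same expanding-radius strategy under
  prior search-space constraints (liver lobe translation box, ±60° rotation
  cone).  The success radius R_S — where the landmark TRE reaches its stable
  minimum — is compared against the planned R_U.

All registration is rigid: the intended use is a globally optimal *initial*
alignment that local, possibly deformable, refinement can build on.

A `synthetic_data` module generates liver-scale vascular trees, ellipsoid
surfaces and simulated tracked sweeps (with centroid noise, pose jitter, and
per-branch or insufflation-style deformation), so the entire pipeline runs
and is tested without patient data.

## The core statistic

For a source point set X registered onto a target tree Y by a rigid
transform T = (R, t), the registration objective is the L2 closest-point
error

    E(T) = Σᵢ min_j ‖R xᵢ + t − y_j‖²

GO-ICP bounds E over rotation cubes (angle-axis parameterisation,
uncertainty radius γ_r per point) nested with translation boxes (γ_t),
pruning any region whose lower bound exceeds the incumbent found by local
ICP.  A captured subset is *unique* iff the accepted alignment (mean
closest-point distance ≤ 2.4 mm) displaces the subset by ≤ 5 mm on average
from where it was captured.

## Worked example

```python
import numpy as np
from lusplan.synthetic import TreeGenParams, generate_tree, generate_surface
from lusplan.planning import PlanningConfig, uniqueness_radius

tree = generate_tree(TreeGenParams(seed=1))      # 31 bifurcations, ~420 points
surface = generate_surface(n_vertices=600, seed=1)

cfg = PlanningConfig()                           # radii 5..100 mm, 2.4 mm threshold
centre = surface.visible_vertices[0]             # a probe contact position
print(uniqueness_radius(centre, tree, cfg))
```

prints

```
45.0
```

meaning: a capture sphere of 45 mm around that surface position is the
smallest (on the 5 mm schedule) whose centreline points admit only the
correct global alignment — the surgeon would need to sweep about that much
liver there.  Positions above vessel-dense regions give smaller radii;
vessel-poor edges give larger ones or none at all (reported as −1).

The same pipeline is scriptable from the shell:

```
lusplan simulate --out fixtures/ --seed 1
lusplan assess-features --tree fixtures/tree.vtk --out assess.csv
lusplan plan --tree fixtures/tree.vtk --surface fixtures/liver.vtk --out map.vtk
lusplan register --sweep fixtures/sweep_00 --tree fixtures/tree.vtk \
                 --map map_samples.csv --out report.json
```

`register` writes the Table-style row R_U / R_S / E_S / E_R / D_R plus the
full TRE-vs-radius curve.

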