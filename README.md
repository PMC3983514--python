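# cardiobuckle

Growth-induced helical buckling of a confined elastic rod — a desk-scale
morphomechanical model of **cardiac looping**, the process that winds the
straight embryonic heart tube into a helical loop.

The oldest mechanical hypothesis for looping attributes the heart's form
changes to compressive loads from the heart growing faster than its
pericardial cavity.  `cardiobuckle` implements the physical test of that
hypothesis in silico: a discrete Kirchhoff rod (stretch + bend +
quasistatic twist, hard end clamps) grows quasi-statically inside a rigid
hemispherical cavity (inner diameter 136 mm) standing on a plane dorsal
floor, fed through a cranial port from 136 mm to 350 mm of intra-cavity
length.  Contact with the dome, the floor and the rod itself is resolved
by one-sided quadratic penalties; equilibria are found by L-BFGS-B with
analytic gradients.  Morphometric classifiers label every state:

* **phase** — STRAIGHT → SINUSOIDAL (planar bending) → SIMPLE_HELICAL
  (single-handed coiling after wall contact) → COMPLEX_HELICAL (a
  two-handed helix whose opposite-handed limbs meet at a *perversion*);
* **handedness** — the open-curve writhe `Wr = (1/4π)∮∮ (t×t')·(r−r')/|r−r'|³`
  maps to the loop enantiomorph: D-loop ⇔ left-handed helix ⇔ `Wr < 0`
  in the frame with +x cranial→caudal, +y embryo-left, +z ventral.

Seeded ensembles under midline or laterally displaced caudal-end
conditions reproduce the chirality statistics: symmetric conditions give
a fair-coin D/L split, while a 1–2 mm pre-buckling displacement of the
caudal end (a few percent of the rod diameter) directs essentially every
run toward the matching enantiomorph.

## A worked example

```
$ python examples/01_confined_growth_run.py
initial length-to-diameter ratio: 5.91
helical onset: 175.0 mm
complex onset: 319.0 mm
final loop/cavity ratio: 2.57  phase: COMPLEX_HELICAL  handedness: L_LOOP  writhe: +0.382
perversion at arclength 135 mm: cranial limb left-handed, caudal limb right-handed
```

The rod starts straight at a length-to-diameter ratio of 5.91 (136 mm of
23 mm rod).  Feeding bends it ventrally in the sagittal plane until the
bow presses the dome and snaps into a single-handed helix at 175 mm fed
length (the bench apparatus showed this switch at 183 mm); the sustained
two-handed configuration appears at 319 mm (bench: 327 mm).  At the final
350 mm the loop is 2.57× the cavity length and carries a perversion
joining limbs of opposite handedness.  The handedness of any single run
depends on its seed; `examples/02_chirality_ensemble.py` prints the
ensemble statistics, and examples 03–05 cover the unconfined gravity-flop
control, the free caudal end, and the morphometric classifiers on
idealized centerlines.

There is also a thin CLI:

```
cardiobuckle simulate --seed 7 --out traj.h5 --summary states.csv
cardiobuckle ensemble --set perturbation.caudal_offset=2 --runs 50 --out table.csv
cardiobuckle report traj.h5
cardiobuckle fixtures --kind helix --handedness left --out helix.csv
cardiobuckle classify helix.csv
```

## Layout

| Module | Contents |
| --- | --- |
| `cardiobuckle.config` | apparatus geometry, material, growth protocol, validation, YAML round trip |
| `cardiobuckle.rod` | discrete rod state, energies, analytic gradients, equilibrium solver |
| `cardiobuckle.contact` | dome/floor/self contact, port windows, friction (sensitivity only) |
| `cardiobuckle.growth` | growth loop, perturbations, the four experiment modes, ensembles |
| `cardiobuckle.morphometrics` | writhe, torsion profiles, phase/handedness classifiers, transitions |
| `cardiobuckle.fixtures` | analytic centerlines: straight, arcs, helices, perversions |
| `cardiobuckle.elastica` | independent planar-elastica shooting oracles |
| `cardiobuckle.io` | HDF5 trajectories, CSV summaries, VTK/OBJ/CSV centerline export |
| `cardiobuckle.cli` | `cardiobuckle` command |

`docs/methods.md` documents the model, its parameters and its limitations.
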