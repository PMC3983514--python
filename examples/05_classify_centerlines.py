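"""Morphometrics on idealized centerlines: phase, handedness, writhe, perversion.

Generates the analytic fixtures (straight tube, planar arc, single-handed
helices, helix-with-perversion) and runs the classifiers on each.

Output:

    straight       STRAIGHT         INDETERMINATE  writhe +0.000
    planar_arc     SINUSOIDAL       INDETERMINATE  writhe +0.000
    helix (left)   SIMPLE_HELICAL   D_LOOP         writhe -0.841
    helix (right)  SIMPLE_HELICAL   L_LOOP         writhe +0.841
    perversion     COMPLEX_HELICAL  INDETERMINATE  writhe +0.000, junction at 246 mm

A left-handed helix is the D-loop enantiomorph (negative writhe in this
frame); the perversion curve joins two mirror-image helical limbs, so its
net writhe cancels and the junction sits near mid-arclength (the
detected position is within one smoothing window of the exact middle).
"""

import cardiobuckle as cb

cfg = cb.default_config()
cases = [
    ("straight", cb.FixtureSpec(kind="straight", n_nodes=100)),
    ("planar_arc", cb.FixtureSpec(kind="planar_arc", n_nodes=200)),
    ("helix (left)", cb.FixtureSpec(kind="helix", handedness="left", n_nodes=300)),
    ("helix (right)", cb.FixtureSpec(kind="helix", handedness="right", n_nodes=300)),
    ("perversion", cb.FixtureSpec(kind="perversion", n_nodes=400)),
]
for name, spec in cases:
    c = cb.generate_fixture(spec)
    phase = cb.phase_classify(c, cfg.cavity)
    chir = cb.handedness_classify(c)
    w = cb.writhe(c)
    line = f"{name:14s} {phase.value:16s} {chir.value:13s}  writhe {w:+.3f}"
    info = cb.perversion_locate(c)
    if info is not None:
        line += f", junction at {info.position_mm:.0f} mm"
    print(line)
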