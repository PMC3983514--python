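"""Free caudal end: helical buckling drags the venous pole sideways.

The caudal clamp may slide along the left-right rail.  A left-handed
(D-loop) helix displaces the caudal end leftward (+y) as it emerges, a
right-handed helix rightward — the displacement is a consequence of the
buckling, not a cause.

Typical output:

    seed 0: D_LOOP  caudal end at +34.9 mm (leftward) at 199 mm fed length
    seed 4: L_LOOP  caudal end at -42.3 mm (rightward) at 199 mm fed length
"""

import cardiobuckle as cb

for seed in (0, 4):
    cfg = cb.ensemble_config(0.0)
    cfg.perturbation.seed = seed
    traj = cb.run_free_caudal(cfg)
    c = cb.caudal_coupling(traj, cfg)
    if c is None:
        print(f"seed {seed}: no determinate coupling state")
        continue
    side = "leftward" if c.caudal_y > 0 else "rightward"
    print(f"seed {seed}: {c.chirality.value}  caudal end at "
          f"{c.caudal_y:+.1f} mm ({side}) at {c.fed_length:.0f} mm fed length")
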