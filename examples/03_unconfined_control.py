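"""Growth without the dome: no helical buckling, only a gravity flop.

With the hemispherical dome removed (the dorsal stage remains) and gravity
on, the growing rod bends further and further in the sagittal plane and
never coils; eventually the tall arch becomes unstable under its own
weight and flops to one side.  Which side depends on the seed.

Typical output:

    seed 0: flop to the right at fed length 307 mm; helical states: 0
    seed 1: flop to the left at fed length 307 mm; helical states: 0
"""

import cardiobuckle as cb
from cardiobuckle.morphometrics import PhaseLabel

for seed in (0, 1):
    cfg = cb.ensemble_config(0.0)
    cfg.growth.final_fed_length = 350.0
    cfg.perturbation.seed = seed
    traj = cb.run_unconfined(cfg)
    rec = cb.onset_lengths(traj)
    n_helical = sum(p in (PhaseLabel.SIMPLE_HELICAL, PhaseLabel.COMPLEX_HELICAL)
                    for p in rec.phases)
    print(f"seed {seed}: flop to the {traj.flop_side} at fed length "
          f"{traj.fed_lengths[-1]:.0f} mm; helical states: {n_helical}")
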