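"""One confined quasi-static growth run through the full buckling sequence.

Feeds the rod from 136 mm to 350 mm inside the hemispherical cavity and
reports the phase transitions and summary ratios.  The run takes a few
minutes; pass a smaller final length for a quick look.

Expected output (seed 0; the handedness varies with the seed):

    initial length-to-diameter ratio: 5.91
    helical onset: 175.0 mm   (printed bench value: 183 mm)
    complex onset: 319.0 mm   (printed bench value: 327 mm)
    final loop/cavity ratio: 2.57  phase: COMPLEX_HELICAL

The onsets are the fed lengths at which planar bending gives way to
single-handed coiling, and at which the sustained two-handed (perverted)
configuration appears.
"""

import sys

import cardiobuckle as cb

cfg = cb.default_config()
if len(sys.argv) > 1:
    cfg.growth.final_fed_length = float(sys.argv[1])

ld0, _ = cb.loop_ratios(cfg.growth.initial_fed_length, cfg.cavity, cfg.rod)
print(f"initial length-to-diameter ratio: {ld0:.2f}")

traj = cb.run_growth(cfg)
rec = cb.onset_lengths(traj)
print(f"helical onset: {rec.helical_onset_mm} mm")
print(f"complex onset: {rec.complex_onset_mm} mm")

m = cb.compute_metrics(traj.final_state, cfg)
print(f"final loop/cavity ratio: {m.loop_to_cavity_ratio:.2f}  "
      f"phase: {m.phase.value}  handedness: {m.chirality.value}  "
      f"writhe: {m.writhe:+.3f}")
if m.perversion:
    print(f"perversion at arclength {m.perversion.position_mm:.0f} mm: "
          f"cranial limb {m.perversion.cranial_handedness}-handed, "
          f"caudal limb {m.perversion.caudal_handedness}-handed")
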