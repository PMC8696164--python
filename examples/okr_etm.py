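"""Optokinetic-reflex quantification: eye-tracking movements per minute.

Drifting gratings (default protocol: eight 30 s trials at 5 deg/s,
0.05 cycles/deg, 4 s gray gaps) evoke slow tracking with rapid resets — a
sawtooth azimuth trace.  ETMs are counted by thresholding the azimuth
derivative at twice the grating speed.  A reflex-absent eye (the
congenital-nystagmus phenotype) drifts with the same positional spread
but produces no fast phases, so its ETM rate collapses.
"""

import numpy as np

from ocutrack.oculometrics import PupilTrace, compute_etm, grating_schedule
from ocutrack.synthetic import okr_scene

epochs = grating_schedule()
print(f"grating protocol: {len(epochs)} trials, total {epochs[-1].t_end:.0f} s")
print(f"first epoch: {epochs[0]}")

for label, intact in (("reflex-intact", True), ("reflex-absent", False)):
    scene = okr_scene(duration_s=60, fps=60, n_fast=10, reflex_intact=intact, rng_seed=4)
    trace = PupilTrace(
        time_s=np.arange(scene.n_frames) / scene.fps,
        area=np.full(scene.n_frames, 100.0),
        azimuth=scene.azimuth_deg,
        azimuth_units="deg",
    )
    res = compute_etm(trace, threshold=10.0)  # 2x the 5 deg/s slow-phase speed
    print(f"{label:>14}: {res.rate_per_min:5.1f} ETM/min  ({len(res.events)} events)")

print(
    "\nThe intact scenario scripts 10 fast phases per minute and the counter"
    "\nrecovers exactly that; the drifting (mutant-like) eye yields ~0,"
    "\nreproducing the discrimination between the two phenotypes."
)
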