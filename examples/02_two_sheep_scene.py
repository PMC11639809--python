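"""Two sheep in one scene, each breathing at its own rate.

Night-time pens often hold several animals; each detected instance gets
its own mask and is processed independently.  Here two synthetic thoraxes
breathe at 24 and 36 breaths/min in one 10 fps NIR scene and the pipeline
recovers each rate from its own mask.
"""

import numpy as np

from sheeprr import (
    InstanceMask,
    PipelineConfig,
    SyntheticSpec,
    generate_two_instance_scene,
    run_pipeline,
)

common = dict(fps=10.0, duration_s=20.0, modality="nir",
              image_size=(100, 220), axes=(30.0, 45.0))
spec_a = SyntheticSpec(rr_bpm=24.0, seed=1, center=(50.0, 55.0), **common)
spec_b = SyntheticSpec(rr_bpm=36.0, seed=2, center=(50.0, 165.0), **common)

frames, masks = generate_two_instance_scene(spec_a, spec_b)
instances = [InstanceMask(mask=m.mask, certainty=0.95, instance_id=i)
             for i, m in enumerate(masks)]

result = run_pipeline(frames, instances, PipelineConfig())
for (inst, series), spec in zip(result.series, (spec_a, spec_b)):
    median = float(np.median(series.rr_smoothed_bpm))
    print(f"instance {inst.instance_id}: true {spec.rr_bpm:.0f} bpm, "
          f"estimated {median:.2f} bpm")
# Each instance's estimate tracks its own truth: the masks isolate the
# motion sources even though both animals share the frame.
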