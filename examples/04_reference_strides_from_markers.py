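"""Reference stride lengths from a heel-marker trajectory.

Generates a synthetic heel path with flat stance phases (configured stride
length 1.30 m), runs the finite-difference + moving-average kinematics, and
recovers stride lengths from the displacement between consecutive stance
centroids — overground and on a treadmill with belt compensation.
"""

import numpy as np

from gaitlen import GaitScenario, generate_markers, reference_strides
from gaitlen.marker_kinematics import StanceConfig

n, L = 30, 1.30

overground = generate_markers(
    GaitScenario(seed=7, n_strides=n, route="overground"), stride_lengths=[L] * n
)["M7"]
refs = reference_strides(overground)
lengths = np.array([d for _, d in refs])
print(f"overground: {len(refs)} strides, mean {lengths.mean():.3f} m "
      f"(configured {L} m), max |error| {np.abs(lengths - L).max() * 100:.1f} cm")

scenario = GaitScenario(seed=7, n_strides=n, route="treadmill")
treadmill = generate_markers(scenario, stride_lengths=[L] * n)["M7"]
belt = L * scenario.frequency  # belt speed = stride length x stride rate
refs_t = reference_strides(treadmill, StanceConfig(belt_speed=belt))
lengths_t = np.array([d for _, d in refs_t])
print(f"treadmill:  {len(refs_t)} strides, mean {lengths_t.mean():.3f} m "
      f"(belt {belt:.2f} m/s; stance points barely move, the belt carries the distance)")
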