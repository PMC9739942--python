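"""Calibrate all six step-length models on the same tuning strides.

Generates strides with known feature-linear truth, fits each model's
constants by least squares, and reports the fitted constants and residual
error.  The adaptive (frequency + magnitude-range) model should recover its
own truth constants almost exactly; the other models compromise.
"""

import numpy as np

from gaitlen import GaitScenario, SubjectProfile, generate_trace
from gaitlen.calibration import fit
from gaitlen.models import MODEL_IDS, estimate_many

subject = SubjectProfile("S01", height=1.75)

# tuning strides across the three speeds, joined (the free-walking protocol)
strides = []
for i, label in enumerate(("slow", "normal", "fast")):
    _, part = generate_trace(
        GaitScenario(seed=20 + i, n_strides=100, speed_label=label,
                     true_k1=0.35, true_k2=0.20)
    )
    strides += part

refs = np.array([s.d_ref for s in strides])
print(f"{len(strides)} tuning strides, true constants K1=0.35 K2=0.20\n")
for model_id in MODEL_IDS:
    params = fit(model_id, strides, subject)
    est = np.array(estimate_many(strides, params, subject))
    rmse = float(np.sqrt(np.mean((est - refs) ** 2)))
    consts = ", ".join(f"{k}={v:.3f}" for k, v in params.constants.items())
    print(f"{model_id:>9}: {consts}   RMSE {100 * rmse:.2f} cm")
# The 'proposed' row should recover (0.35, 0.20) with RMSE near the 2 cm
# injected length noise; single-constant models have higher residuals.
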