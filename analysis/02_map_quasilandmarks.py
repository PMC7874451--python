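"""Demonstrate template-to-surface quasi-landmark mapping accuracy.

For a handful of simulated subjects, build the subject's true surface mesh
from its known configuration, digitize the five anchors at their true
positions, run the anchor + TPS + projection mapper, and measure the RMS
distance between mapped and true landmarks. This quantifies how well the
transparent 5-anchor mapper recovers dense correspondence as the smooth
per-subject deformation grows.

Writes results/mapping_accuracy.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    from morpholong import SimulationParams, make_template, map_template, mesh_from_landmarks, simulate_cohort
    from morpholong.io import AnchorSet

    template = make_template(k_half=120, seed=seed)
    rows = []
    for subject_sd in (0.0, 0.5, 1.0, 1.5, 2.0):
        params = SimulationParams(
            n_subjects=5, seed=seed, noise_sd=0.0, subject_sd=subject_sd,
            max_rotation_deg=0.0, max_translation_mm=0.0, scale_range=(1.0, 1.0),
        )
        _, configs, _ = simulate_cohort(template, params)
        errs = []
        for c in configs[::3]:  # one stage per subject suffices
            mesh = mesh_from_landmarks(template, c.coords)
            anchors = AnchorSet(c.coords[template.anchor_indices])
            mapped = map_template(template, mesh, anchors)
            errs.append(np.sqrt(((mapped.coords - c.coords) ** 2).sum(1).mean()))
        rows.append({"subject_sd_mm": subject_sd,
                     "rms_error_mm": float(np.mean(errs)),
                     "worst_rms_mm": float(np.max(errs))})
    out = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    out.to_csv(ROOT / "results" / "mapping_accuracy.csv", index=False,
               float_format="%.4f")
    print(out.to_string(index=False))
    print("mapping is exact without deformation and degrades gracefully; "
          "pre-mapped configurations can bypass the mapper entirely")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
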