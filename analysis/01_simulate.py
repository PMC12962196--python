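#!/usr/bin/env python
"""Step 1 — simulate the synthetic cohort.

Generates the default study design: 4 subjects, 2 lesioned cervical
segments each, imaged pre- and post-lesion with a unilateral (left)
dorsal-nerve-root lesion.  Each of the 16 bundles holds a DWI stack
(1 b0 + 30 directions at b=1000 s/mm^2), an MT-weighted stack (2 powers x
10 log-spaced offsets) and a Z-spectrum stack (51 offsets + 2 reference
scans), all on a shared 48x48 axial label map with 14 side-resolved ROIs,
under Rician noise.  Writes NIfTI stacks, sidecar tables and the cohort
manifest under results/cohort/.
"""

import sys
from pathlib import Path

from cordmap.config import validate_config
from cordmap.cohort_io import write_cohort
from cordmap.phantom import simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cfg = validate_config(None)
    dwi_p, qmt_p, z_p = cfg.protocols_tuple()
    design = cfg.design(seed=SEED)
    bundles = simulate_cohort(
        design, dwi_p, qmt_p, z_p, noise=cfg.noise_levels(),
        grid_size=tuple(cfg.cohort.grid_size),
        between_subject_cv=cfg.cohort.between_subject_cv, effects=cfg.effects())
    manifest = write_cohort(bundles, OUT, dwi_p, qmt_p, z_p, SEED)
    print(f"wrote {len(bundles)} bundles (seed={SEED})")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
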