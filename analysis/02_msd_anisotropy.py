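#!/usr/bin/env python
"""Recover the anisotropic subdiffusion exponents of the integration site.

Simulates attB-like FBM ensembles at the study's generating exponents
(2D: 0.36; longitudinal 0.426 vs transversal 0.247), fits the time-averaged
MSD power laws and reports the recovered exponents, their ~1.7-fold
anisotropy and the implied walk dimension d_w = 2/alpha.
"""

import json
from pathlib import Path

from locusdyn.dynamics import walk_fractal_dimension
from locusdyn.experiments import recover_msd_exponents

OUT = Path("results")
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    iso = recover_msd_exponents(
        alpha_x=0.36, alpha_y=0.36, D_x=600.0, D_y=600.0,
        n_traj=59, n_frames=90, n_seeds=20, seed=SEED,
    )
    aniso = recover_msd_exponents(
        alpha_x=0.247, alpha_y=0.426, n_traj=60, n_frames=90, n_seeds=20, seed=SEED + 1,
    )
    a2d = iso["r2d"]["alpha"]
    ay, ax = aniso["y"]["alpha"], aniso["x"]["alpha"]
    wd = walk_fractal_dimension(a2d)
    summary = {
        "alpha_2d": round(a2d, 3),
        "alpha_y": round(ay, 3),
        "alpha_x": round(ax, 3),
        "anisotropy_ratio": round(ay / ax, 2),
        "walk_dimension": round(wd.d_w, 2),
        "compact_exploration": wd.compact,
    }
    (OUT / "msd_anisotropy.json").write_text(json.dumps(summary, indent=2))
    print(f"2D exponent recovered: {a2d:.3f} (generated 0.36)")
    print(f"longitudinal {ay:.3f} vs transversal {ax:.3f} "
          f"-> {ay / ax:.2f}-fold anisotropy (generated 1.72-fold)")
    print(f"walk dimension d_w = 2/alpha = {wd.d_w:.2f} "
          f"({'compact, space-filling search' if wd.compact else 'non-compact'})")
    print(f"wrote {OUT / 'msd_anisotropy.json'}")


if __name__ == "__main__":
    main()
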