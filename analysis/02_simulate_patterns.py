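#!/usr/bin/env python
"""Simulate one synthetic subject with four ROIs and export the pattern sets.

ROI effect profiles mirror the hypotheses under study:
  * ca1_like    — holistic reinstatement + repulsion of shared codes
  * ca23dg_like — holistic reinstatement + pattern separation (rho = 0)
  * mpfc_like   — spatial schema: distance and layout-slot codes
  * control     — no planted effects
"""

from pathlib import Path

from overlapmaps.design import build_environment, generate_retrieval_schedule
from overlapmaps.io import save_patterns_text
from overlapmaps.simulate import EffectSpec, simulate_roi_patterns

OUT = Path(__file__).resolve().parents[1] / "results" / "patterns"
SEED = 20

ROI_EFFECTS = {
    "ca1_like": EffectSpec(eta_holistic=0.5, rho_shared=-0.3, gamma_city=0.5),
    "ca23dg_like": EffectSpec(eta_holistic=0.5, rho_shared=0.0, gamma_city=0.5),
    "mpfc_like": EffectSpec(beta_schema=0.5, beta_slot=0.5),
    "control": EffectSpec(),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    env = build_environment()
    schedule = generate_retrieval_schedule(env, rng_seed=SEED)
    rois = simulate_roi_patterns(schedule, ROI_EFFECTS, rng_seed=SEED, env=env)
    for roi, ps in rois.items():
        save_patterns_text(ps, OUT / roi)
        print(f"{roi}: {ps.n_trials} trials x {ps.n_voxels} voxels "
              f"(median tSNR {float(sorted(ps.voxel_tsnr)[ps.n_voxels // 2]):.1f})")


if __name__ == "__main__":
    main()
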