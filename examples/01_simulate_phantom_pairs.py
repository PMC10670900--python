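"""Simulate paired planning-CT / CBCT pelvic slices.

Builds one phantom patient, degrades it with the clinical-like artifact
preset, and prints the resulting image-quality gap — the gap the network
is later trained to close.
"""

from cbctsynth import (
    ArtifactSpec,
    PhantomSpec,
    degrade_to_cbct,
    generate_phantom_ct,
    mae_metric,
    psnr_metric,
    ssim_metric,
)

spec = PhantomSpec(image_size=64)
pct = generate_phantom_ct(spec, seed=0)
cbct = degrade_to_cbct(pct, ArtifactSpec.clinical(seed=0))

print(f"planning CT : {pct.shape}, HU range [{pct.pixels.min():.0f}, {pct.pixels.max():.0f}]")
print(f"CBCT        : cupping + streaks + noise + shift applied")
print(f"MAE(CBCT, pCT)  = {mae_metric(pct, cbct):6.2f} HU   (uncorrected error)")
print(f"SSIM(CBCT, pCT) = {ssim_metric(pct, cbct):6.3f}      (structural similarity)")
print(f"PSNR(CBCT, pCT) = {psnr_metric(pct, cbct):6.2f} dB")
print("These numbers quantify the CBCT quality gap the enhancement model must close.")
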