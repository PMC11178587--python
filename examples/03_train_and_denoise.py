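"""Train a small denoising diffusion model and apply a single-pass step.

Trains the epsilon-prediction U-Net on high-quality (8-shot averaged)
phantom intensities for ~1k steps -- a scaled-down smoke run, not
the desk or full preset -- then treats a held-out single-shot frame as the
t=1 diffusion state and applies one reverse posterior-mean step.
"""

import numpy as np

from mupol import (PhantomSpec, TrainConfig, denoise_frame,
                   forward_intensities, make_phantom, train_pddn)

train_imgs = []
for s in range(2):
    acq = make_phantom(PhantomSpec(H=64, W=64, seed=10 + s,
                                   n_shots=8, averages=(8,)))
    train_imgs.append(acq.averaged[8].reshape(64, 64, 16))

cfg = TrainConfig(patch=32, width=8, T=100, steps=1200, batch=4, seed=0)
model = train_pddn(train_imgs, cfg)
first, last = model.manifest["loss_curve"][0], model.manifest["loss_curve"][-1]
print(f"running L1 loss: {first[2]:.3f} -> {last[2]:.3f}")

held = make_phantom(PhantomSpec(H=64, W=64, seed=99))
clean = forward_intensities(held.ground_truth_M, held.calib)
lq = held.averaged[1]
den = denoise_frame(lq, model, t_star=1)
print(f"single-shot intensity RMSE: {np.sqrt(np.mean((lq - clean)**2)):.5f}")
print(f"after single-pass denoise : {np.sqrt(np.mean((den - clean)**2)):.5f}")
# Longer training (the 'desk' preset, minutes of CPU) strengthens the
# reduction and propagates it into the derived azimuth maps.
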