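# nstm — neural space–time model for dynamic multi-shot imaging

Multi-shot computational imaging systems — quantitative phase from coded
illumination, super-resolution structured illumination, compressive lensless
video — reconstruct one image from several sequentially captured raw
measurements.  When the sample moves during the capture sequence, the
measurements describe slightly different scenes and the reconstruction
blurs, ghosts, or invents structure.  `nstm` removes this failure mode by
reconstructing the scene *and* its motion jointly from the same raw data
used by the conventional algorithm, with no training data and no priors.

The model stores the dynamic scene in two small coordinate networks fed by
multiresolution hash-encoded features:

* a **motion network** `δx = f(hash(x, t) | θ_motion)` mapping a
  spatiotemporal coordinate to a per-pixel displacement, and
* a **scene network** `o(x, t) = f(hash(x + δx) | θ_scene)` mapping the
  motion-adjusted spatial coordinate to the scene value — the scene network
  never sees time, so every frame is a deformation of one static
  reconstruction.

Both networks are trained through the imaging system's physics by
minimising

```
argmin_{θ_motion, θ_scene}  Σ_i ( forward_i( o(·, t_i) ) − I_i )²
```

over the raw measurements `I_i`, using Adam with exponentially decaying
learning rates and a coarse-to-fine schedule on a granularity value
`α ∈ [0, 1]` that gates fine embedding levels out of both networks
(`w_i = ½ − ½ cos(π·trunc(αN − i))`) until the coarse structure and motion
have converged.

Three forward models ship with the package, all differentiable and linear
in the scene:

| modality | raw data | forward model |
| --- | --- | --- |
| DPC (differential phase contrast) | 4 images, half-circle illumination | weak-object transfer functions in 2D Fourier space |
| 3D SIM (structured illumination) | n_z × 3 orientations × 5 phases | real-space three-band illumination × per-band OTF, plane-grouped rendering |
| rolling-shutter DiffuserCam | 1 compressive image | caustic-PSF convolution × binary shutter map, row-chunked rendering |

Everything runs on plain NumPy with hand-derived reverse-mode gradients —
no GPU or autodiff framework required — at desk scale (rasters of tens of
pixels, seconds-to-minutes per reconstruction on one CPU).

## Worked example

Simulate a four-shot DPC acquisition of a bead phantom translating 3 px
during the capture, then reconstruct jointly and with the motion-blind
static baseline:

```python
import numpy as np
from nstm import (DPCSystem, NSTMModel, OptimizerConfig, MLPConfig,
                  make_phantom, MotionSpec, render_dataset, score_recovery)

system = DPCSystem.from_optics((64, 64))            # 4 half-circle patterns
phantom = make_phantom("beads", (64, 64), channels=2,
                       channel_scales=(0.1, 1.0), seed=5)   # absorption, phase
spec = MotionSpec(kind="rigid", magnitude=3.0, seed=5)
measurements, truth = render_dataset(phantom, spec, system, seed=5)

model = NSTMModel(measurements, system,
                  scene_mlp=MLPConfig(width=64, out_channels=2),
                  optimizer=OptimizerConfig(epochs=600, lr_motion=3e-3,
                                            lr_scene=3e-3, tikhonov_weight=1e-4))
results = model.fit()
static  = model.fit_static()

print(score_recovery(results, truth)["scene_psnr_db"])          # 24.5
print(score_recovery(static,  truth)["scene_psnr_db"])          # 14.6
print(score_recovery(results, truth)["max_frame_displacement_error_px"])  # 0.37
```

The joint reconstruction recovers the phase scene ~10 dB above the static
baseline, and the recovered per-frame mean displacement is within half a
pixel of the imposed motion.  The fitted `results` object answers post-hoc
queries without refitting:

```python
frames = results.interpolate(np.linspace(0, 1, 11))   # temporal interpolation
traj   = results.motion_trajectory([32, 40], [0, 0.5, 1.0])  # px positions
kernel = results.motion_kernel(1.0, t_prev=0.0)       # dense (2, 64, 64) field
print(results.summary())
results.save("ckpt.h5")
```

A command-line surface wraps the same pipeline:

```bash
nstm simulate --modality dpc --motion rigid --magnitude 3 --size 64 --out toy.h5
nstm reconstruct --config run.yaml --raw toy.h5 --out ckpt.h5
nstm render --ckpt ckpt.h5 --config run.yaml --raw toy.h5 --times 0:1:0.1 --out frames.tif
nstm score --ckpt ckpt.h5 --config run.yaml --raw toy.h5
```

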