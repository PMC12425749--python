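# stgf — adaptive spatio-temporal graph filtering for dynamic PET

Dynamic PET acquires a sequence of short time frames to follow tracer
kinetics, so each frame's sinogram is severely count-starved and the
reconstructed images are noisy. `stgf` denoises the *dynamic sinogram*
before reconstruction by exploiting two kinds of structure that noise
obscures: bins whose time-activity behavior is similar (spatial structure
within frames) and frames whose spatial content is similar (temporal
structure across frames). It is a single-scan method: the filters are
estimated from the scan being processed, with no external training data.

The package is aimed at researchers in emission-tomography image quality:
it contains the full simulation protocol needed to exercise the method end
to end (phantom, compartment-model kinetics, Poisson count noise), a
sparse Siddon projector with MLEM reconstruction, the graph-filtering
engine, and the evaluation metrics — so every number it reports can be
regenerated from a seed.

## Method

Let `Y ∈ R^(m_s x F)` be the dynamic sinogram (bins × frames). Spatial and
temporal similarity graphs are built from the current estimate and turned
into symmetrically normalized low-pass filters

```
F_S = D_s^(-1/2) W_s D_s^(-1/2),   F_T = D_t^(-1/2) W_t D_t^(-1/2)
```

where `W_s` is a k-nearest-neighbor Gaussian-kernel graph over sinogram
bins (features: each bin's values across duration-weighted composite
frames) and `W_t` is a windowed Gaussian-kernel graph over frames. One
filtering pass is the two-sided update

```
Y^(i+1) = F_S^(i) · Y^(i) · (F_T^(i))^T
```

and the filters are *re-estimated from the cleaner signal* at every pass.
Each pass is followed by an MLEM reconstruction

```
x^(t+1) = x^t ⊙ ( Hᵀ( p ⊘ (H x^t + r) ) ) ⊘ ( Hᵀ1 )
```

and the loop stops when the dual-domain measure

```
w1·‖ΔY‖_F/‖Y‖_F + w2·‖ΔI‖_F/‖I‖_F < ε      (ε = 0.01, w1 = w2 = 0.5)
```

falls below threshold, when it stops decreasing (stagnation), or after
`T_max` passes. Ablation modes `sgf` / `tgf` fix the temporal / spatial
filter at the identity. See `docs/methods.md` for the simulation model,
parameter table and numerical details.

## Worked example

```python
import stgf

config = stgf.RunConfig.demo()            # 63x63 phantom, 5 realizations
dataset = stgf.simulate_dataset(config, seed=1)
result = stgf.STGFModel.from_dataset(dataset, realization=0).fit()
print(result.summary())
```

```
         Spatio-Temporal Graph Filtering Results
==========================================================
Mode:                   STGF
Sinogram bins:          3969
Frames:                 24
Iterations:             4
Converged:              False
Stop reason:            stagnation
Epsilon:                0.01
Weights (w1, w2):       (0.5, 0.5)
T_max:                  12
Final measure:          0.102241
----------------------------------------------------------
 iteration  measure   rel_dY   rel_dI
         1 0.307347 0.114495 0.500198
         2 0.144389 0.054426 0.234352
         3 0.102670 0.039652 0.165688
         4 0.102241 0.040210 0.164271
==========================================================
```

The measure is the dual-domain relative change: here it contracts for four
passes and then stagnates, so the fourth iterate is returned. The same
pipeline from the shell:

```bash
stgf demo --seed 1 --side 63 --realizations 2
```

```
simulating 63x63 phantom, 2 realizations, seed 1 ...
realization 0: iterations=4 converged=False image MSE noisy=151.94% -> ST-GF=40.72%
realization 1: iterations=3 converged=False image MSE noisy=148.27% -> ST-GF=36.33%
mean image MSE: noisy MLEM 150.11% | ST-GF 38.52%
```

Image MSE is the truth-normalized error `Σ(x−x_true)²/Σx_true²` averaged
over the 24 frames: filtering cuts it by roughly a factor of four relative
to reconstructing the raw noisy sinograms. The full pipeline is also
available as composable subcommands
(`stgf simulate|denoise|reconstruct|evaluate`), all reading and writing a
documented HDF5/NPZ container.

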