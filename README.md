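# palmfuse

Illumination-invariant identification from multispectral palm images.

Biometric palm recognition degrades badly when the lighting is uneven: a
multiplicative shading field distorts every spectral band and breaks naive
image matching. `palmfuse` implements a recognition chain that is robust to
this, aimed at researchers working on multispectral biometrics and, more
generally, on fusing co-registered single-channel images (Blue/Green/Red/NIR)
into one discriminative representation:

1. **FABEMD decomposition + illumination compensation.** Each band image `I`
   is decomposed by fast and adaptive bidimensional empirical mode
   decomposition into `K` bidimensional intrinsic mode functions (BIMFs) and a
   residue, `I = Σᵢ Sᵢ + R`, using MAX/MIN order-statistics filters whose
   window size adapts to the spacing of the local extrema. The residue tracks
   the smooth illumination trend, so dividing every BIMF by the averaged
   residue, `S̃ᵢ = Sᵢ / R_s` (guarded by a small `eps` where `R_s ≈ 0`),
   cancels multiplicative shading.

2. **Weighted-Fisher image fusion.** The compensated BIMFs of all four bands
   are stacked column-wise into `V ∈ R^{pixels × 4K}` and fused as
   `F = V φ`. The coefficients maximize a contribution-weighted Fisher ratio
   `φᵀ D φ / φᵀ D_w φ`, where each training sample is weighted by a
   contribution factor `μ ∈ [0, 1]` — the Gaussian-weighted fraction of its
   `k` nearest neighbors that belong to *other* classes — so border samples
   shape the discriminant and interior ones do not. `φ` is the leading
   generalized eigenvector of `(D, D_w)`. Setting `μ ≡ 1` gives the classic
   Fisher criterion; `φ ≡ 1` gives the plain sum rule (both available as
   baselines).

3. **Tensor extreme learning machine (TELM).** Fused training images form an
   order-3 tensor `Γ` (samples × rows × cols). Its truncated HOSVD factor
   matrices `U₂ ∈ R^{I₁×Ñ₁}`, `U₃ ∈ R^{I₂×Ñ₂}` replace the random input
   weights of a single-hidden-layer network: `H = sigmoid(Z⁽¹⁾)` with
   `Z = Γ ×₂ U₂ᵀ ×₃ U₃ᵀ`, and the output weights solve `β = H† T` against
   one-hot targets. Classic random-weight ELM and 1-NN are included as
   baselines, with recognition accuracy (RA) and CMC curves as metrics.

Because the reference multispectral palmprint database is licensed, the
package ships a synthetic-data generator that emulates its structure:
class-specific curvilinear line patterns shared across bands, extra vein
strokes in Red/NIR, within-class jitter, and smooth multiplicative
uneven-illumination fields applied to test images.

## Worked example

```python
from palmfuse import PipelineConfig, SyntheticDatasetSpec, generate_dataset, run_pipeline

spec = SyntheticDatasetSpec(seed=7, illumination="gaussian_bump", illumination_strength=0.4)
train, test = generate_dataset(spec)

result = run_pipeline(PipelineConfig(seed=7), train, test)
print(f"recognition accuracy (rank-1): {result.ra:.4f}")
print("CMC ranks 1-5:", [round(float(x), 4) for x in result.cmc[:5]])

baseline = run_pipeline(PipelineConfig(seed=7, fusion_rule="sum", classifier="elm"), train, test)
print(f"sum-rule + random-weight ELM baseline: {baseline.ra:.4f}")
```

prints

```
recognition accuracy (rank-1): 0.9833
CMC ranks 1-5: [0.9833, 0.9833, 1.0, 1.0, 1.0]
sum-rule + random-weight ELM baseline: 0.5667
```

The fixture is 10 identities × 6 training + 6 test samples at 64×64 in four
bands; every test image is corrupted by a multiplicative Gaussian-bump
shading field of strength 0.4 that the training images never saw. The full
chain (weighted-Fisher fusion + TELM) identifies 59 of 60 shaded test
samples and reaches rank-3 perfect retrieval, while equal-weight fusion fed
to a random-projection ELM gets barely over half of them — the gap the
discriminative fusion and the structured input weights are there to close.

A command-line interface mirrors the library (`palmfuse simulate`,
`decompose`, `fuse`, `train`, `classify`, `evaluate`); see `palmfuse --help`.

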