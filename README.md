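# duformer

EEG classification with separable self-attention and Gaussian
data-uncertainty learning — plus everything around it: a seven-band
preprocessing pipeline, a synthetic EEG generator, a cross-validation
harness with baseline models and an ablation runner, and Monte-Carlo
prediction-uncertainty analysis.

The package is aimed at researchers who want to classify pre- vs
post-intervention EEG sessions from short epochs (here: 16 channels x 2 s
at 1 kHz) and to know how much to trust each prediction.

## The model

**DU-former** stacks three components:

1. **Dual-branch convolution.** Both branches apply a 1x25 temporal kernel
   per electrode and a 16x1 spatial kernel across electrodes; the large
   branch (strided, batch-norm, ReLU) and the small branch (fine stride,
   ReLU, max-pool to the same token count, layer-norm) are fused by
   elementwise sum into a token sequence.
2. **Two encoder blocks with separable multi-head self-attention.** Per
   head, token features are projected to context logits *I*, keys *K* and
   values *V*; softmax over tokens turns *I* into context scores, the
   score-weighted sum of *K* forms a single context vector *c*, and the
   output rows are `relu(V) ⊙ c` — attention in O(tokens), with no
   token x token matrix. A standard two-layer FFN and pre-norm residuals
   complete each block.
3. **Gaussian reparameterization.** Two branches predict an embedding
   distribution: `mu = LN(avgpool(conv(tokens)))` and
   `sigma = softplus(LN(avgpool(tokens))) + 1e-4`. Training samples
   `S = mu + eps * sigma`, `eps ~ N(0, I)`, so noisy epochs map to
   high-variance embeddings; inference uses `S = mu`. The loss is
   cross-entropy plus a small `KL(N(mu, sigma^2) || N(0, I))` term.

Repeating the stochastic forward pass K times at inference yields a
per-epoch **uncertainty level**: the normalized predictive entropy
`H(p_bar)/ln 2` of the Monte-Carlo mean probabilities, in [0, 1].

The networks (including CNN / depthwise-separable / quadratic-attention
baselines) run on a small numpy reverse-mode autodiff engine bundled with
the package; every primitive is verified against finite differences and the
attention against a brute-force oracle. See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
import duformer as df

# 1. simulate a small cohort: 6 subjects, 11 s recordings,
#    post-training Gamma power doubled
cfg = df.SynthConfig(n_subjects=6, duration_s=11.0,
                     effect_band="Gamma", effect_ratio=2.0, seed=7)
recordings = df.generate_dataset(cfg)

# 2. preprocess into Gamma-band epochs (2 s window, 1 s step)
pipeline = df.PipelineConfig(bands=(df.get_band("Gamma"),))
gamma = df.preprocess_dataset(recordings, pipeline)["Gamma"]
print(f"epochs: {gamma.segments.shape}, classes: {np.bincount(gamma.labels)}")

# 3. subject-wise 6-fold cross-validation of a reduced DU-former
hyper = df.TrainConfig.reduced(seed=0, epochs=25, batch_size=32)
report = df.cross_validate(
    gamma, df.ModelConfig.reduced(seed=0), hyper,
    k=6, seed=0, strategy="subject",
)
print({k: round(v, 3) for k, v in report.means.items()})

# 4. train on five subjects, Monte-Carlo uncertainty on the held-out one
holdout = gamma.subject_ids == "S06"
model, _ = df.train(df.ModelConfig.reduced(seed=0), gamma.subset(~holdout), hyper)
mc = df.mc_predict(model, gamma.subset(holdout).segments, k=30, seed=0)
print(f"acceptance rate at 0.3: {df.acceptance_rate(mc, 0.3):.3f}")
```

Output:

```
epochs: (120, 16, 2000), classes: [60 60]
{'accuracy': 0.825, 'precision': 0.78, 'recall': 0.933, 'f1': 0.845, 'auc': 0.942}
acceptance rate at 0.3: 0.700
```

Reading it: each recording yields 10 overlapping 2 s epochs (120 total,
balanced). A doubled Gamma-band power in the "post" class is decoded on
held-out subjects at 0.825 accuracy / 0.942 AUC, and 70% of the held-out
subject's epochs are classified with uncertainty at or below 0.3 — the
fraction one would report as "acceptably confident" predictions.

A command-line interface mirrors the library
(`duformer simulate | preprocess | train | evaluate | compare | ablate |
uncertainty | stats`); run `duformer --help`.

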