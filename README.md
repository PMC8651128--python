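# stdgnn

Forecasting the post-treatment DCE-MRI of hepatocellular carcinoma (HCC)
after transarterial chemoembolization (TACE), before treatment begins.

Given a pre-treatment dynamic contrast-enhanced MRI sequence (a series of
3-D volumes acquired at known times after contrast injection) and the
tumor annotation, the package predicts the follow-up sequence, the
follow-up tumor mask, and the tumor viability class — viable (V),
equivocal (E) or non-viable (NV) — and extracts standard liver perfusion
measures from any sequence.  It is aimed at researchers studying
treatment-response modeling on dynamic liver MRI who need a complete,
inspectable, CPU-scale implementation with exact synthetic ground truth.

## The model

The spatio-temporal discriminant graph neural network (STDGNN) embeds a
sequence's patch features as nodes of a pair of discriminant graphs —
**W_w** connecting nearest same-class samples (pulled together) and
**W_b** connecting nearest other-class samples (pushed apart) — and runs
graph convolutions of the form

    X_k = Ŵ_b X_{k-1} B_k − Ŵ_w X_{k-1} B_k

through a K-layer temporal branch (all T×P patches of the sequence, with
residual shortcuts) and an M-layer structural branch (per-volume
patches, widths halving per layer), alongside a global domain-translation
branch trained adversarially with an optimal-transport weight: the fake
term of the adversarial loss is scaled by φ·c + ξ, where c is the mean
pairwise sliced-Wasserstein distance between the class-conditional
prediction distributions in the batch.  A decoder fuses
[f_global, f_t, f_s] into the predicted follow-up phases and a voxelwise
tumor-mask softmax.  The overall objective is

    E_overall = (E_tumor + λ_w·E_weight + λ_a·E_adv)
                + E_triplet_t + E_triplet_s + E_softmax

at the operating point λ_w = 0.2, λ_a = 0.5, φ = 30, ξ = 0.35.

Perfusion analysis implements the dual-input single-compartment model
dC/dt = K_a·AIF(t) + K_p·PIF(t) − K_2·C(t), fitted by bounded
multi-start least squares (reporting DV = 100·(K_a+K_p)/K_2 and
ART = K_a/(K_a+K_p)), plus the non-parametric descriptors T0, TTP, ΔS,
PER, nMITR and S0-normalized wash-in/wash-out slopes.

Since patient imaging of this kind is not publicly shareable, the
package ships a phantom generator that produces pre/post study pairs
with known class, kinetics and geometry; every accuracy claim in the
test suite is made against that exact ground truth.  The network and its
training run on a hand-written reverse-mode autodiff engine over numpy
(`stdgnn.autodiff`) — no deep-learning framework is required.

## Worked example

```python
import numpy as np
from stdgnn import (desk_config, generate_cohort, analyze_roi,
                    train, predict, dice)

cohort = generate_cohort(30, seed=7)              # 90 pre/post pairs
state  = train(cohort, desk_config(seed=7), val_fraction=0.2,
               augment_prob=0.3)

test = generate_cohort(6, seed=1007)              # held-out, balanced
hits, dices = [], []
for pre, post, truth in test:
    p = predict(pre, state, use_best=True)
    hits.append(p.viability_class == pre.label)
    dices.append(dice(p.post_mask > 0.5, post.tumor_mask))
print(f"accuracy {np.mean(hits):.2f}  mean Dice {np.mean(dices):.1f}%")

pre, _, truth = test[0]          # a viable-class study
r = analyze_roi(pre, pre.tumor_mask, aif_roi=truth["aif_mask"],
                pif_roi=truth["pif_mask"], enhancement_gain=120.0)
print(f"TTP {r.TTP:.0f}s  PER {r.PER:.2f}  wash-in {1000*r.wash_in:.1f}e-3/s")
```

On the fixed seeds above this prints

```
accuracy 1.00  mean Dice 64.2%
TTP 60s  PER 0.39  wash-in 6.4e-3/s
```

— all 18 held-out phantoms classified correctly, predicted follow-up
masks overlapping truth at Dice ≈ 64 %, and the viable-class example
tumor peaking early (TTP 60 s) with a wash-in slope on the 1e-3 1/s
scale typical of clinical reports, as constructed.  Note that from the
5-phase clinical sampling the arterial/portal split of the kinetic fit
is poorly identifiable (the vessel input curves miss the arterial peak);
K_a + K_p is the reliable fitted quantity, and the dense-grid recovery
properties are exercised in the test suite.

The same pipeline is scriptable from the shell:

```sh
stdgnn simulate --n-per-class 30 --out cohort/ --seed 7
stdgnn train --data cohort/ --out model/
stdgnn predict --seq cohort/study_000_V --model model/checkpoint.npz --out pred/study_000_V
stdgnn evaluate --pred pred/ --truth cohort/ --out report.json
stdgnn perfusion --seq cohort/study_000_V --out perf.csv
```

## Layout

| module | contents |
| --- | --- |
| `stdgnn.io_core` | `DceSequence`, NIfTI + CSV sequence I/O, `RunConfig`, seeding |
| `stdgnn.phantom` | input functions, kinetic simulation, pre/post phantom cohorts |
| `stdgnn.perfusion` | ROI curves, non-parametric metrics, model fitting |
| `stdgnn.graphs` | patch features, discriminant graphs, normalization, Laplacian |
| `stdgnn.autodiff` | reverse-mode autodiff on numpy (conv3d, pooling, BN, Adam) |
| `stdgnn.network` | trunk, temporal/structural/global branches, decoder, critic |
| `stdgnn.losses` | tumor CE, sliced Wasserstein, adversarial, triplet, overall |
| `stdgnn.train_predict` | training loop, augmentation, checkpointing, inference |
| `stdgnn.evaluation` | Dice, Hausdorff, surface MSE, confusion/AUC, Wilcoxon |
| `stdgnn.cli` | `stdgnn simulate / train / predict / evaluate / perfusion` |

See `docs/methods.md` for the model, the phantom's scope and the
numerical choices in detail.
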