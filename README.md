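# sacssl — subclass-aware contrastive semi-supervised learning

`sacssl` is a semi-supervised image classifier for tasks where classes
look alike, each class hides several visually distinct presentation modes,
and labels are scarce — the situation of colonoscopy-based grading of
inflammatory bowel disease, where a handful of expert-labeled images sit
beside large unlabeled archives and a single disease class spans very
different appearances.

The method couples confidence-thresholded pseudo-labeling with a
subclass-aware contrastive module. Each training batch mixes B_l labeled
and B_u unlabeled images; unlabeled images get one weak and two strong
augmented views. The objective is

```
L_total = L_s + λ1·L_u + λ2·L_sac
```

where L_s is cross-entropy on labeled weak views; L_u is masked
cross-entropy of hard pseudo-labels q̂ = argmax p(y|weak view) against the
first strong view, kept only when max q > T; and L_sac is computed on the
2B_u strong views: views with max q̃ ≤ T_conf are *uncertain* and receive
an instance-level contrastive loss (only their partner view is positive),
while *confident* views are grouped by predicted class, assigned to K
unit-norm class prototypes by entropic optimal transport under an
equipartition constraint (Sinkhorn–Knopp), and pulled toward their
subclass peers by a confidence-weighted supervised contrastive loss.
Prototypes are momentum state, updated each iteration toward the
normalized center of their assigned embeddings. See `docs/methods.md` for
the full formulation, defaults, and design notes.

Because the reference clinical datasets are not redistributable, the
package ships a synthetic-data module that generates image datasets with
known class *and* latent-subclass structure (shared color tint, per-class
texture family, per-subclass geometric variant, patient-level splits), so
every stage — losses, transport assignment, prototype updates, end-to-end
training — is testable against ground truth.

## Worked example

```python
import sacssl as S
from sacssl.trainer import SACSSL, TrainConfig

# 360-image synthetic dataset: 3 classes x 3 latent subclasses, 32x32,
# patient-level 20% labeled / 80% unlabeled split
spec = S.SyntheticSpec(seed=7)
manifest = S.generate_dataset(spec, "demo")
manifest = S.split_by_patient(manifest, labeled_fraction=0.2,
                              test_fraction=0.2, seed=7)
manifest.to_csv("demo/manifest.csv", index=False)

config = TrainConfig.desk(seed=1)          # CPU-scale preset, 30 epochs
model = SACSSL.from_manifest("demo/manifest.csv", config)
results = model.fit()
print(results.summary())
print(results.evaluate(model.manifest, "demo").as_dict())
```

which prints (about a minute on one core):

```
SACSSL training results
============================================================
encoder preset      : small-conv
parameters          : 69027
classes / prototypes: C=3, K=3, D=64
thresholds          : T=0.8, T_conf=0.9, tau=0.1, kappa=0.05, alpha=0.99
loss weights        : lambda1=1.0, lambda2=2.0
schedule            : 30 epochs, lr 0.001 -> 1e-06, wd 0.0005, Bl=8, Bu=16
------------------------------------------------------------
final iteration     : L_s=0.1020  L_u=0.3458  L_sac=2.3113  L_total=5.0704
pseudo-label coverage=0.81  confident fraction=0.62

{'accuracy': 0.989, 'per_class_avg_accuracy': 0.993,
 'sensitivity': 0.989, 'specificity': 0.994, 'f1': 0.989}
```

The final-iteration line shows the semi-supervised machinery engaged: 81%
of unlabeled samples pass the pseudo-label threshold and 62% of the
multi-view batch is confident enough to enter subclass assignment. With
only 45 labeled training images the full objective reaches 98.9% test
accuracy; the labeled-only baseline (`model.fit_supervised()`) reaches
97.8% on the same seed. `results.export_embeddings(...)` writes the
unit-norm projections for cluster analysis, and
`sacssl.bootstrap_f1_diff` gives a percentile-bootstrap confidence
interval for the macro-F1 difference between two models on a shared test
set.

A thin CLI wraps the same calls:

```
sacssl synth --out demo
sacssl train --data demo --out run
sacssl eval --checkpoint run/checkpoint.npz --data demo
sacssl embed --checkpoint run/checkpoint.npz --data demo --out emb.tsv
sacssl compare --preds-a a.csv --preds-b b.csv --truth t.csv
```

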