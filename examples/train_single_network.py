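"""Train one base network on planted-motif data and evaluate it.

A small end-to-end run: generate sequences, split 3:1:1 by sequence,
train the ffmod-0 network with balanced subsets, then report held-out
metrics. Takes roughly a minute on one CPU.
"""

from ppistack import (
    PPINetConfig,
    SyntheticConfig,
    TrainConfig,
    auprc,
    auroc,
    confusion_from_scores,
    scalar_metrics,
    split_dataset,
    train_ppinet,
)
from ppistack.features import featurize_dataset
from ppistack.synthetic import generate_dataset

records = generate_dataset(SyntheticConfig(n_sequences=60, noise_rate=0.05, seed=5))
split = split_dataset(records, seed=5)
by_id = {r.id: r for r in records}

net, history = train_ppinet(
    [by_id[i] for i in split.train],
    ffmod=0,
    config=TrainConfig(seed=5, max_epochs=10),
    net_config=PPINetConfig(ffmod=0, window=8, seed=5),
    val_records=[by_id[i] for i in split.validation],
)

test_records = [by_id[i] for i in split.test]
f_tr, f_ctx, pad, y, _ = featurize_dataset(test_records, 8, 0)
scores = net.predict(f_ctx, pad, f_tr)

m = scalar_metrics(confusion_from_scores(y, scores))
print(f"trained {len(history['train_loss'])} epochs; "
      f"train loss {history['train_loss'][0]:.3f} -> {history['train_loss'][-1]:.3f}")
print(f"test AUROC {auroc(y, scores):.3f}  AUPRC {auprc(y, scores):.3f}  "
      f"F1 {m['F1']:.3f}  MCC {m['MCC']:.3f}")
# AUROC well above 0.5 shows the network recovered the planted motif;
# AUPRC should clear the ~15% positive base rate by a wide margin.
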