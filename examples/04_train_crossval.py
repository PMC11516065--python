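"""Train the model with k-fold cross-validation on a small benchmark.

Every fold trains a fresh model on the remaining folds (Adam, minibatch
cross-entropy) and is scored on the held-out cells; the report carries
per-fold and mean accuracy, F1, precision, recall, and AUC.
Runs in about half a minute.
"""

import drugformer as df

dataset = df.generate_dataset(df.SyntheticConfig(
    n_cells=200, n_genes=150, n_signature_genes=15,
    effect_size=3.0, score_cluster_spread=0.0, seed=0,
))
graph = df.build_graph(dataset.scores, tau=0.05)

model_cfg = df.ModelConfig(embed_dim=32, n_heads=4, n_tokens=32,
                           encoder_count=2, ffn_hidden=64)
train_cfg = df.TrainConfig(batch_size=64, epochs=5, folds=5, seed=0)

report = df.cross_validate(dataset, graph, model_cfg, train_cfg, verbose=True)
print("mean:  " + ", ".join(f"{k}={v:.3f}" for k, v in report.mean.items()))
print("loss trace (fold 0):", [round(x, 3) for x in report.loss_traces[0]])
print("-> held-out AUC well above 0.5 shows the model recovered the planted")
print("   signature; the falling loss trace shows optimization progressed")
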