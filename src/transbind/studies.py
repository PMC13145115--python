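"""End-to-end synthetic studies at CPU scale.

These functions define the package's reference experiments on planted-motif
synthetic data: a memorization sanity check, motif recovery through both
interpretability routes, and label-zero-shot generalization across a
family-structured TF panel. Each is a pure function of its seed, runs the
whole pipeline (generator -> preparation -> training -> evaluation /
interpretation), and returns plain dictionaries of measured numbers.

Problem sizes are deliberately small — a few thousand 200 bp windows, a
32-filter encoder with d1 = 32 — so every study finishes in minutes on one
CPU core; see docs/methods.md for the rationale behind each setting.
"""

from __future__ import annotations

import numpy as np

from .interpret import (
    attribution_to_pwm,
    integrated_gradients_batch,
    kernel_to_pwm_activations,
)
from .model import ModelConfig, PairwiseTransBind, TransBindModel
from .nn import AdamW
from .pipeline import SplitSpec, build_dataset
from .pwm import PositionWeightMatrix
from .synthetic import SyntheticSpec, default_motifs, generate_genome, plant_peaks, synth_tf_embeddings
from .training import TrainConfig, bce_with_logits, per_label_metrics, train, train_pairwise

__all__ = [
    "small_model_config",
    "synthetic_dataset",
    "memorization_study",
    "motif_recovery_study",
    "zeroshot_family_study",
    "best_motif_match",
]

BIN_SIZE = 100
# a peak overlapping a bin by >= 50% lies within bin +/- 50 bp, so a 50 bp
# flank guarantees the planted motif is inside the 200 bp window
FLANK = 50
# width-10 motifs carry enough information content (~20 bits at 0.95
# consensus probability) for de-novo discovery at this data scale
MOTIF_WIDTH = 10
MOTIF_SHARPNESS = 0.95  # "strong motif": consensus base probability


def small_model_config(n_labels: int, d2: int = 64, seed: int = 0,
                       **overrides) -> ModelConfig:
    """The scaled-down architecture used by all studies: 32 filters,
    kernel 12, pool 10 (so L = 18 on the 200 bp window), d1 = 32, 4 heads."""
    fields = dict(
        input_len=BIN_SIZE + 2 * FLANK,
        conv_filters=32,
        conv_kernel=12,
        pool_window=10,
        lstm_hidden_per_dir=16,
        lstm_layers=1,
        transformer_heads=4,
        transformer_ffn=64,
        d2=d2,
        cross_attn_heads=4,
        dropout_p=0.05,
        n_labels=n_labels,
        seed=seed,
    )
    fields.update(overrides)
    return ModelConfig(**fields).validate()


def synthetic_dataset(spec: SyntheticSpec, split: SplitSpec,
                      augment: bool = True):
    """Generator -> preparation pipeline; returns (dataset, embeddings,
    spec) with the planted motifs accessible via spec.motif_pwms."""
    genome = generate_genome(spec)
    genome, peaks, _placements = plant_peaks(genome, spec)
    emb = synth_tf_embeddings(spec)
    ds = build_dataset(genome, peaks, spec.chrom_lengths,
                       bin_size=BIN_SIZE, flank=FLANK, split=split,
                       augment=augment)
    return ds, emb


def memorization_study(seed: int = 0, n_bins: int = 64, n_labels: int = 4,
                       max_epochs: int = 200) -> dict:
    """Overfit a tiny bin set: a healthy model must drive training loss
    near zero and rank its own training bins almost perfectly."""
    spec = SyntheticSpec(
        chrom_lengths={"chr1": (n_bins + 2) * BIN_SIZE},
        n_experiments=n_labels,
        n_families=2,
        peaks_per_experiment=15,
        peak_width=BIN_SIZE,
        motif_insert_prob=1.0,
        embedding_dim=64,
        seed=seed,
    )
    ds, emb = synthetic_dataset(
        spec, SplitSpec(test_chroms=set(), val_chroms=set(),
                        excluded_chroms=set()),
        augment=False,
    )
    X = ds["train"]["X"].astype(float)
    Y = ds["train"]["Y"].astype(float)
    # regularization off: this is a capacity check, not a generalization fit
    cfg = small_model_config(n_labels=n_labels, seed=seed, dropout_p=0.0)
    model = TransBindModel(cfg, np.stack([emb[e] for e in ds["experiments"]]))
    opt = AdamW(model.parameters(), lr=2e-3, weight_decay=0.0)
    droprng = np.random.default_rng(seed + 1)
    macro_auroc, final_loss, epoch = float("nan"), float("nan"), 0
    for epoch in range(1, max_epochs + 1):
        opt.zero_grad()
        loss = bce_with_logits(model(X, rng=droprng, training=True), Y)
        loss.backward()
        opt.step()
        final_loss = loss.item()
        if epoch % 10 == 0 or epoch == max_epochs:
            mt = per_label_metrics(model.predict(X), Y.astype(int))
            macro_auroc = mt.macro_auroc
            if macro_auroc >= 0.995 and final_loss < 0.05:
                break
    return {
        "macro_auroc": macro_auroc,
        "final_train_loss": final_loss,
        "epochs_run": epoch,
        "n_bins": int(len(X)),
        "n_labels": n_labels,
    }


def best_motif_match(candidate: PositionWeightMatrix,
                     motif: PositionWeightMatrix) -> dict:
    """Best alignment of a planted motif inside a candidate PWM.

    Slides the shorter matrix along the longer one, on both strands, and
    returns the alignment minimizing the mean per-column total-variation
    distance (max per column also reported)."""
    best = None
    for strand, m in (("+", motif), ("-", motif.reverse_complement())):
        a, b = (candidate.probs, m.probs)
        swap = a.shape[0] < b.shape[0]
        long, short = (b, a) if swap else (a, b)
        w = short.shape[0]
        for off in range(long.shape[0] - w + 1):
            tv = 0.5 * np.abs(long[off : off + w] - short).sum(axis=1)
            entry = {"mean_tv": float(tv.mean()), "max_tv": float(tv.max()),
                     "offset": off, "strand": strand}
            if best is None or entry["mean_tv"] < best["mean_tv"]:
                best = entry
    return best


def motif_recovery_study(seed: int = 0, n_bins: int = 2000,
                         epochs: int = 60) -> dict:
    """Train the small 2-experiment model on planted-motif data, then
    recover the motif through both interpretability routes.

    Reports the best kernel activation-PWM match and the TF-conditioned
    attribution-PWM match against the planted motifs (mean per-column TV),
    plus the integrated-gradients completeness gap at 256 steps.
    """
    lengths = {"chr1": 1000 * BIN_SIZE, "chr2": 600 * BIN_SIZE,
               "chr7": 200 * BIN_SIZE, "chr8": 200 * BIN_SIZE}
    assert sum(lengths.values()) // BIN_SIZE == n_bins
    spec = SyntheticSpec(
        chrom_lengths=lengths,
        n_experiments=2,
        n_families=2,
        motif_pwms=default_motifs(2, width=MOTIF_WIDTH,
                                  sharpness=MOTIF_SHARPNESS, seed=seed),
        peaks_per_experiment=350,
        peak_width=BIN_SIZE,
        motif_insert_prob=1.0,
        embedding_dim=64,
        seed=seed,
    )
    split = SplitSpec(test_chroms={"chr8"}, val_chroms={"chr7"},
                      excluded_chroms=set())
    ds, emb = synthetic_dataset(spec, split, augment=True)
    cfg = small_model_config(n_labels=2, seed=seed, dropout_p=0.1)
    model = TransBindModel(cfg, np.stack([emb[e] for e in ds["experiments"]]))
    tcfg = TrainConfig(lr=3e-3, weight_decay=0.028, max_epochs=epochs,
                       batch_size=128, patience=epochs, seed=seed,
                       eval_every=5)
    result = train(model, ds, tcfg)
    val_metrics = per_label_metrics(
        model.predict(ds["val"]["X"].astype(float)), ds["val"]["Y"]
    )
    test_scores = model.predict(ds["test"]["X"].astype(float))
    test_metrics = per_label_metrics(test_scores, ds["test"]["Y"])

    # route 1: activation-counting PWMs from every learned kernel,
    # scanning the full training set for stable site counts
    scan_X = ds["train"]["X"].astype(float)
    weights = model.core.encoder.conv.weight.data  # (32, 12, 4)
    kernel_matches = {m.name: None for m in spec.motif_pwms}
    for f in range(weights.shape[0]):
        try:
            kpwm = kernel_to_pwm_activations(weights[f], scan_X,
                                             frac_of_max=0.7,
                                             name=f"kernel_{f}")
        except ValueError:
            continue
        if kpwm.counts is not None and kpwm.counts.sum(axis=1).max() < 20:
            continue  # too few sites to call a motif
        for motif in spec.motif_pwms:
            match = best_motif_match(kpwm, motif)
            prev = kernel_matches[motif.name]
            if prev is None or match["mean_tv"] < prev["mean_tv"]:
                kernel_matches[motif.name] = match
    best_kernel_tv = min(m["mean_tv"] for m in kernel_matches.values()
                         if m is not None)

    # route 2: integrated-gradients attribution conditioned on the
    # best-learned experiment (highest validation AUROC) — interpretation
    # targets a model that has demonstrably acquired the signal
    label = int(np.nanargmax(val_metrics.auroc))
    ytr = ds["train"]["Y"][:, label]
    pos = np.flatnonzero(ytr == 1)[:128]
    Xpos = ds["train"]["X"][pos].astype(float)
    maps = integrated_gradients_batch(
        lambda t: model(t)[:, label], Xpos, steps=24
    )
    bases = "ACGT"
    seqs = ["".join(bases[b] for b in x.argmax(axis=1)) for x in Xpos]
    apwm = attribution_to_pwm(maps, seqs, window_width=MOTIF_WIDTH,
                              top_frac=0.5)
    attribution_match = best_motif_match(
        apwm, spec.motif_pwms[spec.family_of_experiment(label)]
    )

    # completeness at high step count on one trained-model input
    gap_map = integrated_gradients_batch(
        lambda t: model(t)[:, label], Xpos[:1], steps=256
    )[0]
    gap_ratio = (gap_map.convergence_gap / abs(gap_map.output_delta)
                 if gap_map.output_delta != 0 else float("inf"))

    target_motif = spec.motif_pwms[spec.family_of_experiment(label)]
    return {
        "n_train": int(len(ds["train"]["X"])),
        "n_bins": n_bins,
        "epochs": epochs,
        "final_train_loss": result["history"][-1]["train_loss"],
        "best_epoch": result["best_epoch"],
        "interpreted_label": label,
        "val_auroc_per_label": [float(v) for v in val_metrics.auroc],
        "test_macro_auroc": test_metrics.macro_auroc,
        "test_auroc_interpreted": float(test_metrics.auroc[label]),
        "best_kernel_tv": float(kernel_matches[target_motif.name]["mean_tv"]),
        "kernel_matches": kernel_matches,
        "attribution_tv": float(attribution_match["mean_tv"]),
        "attribution_consensus": apwm.consensus(),
        "planted_consensus": target_motif.consensus(),
        "ig_gap_ratio_256": float(gap_ratio),
    }


def zeroshot_family_study(seed: int = 0, n_tfs: int = 9, n_families: int = 3,
                          heldout_index: int = 8, epochs: int = 40,
                          n_permutations: int = 1000) -> dict:
    """Hold one TF out of a family-structured panel and test whether the
    pairwise model ranks its binding windows above a permutation null.

    The held-out TF's labels never enter training; only its protein
    embedding is supplied at evaluation. Families are tight (small
    embedding noise) and paralogs share most of their binding repertoire
    (``family_peak_share`` 0.9), so a model that couples binding sites to
    embedding-family directions transfers sibling knowledge to the unseen
    TF — within-family label-zero-shot generalization. Training loss
    itself certifies family discrimination: an embedding-blind predictor
    cannot fit windows whose labels conflict across families.
    """
    spec = SyntheticSpec(
        chrom_lengths={"chr1": 1000 * BIN_SIZE},
        n_experiments=n_tfs,
        n_families=n_families,
        motif_pwms=default_motifs(n_families, width=MOTIF_WIDTH,
                                  sharpness=MOTIF_SHARPNESS, seed=seed),
        peaks_per_experiment=150,
        peak_width=BIN_SIZE,
        motif_insert_prob=1.0,
        embedding_dim=64,
        within_family_noise=0.02,
        family_peak_share=0.9,
        seed=seed,
    )
    ds, emb = synthetic_dataset(
        spec, SplitSpec(test_chroms=set(), val_chroms=set(),
                        excluded_chroms=set()),
        augment=False,
    )
    X = ds["train"]["X"].astype(float)
    Y = ds["train"]["Y"]
    names = ds["experiments"]
    held = names[heldout_index]
    train_tfs = [n for n in names if n != held]
    assert held not in train_tfs

    def pair_block(tfs):
        xs, es, ys = [], [], []
        for tf in tfs:
            e = names.index(tf)
            xs.append(X)
            es.append(np.tile(emb[tf], (len(X), 1)))
            ys.append(Y[:, e])
        return {"X": np.concatenate(xs), "E": np.concatenate(es),
                "y": np.concatenate(ys)}

    pairs = {"train": pair_block(train_tfs)}
    cfg = small_model_config(n_labels=1, seed=seed, dropout_p=0.05)
    model = PairwiseTransBind(cfg)
    tcfg = TrainConfig(lr=2e-3, weight_decay=1e-4, max_epochs=epochs,
                       batch_size=256, patience=epochs, seed=seed)
    result = train_pairwise(model, pairs, tcfg)

    test = pair_block([held])
    scores = model.predict(test["X"], test["E"])
    mt = per_label_metrics(scores, test["y"].astype(int))
    auroc = mt.macro_auroc

    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed + 17)
    null = np.array([
        roc_auc_score(rng.permutation(test["y"]), scores)
        for _ in range(n_permutations)
    ])
    return {
        "heldout_tf": held,
        "heldout_auroc": float(auroc),
        "heldout_aupr": mt.macro_aupr,
        "null_auroc_p95": float(np.quantile(null, 0.95)),
        "null_auroc_mean": float(null.mean()),
        "n_train_pairs": int(len(pairs["train"]["X"])),
        "n_test_pairs": int(len(test["X"])),
        "n_positives_heldout": int(test["y"].sum()),
        "final_train_loss": result["history"][-1]["train_loss"],
    }
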