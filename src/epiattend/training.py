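"""Splits, shift augmentation, class weighting, training loops, metrics.

The study design these utilities implement: a 90/10 train/test split with a
further 5% of the train pool held out for validation; class imbalance of
1:20 handled either by shift augmentation of positives (whole-window shifts
of 10-50 bp, applied after splitting and to the training split only, so no
augmented copy of a positive can leak across split boundaries) or by a
balanced inverse-frequency class-weighted cross-entropy; model selection by
validation AUPR; evaluation by AUROC and AUPR, the imbalance-appropriate
metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import ModelConfig
from .nn import Adam, EPINetwork
from .records import SequencePairRecord


class TrainingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    test_frac: float = 0.10
    val_frac_of_train: float = 0.05
    seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        for name, frac in (("test_frac", self.test_frac), ("val_frac_of_train", self.val_frac_of_train)):
            if not 0.0 < frac < 1.0:
                raise TrainingError(f"{name} must be in (0,1), got {frac}")


def _stratified_take(by_class: dict[int, list[int]], n_take: int,
                     rng: np.random.Generator) -> list[int]:
    """Draw n_take indices, allocating per class by largest remainder."""
    total = sum(len(v) for v in by_class.values())
    quotas, fracs = {}, {}
    for c, idxs in by_class.items():
        exact = n_take * len(idxs) / total
        quotas[c] = int(np.floor(exact))
        fracs[c] = exact - quotas[c]
    short = n_take - sum(quotas.values())
    for c in sorted(by_class, key=lambda c: (-fracs[c], c))[:short]:
        quotas[c] += 1
    taken: list[int] = []
    for c in sorted(by_class):
        idxs = by_class[c]
        pick = rng.choice(len(idxs), size=min(quotas[c], len(idxs)), replace=False)
        chosen = [idxs[i] for i in sorted(pick)]
        taken.extend(chosen)
        by_class[c] = [i for i in idxs if i not in set(chosen)]
    return taken


def split(records: list[SequencePairRecord], spec: SplitSpec
          ) -> tuple[list[SequencePairRecord], list[SequencePairRecord], list[SequencePairRecord]]:
    """Partition records into (train, val, test), deterministically by seed.

    |test| = round(test_frac * N); |val| = round(val_frac_of_train * (N - |test|)),
    stratified by label within rounding.
    """
    N = len(records)
    if N < 20:
        raise TrainingError(f"need at least 20 records to split, got {N}")
    labels = [r.label for r in records]
    if len(set(labels)) < 2:
        raise TrainingError("both classes must be present to split")

    rng = np.random.default_rng(spec.seed)
    n_test = int(round(spec.test_frac * N))
    n_val = int(round(spec.val_frac_of_train * (N - n_test)))

    if spec.stratify:
        by_class: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            by_class.setdefault(lab, []).append(i)
        test_idx = _stratified_take(by_class, n_test, rng)
        val_idx = _stratified_take(by_class, n_val, rng)
        train_idx = [i for idxs in by_class.values() for i in idxs]
        splits = {"train": train_idx, "val": val_idx, "test": test_idx}
        for name, idxs in splits.items():
            if idxs and len({labels[i] for i in idxs}) < 2:
                warnings.warn(
                    f"stratified {name} split contains a single class at N={N}; "
                    "consider stratify=False or a larger dataset"
                )
    else:
        perm = rng.permutation(N)
        test_idx = list(perm[:n_test])
        val_idx = list(perm[n_test:n_test + n_val])
        train_idx = list(perm[n_test + n_val:])

    train = [records[i] for i in sorted(train_idx)]
    val = [records[i] for i in sorted(val_idx)]
    test = [records[i] for i in sorted(test_idx)]
    return train, val, test


# ---------------------------------------------------------------------------
# Shift augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentSpec:
    """Whole-window shifts of 10-50 bp applied to positive pairs.

    A positive shift moves the sequence downstream (output[i] = input[i-s]);
    vacated positions are filled with ``fill`` (default 'N', since synthetic
    windows carry no flanking genome).
    """

    shifts: tuple[int, ...] = (50,)
    fill: str = "N"

    def __post_init__(self):
        for s in self.shifts:
            if not 10 <= abs(s) <= 50:
                raise TrainingError(f"|shift| must be within [10, 50], got {s}")
        if len(self.fill) != 1 or self.fill not in "ACGTN":
            raise TrainingError(f"fill must be a single base or N, got {self.fill!r}")


def _shift_seq(seq: str, s: int, fill: str) -> str:
    if s > 0:
        return fill * s + seq[:-s]
    return seq[-s:] + fill * (-s)


def augment_positives(records: list[SequencePairRecord], spec: AugmentSpec
                      ) -> list[SequencePairRecord]:
    """Return records plus shifted copies of every positive (labels kept,
    derived ids); negatives pass through untouched."""
    out = list(records)
    for rec in records:
        if rec.label != 1:
            continue
        for s in spec.shifts:
            out.append(SequencePairRecord(
                id=f"{rec.id}__shift{s:+d}",
                enhancer=_shift_seq(rec.enhancer, s, spec.fill),
                promoter=_shift_seq(rec.promoter, s, spec.fill),
                label=1,
                cell_line=rec.cell_line,
            ))
    return out


def augmentation_source_id(record_id: str) -> str:
    """Id of the original positive an augmented copy derives from."""
    return record_id.split("__shift")[0]


# ---------------------------------------------------------------------------
# Class weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassWeights:
    w_pos: float
    w_neg: float

    def per_sample(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels)
        return np.where(labels == 1, self.w_pos, self.w_neg)


def class_weights(labels) -> ClassWeights:
    """Balanced inverse-frequency weights: w_c = N / (2 * N_c)."""
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingError("both classes must be present to compute class weights")
    N = n_pos + n_neg
    return ClassWeights(w_pos=N / (2.0 * n_pos), w_neg=N / (2.0 * n_neg))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate(probabilities, labels) -> tuple[float, float]:
    """(AUROC, AUPR) for a probability ranking of binary labels.

    AUROC is the trapezoid/rank area; AUPR uses precision-recall step
    interpolation (average precision).  Both classes must be present.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities)
    if len(set(labels.tolist())) < 2:
        raise TrainingError("both classes must be present to evaluate")
    return (float(roc_auc_score(labels, probabilities)),
            float(average_precision_score(labels, probabilities)))


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def encode_records(net: EPINetwork, records: list[SequencePairRecord]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xe = net.encode_batch([r.enhancer for r in records], "enhancer")
    xp = net.encode_batch([r.promoter for r in records], "promoter")
    y = np.array([r.label for r in records], dtype=np.float64)
    return xe, xp, y


def predict_network(net: EPINetwork, records: list[SequencePairRecord],
                    batch_size: int = 256) -> np.ndarray:
    """Inference probabilities (dropout off, deterministic)."""
    probs = []
    for lo in range(0, len(records), batch_size):
        chunk = records[lo:lo + batch_size]
        xe, xp, _ = encode_records(net, chunk)
        probs.append(net.forward(xe, xp, training=False))
    return np.concatenate(probs) if probs else np.zeros(0)


def train(net: EPINetwork,
          train_records: list[SequencePairRecord],
          val_records: list[SequencePairRecord],
          cfg: ModelConfig | None = None,
          mode: str = "none",
          augment_spec: AugmentSpec | None = None,
          seed: int = 0,
          max_epochs: int = 100,
          patience: int = 10,
          monitor: str = "aupr",
          restore_best: bool = True,
          verbose: bool = False) -> dict:
    """Fit the network with Adam on (weighted) binary cross-entropy.

    ``mode`` selects the imbalance strategy: ``"augment"`` adds shifted
    copies of positives to the training split only; ``"class_weight"``
    multiplies each sample's loss by its balanced inverse-frequency class
    weight; ``"none"`` does neither.  Early stopping monitors validation
    AUPR by default (``monitor="loss"`` tracks validation loss instead,
    which keeps improving after the ranking metrics saturate and is the
    better stopping signal when sharp attention maps matter downstream);
    the best weights are restored at the end.

    Returns a history dict (train_loss, val_auroc, val_aupr per epoch,
    best_epoch, epochs_run, augmented_ids).
    """
    cfg = cfg or net.cfg
    if not train_records:
        raise TrainingError("empty training set")
    if mode not in ("none", "augment", "class_weight"):
        raise TrainingError(f"unknown training mode {mode!r}")
    if monitor not in ("aupr", "loss"):
        raise TrainingError(f"unknown early-stopping monitor {monitor!r}")

    augmented_ids: list[str] = []
    if mode == "augment":
        spec = augment_spec or AugmentSpec()
        before = {r.id for r in train_records}
        train_records = augment_positives(train_records, spec)
        augmented_ids = [r.id for r in train_records if r.id not in before]

    xe, xp, y = encode_records(net, train_records)
    weights = None
    if mode == "class_weight":
        weights = class_weights(y).per_sample(y)

    have_val = bool(val_records)
    if have_val:
        xe_v, xp_v, y_v = encode_records(net, val_records)
        val_two_class = len(set(y_v.tolist())) == 2

    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate,
               beta1=cfg.adam_beta1, beta2=cfg.adam_beta2, eps=cfg.adam_eps)
    history = {"train_loss": [], "val_auroc": [], "val_aupr": [], "val_loss": [],
               "augmented_ids": augmented_ids}
    best_metric, best_weights, best_epoch, stale = -np.inf, None, -1, 0
    B = cfg.batch_size
    n = len(train_records)

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, B):
            idx = order[lo:lo + B]
            probs = net.forward(xe[idx], xp[idx], training=True, rng=rng)
            w = weights[idx] if weights is not None else None
            loss, dlogits = net.loss_and_grad(probs, y[idx], w)
            opt.zero_grad()
            net.backward_from_logits(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)

        if have_val:
            pv = net.forward(xe_v, xp_v, training=False)
            vloss, _ = net.loss_and_grad(pv, y_v)
            history["val_loss"].append(vloss)
            if val_two_class:
                auroc, aupr = evaluate(pv, y_v)
                history["val_auroc"].append(auroc)
                history["val_aupr"].append(aupr)
                metric = aupr if monitor == "aupr" else -vloss
            else:
                metric = -vloss
        else:
            metric = -history["train_loss"][-1]

        if verbose:
            print(f"epoch {epoch}: loss {history['train_loss'][-1]:.4f} metric {metric:.4f}")
        if metric > best_metric + 1e-12:
            best_metric, best_epoch, stale = metric, epoch, 0
            if restore_best:
                best_weights = net.get_weights()
        else:
            stale += 1
            if stale >= patience:
                break

    if restore_best and best_weights is not None:
        net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["epochs_run"] = len(history["train_loss"])
    return history


def train_pooled_then_finetune(
        per_cell: dict[str, tuple[list[SequencePairRecord], list[SequencePairRecord]]],
        cfg: ModelConfig,
        seed: int = 0,
        mode: str = "none",
        augment_spec: AugmentSpec | None = None,
        max_epochs: int = 100,
        patience: int = 10,
        kmer_table=None,
) -> dict:
    """Two-stage protocol: train one model on the pooled training splits of
    all cells, then clone its weights and fine-tune separately per cell.

    ``per_cell`` maps cell tag -> (train_records, val_records).  Record ids
    must be globally unique across cells.  Returns
    ``{"pooled": (net, history), "cells": {cell: (net, history)},
       "pooled_weights": {...}}`` where pooled_weights is the stage-1 final
    state each stage-2 model was initialized from.
    """
    if len(per_cell) < 2:
        raise TrainingError("pooled-then-finetune needs >= 2 cell tags")
    seen: dict[str, str] = {}
    for cell, (tr, va) in per_cell.items():
        for r in tr + va:
            if r.id in seen and seen[r.id] != cell:
                raise TrainingError(f"record id {r.id!r} appears in cells {seen[r.id]!r} and {cell!r}")
            seen[r.id] = cell

    pooled_train = [r for tr, _ in per_cell.values() for r in tr]
    pooled_val = [r for _, va in per_cell.values() for r in va]
    pooled_net = EPINetwork(cfg, seed=seed, kmer_table=kmer_table)
    pooled_hist = train(pooled_net, pooled_train, pooled_val, cfg, mode=mode,
                        augment_spec=augment_spec, seed=seed,
                        max_epochs=max_epochs, patience=patience)
    pooled_weights = pooled_net.get_weights()

    cells = {}
    for i, (cell, (tr, va)) in enumerate(sorted(per_cell.items())):
        net = EPINetwork(cfg, seed=seed, kmer_table=kmer_table)
        net.set_weights(pooled_weights)
        hist = train(net, tr, va, cfg, mode=mode, augment_spec=augment_spec,
                     seed=seed + 1 + i, max_epochs=max_epochs, patience=patience)
        cells[cell] = (net, hist)

    return {"pooled": (pooled_net, pooled_hist), "cells": cells,
            "pooled_weights": pooled_weights}
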