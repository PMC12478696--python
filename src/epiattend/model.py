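"""Model/Results interface over the interaction network.

`EPIModel` is constructed from a dataset of labeled enhancer/promoter pairs
(list of records or a DataFrame) plus a :class:`~epiattend.config.ModelConfig`;
:meth:`EPIModel.fit` runs the split/augment/weight/train protocol and
returns an :class:`EPIResults` carrying the trained network, the training
history, the held-out metrics, and the interpretability entry points
(attention capture, region PWMs).

    >>> model = EPIModel(records, config=scaled_test_config())
    >>> res = model.fit(mode="class_weight", seed=0)
    >>> res.test_auroc, res.test_aupr
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ModelConfig
from .encodings import KmerVectorTable
from .nn import EPINetwork
from .records import SequencePairRecord, validate_records
from .training import (
    AugmentSpec, SplitSpec, evaluate, predict_network, split, train,
)


class EPIModel:
    """Sequence-only enhancer-promoter interaction classifier.

    Parameters
    ----------
    records : list of SequencePairRecord
        The full labeled dataset; splitting happens inside :meth:`fit`.
    config : ModelConfig, optional
        Network geometry and optimizer settings (published defaults if
        omitted).
    kmer_table : KmerVectorTable, optional
        Required when ``config.encoding == "dna2vec"``.
    """

    def __init__(self, records: list[SequencePairRecord],
                 config: ModelConfig | None = None,
                 kmer_table: KmerVectorTable | None = None):
        self.config = config or ModelConfig()
        validate_records(records, self.config.enh_len, self.config.prom_len)
        self.records = list(records)
        self.kmer_table = kmer_table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ModelConfig | None = None,
                       kmer_table: KmerVectorTable | None = None) -> "EPIModel":
        """Build from a DataFrame with columns id, enhancer, promoter, label
        and (optionally) cell_line."""
        required = {"id", "enhancer", "promoter", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        records = [
            SequencePairRecord(
                str(row.id), str(row.enhancer).upper(), str(row.promoter).upper(),
                int(row.label),
                str(getattr(row, "cell_line", "synthetic")),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records, config=config, kmer_table=kmer_table)

    def fit(self, mode: str = "none",
            split_spec: SplitSpec | None = None,
            augment_spec: AugmentSpec | None = None,
            seed: int = 0,
            max_epochs: int = 100,
            patience: int = 10,
            monitor: str = "aupr",
            restore_best: bool = True,
            init_weights: dict | None = None) -> "EPIResults":
        """Split, train and evaluate; returns an :class:`EPIResults`.

        ``mode`` is the imbalance strategy ({"none", "augment",
        "class_weight"}); augmentation is applied after splitting and to the
        training split only.  ``init_weights`` warm-starts the network (used
        by the pooled-then-finetune protocol).
        """
        spec = split_spec or SplitSpec(seed=seed)
        train_recs, val_recs, test_recs = split(self.records, spec)
        net = EPINetwork(self.config, seed=seed, kmer_table=self.kmer_table)
        if init_weights is not None:
            net.set_weights(init_weights)
        history = train(net, train_recs, val_recs, self.config, mode=mode,
                        augment_spec=augment_spec, seed=seed,
                        max_epochs=max_epochs, patience=patience,
                        monitor=monitor, restore_best=restore_best)
        return EPIResults(self, net, history, train_recs, val_recs, test_recs,
                          mode=mode, seed=seed)


class EPIResults:
    """Fitted-model results: held-out metrics, history, prediction and
    attention capture."""

    def __init__(self, model: EPIModel, network: EPINetwork, history: dict,
                 train_records, val_records, test_records,
                 mode: str, seed: int):
        self.model = model
        self.network = network
        self.history = history
        self.train_records = train_records
        self.val_records = val_records
        self.test_records = test_records
        self.mode = mode
        self.seed = seed
        self._test_metrics: tuple[float, float] | None = None

    # ----- prediction & metrics --------------------------------------------

    def predict(self, records: list[SequencePairRecord] | None = None) -> np.ndarray:
        """Interaction probabilities (dropout off); defaults to the test split."""
        records = self.test_records if records is None else records
        return predict_network(self.network, records)

    def evaluate(self, records: list[SequencePairRecord] | None = None) -> tuple[float, float]:
        records = self.test_records if records is None else records
        probs = self.predict(records)
        return evaluate(probs, [r.label for r in records])

    @property
    def test_auroc(self) -> float:
        if self._test_metrics is None:
            self._test_metrics = self.evaluate()
        return self._test_metrics[0]

    @property
    def test_aupr(self) -> float:
        if self._test_metrics is None:
            self._test_metrics = self.evaluate()
        return self._test_metrics[1]

    # ----- interpretability -------------------------------------------------

    def capture_attention(self, records: list[SequencePairRecord]) -> np.ndarray:
        """Per-head attention maps for the given (positive) records — see
        :func:`epiattend.interpret.capture_attention`."""
        from .interpret import capture_attention
        return capture_attention(self, records)

    # ----- reporting --------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        n_pos = sum(r.label for r in self.model.records)
        n_neg = len(self.model.records) - n_pos
        auroc, aupr = self.evaluate()
        lines = [
            "Enhancer-Promoter Interaction Model Results",
            "=" * 47,
            f"{'Records (pos/neg)':<30}{n_pos}/{n_neg}",
            f"{'Splits (train/val/test)':<30}"
            f"{len(self.train_records)}/{len(self.val_records)}/{len(self.test_records)}",
            f"{'Imbalance mode':<30}{self.mode}",
            f"{'Encoding':<30}{cfg.encoding}",
            f"{'Geometry (enh+prom=merged)':<30}"
            f"{cfg.enh_pooled_len}+{cfg.prom_pooled_len}={cfg.merged_len}",
            f"{'Heads x head dim':<30}{cfg.n_heads} x {cfg.head_dim}",
            f"{'Epochs run (best)':<30}"
            f"{self.history['epochs_run']} ({self.history['best_epoch']})",
            f"{'Final train loss':<30}{self.history['train_loss'][-1]:.4f}",
            f"{'Test AUROC':<30}{auroc:.4f}",
            f"{'Test AUPR':<30}{aupr:.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<EPIResults mode={self.mode!r} seed={self.seed} "
                f"epochs={self.history['epochs_run']}>")
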