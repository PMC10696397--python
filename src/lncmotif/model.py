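"""Trainable binary sequence classifier over k-mer token streams.

``ClassifierConfig`` defaults follow the standard fine-tuning recipe for
pre-trained DNA language models (learning rate 2e-5, 4.0 epochs, batch 4,
warmup 10%, dropout 0.1, weight decay 0.01);
:func:`tiny_reference_config` is the desk-scale configuration
used throughout the tests (2 layers, 64-dim, 4 heads, 256-token windows,
trained from random initialization, which needs a larger step size than
fine-tuning a pre-trained network).
"""
from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .types import ClassScore, KmerDocument, LNCRNA, NON_LNCRNA

logger = logging.getLogger(__name__)

SPECIAL_TOKENS = ["[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"]
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)

CHECKPOINT_FORMAT = 1

Label = Union[str, int]


def _label_to_int(label: Label) -> int:
    if isinstance(label, str):
        if label == LNCRNA:
            return 1
        if label == NON_LNCRNA:
            return 0
        raise ValueError(f"unknown label {label!r}")
    if label in (0, 1):
        return int(label)
    raise ValueError(f"unknown label {label!r}")


@dataclass(frozen=True)
class Vocabulary:
    """All 4^k k-mers (lexicographic order) plus the five special tokens."""

    k: int
    token_to_id: Dict[str, int]

    @classmethod
    def build(cls, k: int) -> "Vocabulary":
        if not (3 <= k <= 6):
            raise ValueError("k must lie in [3, 6]")
        mapping = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
        for i, tup in enumerate(itertools.product("ACGT", repeat=k)):
            mapping["".join(tup)] = len(SPECIAL_TOKENS) + i
        return cls(k=k, token_to_id=mapping)

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def id_to_token(self) -> List[str]:
        out = [""] * len(self.token_to_id)
        for tok, i in self.token_to_id.items():
            out[i] = tok
        return out


def build_vocabulary(k: int) -> Vocabulary:
    return Vocabulary.build(k)


def _token_ids(doc: KmerDocument, vocab: Vocabulary) -> np.ndarray:
    if doc.k != vocab.k:
        raise ValueError(f"document k={doc.k} does not match vocabulary k={vocab.k}")
    ids = np.empty(len(doc.tokens), dtype=np.int32)
    for i, tok in enumerate(doc.tokens):
        tid = vocab.token_to_id.get(tok)
        if tid is None:
            if set(tok) <= set("ACGTN"):
                tid = UNK_ID  # k-mers containing N map to the unknown token
            else:
                raise ValueError(f"token {tok!r} contains characters outside ACGTN")
        ids[i] = tid
    return ids


def encode(doc: KmerDocument, vocab: Vocabulary, max_len: int) -> np.ndarray:
    """[CLS] + token ids + [SEP], truncated from the end to max_len, PAD-padded."""
    if max_len < 3:
        raise ValueError("max_len must be at least 3 (CLS + one token + SEP)")
    ids = _token_ids(doc, vocab)
    content = ids[: max_len - 2]
    out = np.full(max_len, PAD_ID, dtype=np.int32)
    out[0] = CLS_ID
    out[1 : 1 + len(content)] = content
    out[1 + len(content)] = SEP_ID
    return out


def encode_windows(doc: KmerDocument, vocab: Vocabulary, max_len: int) -> np.ndarray:
    """Encode as non-overlapping windows of max_len (CLS/SEP per window).

    Returns an (n_windows, max_len) int32 array covering every token of the
    document; nothing is discarded.
    """
    if max_len < 3:
        raise ValueError("max_len must be at least 3")
    ids = _token_ids(doc, vocab)
    width = max_len - 2
    n_win = max(1, math.ceil(len(ids) / width))
    out = np.full((n_win, max_len), PAD_ID, dtype=np.int32)
    for w in range(n_win):
        chunk = ids[w * width : (w + 1) * width]
        out[w, 0] = CLS_ID
        out[w, 1 : 1 + len(chunk)] = chunk
        out[w, 1 + len(chunk)] = SEP_ID
    return out


@dataclass(frozen=True)
class ClassifierConfig:
    k: int = 3
    max_seq_length: int = 2048
    n_layers: int = 2
    n_heads: int = 4
    hidden_dim: int = 64
    ffn_dim: int = 256
    conv_width: int = 7
    pooling: str = "mean_max"  # "mean_max" or "mean"
    dropout: float = 0.1
    learning_rate: float = 2e-5
    epochs: float = 4.0
    batch_size: int = 4
    warmup_fraction: float = 0.1
    weight_decay: float = 0.01
    logging_steps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.max_seq_length < 1:
            raise ValueError("max_seq_length must be >= 1")
        if not (3 <= self.k <= 6):
            raise ValueError("k must lie in [3, 6]")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.pooling not in ("mean_max", "mean"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")

    def replace(self, **kwargs) -> "ClassifierConfig":
        return dataclasses.replace(self, **kwargs)


def tiny_reference_config(k: int = 3, seed: int = 0, **overrides) -> ClassifierConfig:
    """Desk-scale reference configuration trained from random initialization."""
    base = dict(
        k=k,
        max_seq_length=256,
        n_layers=2,
        n_heads=4,
        hidden_dim=64,
        ffn_dim=256,
        conv_width=7,
        pooling="mean_max",
        dropout=0.1,
        learning_rate=2e-3,
        epochs=3.0,
        batch_size=8,
        warmup_fraction=0.1,
        weight_decay=0.01,
        logging_steps=100,
        seed=seed,
    )
    base.update(overrides)
    return ClassifierConfig(**base)


@dataclass
class TrainedClassifier:
    config: ClassifierConfig
    vocabulary: Vocabulary
    parameters: nn.Params
    training_log: List[dict] = field(default_factory=list)

    # -- inference ---------------------------------------------------------
    def _windows(self, doc: KmerDocument) -> np.ndarray:
        if doc.k != self.vocabulary.k:
            raise ValueError(
                f"document k={doc.k} incompatible with model k={self.vocabulary.k}"
            )
        return encode_windows(doc, self.vocabulary, self.config.max_seq_length)

    def predict_proba(self, docs: Sequence[KmerDocument], batch_size: int = 24) -> np.ndarray:
        """p(lncRNA) per document: sigmoid of the aggregated window evidence."""
        chunk_list = [self._windows(d) for d in docs]
        probs = np.empty(len(docs), dtype=np.float64)
        for lo in range(0, len(docs), batch_size):
            batch = chunk_list[lo : lo + batch_size]
            seg = np.repeat(np.arange(len(batch)), [c.shape[0] for c in batch])
            ids = np.concatenate(batch, axis=0)
            scores, _, _ = nn.sequence_scores(
                self.parameters, ids, seg, len(batch), self.config, PAD_ID
            )
            probs[lo : lo + len(batch)] = nn._sigmoid(scores)
        return probs


def train(
    train_set: Sequence[Tuple[KmerDocument, Label]],
    eval_set: Optional[Sequence[Tuple[KmerDocument, Label]]],
    config: ClassifierConfig,
) -> TrainedClassifier:
    """Fit the classifier with AdamW, linear warmup then linear decay.

    Deterministic under (config.seed, data) on a single worker.  ``epochs``
    may be fractional; 0 returns the randomly initialized model.
    """
    labels = np.array([_label_to_int(lbl) for _, lbl in train_set], dtype=np.int64)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    vocab = Vocabulary.build(config.k)
    rng = np.random.default_rng(config.seed)
    params = nn.init_params(len(vocab), config, rng)

    chunk_list = [encode_windows(doc, vocab, config.max_seq_length) for doc, _ in train_set]
    n_long = sum(1 for c in chunk_list if c.shape[0] > 1)
    if n_long:
        logger.info(
            "%d/%d training sequences exceed one %d-token window",
            n_long, len(chunk_list), config.max_seq_length,
        )

    n = len(train_set)
    batches_per_epoch = math.ceil(n / config.batch_size)
    total_steps = int(round(config.epochs * batches_per_epoch))
    model = TrainedClassifier(config, vocab, params)
    if total_steps == 0:
        return model

    opt = nn.AdamW(
        params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
        total_steps=total_steps,
        warmup_fraction=config.warmup_fraction,
    )

    eval_docs = [doc for doc, _ in eval_set] if eval_set else None
    eval_labels = (
        np.array([_label_to_int(lbl) for _, lbl in eval_set]) if eval_set else None
    )

    def evaluate() -> Optional[float]:
        if not eval_docs:
            return None
        probs = model.predict_proba(eval_docs)
        return float(np.mean((probs >= 0.5).astype(int) == eval_labels))

    order = np.empty(0, dtype=np.int64)
    step = 0
    while step < total_steps:
        if len(order) < config.batch_size:
            order = np.concatenate([order, rng.permutation(n)])
        idx, order = order[: config.batch_size], order[config.batch_size :]
        batch_chunks = [chunk_list[i] for i in idx]
        seg = np.repeat(np.arange(len(idx)), [c.shape[0] for c in batch_chunks])
        ids = np.concatenate(batch_chunks, axis=0)
        loss, grads = nn.train_step(
            params, ids, seg, labels[idx], config, PAD_ID, rng
        )
        opt.step(params, grads)
        step += 1
        if step % config.logging_steps == 0 or step == total_steps:
            entry = {"step": step, "loss": loss, "eval_accuracy": evaluate()}
            model.training_log.append(entry)
            logger.info("step %d/%d loss %.4f eval %s", step, total_steps, loss,
                        entry["eval_accuracy"])
    return model


def predict(model: TrainedClassifier, doc: KmerDocument) -> ClassScore:
    p = float(model.predict_proba([doc])[0])
    return ClassScore.from_probability(doc.source_id, p)


def predict_batch(model: TrainedClassifier, docs: Sequence[KmerDocument]) -> List[ClassScore]:
    probs = model.predict_proba(docs)
    return [
        ClassScore.from_probability(doc.source_id, float(p))
        for doc, p in zip(docs, probs)
    ]


# ---------------------------------------------------------------------------
# Persistence: a checkpoint directory with a JSON config sidecar


def save_model(model: TrainedClassifier, path: Path | str) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": dataclasses.asdict(model.config),
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "weights.npz", **model.parameters)
    with (path / "training_log.tsv").open("w") as fh:
        fh.write("step\tloss\teval_accuracy\n")
        for e in model.training_log:
            fh.write(f"{e['step']}\t{e['loss']}\t{e['eval_accuracy']}\n")


def load_model(path: Path | str) -> TrainedClassifier:
    path = Path(path)
    cfg_path = path / "config.json"
    weights_path = path / "weights.npz"
    if not cfg_path.exists() or not weights_path.exists():
        raise FileNotFoundError(f"no checkpoint found at {path}")
    meta = json.loads(cfg_path.read_text())
    if meta.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(
            f"checkpoint format {meta.get('format')} not supported "
            f"(expected {CHECKPOINT_FORMAT})"
        )
    config = ClassifierConfig(**meta["config"])
    vocab = Vocabulary.build(config.k)
    with np.load(weights_path) as npz:
        params = {k: npz[k] for k in npz.files}
    expected = nn.init_params(len(vocab), config, np.random.default_rng(0))
    for key, val in expected.items():
        if key not in params or params[key].shape != val.shape:
            raise ValueError(
                f"checkpoint weights incompatible with config (parameter {key})"
            )
    return TrainedClassifier(config, vocab, params)
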