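"""The IMF scorer: a five-block 1-D CNN with LOSO training.

The default architecture uses decreasing kernel sizes [31, 21, 15, 11,
7] (large receptive fields early for slow maternal trends, small ones
late for fast fetal QRS detail), pyramid channels [32, 64, 128, 256,
512], stride 2 in the first convolution, hybrid pooling (max pooling
after blocks 1-4, adaptive average pooling to 8 time steps after block
5), and a 1024 -> 256 -> 1 fully connected head emitting a single
fetal-relatedness logit. With batch normalization this totals
5,905,793 trainable scalars, i.e. 5.91 M.

Training follows the published protocol: Adam (lr 1e-4, weight decay
5e-4), batch 64, binary cross-entropy with logits, 60 epochs, training
negatives subsampled to about twice the positives, leave-one-subject-
out folds repeated over independent seeds, AUC per held-out subject
with a 0.5 fallback for single-class validation sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .eemd import IMFSet
from .labeling import LabeledIMF

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "FoldResult",
    "ModelHandle",
    "build_classifier",
    "count_parameters",
    "resample_to_input_len",
    "score_imfs",
    "train_fold",
    "roc_auc_safe",
    "loso_cv",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture description for the IMF scorer."""

    kernel_sizes: Tuple[int, ...] = (31, 21, 15, 11, 7)
    channels: Tuple[int, ...] = (32, 64, 128, 256, 512)
    first_stride: int = 2
    pooling: str = "hybrid"  # hybrid | pure_max | pure_adaptive
    adaptive_out_len: int = 8
    fc_dims: Tuple[int, ...] = (1024, 256, 1)
    dropout: float = 0.5
    input_len: int = 10000

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != 5 or len(self.channels) != 5:
            raise ValueError("kernel_sizes and channels must both have 5 entries")
        if self.fc_dims[-1] != 1:
            raise ValueError("fc_dims must end with an output dimension of 1")
        if self.pooling not in ("hybrid", "pure_max", "pure_adaptive"):
            raise ValueError(f"unknown pooling mode: {self.pooling!r}")

    @staticmethod
    def smoke(input_len: int = 1250) -> "ClassifierSpec":
        """A slimmed desk-scale variant of the same five-block family."""
        return ClassifierSpec(
            channels=(8, 16, 32, 64, 64),
            fc_dims=(256, 64, 1),
            dropout=0.3,
            input_len=input_len,
        )


@dataclass
class ModelHandle:
    """A built (possibly trained) scorer with its spec."""

    spec: ClassifierSpec
    net: nn.Sequential


def _conv_output_len(spec: ClassifierSpec) -> int:
    """Temporal length entering the flatten stage."""
    L = spec.input_len
    for b in range(5):
        stride = spec.first_stride if b == 0 else 1
        L = (L + stride - 1) // stride  # "same" convolution
        if spec.pooling == "hybrid":
            L = L // 2 if b < 4 else spec.adaptive_out_len
        elif spec.pooling == "pure_max":
            L = L // 2
        else:  # pure_adaptive
            L = L // 2 if b < 4 else spec.adaptive_out_len
    return L


def build_classifier(spec: ClassifierSpec = ClassifierSpec(), seed: int = 0) -> ModelHandle:
    """Instantiate the network with seeded Kaiming initialization."""
    rng = np.random.default_rng(seed)
    layers: List[nn._Layer] = []
    c_prev = 1
    for b in range(5):
        layers.append(
            nn.Conv1d(
                c_prev,
                spec.channels[b],
                spec.kernel_sizes[b],
                stride=spec.first_stride if b == 0 else 1,
                rng=rng,
            )
        )
        layers.append(nn.BatchNorm1d(spec.channels[b]))
        layers.append(nn.ReLU())
        if spec.pooling == "hybrid":
            layers.append(nn.MaxPool1d(2) if b < 4 else nn.AdaptiveAvgPool1d(spec.adaptive_out_len))
        elif spec.pooling == "pure_max":
            layers.append(nn.MaxPool1d(2))
        else:  # pure_adaptive: average pooling throughout
            layers.append(nn.AvgPool1d(2) if b < 4 else nn.AdaptiveAvgPool1d(spec.adaptive_out_len))
        c_prev = spec.channels[b]
    layers.append(nn.Flatten())
    d_prev = spec.channels[-1] * _conv_output_len(spec)
    for i, d in enumerate(spec.fc_dims):
        layers.append(nn.Linear(d_prev, d, rng=rng))
        if i < len(spec.fc_dims) - 1:
            layers.append(nn.ReLU())
            layers.append(nn.Dropout(spec.dropout, rng=rng))
        d_prev = d
    return ModelHandle(spec=spec, net=nn.Sequential(layers))


def count_parameters(model: ModelHandle) -> int:
    """Number of trainable scalars (conv/linear weights and biases plus
    batch-norm scale and shift)."""
    return model.net.n_parameters()


def resample_to_input_len(imf: np.ndarray, input_len: int = 10000) -> np.ndarray:
    """Resample an IMF to the classifier's fixed input length.

    Polyphase resampling when the rate ratio reduces to small integers,
    linear interpolation otherwise. The caller keeps the original
    sequence for reconstruction; only the scorer sees this copy.
    """
    from scipy.signal import resample_poly

    x = np.asarray(imf, dtype=np.float64)
    if x.size < 16:
        raise ValueError("IMF too short to resample")
    if x.size == input_len:
        return x
    g = gcd(input_len, x.size)
    up, down = input_len // g, x.size // g
    if max(up, down) <= 64:
        y = resample_poly(x, up, down)
        if y.size != input_len:  # guard against off-by-one at odd ratios
            y = np.interp(
                np.linspace(0, y.size - 1, input_len), np.arange(y.size), y
            )
        return y
    return np.interp(np.linspace(0, x.size - 1, input_len), np.arange(x.size), x)


def _prepare_batch(waveforms: Sequence[np.ndarray], input_len: int) -> np.ndarray:
    """z-score each IMF and stack as a (batch, 1, input_len) tensor."""
    out = np.empty((len(waveforms), 1, input_len))
    for i, w in enumerate(waveforms):
        w = resample_to_input_len(w, input_len)
        sd = np.std(w)
        out[i, 0] = (w - np.mean(w)) / (sd if sd > 0 else 1.0)
    return out


def score_imfs(model: ModelHandle, imfs: IMFSet | Sequence[np.ndarray]) -> np.ndarray:
    """Fetal-relatedness probability per IMF (sigmoid of the logit)."""
    waveforms = imfs.imfs if isinstance(imfs, IMFSet) else list(imfs)
    if len(waveforms) == 0:
        return np.empty(0)
    x = _prepare_batch(list(waveforms), model.spec.input_len)
    model.net.set_mode(False)
    logits = model.net.forward(x)[:, 0]
    return nn.sigmoid(logits)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 5e-4
    batch_train: int = 64
    batch_val: int = 128
    epochs: int = 60
    runs: int = 3
    neg_pos_ratio: float = 2.0
    seeds: Tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if self.runs != len(self.seeds):
            raise ValueError("runs must equal len(seeds)")
        if min(self.lr, self.weight_decay, self.batch_train, self.epochs) <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class FoldResult:
    held_out_subject: str
    auc_per_run: List[float]
    n_val_imfs: int
    n_val_pos: int


def _balance_2to1(
    rows: List[LabeledIMF], ratio: float, rng: np.random.Generator
) -> List[LabeledIMF]:
    pos = [r for r in rows if r.label == 1]
    neg = [r for r in rows if r.label == 0]
    n_keep = int(round(ratio * len(pos)))
    if len(neg) > n_keep:
        idx = rng.choice(len(neg), size=n_keep, replace=False)
        neg = [neg[i] for i in sorted(idx)]
    return pos + neg


def train_fold(
    train_rows: List[LabeledIMF],
    cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
    spec: ClassifierSpec = ClassifierSpec(),
) -> ModelHandle:
    """Train one scorer on the given rows (one LOSO fold's training set).

    Negatives are subsampled once per fold (without replacement) to
    ``neg_pos_ratio`` times the positives; minibatches are reshuffled
    each epoch from the fold seed. Deterministic per (rows, cfg, seed).
    """
    labels = [r.label for r in train_rows]
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    # canonical row order: results depend only on the set of rows, not
    # on the order the caller assembled them in
    train_rows = sorted(
        train_rows, key=lambda r: (r.subject_id, r.segment_index, r.imf_index)
    )
    rng = np.random.default_rng(seed)
    rows = _balance_2to1(train_rows, cfg.neg_pos_ratio, rng)
    x = _prepare_batch([r.waveform for r in rows], spec.input_len)
    y = np.array([r.label for r in rows], dtype=np.float64)

    model = build_classifier(spec, seed=seed)
    opt = nn.Adam(model.net.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        model.net.set_mode(True)
        for lo in range(0, n, cfg.batch_train):
            sel = order[lo : lo + cfg.batch_train]
            logits = model.net.forward(x[sel])[:, 0]
            _, dlogits = nn.bce_with_logits(logits, y[sel])
            model.net.zero_grad()
            model.net.backward(dlogits[:, None])
            opt.step()
    model.net.set_mode(False)
    return model


def roc_auc_safe(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC with the single-class fallback pinned to 0.5."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.size == 0 or y.size != s.size:
        raise ValueError("labels and scores must be equal-length and non-empty")
    if len(np.unique(y)) < 2:
        return 0.5
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, s))


def loso_cv(
    dataset: List[LabeledIMF],
    cfg: TrainConfig = TrainConfig(),
    spec: ClassifierSpec = ClassifierSpec(),
    return_models: bool = False,
):
    """Leave-one-subject-out cross-validation of the IMF scorer.

    For every subject: hold out all of their IMFs, train ``cfg.runs``
    models with ``cfg.seeds`` on the rest, and evaluate each on the
    held-out IMFs with :func:`roc_auc_safe`. Returns the per-fold
    results (and, optionally, the first-run model per fold so the
    extraction pipeline can score a subject with a model that never saw
    that subject).
    """
    subjects = sorted({r.subject_id for r in dataset})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    results: List[FoldResult] = []
    models = {}
    for subject in subjects:
        val = [r for r in dataset if r.subject_id == subject]
        train = [r for r in dataset if r.subject_id != subject]
        if not val:
            continue
        aucs = []
        for run, seed in enumerate(cfg.seeds):
            model = train_fold(train, cfg, seed=seed, spec=spec)
            scores = score_imfs(model, [r.waveform for r in val])
            aucs.append(roc_auc_safe([r.label for r in val], scores))
            if run == 0:
                models[subject] = model
        results.append(
            FoldResult(
                held_out_subject=subject,
                auc_per_run=aucs,
                n_val_imfs=len(val),
                n_val_pos=sum(r.label for r in val),
            )
        )
    if return_models:
        return results, models
    return results
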