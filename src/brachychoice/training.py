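"""Training: loss, balanced sampling, augmentation, schedules, grouped CV.

The loss is binary cross-entropy with an L1 penalty on the network weights,

    L = -(1/N) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
        + lambda * sum_j |W_j|,

where y_i = 1 marks a Syed insertion and p_i is the network's suitability
score.  The L1 term enforces sparsity to counter the small-cohort setting.

Class imbalance is handled by balanced patient-level sampling: each batch
slot independently draws a class with probability 0.5, then a uniform
patient of that class, then a uniform insertion of that patient.
Augmentation is anatomically constrained: with probability 0.75 a sample is
augmented (equal chance of a translation or a rotation of up to 10 degrees
about the superior-inferior axis), followed by an independent left-right
flip with probability 0.5; no deformation is ever applied, since absolute
volume and distance information drives applicator choice.  Cross-validation
splits at the patient level so correlated insertions never straddle the
train/validation boundary.

The model-fitting surface follows the statsmodels idiom: build a
:class:`SuitabilityModel` from insertion records, call :meth:`fit` and get
back a :class:`TrainingResults` carrying the trained network, per-epoch
history, predictions, and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .encode import InputMode, ModelInput
from .errors import ClassMissing, FoldError, TrainingDiverged
from .network import Network, NetworkSpec, build_network, classify
from .structures import SYED, TANDO

__all__ = [
    "InsertionRecord",
    "TrainingConfig",
    "FoldAssignment",
    "bce_l1_loss",
    "sample_batch",
    "augment",
    "lr_at",
    "make_folds",
    "SuitabilityModel",
    "TrainingResults",
    "CrossValidationResults",
    "cross_validate",
    "summarize_folds",
]


@dataclass
class InsertionRecord:
    """One applicator insertion: its encoded input and ground-truth label."""

    patient_id: str
    insertion_id: str
    input: ModelInput
    y: int  # 1 Syed, 0 T&O

    def __post_init__(self):
        if self.y not in (0, 1):
            raise ValueError("label must be 0 (T&O) or 1 (Syed)")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters; defaults are the tuned full-scale values.

    ``lambda_l1`` 0.03, learning rate 0.001 decaying by 0.93 every 200
    batches (staircase), dropout 10%, 400 epochs of 40 batches (50 for
    final full-cohort training) of 8 samples.
    """

    lambda_l1: float = 0.03
    lr0: float = 0.001
    lr_decay: float = 0.93
    decay_every: int = 200
    dropout: float = 0.10
    epochs: int = 400
    batch_size: int = 8
    batches_per_epoch: int = 40
    augment_prob: float = 0.75
    flip_prob: float = 0.5
    max_rotation_deg: float = 10.0
    max_translation_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("lambda_l1", "lr0", "lr_decay", "dropout", "augment_prob", "flip_prob"):
            v = getattr(self, name)
            if name in ("dropout", "augment_prob", "flip_prob", "lr_decay") and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.batch_size <= 0 or self.epochs < 0 or self.batches_per_epoch <= 0:
            raise ValueError("epochs/batch sizes must be positive")


@dataclass
class FoldAssignment:
    """patient_id -> fold index; every insertion of a patient shares a fold."""

    mapping: dict
    k: int

    def fold_of(self, patient_id) -> int:
        return self.mapping[patient_id]

    def patients_in(self, fold: int):
        return [p for p, f in self.mapping.items() if f == fold]


# ---------------------------------------------------------------------------
# loss / schedule
# ---------------------------------------------------------------------------

_EPS = np.finfo(float).eps


def bce_l1_loss(scores, labels, weights=None, lambda_l1: float = 0.0) -> float:
    """Binary cross-entropy plus lambda * sum |W_j|.

    ``weights`` is any iterable of parameter arrays (or a flat vector);
    scores at exactly 0 or 1 are clamped to machine epsilon with a warning.
    """
    p = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("scores at 0 or 1 clamped to machine epsilon", stacklevel=2)
        p = np.clip(p, _EPS, 1 - _EPS)
    bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    l1 = 0.0
    if weights is not None and lambda_l1 != 0.0:
        arrays = [np.asarray(w) for w in (weights if not np.isscalar(weights) else [weights])]
        l1 = lambda_l1 * sum(float(np.abs(a).sum()) for a in arrays)
    return float(bce + l1)


def lr_at(step: int, config: TrainingConfig) -> float:
    """Staircase-decayed learning rate at a (0-based) global batch index."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return config.lr0 * config.lr_decay ** (step // config.decay_every)


# ---------------------------------------------------------------------------
# sampling / folds
# ---------------------------------------------------------------------------


def _group_by_class_and_patient(records):
    groups = {SYED: {}, TANDO: {}}
    for rec in records:
        groups[rec.y].setdefault(rec.patient_id, []).append(rec)
    return groups


def sample_batch(records, n: int, rng: np.random.Generator):
    """Balanced batch: class w.p. 0.5, then uniform patient, then insertion."""
    groups = _group_by_class_and_patient(records)
    for cls in (SYED, TANDO):
        if not groups[cls]:
            raise ClassMissing(f"no patients with label {cls} to sample from")
    patients = {cls: sorted(groups[cls]) for cls in (SYED, TANDO)}
    batch = []
    for _ in range(n):
        cls = SYED if rng.random() < 0.5 else TANDO
        pid = patients[cls][rng.integers(len(patients[cls]))]
        insertions = groups[cls][pid]
        batch.append(insertions[rng.integers(len(insertions))])
    return batch


def make_folds(records, k: int = 5, rng: np.random.Generator | None = None) -> FoldAssignment:
    """Patient-level k-fold partition, stratified by class where possible."""
    rng = rng or np.random.default_rng(0)
    label_of = {}
    for rec in records:
        label_of.setdefault(rec.patient_id, rec.y)
    patients = sorted(label_of)
    if len(patients) < k:
        raise FoldError(f"{len(patients)} patients cannot fill {k} folds")
    assignment = {}
    start = 0  # continue round-robin across classes to keep fold sizes within 1
    for cls in (SYED, TANDO):
        cls_patients = [p for p in patients if label_of[p] == cls]
        order = rng.permutation(len(cls_patients))
        for i, j in enumerate(order):
            assignment[cls_patients[j]] = (start + i) % k
        start += len(cls_patients)
    return FoldAssignment(assignment, k)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _rigid_transform_channels(channels, angle_deg=0.0, shift_vox=(0.0, 0.0, 0.0)):
    """Nearest-neighbor rigid transport of all channels about the SI axis.

    Labels are categorical and the distance channels are invariant under a
    rigid motion applied jointly to the anatomy and the tandem, so every
    channel is transported rigidly (values unchanged, positions moved).
    """
    out = np.empty_like(channels)
    rot = math.radians(angle_deg)
    c, s = math.cos(rot), math.sin(rot)
    # rotation in the (y, x) plane about the volume center, then translation
    matrix = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    center = (np.asarray(channels.shape[1:]) - 1) / 2.0
    offset = center - matrix @ center - matrix @ np.asarray(shift_vox)
    for ci in range(channels.shape[0]):
        out[ci] = ndimage.affine_transform(
            channels[ci], matrix, offset=offset, order=0, cval=0.0, prefilter=False
        )
    return out


def draw_augmentation(rng: np.random.Generator, config: TrainingConfig) -> dict:
    """Sample one augmentation decision.

    Returns a dict with ``augmented`` (prob ``augment_prob``), the chosen
    ``kind`` ("translate" or "rotate", equally likely), its magnitude, and
    ``flip`` (prob ``flip_prob``, conditional on having been augmented).
    """
    if rng.random() >= config.augment_prob:
        return {"augmented": False, "kind": None, "flip": False}
    if rng.random() < 0.5:
        shift_mm = rng.uniform(-config.max_translation_mm, config.max_translation_mm, size=3)
        decision = {"augmented": True, "kind": "translate", "shift_mm": shift_mm}
    else:
        angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        decision = {"augmented": True, "kind": "rotate", "angle_deg": angle}
    decision["flip"] = bool(rng.random() < config.flip_prob)
    return decision


def augment(model_input: ModelInput, rng: np.random.Generator, config: TrainingConfig) -> ModelInput:
    """Anatomically constrained augmentation of one sample.

    With probability ``1 - augment_prob`` the sample is returned unchanged.
    Otherwise a translation or a rotation is applied (equally likely,
    uniform magnitude within bounds), followed by an independent left-right
    flip with probability ``flip_prob``.
    """
    decision = draw_augmentation(rng, config)
    channels = model_input.channels
    if decision["augmented"]:
        if decision["kind"] == "translate":
            shift_vox = decision["shift_mm"] / np.asarray(model_input.grid.spacing)
            channels = _rigid_transform_channels(channels, shift_vox=shift_vox)
        elif decision["angle_deg"] != 0.0:
            channels = _rigid_transform_channels(channels, angle_deg=decision["angle_deg"])
        if decision["flip"]:
            channels = np.flip(channels, axis=3).copy()  # left-right axis
    return ModelInput(model_input.grid, channels, model_input.mode)


def flip_lr(model_input: ModelInput) -> ModelInput:
    """Left-right mirror of all channels (exact involution)."""
    return ModelInput(
        model_input.grid, np.flip(model_input.channels, axis=3).copy(), model_input.mode
    )


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class _Adam:
    """Adam with the staircase learning-rate schedule of the config."""

    def __init__(self, network: Network, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for _, _, p in network.parameters()]
        self.v = [np.zeros_like(p) for _, _, p in network.parameters()]
        self.t = 0

    def step(self, network: Network, lr: float):
        self.t += 1
        for i, (layer, key, p) in enumerate(network.parameters()):
            g = layer.grads[key]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class SuitabilityModel:
    """The applicator-suitability classifier bound to a training cohort.

    Parameters
    ----------
    records : sequence of InsertionRecord
        Encoded insertions with patient ids and ground-truth labels.
    spec : NetworkSpec, optional
        Architecture; defaults to the production 3-channel network (or its
        1-channel variant when the records are mask-only).
    config : TrainingConfig, optional
        Hyperparameters; defaults to the tuned full-scale values.
    """

    def __init__(self, records, spec: NetworkSpec | None = None, config: TrainingConfig | None = None):
        self.records = list(records)
        if not self.records:
            raise ValueError("no records")
        if spec is None:
            mode = self.records[0].input.mode
            spec = NetworkSpec.default(in_channels=1 if mode == InputMode.MASK_ONLY else 3)
        self.spec = spec
        self.config = config or TrainingConfig()
        if self.spec.dropout_rate != self.config.dropout:
            self.spec = replace(self.spec, dropout_rate=self.config.dropout)

    def fit(self, verbose: bool = False) -> "TrainingResults":
        """Run the full optimization loop; reproducible under the seed."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = build_network(self.spec, seed=cfg.seed)
        opt = _Adam(net)
        history = []
        step = 0
        for epoch in range(cfg.epochs):
            ep_loss, ep_correct, ep_n = 0.0, 0, 0
            for _ in range(cfg.batches_per_epoch):
                batch = sample_batch(self.records, cfg.batch_size, rng)
                xs = np.stack([augment(r.input, rng, cfg).channels for r in batch])
                ys = np.array([r.y for r in batch], dtype=float)
                p = net.forward(xs, training=True, rng=rng)
                loss = bce_l1_loss(
                    np.clip(p, _EPS, 1 - _EPS), ys, lambda_l1=0.0
                ) + cfg.lambda_l1 * net.l1_norm()
                if not np.isfinite(loss):
                    raise TrainingDiverged(f"non-finite loss at step {step}")
                net.backward_from_logits((p - ys) / len(ys))
                if cfg.lambda_l1 != 0.0:
                    for layer, key, param in net.parameters():
                        layer.grads[key] = layer.grads[key] + cfg.lambda_l1 * np.sign(param)
                opt.step(net, lr_at(step, cfg))
                step += 1
                ep_loss += loss
                ep_correct += int((classify(p) == ys).sum())
                ep_n += len(ys)
            history.append(
                {
                    "epoch": epoch,
                    "loss": ep_loss / cfg.batches_per_epoch,
                    "accuracy": ep_correct / ep_n,
                    "lr": lr_at(step - 1, cfg),
                }
            )
            if verbose:
                h = history[-1]
                print(f"epoch {epoch:4d}  loss {h['loss']:.4f}  acc {h['accuracy']:.3f}")
        return TrainingResults(self, net, pd.DataFrame(history))


@dataclass
class TrainingResults:
    """Fitted state: trained network, history, and evaluation helpers."""

    model: SuitabilityModel
    network: Network
    history: pd.DataFrame

    def predict_scores(self, records_or_inputs) -> np.ndarray:
        items = [getattr(r, "input", r) for r in records_or_inputs]
        return self.network.predict(items, batch_size=self.model.config.batch_size)

    def predict_labels(self, records_or_inputs, threshold: float = 0.5) -> np.ndarray:
        return classify(self.predict_scores(records_or_inputs), threshold)

    def accuracy(self, records, threshold: float = 0.5) -> float:
        records = list(records)
        pred = self.predict_labels(records, threshold)
        truth = np.array([r.y for r in records])
        return float((pred == truth).mean())

    def summary(self) -> str:
        from .network import count_parameters

        cfg = self.model.config
        last = self.history.iloc[-1] if len(self.history) else None
        lines = [
            "Suitability network training results",
            "====================================",
            f"parameters:            {count_parameters(self.network)}",
            f"input channels:        {self.network.spec.in_channels}",
            f"records:               {len(self.model.records)}",
            f"epochs x batches:      {cfg.epochs} x {cfg.batches_per_epoch} (batch {cfg.batch_size})",
            f"lambda_L1 / dropout:   {cfg.lambda_l1} / {cfg.dropout}",
            f"lr schedule:           {cfg.lr0} x {cfg.lr_decay}^(step/{cfg.decay_every})",
        ]
        if last is not None:
            lines.append(f"final train loss/acc:  {last['loss']:.4f} / {last['accuracy']:.3f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def summarize_folds(values) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) across folds."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


@dataclass
class CrossValidationResults:
    per_fold: pd.DataFrame
    folds: FoldAssignment
    fold_results: list = field(default_factory=list)

    @property
    def mean_val_accuracy(self) -> float:
        return float(self.per_fold["val_accuracy"].mean())

    @property
    def sd_val_accuracy(self) -> float:
        return float(self.per_fold["val_accuracy"].std(ddof=1))

    def summary(self) -> str:
        mean, sd = summarize_folds(self.per_fold["val_accuracy"] * 100)
        out = ["Grouped cross-validation (validation accuracy per insertion)"]
        out.append(self.per_fold.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        out.append(f"mean +/- sd validation accuracy: {mean:.1f} +/- {sd:.1f} %")
        return "\n".join(out)


def cross_validate(
    records,
    spec: NetworkSpec | None = None,
    config: TrainingConfig | None = None,
    folds: FoldAssignment | None = None,
    k: int = 5,
    keep_networks: bool = False,
    verbose: bool = False,
) -> CrossValidationResults:
    """Patient-grouped k-fold cross-validation of the network.

    Validation accuracy is defined per insertion.  Raises FoldError for
    fewer patients than folds; no validation insertion's patient ever
    appears in its fold's training set.
    """
    records = list(records)
    config = config or TrainingConfig()
    if folds is None:
        folds = make_folds(records, k=k, rng=np.random.default_rng(config.seed))
    rows = []
    nets = []
    for fold in range(folds.k):
        val = [r for r in records if folds.fold_of(r.patient_id) == fold]
        train = [r for r in records if folds.fold_of(r.patient_id) != fold]
        assert not {r.patient_id for r in val} & {r.patient_id for r in train}
        res = SuitabilityModel(train, spec=spec, config=config).fit(verbose=verbose)
        p_train = res.predict_scores(train)
        p_val = res.predict_scores(val)
        y_train = np.array([r.y for r in train], dtype=float)
        y_val = np.array([r.y for r in val], dtype=float)
        rows.append(
            {
                "fold": fold,
                "n_val": len(val),
                "train_loss": bce_l1_loss(np.clip(p_train, _EPS, 1 - _EPS), y_train),
                "train_accuracy": float((classify(p_train) == y_train).mean()),
                "val_loss": bce_l1_loss(np.clip(p_val, _EPS, 1 - _EPS), y_val),
                "val_accuracy": float((classify(p_val) == y_val).mean()),
            }
        )
        if keep_networks:
            nets.append(res)
        if verbose:
            print(f"fold {fold}: val acc {rows[-1]['val_accuracy']:.3f}")
    return CrossValidationResults(pd.DataFrame(rows), folds, nets)
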