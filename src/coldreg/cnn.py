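"""Promoter-sequence CNN: architecture grid, training and evaluation.

The classifier maps a one-hot (L, 4) window stack to P(non-DEG) through
[conv -> ReLU -> max-pool] x cl -> flatten -> [dense -> ReLU -> dropout] x
(dl - 1) -> 1-unit sigmoid, trained with Adam on binary cross-entropy.
Following the labelling convention (DEG = 0, non-DEG = 1), the DEG score
of a record is 1 - sigmoid(logit); prAUC is reported with the DEG
(minority) class as positive by default, with the opposite polarity kept
alongside it.

Note on layer counting: ``n_dense_layers`` counts the output layer, so
``n_dense_layers=3`` means two hidden dense layers plus the sigmoid output
(matching how grids of this family of models are usually tabulated).

Model selection during training maximises validation prAUC: after every
epoch the validation set (never oversampled) is scored and the weights of
the best epoch are restored at the end.
"""

from __future__ import annotations

import itertools
import json
import os
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .datasets import DEG_CLASS, LabeledSet


@dataclass(frozen=True)
class HyperParams:
    """One point of the architecture grid.

    cl = n_conv_layers, fl = conv_filters[0], pl = pool_stride,
    dl = n_dense_layers (output layer included), du = dense_units,
    dr = dropout_rate.
    """

    n_conv_layers: int = 1
    conv_filters: tuple[int, ...] = (64,)
    conv_width: int = 4
    pool_width: int = 4
    pool_stride: int = 4
    n_dense_layers: int = 2
    dense_units: tuple[int, ...] = (64,)
    dropout_rate: float = 0.25
    learning_rate: float = 0.0001
    epochs: int = 50

    def __post_init__(self) -> None:
        if len(self.conv_filters) != self.n_conv_layers:
            raise ValueError(
                f"need {self.n_conv_layers} conv_filters entries, got {len(self.conv_filters)}"
            )
        if len(self.dense_units) != self.n_dense_layers - 1:
            raise ValueError(
                "dense_units must list the hidden dense layers "
                f"(n_dense_layers - 1 = {self.n_dense_layers - 1}), got {len(self.dense_units)}"
            )
        for name in ("n_conv_layers", "conv_width", "pool_width", "pool_stride",
                     "n_dense_layers", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        d["dense_units"] = tuple(d["dense_units"])
        return cls(**d)


#: The reduced default grid: the hyperparameter values observed across the
#: best-model table of each training variant.
DEFAULT_GRID_VALUES = {
    "n_conv_layers": [1, 2, 3],
    "conv_filters": [64, 128],
    "conv_width": [4, 8],
    "pool_width": [4, 8],
    "pool_stride": [4, 8],
    "n_dense_layers": [2, 3],
    "dense_units": [64, 128],
    "dropout_rate": [0.1, 0.25],
}


def build_grid(values: dict | None = None, learning_rate: float = 0.0001,
               epochs: int = 50) -> list[HyperParams]:
    """Cartesian product of per-hyperparameter value lists.

    ``conv_filters``/``dense_units`` entries are scalars applied to every
    conv/hidden-dense layer of the combination.
    """
    v = dict(DEFAULT_GRID_VALUES)
    if values:
        v.update(values)
    grid = []
    for cl, f, cw, pw, ps, dl, du, dr in itertools.product(
        v["n_conv_layers"], v["conv_filters"], v["conv_width"], v["pool_width"],
        v["pool_stride"], v["n_dense_layers"], v["dense_units"], v["dropout_rate"],
    ):
        grid.append(
            HyperParams(
                n_conv_layers=cl, conv_filters=(f,) * cl, conv_width=cw,
                pool_width=pw, pool_stride=ps, n_dense_layers=dl,
                dense_units=(du,) * (dl - 1), dropout_rate=dr,
                learning_rate=learning_rate, epochs=epochs,
            )
        )
    return grid


def build_model(hp: HyperParams, input_length: int, n_channels: int = 4,
                seed: int = 0) -> nn.Sequential:
    """Instantiate the architecture; raises ArchitectureError when pooling
    collapses the sequence to nothing."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    length, channels = input_length, n_channels
    for li in range(hp.n_conv_layers):
        layers.append(nn.Conv1D(channels, hp.conv_filters[li], hp.conv_width, rng))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D(hp.pool_width, hp.pool_stride))
        length = length - hp.conv_width + 1
        if length < hp.pool_width:
            raise nn.ArchitectureError(
                f"conv block {li + 1}: pooled length collapses to zero "
                f"(length {length} < pool width {hp.pool_width})"
            )
        length = (length - hp.pool_width) // hp.pool_stride + 1
        channels = hp.conv_filters[li]
    layers.append(nn.Flatten())
    units = length * channels
    for du in hp.dense_units:
        layers.append(nn.Dense(units, du, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(hp.dropout_rate, rng))
        units = du
    layers.append(nn.Dense(units, 1, rng))
    return nn.Sequential(layers, (input_length, n_channels))


# ---------------------------------------------------------------------------
# metrics


def prauc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration
    (sum over thresholds of precision x recall-increment), positives = 1.

    ``labels`` are 1 for the positive class; ``scores`` rank positives high.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("prAUC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    tp = np.cumsum(l)
    fp = np.cumsum(~l)
    # evaluate only at the last index of each tied-score block
    distinct = np.nonzero(np.diff(s, append=-np.inf))[0]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    return float(np.sum(np.diff(recall, prepend=0.0) * precision))


def deg_scores(model: nn.Sequential, X: np.ndarray) -> np.ndarray:
    """Score of being a DEG (class 0): 1 - P(label = 1)."""
    return 1.0 - model.predict_proba(X)


def prauc_for(model: nn.Sequential, data: LabeledSet, positive: str = "deg") -> float:
    p1 = model.predict_proba(data.X)
    y = data.y
    if positive == "deg":
        return prauc(1.0 - p1, y == DEG_CLASS)
    return prauc(p1, y == 1)


def class_difference(acc_class_deg: float, acc_class_non: float) -> float:
    """Absolute difference of the two within-class accuracies."""
    return abs(acc_class_deg - acc_class_non)


def overfit_flag(prauc_test: float, acc_class_deg: float, acc_class_non: float) -> str:
    """"to_deg"/"to_non" when the test prAUC is extreme (> 0.8 or < 0.2),
    i.e. the model has effectively collapsed onto one class; else "none"."""
    if prauc_test > 0.8 or prauc_test < 0.2:
        return "to_deg" if acc_class_deg >= acc_class_non else "to_non"
    return "none"


def evaluate(model: nn.Sequential, test_set: LabeledSet,
             positive: str = "deg") -> dict[str, float]:
    """Test-set metrics: prAUC (both polarities), within-class accuracies
    at the 0.5 threshold, and their absolute difference."""
    y = test_set.y
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes")
    p1 = model.predict_proba(test_set.X)
    pred = (p1 >= 0.5).astype(np.int8)
    acc_deg = float(np.mean(pred[y == DEG_CLASS] == DEG_CLASS))
    acc_non = float(np.mean(pred[y == 1] == 1))
    pr_deg = prauc(1.0 - p1, y == DEG_CLASS)
    pr_non = prauc(p1, y == 1)
    main, alt = (pr_deg, pr_non) if positive == "deg" else (pr_non, pr_deg)
    return {
        "prauc_test": main,
        "prauc_test_alt": alt,
        "acc_class_deg": acc_deg,
        "acc_class_non": acc_non,
        "class_diff": class_difference(acc_deg, acc_non),
    }


# ---------------------------------------------------------------------------
# model record


@dataclass
class ModelRecord:
    """Everything measured for one trained grid point."""

    hyperparams: HyperParams
    loss: float = np.nan
    accuracy: float = np.nan
    prauc_train: float = np.nan
    prauc_validation: float = np.nan
    prauc_test: float = np.nan
    prauc_test_alt: float = np.nan
    loss_validation: float = np.nan
    acc_class_deg: float = np.nan
    acc_class_non: float = np.nan
    class_diff: float = np.nan
    best_epoch: int = 0
    overfit: str = "none"
    error: str | None = None
    variant: str = ""

    # flat hyperparameter accessors used by the effect models
    @property
    def cl(self) -> int:
        return self.hyperparams.n_conv_layers

    @property
    def fl(self) -> int:
        return self.hyperparams.conv_filters[0]

    @property
    def pl(self) -> int:
        return self.hyperparams.pool_stride

    @property
    def dl(self) -> int:
        return self.hyperparams.n_dense_layers

    @property
    def du(self) -> int:
        return self.hyperparams.dense_units[0] if self.hyperparams.dense_units else 0

    @property
    def dr(self) -> float:
        return self.hyperparams.dropout_rate

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hyperparams"] = self.hyperparams.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelRecord":
        d = dict(d)
        d["hyperparams"] = HyperParams.from_dict(d["hyperparams"])
        return cls(**d)


# ---------------------------------------------------------------------------
# training


def train(
    model: nn.Sequential,
    train_set: LabeledSet,
    validation_set: LabeledSet,
    hp: HyperParams,
    test_set: LabeledSet | None = None,
    seed: int = 0,
    batch_size: int = 64,
    positive: str = "deg",
    warmup_steps: int | None = None,
) -> ModelRecord:
    """Train with per-epoch validation-prAUC checkpointing.

    ``train_set`` is expected oversampled to 1:1; ``validation_set`` keeps
    the original class ratio. After the final epoch the weights of the
    best-validation-prAUC epoch are restored and all metrics are measured
    from that saved model.
    """
    if hp.epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    if warmup_steps is None:
        # a tenth of the run, capped: long enough to avoid the early
        # ReLU-collapse regime, short enough not to dominate small runs
        total = hp.epochs * max(1, -(-len(train_set) // batch_size))
        warmup_steps = min(100, max(1, total // 10))
    opt = nn.Adam(model, lr=hp.learning_rate, warmup_steps=warmup_steps)
    Xtr, ytr = train_set.X, train_set.y
    best = (-np.inf, 0, model.get_weights())
    for epoch in range(1, hp.epochs + 1):
        nn.train_epoch(model, opt, Xtr, ytr, rng, batch_size=batch_size)
        val_pr = prauc_for(model, validation_set, positive=positive)
        if val_pr > best[0]:
            best = (val_pr, epoch, model.get_weights())
    model.set_weights(best[2])

    rec = ModelRecord(hyperparams=hp, best_epoch=best[1], prauc_validation=best[0])
    tr_logits_p1 = model.predict_proba(Xtr)
    rec.loss = _bce(tr_logits_p1, ytr)
    rec.accuracy = float(np.mean((tr_logits_p1 >= 0.5) == (ytr == 1)))
    rec.prauc_train = prauc_for(model, train_set, positive=positive)
    va_p1 = model.predict_proba(validation_set.X)
    rec.loss_validation = _bce(va_p1, validation_set.y)
    if test_set is not None:
        m = evaluate(model, test_set, positive=positive)
        rec.prauc_test = m["prauc_test"]
        rec.prauc_test_alt = m["prauc_test_alt"]
        rec.acc_class_deg = m["acc_class_deg"]
        rec.acc_class_non = m["acc_class_non"]
        rec.class_diff = m["class_diff"]
        rec.overfit = overfit_flag(rec.prauc_test, rec.acc_class_deg, rec.acc_class_non)
    return rec


def _bce(p1: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p1, 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# the Model / Results surface


class SequenceCNN:
    """Model object: an architecture bound to an input length.

    ``fit`` trains on an (oversampled) training set with validation-based
    checkpointing and returns a :class:`CNNResults`.
    """

    def __init__(self, hyperparams: HyperParams, input_length: int,
                 n_channels: int = 4, seed: int = 0, positive: str = "deg"):
        self.hyperparams = hyperparams
        self.input_length = input_length
        self.n_channels = n_channels
        self.seed = seed
        self.positive = positive
        self.network = build_model(hyperparams, input_length, n_channels, seed=seed)

    def fit(self, train_set: LabeledSet, validation_set: LabeledSet,
            test_set: LabeledSet | None = None, batch_size: int = 64) -> "CNNResults":
        record = train(
            self.network, train_set, validation_set, self.hyperparams,
            test_set=test_set, seed=self.seed, batch_size=batch_size,
            positive=self.positive,
        )
        return CNNResults(self, record)


class CNNResults:
    """Results object carrying the trained network and its ModelRecord."""

    def __init__(self, model: SequenceCNN, record: ModelRecord):
        self.model = model
        self.record = record

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.network.predict_proba(X)

    def deg_scores(self, X: np.ndarray) -> np.ndarray:
        return deg_scores(self.model.network, X)

    def evaluate(self, test_set: LabeledSet) -> dict[str, float]:
        return evaluate(self.model.network, test_set, positive=self.model.positive)

    def summary(self) -> str:
        r, hp = self.record, self.record.hyperparams
        lines = [
            "Promoter-sequence CNN results",
            "=============================",
            f"conv layers: {hp.n_conv_layers}  filters: {hp.conv_filters}  width: {hp.conv_width}",
            f"pool width/stride: {hp.pool_width}/{hp.pool_stride}  "
            f"dense layers (incl. output): {hp.n_dense_layers}  units: {hp.dense_units}",
            f"dropout: {hp.dropout_rate}  lr: {hp.learning_rate}  epochs: {hp.epochs}",
            f"best epoch (validation prAUC): {r.best_epoch}",
            f"loss {r.loss:.4f}  accuracy {r.accuracy:.4f}",
            f"prAUC train {r.prauc_train:.4f}  validation {r.prauc_validation:.4f}  "
            f"test {r.prauc_test:.4f}",
            f"within-class accuracy: DEG {r.acc_class_deg:.4f}  non-DEG {r.acc_class_non:.4f}"
            f"  |diff| {r.class_diff:.4f}",
            f"overfit flag: {r.overfit}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# grid search, selection, permutation significance


def grid_search(
    grid: list[HyperParams],
    train_set: LabeledSet,
    validation_set: LabeledSet,
    test_set: LabeledSet,
    seed: int = 0,
    batch_size: int = 64,
    positive: str = "deg",
    checkpoint_dir: str | None = None,
    variant: str = "",
) -> list[ModelRecord]:
    """One ModelRecord per grid point; failures are recorded, not raised.

    With ``checkpoint_dir`` each finished combination is written to (and on
    restart read back from) a JSON file, making long searches resumable.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    records = []
    for i, hp in enumerate(grid):
        ck = os.path.join(checkpoint_dir, f"grid_{i:04d}.json") if checkpoint_dir else None
        if ck and os.path.exists(ck):
            with open(ck) as fh:
                records.append(ModelRecord.from_dict(json.load(fh)))
            continue
        # derive the combination's seed from its hyperparameters, not its grid
        # index, so identical combinations give identical records
        hp_seed = (
            seed * 1000003 + zlib.crc32(json.dumps(hp.to_dict(), sort_keys=True).encode())
        ) % (2**31)
        try:
            model = SequenceCNN(
                hp, train_set.X.shape[1], seed=hp_seed, positive=positive
            )
            rec = model.fit(train_set, validation_set, test_set, batch_size=batch_size).record
        except (nn.ArchitectureError, nn.TrainingError, ValueError) as err:
            rec = ModelRecord(hyperparams=hp, error=str(err))
        rec.variant = variant
        records.append(rec)
        if ck:
            os.makedirs(checkpoint_dir, exist_ok=True)
            with open(ck, "w") as fh:
                json.dump(rec.to_dict(), fh)
    return records


def summarize_grid(records: list[ModelRecord]) -> dict[str, float]:
    ok = [r for r in records if r.error is None]
    pr_tr = np.array([r.prauc_train for r in ok])
    pr_te = np.array([r.prauc_test for r in ok])
    return {
        "n": len(records),
        "n_failed": len(records) - len(ok),
        "median_prauc_train": float(np.median(pr_tr)) if ok else np.nan,
        "mean_prauc_train": float(np.mean(pr_tr)) if ok else np.nan,
        "median_prauc_test": float(np.median(pr_te)) if ok else np.nan,
        "mean_prauc_test": float(np.mean(pr_te)) if ok else np.nan,
        "overfit_fraction": float(np.mean([r.overfit != "none" for r in ok])) if ok else np.nan,
    }


def select_best(records: list[ModelRecord], prauc_min: float = 0.7) -> ModelRecord | None:
    """The record with the smallest class_diff among those with
    prauc_test >= prauc_min; ties go to the larger prAUC, then grid order.
    None when no record passes the filter."""
    if not records:
        raise ValueError("records must be nonempty")
    passing = [
        (r.class_diff, -r.prauc_test, i)
        for i, r in enumerate(records)
        if r.error is None and r.prauc_test >= prauc_min
    ]
    if not passing:
        return None
    _, _, i = min(passing)
    return records[i]


def permutation_significance(
    hp: HyperParams,
    train_set: LabeledSet,
    validation_set: LabeledSet,
    test_set: LabeledSet,
    observed_prauc: float,
    observed_diff: float,
    n_perm: int = 100,
    seed: int = 0,
    batch_size: int = 64,
    positive: str = "deg",
    oversample_after_permute: bool = True,
) -> float:
    """Label-permutation p-value for a selected architecture.

    Training+validation labels are shuffled jointly (test labels untouched),
    the architecture is retrained, and p = (# permuted runs with
    prauc_test >= observed AND class_diff <= observed) / n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    from .datasets import oversample as _oversample
    from dataclasses import replace as _replace

    rng = np.random.default_rng(seed)
    base = train_set.records + validation_set.records
    n_train = len(train_set.records)
    better = 0
    for b in range(n_perm):
        labels = np.array([r.label for r in base])
        rng.shuffle(labels)
        shuffled = [_replace(r, label=int(l)) for r, l in zip(base, labels)]
        tr = LabeledSet(shuffled[:n_train])
        va = LabeledSet(shuffled[n_train:])
        if len(set(labels[:n_train])) < 2 or len(set(labels[n_train:])) < 2:
            continue  # a degenerate shuffle cannot beat the observed model
        if oversample_after_permute:
            tr = _oversample(tr, seed=seed + 1000 + b)
        model = SequenceCNN(hp, tr.X.shape[1], seed=seed + b, positive=positive)
        rec = model.fit(tr, va, test_set, batch_size=batch_size).record
        if rec.prauc_test >= observed_prauc and rec.class_diff <= observed_diff:
            better += 1
    return better / n_perm
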