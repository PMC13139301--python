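"""Training, cross-validation, transfer learning and evaluation metrics.

Protocol: interactions are shuffled once and split into six parts — one
sixth held out as the common test set, the remaining five sixths forming
the 5 cross-validation folds.  Models are trained with the Adam optimizer
on a mean-squared-error loss, with early stopping on validation MSE.

Metrics on paired observed/predicted affinities (y, y_hat):

* MSE  = sum_i (y_i - yhat_i)^2 / m
* CI   = sum_{y_i > y_j} h(yhat_i - yhat_j) / Z, with h(x) = 1 if x > 0,
  0.5 if x = 0, 0 if x < 0, and Z the number of ordered pairs with
  y_i > y_j (pairwise ranking consistency).
* R^2  = 1 - sum (y - yhat)^2 / sum (y - ybar)^2
* PCC  = centered cross-moment of y and yhat over the product of their
  standard deviations (Pearson correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compound_features import (
    FeaturePostprocessor,
    SmilesVocabulary,
    build_vocabulary,
    compute_compound_descriptors,
    compute_ecfp4,
    encode_smiles,
    DEFAULT_COMPOUND_PROVIDER,
)
from .data_io import CPIDataset
from .model_core import FeatureBatch, FusionRegressor, ModelConfig, build_model
from .protein_features import (
    DEFAULT_PROTEIN_PROVIDER,
    compute_protein_descriptors,
    encode_sequence,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration and split plan
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 50
    patience: int = 5  # early-stop patience on validation MSE
    fine_tune_learning_rate: float = 1e-4
    seed: int = 0
    freeze: str = "none"  # "none" (default) or "local": freeze local heads in finetune

    def __post_init__(self):
        if self.learning_rate <= 0 or self.fine_tune_learning_rate < 0:
            raise ValueError("learning rates must be positive (fine-tune rate >= 0)")
        if self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.freeze not in ("none", "local"):
            raise ValueError("freeze must be 'none' or 'local'")


@dataclass
class SplitPlan:
    """One-sixth test split plus five CV folds over the remainder."""

    test_indices: np.ndarray
    folds: list[np.ndarray]

    def train_indices_for_fold(self, k: int) -> np.ndarray:
        return np.concatenate([f for i, f in enumerate(self.folds) if i != k])

    @property
    def non_test_indices(self) -> np.ndarray:
        return np.concatenate(self.folds)


def make_split(n_or_dataset, seed: int, n_folds: int = 5) -> SplitPlan:
    """Seeded uniform partition: |test| = floor(n/6), rest in 5 folds."""
    n = n_or_dataset if isinstance(n_or_dataset, (int, np.integer)) else n_or_dataset.n_interactions
    if n < 6:
        raise ValueError(f"need at least 6 interactions to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = n // 6
    return SplitPlan(
        test_indices=np.sort(order[:n_test]),
        folds=[np.sort(f) for f in np.array_split(order[n_test:], n_folds)],
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

class MetricUndefinedError(ValueError):
    pass


@dataclass
class MetricsReport:
    mse: float
    ci: float
    r2: float
    pcc: float
    per_fold: pd.DataFrame | None = None
    mean: dict | None = None
    std: dict | None = None

    def as_dict(self) -> dict:
        return {"mse": self.mse, "ci": self.ci, "r2": self.r2, "pcc": self.pcc}


def mean_squared_error(y: np.ndarray, y_hat: np.ndarray) -> float:
    return float(np.mean((np.asarray(y, float) - np.asarray(y_hat, float)) ** 2))


def concordance_index(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pairwise ranking consistency with half credit for tied predictions.

    Over all ordered pairs with y_i > y_j, the score is 1 when
    yhat_i > yhat_j, 0.5 when equal, 0 otherwise, normalized by the number
    Z of such pairs.  Undefined (raises) when y is all-tied.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    _check_pairs(y, y_hat)
    # vectorized over all ordered pairs; chunked to bound memory on large m
    total, z = 0.0, 0
    chunk = 2048
    for start in range(0, len(y), chunk):
        sl = slice(start, start + chunk)
        gt = y[sl, None] > y[None, :]
        d = y_hat[sl, None] - y_hat[None, :]
        h = np.where(d > 0, 1.0, np.where(d == 0, 0.5, 0.0))
        total += float(h[gt].sum())
        z += int(gt.sum())
    if z == 0:
        raise MetricUndefinedError("concordance index undefined: all observed values tied")
    return total / z


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    _check_pairs(y, y_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise MetricUndefinedError("R^2 undefined: observed values are constant")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def pearson_correlation(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    _check_pairs(y, y_hat)
    yc, pc = y - y.mean(), y_hat - y_hat.mean()
    denom = np.sqrt(np.sum(pc**2)) * np.sqrt(np.sum(yc**2))
    if denom == 0:
        raise MetricUndefinedError("PCC undefined: a vector is constant")
    return float(np.sum(pc * yc) / denom)


def _check_pairs(y: np.ndarray, y_hat: np.ndarray) -> None:
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError(f"paired vectors must be 1-D and equal length, got {y.shape} vs {y_hat.shape}")
    if len(y) < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.isfinite(y).all() and np.isfinite(y_hat).all()):
        raise ValueError("paired vectors must be finite")


def evaluate(y: np.ndarray, y_hat: np.ndarray) -> MetricsReport:
    """All four metrics on one paired prediction set."""
    return MetricsReport(
        mse=mean_squared_error(y, y_hat),
        ci=concordance_index(y, y_hat),
        r2=r_squared(y, y_hat),
        pcc=pearson_correlation(y, y_hat),
    )


# --------------------------------------------------------------------------
# featurization pipeline
# --------------------------------------------------------------------------

class CPIFeaturizer:
    """Turns a CPIDataset into aligned model inputs.

    Fitting builds the SMILES vocabulary and the two descriptor
    postprocessors from *training rows only*; entity-level raw features
    (encodings, fingerprints, raw descriptors) are cached per compound and
    protein so repeated transforms are cheap.
    """

    def __init__(self, compound_provider=None, protein_provider=None):
        self.compound_provider = compound_provider or DEFAULT_COMPOUND_PROVIDER
        self.protein_provider = protein_provider or DEFAULT_PROTEIN_PROVIDER
        self.vocab: SmilesVocabulary | None = None
        self.compound_pp: FeaturePostprocessor | None = None
        self.protein_pp: FeaturePostprocessor | None = None
        self._cache_key = None
        self._raw = None

    # -- raw per-entity features (independent of the split) --------------
    def _raw_features(self, dataset: CPIDataset) -> dict:
        if self._cache_key == id(dataset) and self._raw is not None:
            return self._raw
        comp_desc, comp_fp = {}, {}
        for c in dataset.compounds:
            comp_fp[c.compound_id] = compute_ecfp4(c.smiles, c.compound_id)
            comp_desc[c.compound_id] = compute_compound_descriptors(
                c.smiles, self.compound_provider, c.compound_id
            )
        prot_desc = {
            p.protein_id: compute_protein_descriptors(p.sequence, self.protein_provider)
            for p in dataset.proteins
        }
        prot_tok = {p.protein_id: encode_sequence(p.sequence) for p in dataset.proteins}
        self._raw = {
            "comp_fp": comp_fp, "comp_desc": comp_desc,
            "prot_desc": prot_desc, "prot_tok": prot_tok,
        }
        self._cache_key = id(dataset)
        return self._raw

    def fit(self, dataset: CPIDataset, train_indices) -> "CPIFeaturizer":
        raw = self._raw_features(dataset)
        rows = [dataset.interactions[i] for i in np.asarray(train_indices)]
        if not rows:
            raise ValueError("cannot fit the featurizer on an empty training split")
        self.vocab = build_vocabulary(
            dataset.compound(it.compound_id).smiles for it in rows
        )
        self.compound_pp = FeaturePostprocessor().fit(
            np.stack([raw["comp_desc"][it.compound_id] for it in rows])
        )
        self.protein_pp = FeaturePostprocessor().fit(
            np.stack([raw["prot_desc"][it.protein_id] for it in rows])
        )
        return self

    def refit_postprocessors(self, dataset: CPIDataset, train_indices) -> None:
        """Adapt standardization statistics to a new (transfer) training set,
        keeping column identities so the model input width is unchanged."""
        raw = self._raw_features(dataset)
        rows = [dataset.interactions[i] for i in np.asarray(train_indices)]
        self.compound_pp.refit_statistics(
            np.stack([raw["comp_desc"][it.compound_id] for it in rows])
        )
        self.protein_pp.refit_statistics(
            np.stack([raw["prot_desc"][it.protein_id] for it in rows])
        )

    def transform(self, dataset: CPIDataset, indices=None) -> tuple[FeatureBatch, np.ndarray]:
        if self.vocab is None:
            raise RuntimeError("featurizer must be fitted before transform")
        raw = self._raw_features(dataset)
        rows = (
            dataset.interactions
            if indices is None
            else [dataset.interactions[i] for i in np.asarray(indices)]
        )
        comp_tok = {}
        for it in rows:
            cid = it.compound_id
            if cid not in comp_tok:
                comp_tok[cid] = encode_smiles(dataset.compound(cid).smiles, self.vocab)
        comp_desc = self.compound_pp.transform(
            np.stack([raw["comp_desc"][it.compound_id] for it in rows])
        )
        comp_fp = np.stack([raw["comp_fp"][it.compound_id] for it in rows])
        prot_desc = self.protein_pp.transform(
            np.stack([raw["prot_desc"][it.protein_id] for it in rows])
        )
        batch = FeatureBatch(
            compound_tokens=np.stack([comp_tok[it.compound_id] for it in rows]),
            compound_global=np.concatenate([comp_fp, comp_desc], axis=1).astype(np.float32),
            protein_tokens=np.stack([raw["prot_tok"][it.protein_id] for it in rows]),
            protein_global=prot_desc.astype(np.float32),
        )
        y = np.array([it.affinity for it in rows], dtype=np.float64)
        return batch, y

    def model_config(self, **overrides) -> ModelConfig:
        """A ModelConfig whose input widths match this fitted featurizer."""
        if self.vocab is None:
            raise RuntimeError("featurizer must be fitted first")
        kwargs = dict(
            compound_vocab_size=self.vocab.size,
            compound_global_in=1024 + self.compound_pp.n_output_columns,
            protein_global_in=self.protein_pp.n_output_columns,
        )
        kwargs.update(overrides)
        return ModelConfig(**kwargs)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def pp_dict(pp):
            return {
                "kept_columns": pp.kept_columns.tolist(),
                "mean": pp.mean.tolist(),
                "std": pp.std.tolist(),
                "n_input_columns": pp.n_input_columns,
            }

        return {
            "vocab": {"index": self.vocab.index, "unknown_index": self.vocab.unknown_index},
            "compound_pp": pp_dict(self.compound_pp),
            "protein_pp": pp_dict(self.protein_pp),
            "compound_provider": type(self.compound_provider).__name__,
            "protein_provider": type(self.protein_provider).__name__,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CPIFeaturizer":
        fz = cls()

        def pp_from(dd):
            pp = FeaturePostprocessor()
            pp.kept_columns = np.asarray(dd["kept_columns"], dtype=np.int64)
            pp.mean = np.asarray(dd["mean"], dtype=np.float64)
            pp.std = np.asarray(dd["std"], dtype=np.float64)
            pp.n_input_columns = dd["n_input_columns"]
            pp._fitted = True
            return pp

        fz.vocab = SmilesVocabulary(
            index=dict(d["vocab"]["index"]), unknown_index=d["vocab"]["unknown_index"]
        )
        fz.compound_pp = pp_from(d["compound_pp"])
        fz.protein_pp = pp_from(d["protein_pp"])
        return fz


# --------------------------------------------------------------------------
# optimizer and training loop
# --------------------------------------------------------------------------

class Adam:
    def __init__(self, slots, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = list(slots)  # (name, slot) pairs
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(slot.get()) for name, slot in self.slots}
        self.v = {name: np.zeros_like(slot.get()) for name, slot in self.slots}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, slot in self.slots:
            g = slot.grad()
            m = self.m[name] = b1 * self.m[name] + (1 - b1) * g
            v = self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            slot.set(slot.get() - self.lr * mhat / (np.sqrt(vhat) + self.eps))


@dataclass
class TrainResult:
    model: FusionRegressor
    history: pd.DataFrame  # columns: epoch, train_mse, val_mse
    best_epoch: int
    best_val_mse: float


def train(
    model: FusionRegressor,
    train_data: tuple[FeatureBatch, np.ndarray],
    val_data: tuple[FeatureBatch, np.ndarray],
    config: TrainConfig,
    learning_rate: float | None = None,
    freeze: str | None = None,
) -> TrainResult:
    """Minimize MSE with Adam; return the best-validation checkpoint.

    Early stopping: training ends ``patience`` epochs after the last
    improvement of validation MSE (patience 0 = exactly one epoch beyond
    the best).  Fully reproducible for a fixed ``config.seed``.
    """
    X_train, y_train = train_data
    X_val, y_val = val_data
    if len(X_train) == 0:
        raise ValueError("empty training set")
    lr = config.learning_rate if learning_rate is None else learning_rate
    freeze = config.freeze if freeze is None else freeze
    slots = [
        (name, slot)
        for name, slot in model.named_parameters()
        if not (freeze == "local" and ("_local" in name.split(".")[0]))
    ]
    opt = Adam(slots, lr=lr)
    rng = np.random.default_rng(config.seed)
    n = len(X_train)
    y_train32 = y_train.astype(np.float32)

    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_sse = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            yb = y_train32[idx]
            pred = model.forward(X_train.take(idx), train=True, rng=rng)
            err = pred - yb
            if not np.isfinite(err).all():
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; reduce the learning rate"
                )
            epoch_sse += float(np.sum(err.astype(np.float64) ** 2))
            model.backward((2.0 * err / len(idx)).astype(np.float32))
            if lr > 0:
                opt.step()
        train_mse = epoch_sse / n
        val_mse = mean_squared_error(y_val, model.predict(X_val))
        rows.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse})
        logger.debug("epoch %d: train %.5f val %.5f", epoch, train_mse, val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_weights = model.get_weights()
            best_epoch = epoch
        elif epoch - best_epoch > config.patience:
            break
    model.set_weights(best_weights)
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_mse=float(best_val),
    )


def finetune(
    pretrained: FusionRegressor,
    train_data: tuple[FeatureBatch, np.ndarray],
    val_data: tuple[FeatureBatch, np.ndarray],
    config: TrainConfig,
) -> TrainResult:
    """Continue training a pretrained model on a (small) target dataset.

    All layers are updated end-to-end at ``fine_tune_learning_rate``
    (or only the global heads + fusion when ``config.freeze == 'local'``);
    the output head is re-used, not re-initialized.  The input model is not
    modified: a copy is trained.
    """
    model = pretrained.copy()
    return train(
        model, train_data, val_data, config,
        learning_rate=config.fine_tune_learning_rate,
    )


# --------------------------------------------------------------------------
# high-level experiment drivers
# --------------------------------------------------------------------------

def fit_on_dataset(
    dataset: CPIDataset,
    train_indices,
    val_indices,
    model_overrides: dict | None = None,
    train_config: TrainConfig | None = None,
    featurizer: CPIFeaturizer | None = None,
) -> TrainResult:
    """Featurize, build and train a model on explicit index splits."""
    train_config = train_config or TrainConfig()
    fz = featurizer or CPIFeaturizer()
    fz.fit(dataset, train_indices)
    cfg = fz.model_config(random_seed=train_config.seed, **(model_overrides or {}))
    model = build_model(cfg)
    model.featurizer = fz
    result = train(
        model,
        fz.transform(dataset, train_indices),
        fz.transform(dataset, val_indices),
        train_config,
    )
    return result


def cross_validate(
    dataset: CPIDataset,
    train_config: TrainConfig | None = None,
    model_overrides: dict | None = None,
    split: SplitPlan | None = None,
    featurizer_factory=CPIFeaturizer,
) -> MetricsReport:
    """1/6-test + 5-fold CV; every fold model is evaluated on the shared test set.

    Per-fold metrics are aggregated as mean and sample (n-1) standard
    deviation.  The SMILES vocabulary is built on the non-test rows;
    descriptor postprocessors are refitted per fold on that fold's
    training rows only.
    """
    train_config = train_config or TrainConfig()
    split = split or make_split(dataset, seed=train_config.seed)
    fold_rows = []
    for k, val_idx in enumerate(split.folds):
        train_idx = split.train_indices_for_fold(k)
        fz = featurizer_factory()
        fz.fit(dataset, train_idx)
        cfg = fz.model_config(random_seed=train_config.seed + k, **(model_overrides or {}))
        model = build_model(cfg)
        model.featurizer = fz
        try:
            train(
                model,
                fz.transform(dataset, train_idx),
                fz.transform(dataset, val_idx),
                train_config,
            )
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {k}") from exc
        X_test, y_test = fz.transform(dataset, split.test_indices)
        report = evaluate(y_test, model.predict(X_test))
        fold_rows.append({"fold": k, **report.as_dict()})
    per_fold = pd.DataFrame(fold_rows).set_index("fold")
    mean = per_fold.mean()
    std = per_fold.std(ddof=1)
    return MetricsReport(
        mse=float(mean["mse"]), ci=float(mean["ci"]),
        r2=float(mean["r2"]), pcc=float(mean["pcc"]),
        per_fold=per_fold, mean=mean.to_dict(), std=std.to_dict(),
    )
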