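"""End-to-end optimization of property models.

Adam with the default schedule: the learning rate rises linearly from
``init_lr`` (1e-4) to ``max_lr`` (1e-3) over the first two warmup epochs,
then decays exponentially to ``final_lr`` (1e-4) at the last optimizer
step.  Warmup is measured in optimizer steps.  Regression targets are
standardized per task before training and predictions are returned in
original units.  Ensembles train independent weight seeds on the shared
split; cross-validation re-splits per fold.  Transfer learning freezes the
message-passing weights and optionally the first k readout layers.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor
from .encoder import PropertyModel, AtomBondModel, TargetSpec
from .featurization import MolGraph, batch_graphs
from . import losses as L


# ---------------------------------------------------------------------------
@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 50
    init_lr: float = 1e-4
    max_lr: float = 1e-3
    final_lr: float = 1e-4
    warmup_epochs: float = 2.0
    ensemble_size: int = 1
    folds: int = 1
    seed: int = 0
    patience: int | None = None          # early stopping, in epochs
    dropout: float = 0.0
    freeze_mpnn: bool = False
    freeze_ffn_layers: int = 0           # first k readout layers frozen

    def __post_init__(self):
        if not (self.init_lr <= self.max_lr and self.final_lr <= self.max_lr):
            raise ValueError("learning-rate endpoints must satisfy "
                             "init_lr <= max_lr and final_lr <= max_lr")
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup must be shorter than training")


def lr_at_step(step: int, steps_per_epoch: int, config: TrainConfig) -> float:
    """Learning rate at optimizer step ``step`` (0-based).

    Linear warmup over ``warmup_epochs * steps_per_epoch`` steps from
    ``init_lr`` to ``max_lr``, then exponential decay reaching
    ``final_lr`` exactly at the final step.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    warm = max(int(round(config.warmup_epochs * steps_per_epoch)), 1)
    total = config.epochs * steps_per_epoch
    if config.max_lr <= 0.0:
        return 0.0
    if step < warm:
        return config.init_lr + (config.max_lr - config.init_lr) * step / warm
    last = max(total - 1, warm + 1)
    frac = min((step - warm) / (last - warm), 1.0)
    return config.max_lr * (config.final_lr / config.max_lr) ** frac


class Adam:
    """Adam over a dict of named tensors; frozen names are skipped."""

    def __init__(self, params: dict[str, Tensor],
                 frozen: set[str] = frozenset(),
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = {k: v for k, v in params.items() if k not in frozen}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
class Scaler:
    """Per-task standardization of regression targets (identity otherwise)."""

    def __init__(self, means: np.ndarray | None = None,
                 stds: np.ndarray | None = None):
        self.means = means
        self.stds = stds

    @classmethod
    def fit(cls, targets: np.ndarray, mask: np.ndarray | None = None) -> "Scaler":
        t = np.asarray(targets, dtype=np.float64)
        m = np.ones_like(t, dtype=bool) if mask is None else np.asarray(mask, bool)
        means = np.array([t[m[:, j], j].mean() if m[:, j].any() else 0.0
                          for j in range(t.shape[1])])
        stds = np.array([t[m[:, j], j].std() if m[:, j].sum() > 1 else 1.0
                         for j in range(t.shape[1])])
        stds[stds < 1e-12] = 1.0
        return cls(means, stds)

    def transform(self, targets: np.ndarray) -> np.ndarray:
        if self.means is None:
            return targets
        return (targets - self.means) / self.stds

    def inverse(self, preds: np.ndarray) -> np.ndarray:
        if self.means is None:
            return preds
        return preds * self.stds + self.means

    def to_dict(self) -> dict:
        if self.means is None:
            return {}
        return {"means": self.means.tolist(), "stds": self.stds.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        if not d:
            return cls()
        return cls(np.asarray(d["means"]), np.asarray(d["stds"]))


# ---------------------------------------------------------------------------
@dataclass
class MoleculeDataset:
    """In-memory training table: featurized graphs plus targets.

    ``graphs[i]`` is the list of per-column graphs of row ``i``;
    ``targets`` is (n, n_tasks) floats (class indices for multiclass,
    bin intensities for spectra), ``mask`` flags observed entries, and
    ``relations`` holds "="/"<"/">" for inequality-bounded targets.
    """

    graphs: list[list[MolGraph]]
    targets: np.ndarray
    spec: TargetSpec
    mask: np.ndarray | None = None
    relations: np.ndarray | None = None
    features: np.ndarray | None = None
    smiles: list[list[str]] = field(default_factory=list)

    def __post_init__(self):
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=np.float64))
        if self.mask is None:
            self.mask = ~np.isnan(self.targets)
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.graphs)

    def subset(self, idx) -> "MoleculeDataset":
        idx = np.asarray(idx, dtype=int)
        return MoleculeDataset(
            graphs=[self.graphs[i] for i in idx],
            targets=self.targets[idx],
            spec=self.spec,
            mask=self.mask[idx],
            relations=None if self.relations is None else self.relations[idx],
            features=None if self.features is None else self.features[idx],
            smiles=[self.smiles[i] for i in idx] if self.smiles else [],
        )

    def batches(self, batch_size: int, rng: np.random.Generator | None = None):
        order = np.arange(len(self))
        if rng is not None:
            rng.shuffle(order)
        for k in range(0, len(order), batch_size):
            yield self.subset(order[k:k + batch_size])

    def column_batches(self):
        """One BatchedGraph per molecule column."""
        n_cols = len(self.graphs[0])
        return [batch_graphs([row[c] for row in self.graphs])
                for c in range(n_cols)]


# ---------------------------------------------------------------------------
def compute_loss(model: PropertyModel, batch: MoleculeDataset,
                 scaler: Scaler, rng: np.random.Generator | None = None) -> Tensor:
    spec = model.spec
    spectra_mask = batch.mask.astype(np.float64) if spec.task == "spectra" else None
    out = model.forward(batch.column_batches(), batch.features, rng,
                        spectra_mask=spectra_mask)["output"]
    y = np.nan_to_num(batch.targets)
    m = batch.mask.astype(np.float64)
    if spec.task == "regression":
        ys = scaler.transform(y)
        n = spec.n_tasks
        if spec.loss == "mse":
            return L.mse_loss(out, ys, m)
        if spec.loss == "bounded_mse":
            rel = (batch.relations if batch.relations is not None
                   else np.full(y.shape, "="))
            return L.bounded_mse(out, ys, rel, m)
        if spec.loss == "mve":
            return L.mve_nll(out[:, :n], out[:, n:], ys, m)
        if spec.loss == "evidential":
            return L.evidential_regression_loss(
                out[:, :n], out[:, n:2 * n], out[:, 2 * n:3 * n], out[:, 3 * n:],
                ys, mask=m)
    if spec.task == "binary":
        return L.classification_losses(out, y, spec.loss, n_classes=2, mask=m)
    if spec.task == "multiclass":
        kind = spec.loss if spec.loss != "mcc" else "mcc"
        return L.classification_losses(out, y.astype(int), kind,
                                       n_classes=spec.n_classes,
                                       mask=m[:, :spec.n_tasks])
    if spec.loss == "sid":
        return L.sid_loss(out, y, mask=m)
    return L.wasserstein_loss(out, y, mask=m)


def predict(models: PropertyModel | list[PropertyModel],
            dataset: MoleculeDataset, scaler: Scaler | None = None,
            ) -> np.ndarray:
    """Ensemble-mean predictions in original target units."""
    if isinstance(models, PropertyModel):
        models = [models]
    scaler = scaler or Scaler()
    cols = dataset.column_batches()
    spectra_mask = (dataset.mask.astype(np.float64)
                    if models[0].spec.task == "spectra" else None)
    preds = []
    for model in models:
        out = model.forward(cols, dataset.features,
                            spectra_mask=spectra_mask)["output"].data
        spec = model.spec
        if spec.task == "regression":
            n = spec.n_tasks
            mean = out[:, :n] if spec.loss in ("mve", "evidential") else out
            preds.append(scaler.inverse(mean))
        else:
            preds.append(out)
    return np.mean(preds, axis=0)


DEFAULT_VAL_METRICS = {"regression": "rmse", "binary": "auroc",
                       "multiclass": "cross_entropy", "spectra": "sid"}
LOWER_IS_BETTER = {"rmse": True, "mae": True, "cross_entropy": True,
                   "sid": True, "wasserstein": True, "auroc": False,
                   "auprc": False, "accuracy": False, "mcc": False,
                   "r2": False}


def _validation_score(models, val: MoleculeDataset, scaler, metric: str) -> float:
    preds = predict(models, val, scaler)
    if models[0].spec.task == "multiclass":
        # cross entropy on the probability blocks
        return float(L.cross_entropy_loss(
            Tensor(preds), val.targets.astype(int),
            models[0].spec.n_classes,
            val.mask[:, :models[0].spec.n_tasks].astype(float)).data)
    try:
        return L.evaluation_metrics(preds, val.targets, metric,
                                    mask=val.mask)
    except L.UndefinedMetricError:
        return math.nan


@dataclass
class TrainResult:
    models: list[PropertyModel]
    scaler: Scaler
    history: list[dict]
    best_val: float
    config: TrainConfig


def _snapshot(model: PropertyModel) -> dict[str, np.ndarray]:
    return {k: v.data.copy() for k, v in model.parameters().items()}


def _restore(model: PropertyModel, snap: dict[str, np.ndarray]) -> None:
    for k, v in model.parameters().items():
        v.data = snap[k].copy()


def _frozen_names(model: PropertyModel, config: TrainConfig) -> set[str]:
    frozen: set[str] = set()
    if config.freeze_mpnn:
        for enc in model.encoders:
            frozen.update(enc.parameters().keys())
    for i in range(config.freeze_ffn_layers):
        if i < len(model.ffn.layers):
            frozen.update(model.ffn.layers[i].parameters().keys())
    return frozen


def train(train_set: MoleculeDataset,
          val_set: MoleculeDataset | None = None,
          model_factory=None,
          config: TrainConfig | None = None,
          models: list[PropertyModel] | None = None,
          metric: str | None = None,
          run_dir: str | None = None) -> TrainResult:
    """Train one model or an ensemble.

    ``model_factory(seed) -> PropertyModel`` builds each ensemble member;
    alternatively pass pre-built ``models`` (e.g. from a checkpoint for
    transfer learning).  The best-validation weights are retained per
    member; with no validation set the final weights are kept.
    """
    config = config or TrainConfig()
    if models is None:
        if model_factory is None:
            raise ValueError("provide model_factory or models")
        models = [model_factory(config.seed + k)
                  for k in range(config.ensemble_size)]
    if len(train_set) == 0:
        raise ValueError("empty training split")
    spec = models[0].spec
    metric = metric or DEFAULT_VAL_METRICS[spec.task]
    lower = LOWER_IS_BETTER[metric]
    scaler = (Scaler.fit(train_set.targets, train_set.mask)
              if spec.task == "regression" else Scaler())
    steps_per_epoch = max(math.ceil(len(train_set) / config.batch_size), 1)
    history: list[dict] = []
    best_vals = []

    for k, model in enumerate(models):
        rng = np.random.default_rng(config.seed * 100003 + k)
        frozen = _frozen_names(model, config)
        opt = Adam(model.parameters(), frozen=frozen)
        step = 0
        best = math.inf if lower else -math.inf
        best_snap = _snapshot(model)
        stale = 0
        drop_rng = (np.random.default_rng(rng.integers(2 ** 31))
                    if config.dropout > 0 else None)
        for epoch in range(config.epochs):
            epoch_loss = 0.0
            nb = 0
            for batch in train_set.batches(config.batch_size, rng):
                opt.zero_grad()
                loss = compute_loss(model, batch, scaler, drop_rng)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, step {step}; "
                        "lower the learning rate or inspect the targets")
                loss.backward()
                opt.step(lr_at_step(step, steps_per_epoch, config))
                epoch_loss += float(loss.data)
                nb += 1
                step += 1
            rec = {"member": k, "epoch": epoch, "train_loss": epoch_loss / nb,
                   "lr": lr_at_step(step - 1, steps_per_epoch, config)}
            if val_set is not None and len(val_set):
                score = _validation_score([model], val_set, scaler, metric)
                rec[f"val_{metric}"] = score
                improved = (score < best) if lower else (score > best)
                if np.isfinite(score) and improved:
                    best, best_snap, stale = score, _snapshot(model), 0
                else:
                    stale += 1
                    if config.patience is not None and stale > config.patience:
                        history.append(rec)
                        break
            history.append(rec)
        if val_set is not None and len(val_set):
            _restore(model, best_snap)
            best_vals.append(best)
    best_val = float(np.mean(best_vals)) if best_vals else math.nan

    if run_dir is not None:
        os.makedirs(run_dir, exist_ok=True)
        for k, model in enumerate(models):
            model.save(os.path.join(run_dir, f"model_{k}.npz"),
                       extra={"scaler": scaler.to_dict(),
                              "config_hash": config_hash(config)})
        with open(os.path.join(run_dir, "metrics.tsv"), "w") as fh:
            keys = sorted({k for r in history for k in r})
            fh.write("\t".join(keys) + "\n")
            for r in history:
                fh.write("\t".join(str(r.get(k, "")) for k in keys) + "\n")
        manifest = {"seed": config.seed, "config": vars(config).copy(),
                    "config_hash": config_hash(config),
                    "n_train": len(train_set),
                    "best_val": best_val, "metric": metric}
        with open(os.path.join(run_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return TrainResult(models, scaler, history, best_val, config)


def config_hash(config: TrainConfig) -> str:
    import hashlib
    payload = json.dumps(vars(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
def transfer(checkpoint_path: str, freeze: str | None = "mpnn",
             freeze_ffn_layers: int = 0,
             config: TrainConfig | None = None
             ) -> tuple[PropertyModel, TrainConfig, Scaler]:
    """Load a pretrained checkpoint for fine-tuning.

    ``freeze`` is None (warm start), "mpnn", or "mpnn+ffn" combined with
    ``freeze_ffn_layers`` = number of leading readout layers to hold fixed.
    Returns the model plus a config with the freeze flags set.
    """
    model, extra = PropertyModel.load(checkpoint_path)
    config = config or TrainConfig()
    if freeze is None:
        cfg = replace(config, freeze_mpnn=False, freeze_ffn_layers=0)
    elif freeze == "mpnn":
        cfg = replace(config, freeze_mpnn=True, freeze_ffn_layers=0)
    elif freeze == "mpnn+ffn":
        cfg = replace(config, freeze_mpnn=True,
                      freeze_ffn_layers=freeze_ffn_layers)
    else:
        raise ValueError(f"unknown freeze spec {freeze!r}")
    scaler = Scaler.from_dict(extra.get("scaler", {}))
    return model, cfg, scaler


# ---------------------------------------------------------------------------
def split_data(n_or_smiles, scheme: str = "random",
               fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
               seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test indices.

    ``random`` shuffles rows; ``scaffold`` keeps molecules sharing a
    Murcko scaffold in the same partition (pass the SMILES list), filling
    train, then val, then test with scaffold groups largest-first.
    """
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError("split fractions must sum to 1")
    if isinstance(n_or_smiles, (int, np.integer)):
        n = int(n_or_smiles)
        smiles = None
    else:
        smiles = list(n_or_smiles)
        n = len(smiles)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 0 or (n_val == 0 and fractions[1] > 0):
        raise ValueError(f"fractions {fractions} infeasible for {n} rows")
    rng = np.random.default_rng(seed)
    if scheme == "random":
        order = rng.permutation(n)
        return (order[:n_train], order[n_train:n_train + n_val],
                order[n_train + n_val:])
    if scheme != "scaffold":
        raise ValueError(f"unknown split scheme {scheme!r}")
    if smiles is None:
        raise ValueError("scaffold split needs the SMILES list")
    from rdkit.Chem.Scaffolds import MurckoScaffold
    groups: dict[str, list[int]] = {}
    for i, smi in enumerate(smiles):
        scaf = MurckoScaffold.MurckoScaffoldSmiles(smiles=smi)
        groups.setdefault(scaf, []).append(i)
    buckets = sorted(groups.values(), key=len, reverse=True)
    # shuffle ties deterministically so equal-size scaffolds vary with seed
    sizes = np.array([len(b) for b in buckets])
    for s in np.unique(sizes):
        pos = np.flatnonzero(sizes == s)
        perm = rng.permutation(len(pos))
        reordered = [buckets[pos[j]] for j in perm]
        for p, b in zip(pos, reordered):
            buckets[p] = b
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for bucket in buckets:
        if len(train_idx) + len(bucket) <= n_train:
            train_idx += bucket
        elif len(val_idx) + len(bucket) <= n_val:
            val_idx += bucket
        else:
            test_idx += bucket
    return (np.array(train_idx, dtype=int), np.array(val_idx, dtype=int),
            np.array(test_idx, dtype=int))


def cross_validate(dataset: MoleculeDataset, model_factory,
                   config: TrainConfig, metric: str | None = None,
                   val_fraction: float = 0.1) -> list[TrainResult]:
    """k independent random re-splits (k = config.folds), each trained with
    the shared ensemble settings; returns one result per fold."""
    results = []
    for fold in range(config.folds):
        tr, va, te = split_data(len(dataset), "random",
                                (1.0 - 2 * val_fraction, val_fraction,
                                 val_fraction),
                                seed=config.seed + fold)
        fold_cfg = replace(config, seed=config.seed + fold)
        results.append(train(dataset.subset(tr), dataset.subset(va),
                             model_factory, fold_cfg, metric=metric))
    return results


# ---------------------------------------------------------------------------
def hyperparameter_search(space: dict[str, list], objective, n_trials: int,
                          seed: int = 0, log_path: str | None = None,
                          sampler=None) -> tuple[dict, list[dict]]:
    """Random search over a discrete space; minimizes ``objective(params)``.

    ``sampler`` is an optional pluggable backend (e.g. a Tree-structured
    Parzen Estimator): a callable ``sampler(space, trials, rng) -> params``
    consulted after the first trial.  The trial log is written as JSON
    lines with O_APPEND so parallel workers can share one file.
    """
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("hyperparameter space must be non-empty")
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    for i in range(n_trials):
        if sampler is not None and trials:
            params = sampler(space, trials, rng)
        else:
            params = {k: v[rng.integers(len(v))] for k, v in space.items()}
        score = float(objective(params))
        rec = {"trial": i, "params": {k: (v.item() if hasattr(v, "item") else v)
                                      for k, v in params.items()},
               "score": score}
        trials.append(rec)
        if log_path:
            line = (json.dumps(rec) + "\n").encode()
            fd = os.open(log_path, os.O_WRONLY | os.O_CREAT | os.O_APPEND)
            try:
                os.write(fd, line)
            finally:
                os.close(fd)
    best = min(trials, key=lambda r: r["score"])
    return best, trials


def read_trial_log(log_path: str) -> list[dict]:
    with open(log_path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
def train_atom_bond(model: AtomBondModel, graphs: list[MolGraph],
                    targets: dict[str, list[np.ndarray]],
                    constraints: dict[str, np.ndarray] | None = None,
                    config: TrainConfig | None = None) -> list[float]:
    """Fit an atom/bond-level model with per-entity squared error.

    ``targets[name][i]`` holds the per-atom (or per-bond) values of
    molecule ``i``; constrained properties receive their molecular net
    values through ``constraints``.  Returns the per-epoch mean loss.
    """
    config = config or TrainConfig()
    opt = Adam(model.parameters())
    rng = np.random.default_rng(config.seed)
    n = len(graphs)
    steps_per_epoch = max(math.ceil(n / config.batch_size), 1)
    losses_log = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for k in range(0, n, config.batch_size):
            idx = order[k:k + config.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            cons = None
            if constraints:
                cons = {name: np.asarray(vals)[idx]
                        for name, vals in constraints.items()}
            out = model.forward(batch, cons)
            loss = None
            for name, pred in out.items():
                y = np.concatenate([np.asarray(targets[name][i], dtype=float)
                                    for i in idx])[:, None]
                term = L.mse_loss(pred, y)
                loss = term if loss is None else loss + term
            opt.zero_grad()
            loss.backward()
            opt.step(lr_at_step(step, steps_per_epoch, config))
            epoch_loss += float(loss.data)
            nb += 1
            step += 1
        losses_log.append(epoch_loss / nb)
    return losses_log
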