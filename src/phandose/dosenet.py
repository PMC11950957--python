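"""Training, cross-validation and ensemble prediction for the dose model.

Slices are treated as independent training examples: each phantom
contributes its selected slices as (7-channel input, normalised dose
target) pairs.  Training minimises the mean squared error between planned
and predicted normalised doses with Adam.  A k-fold split over *samples*
(never slices, so no patient leaks across folds) yields one model per
fold; the final predictor averages the fold models' voxelwise predictions,
then the dose is denormalised by the training cohort's global maximum,
clamped at zero and rescaled to the PTV coverage goal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import preprocess as _pp
from .nn.layers import mse_loss
from .nn.unet import NetConfig, UNet, build_unet, make_optimizer
from .volumes import DoseGrid, PlanSample

log = logging.getLogger(__name__)

__all__ = [
    "NetConfig", "TrainConfig", "make_folds", "train_fold", "cross_validate",
    "ensemble_predict", "predict_sample", "save_models", "load_models",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (Adam + MSE).

    ``lr_schedule`` is ``"constant"`` or ``"cosine"`` (cosine decay from
    ``learning_rate`` to a tenth of it over the epochs).
    """

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0
    batch_size: int = 15
    epochs: int = 30
    folds: int = 5
    seed: int = 0
    lr_schedule: str = "constant"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    def lr_at(self, epoch: int) -> float:
        if self.lr_schedule == "constant":
            return self.learning_rate
        lo = 0.1 * self.learning_rate
        cos = 0.5 * (1.0 + np.cos(np.pi * epoch / max(self.epochs - 1, 1)))
        return lo + (self.learning_rate - lo) * cos


def make_folds(sample_ids: list[str], n_folds: int, seed: int) -> list[list[str]]:
    """Random partition of sample ids into ``n_folds`` validation subsets.

    The subsets are disjoint, exhaustive, and equal in size within one.
    """
    if len(sample_ids) < n_folds:
        raise ValueError(f"cohort of {len(sample_ids)} smaller than {n_folds} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    perm = list(np.array(sample_ids, dtype=object)[rng.permutation(len(sample_ids))])
    return [perm[k::n_folds] for k in range(n_folds)]


def _gather_slices(stacks: dict[str, np.ndarray], targets: dict[str, np.ndarray],
                   ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    xs = np.concatenate([stacks[i] for i in ids], axis=0)
    ys = np.concatenate([targets[i][:, None] for i in ids], axis=0)
    return xs.astype(np.float32), ys.astype(np.float32)


def train_fold(
    stacks: dict[str, np.ndarray],
    targets: dict[str, np.ndarray],
    train_ids: list[str],
    val_ids: list[str],
    net_cfg: NetConfig,
    tcfg: TrainConfig,
    fold_index: int = 0,
) -> tuple[UNet, dict[str, list[float]]]:
    """Train one model on ``train_ids``, tracking train/val MSE per epoch.

    ``stacks[i]`` has shape (S_i, 7, H, W); ``targets[i]`` is the matching
    normalised dose (S_i, H, W) in [0, 1].  All randomness (weights,
    shuffling, dropout) derives from ``tcfg.seed`` and ``fold_index``.
    """
    if not train_ids:
        raise ValueError("empty training fold")
    x_tr, y_tr = _gather_slices(stacks, targets, train_ids)
    model = build_unet(net_cfg, seed=int(np.random.SeedSequence([tcfg.seed, fold_index]).generate_state(1)[0] % 2**31))
    opt = make_optimizer(model, lr=tcfg.learning_rate, beta1=tcfg.beta1,
                         beta2=tcfg.beta2, weight_decay=tcfg.weight_decay)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, fold_index, 1]))
    n = x_tr.shape[0]
    history: dict[str, list[float]] = {"train_mse": [], "val_mse": []}
    for epoch in range(tcfg.epochs):
        opt.lr = tcfg.lr_at(epoch)
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            pred = model.forward(x_tr[idx], train=True)
            loss, grad = mse_loss(pred, y_tr[idx])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history["train_mse"].append(float(np.mean(losses)))
        history["val_mse"].append(
            evaluate_mse(model, stacks, targets, val_ids, tcfg.batch_size) if val_ids else np.nan
        )
        log.debug("fold %d epoch %d train %.3e val %.3e", fold_index, epoch,
                  history["train_mse"][-1], history["val_mse"][-1])
    return model, history


def evaluate_mse(model: UNet, stacks, targets, ids: list[str], batch_size: int = 15) -> float:
    x, y = _gather_slices(stacks, targets, ids)
    se, count = 0.0, 0
    for start in range(0, x.shape[0], batch_size):
        pred = model.predict(x[start : start + batch_size])
        t = y[start : start + batch_size]
        se += float(np.sum((pred - t) ** 2))
        count += t.size
    return se / count


def cross_validate(
    stacks: dict[str, np.ndarray],
    targets: dict[str, np.ndarray],
    net_cfg: NetConfig,
    tcfg: TrainConfig,
) -> tuple[list[UNet], dict]:
    """k-fold cross-validation over samples; returns fold models + metrics.

    Fold k trains on all samples outside validation subset k.  Reported
    metrics are each fold's final train/val MSE and their mean +/- SD.
    """
    ids = sorted(stacks)
    folds = make_folds(ids, tcfg.folds, tcfg.seed)
    models, fold_metrics = [], []
    for k, val_ids in enumerate(folds):
        train_ids = [i for i in ids if i not in set(val_ids)]
        model, hist = train_fold(stacks, targets, train_ids, val_ids, net_cfg, tcfg, fold_index=k)
        models.append(model)
        fold_metrics.append({
            "fold": k,
            "n_val": len(val_ids),
            "val_ids": list(val_ids),
            "final_train_mse": hist["train_mse"][-1],
            "final_val_mse": hist["val_mse"][-1],
            "history": hist,
        })
        log.info("fold %d/%d: train MSE %.3e, val MSE %.3e", k + 1, tcfg.folds,
                 hist["train_mse"][-1], hist["val_mse"][-1])
    vals = np.array([m["final_val_mse"] for m in fold_metrics], dtype=float)
    summary = {
        "folds": fold_metrics,
        "val_mse_mean": float(np.nanmean(vals)),
        "val_mse_sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
    }
    return models, summary


def ensemble_predict(models: list[UNet], stack: np.ndarray, batch_size: int = 15) -> np.ndarray:
    """Voxelwise mean of the member models' predicted normalised doses.

    ``stack`` is (S, 7, H, W); the result is (S, H, W) still on the
    normalised scale.
    """
    if not models:
        raise ValueError("empty model ensemble")
    cfgs = {m.cfg for m in models}
    if len(cfgs) != 1:
        raise ValueError("ensemble members have mismatched architectures")
    acc = None
    for m in models:
        parts = [m.predict(stack[s : s + batch_size]) for s in range(0, stack.shape[0], batch_size)]
        pred = np.concatenate(parts, axis=0)[:, 0]
        acc = pred if acc is None else acc + pred
    return acc / len(models)


def predict_sample(
    models: list[UNet],
    sample: PlanSample,
    pp_cfg: _pp.PreprocessConfig,
    norm_constant: float,
    rescale_by: str = "predicted",
) -> DoseGrid:
    """Full prediction path for one (preprocessed) sample.

    Ensemble-average the per-slice predictions, place them back into the 3D
    grid (slices outside the selected range get zero dose), denormalise by
    the *training* global maximum, clamp negatives to zero, and rescale to
    the PTV coverage goal.  ``rescale_by='predicted'`` uses the predicted
    PTV D95% for that last step (a pre-treatment prediction has no planned
    dose to lean on); ``'planned'`` uses the planned dose's scale instead.
    """
    stack, index_map = _pp.assemble_channels(sample, pp_cfg)
    pred_slices = ensemble_predict(models, stack)
    vol = np.zeros(sample.shape, dtype=np.float64)
    vol[index_map] = pred_slices
    vol = np.maximum(_pp.denormalize(vol, norm_constant), 0.0)
    dose = DoseGrid(values=vol, prescription=sample.dose.prescription,
                    n_fractions=sample.dose.n_fractions, spacing=sample.image.spacing)
    if rescale_by == "predicted":
        dose, _ = _pp.rescale_to_coverage(dose, sample.masks["PTV"], pp_cfg)
    elif rescale_by == "planned":
        planned, factor = _pp.rescale_to_coverage(sample.dose, sample.masks["PTV"], pp_cfg)
        dose = dose.with_values(dose.values * factor)
    else:
        raise ValueError(f"unknown rescale_by {rescale_by!r}")
    return dose


# -- checkpointing ----------------------------------------------------------

def save_models(models: list[UNet], tcfg: TrainConfig, out_dir: str | Path) -> None:
    """Persist fold models as .npz plus a JSON sidecar with the configs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k, m in enumerate(models):
        np.savez(out_dir / f"fold_{k}.npz", **m.state_arrays())
    sidecar = {"net": asdict(models[0].cfg), "train": asdict(tcfg), "n_models": len(models)}
    (out_dir / "models.json").write_text(json.dumps(sidecar, indent=2))


def load_models(model_dir: str | Path) -> tuple[list[UNet], TrainConfig]:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "models.json").read_text())
    net_cfg = NetConfig(**sidecar["net"])
    tcfg = TrainConfig(**sidecar["train"])
    models = []
    for k in range(sidecar["n_models"]):
        m = build_unet(net_cfg, seed=0)
        with np.load(model_dir / f"fold_{k}.npz") as state:
            m.load_state_arrays(dict(state))
        models.append(m)
    return models, tcfg
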