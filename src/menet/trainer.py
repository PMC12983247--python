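"""Data splitting, two-stage training, transfer learning, and grid search.

Training is two-stage: the relatedness encoder is pre-trained with the
trait-aware triplet loss on the training split (stage 1) and frozen by
default while the VE branch, fusion module and prediction head are trained
on mean absolute error with AdamW (stage 2).  Checkpoints are selected by
validation R2 (squared Pearson); the learning rate is reduced on validation
plateaus.

Cross-environment transfer freezes the RepGeno encoder, the VE trunk and
F_RepGeno, fine-tuning exactly the F_VE correction network and the
three-layer head on a small fraction (default 5% train / 5% validation)
of the target environment.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .evaluation import compute_metrics
from .genotype_io import GenotypeMatrix
from .menet_model import MeNetNetwork, ModelConfig
from .repgeno import RepGenoEncoder, TripletConfig, train_repgeno

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "TrainHistory",
    "make_splits",
    "train_menet",
    "transfer_finetune",
    "grid_search",
]

RATIO_PRESETS = {
    "6:2:2": (6.0, 2.0, 2.0),
    "3:2:5": (3.0, 2.0, 5.0),
    "0.5:0.5:9": (0.5, 0.5, 9.0),
}


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test ratios; stratification is by phenotype quantile."""

    ratios: tuple[float, float, float] = (6.0, 2.0, 2.0)
    stratify: bool = False
    n_bins: int = 4
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or min(self.ratios) <= 0:
            raise ValueError("ratios must be three positive numbers")

    @classmethod
    def preset(cls, name: str, **kw) -> "SplitSpec":
        return cls(ratios=RATIO_PRESETS[name], **kw)


@dataclass(frozen=True)
class TrainConfig:
    """Stage-2 optimisation settings (AdamW on mean absolute error)."""

    batch_size: int = 128
    lr: float = 3e-3  # desk-scale default; the plateau schedule anneals it
    weight_decay: float = 1e-4
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    min_lr: float = 1e-6
    max_epochs: int = 200
    early_stop_patience: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch training record."""

    train_mae: list[float] = field(default_factory=list)
    val_r2: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_mae)),
            "train_mae": self.train_mae,
            "val_r2": self.val_r2,
            "lr": self.lr})


def _allocate(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    total = sum(ratios)
    raw = [n * r / total for r in ratios]
    sizes = [int(np.floor(x)) for x in raw]
    # distribute the rounding remainder by largest fractional part
    remainder = n - sum(sizes)
    order = np.argsort([-(x - np.floor(x)) for x in raw])
    for k in range(remainder):
        sizes[order[k]] += 1
    return tuple(sizes)  # type: ignore[return-value]


def make_splits(n_samples: int, phenotypes: np.ndarray | None = None,
                spec: SplitSpec | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index sets.

    Stratified mode bins the phenotype into quantiles and splits each bin
    at the requested ratios, so all three sets show the same phenotype
    distribution.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    if spec.stratify:
        if phenotypes is None:
            raise ValueError("stratified splitting requires phenotypes")
        if n_samples < 10:
            raise ValueError("stratified splitting needs n >= 10")
        bins = pd.qcut(np.asarray(phenotypes, dtype=float), q=spec.n_bins,
                       labels=False, duplicates="drop")
        parts: list[list[np.ndarray]] = [[], [], []]
        for b in np.unique(bins):
            idx = rng.permutation(np.flatnonzero(bins == b))
            s = _allocate(idx.size, spec.ratios)
            parts[0].append(idx[:s[0]])
            parts[1].append(idx[s[0]:s[0] + s[1]])
            parts[2].append(idx[s[0] + s[1]:])
        return tuple(np.sort(np.concatenate(p)) for p in parts)  # type: ignore
    idx = rng.permutation(n_samples)
    s = _allocate(n_samples, spec.ratios)
    return (np.sort(idx[:s[0]]), np.sort(idx[s[0]:s[0] + s[1]]),
            np.sort(idx[s[0] + s[1]:]))


def _epoch_pass(net: MeNetNetwork, opt: _nn.AdamW, X: np.ndarray, y: np.ndarray,
                batch_size: int, rng: np.random.Generator) -> float:
    order = rng.permutation(X.shape[0])
    total = 0.0
    for start in range(0, order.size, batch_size):
        idx = order[start:start + batch_size]
        yhat = net.forward(X[idx])
        resid = yhat - y[idx]
        loss = np.abs(resid).mean()
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        total += loss * idx.size
        opt.zero_grad()
        net.backward(np.sign(resid) / idx.size)
        opt.step()
    return total / order.size


def _val_r2(net: MeNetNetwork, X: np.ndarray, y: np.ndarray) -> float:
    yhat = net.forward(X)
    return compute_metrics(y, yhat).R2_pearson


def _fit_loop(net: MeNetNetwork, opt: _nn.AdamW, X_tr, y_tr, X_val, y_val,
              cfg: TrainConfig) -> TrainHistory:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    history = TrainHistory()
    best_r2 = -np.inf
    best_state = net.state()
    since_improve = 0
    since_lr_drop = 0
    for epoch in range(cfg.max_epochs):
        try:
            mae = _epoch_pass(net, opt, X_tr, y_tr, cfg.batch_size, rng)
        except FloatingPointError:
            logger.warning("training diverged at epoch %d; restoring last "
                           "finite checkpoint", epoch)
            net.load_state(best_state)
            break
        r2 = _val_r2(net, X_val, y_val)
        history.train_mae.append(mae)
        history.val_r2.append(r2)
        history.lr.append(opt.lr)
        if r2 > best_r2:
            best_r2 = r2
            best_state = net.state()
            history.best_epoch = epoch
            since_improve = 0
            since_lr_drop = 0
        else:
            since_improve += 1
            since_lr_drop += 1
        if since_lr_drop >= cfg.plateau_patience and opt.lr > cfg.min_lr:
            opt.lr = max(opt.lr * cfg.plateau_factor, cfg.min_lr)
            since_lr_drop = 0
        if since_improve >= cfg.early_stop_patience:
            break
    net.load_state(best_state)
    return history


def train_menet(G: GenotypeMatrix, y: np.ndarray, encoder: RepGenoEncoder,
                splits: tuple[np.ndarray, np.ndarray, np.ndarray],
                model_cfg: ModelConfig | None = None,
                train_cfg: TrainConfig | None = None,
                train_encoder: bool = False
                ) -> tuple[MeNetNetwork, TrainHistory]:
    """Stage-2 training of VE + fusion + head (RepGeno frozen by default).

    Returns the network restored to the checkpoint with the best validation
    R2, plus the per-epoch history.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    y = np.asarray(y, dtype=float)
    tr, val, _ = splits
    net = MeNetNetwork(G, encoder, model_cfg, seed=train_cfg.seed,
                       train_encoder=train_encoder)
    net.y_mean = float(y[tr].mean())
    net.y_std = float(y[tr].std()) or 1.0
    opt = _nn.AdamW(net.trainable_params(), lr=train_cfg.lr,
                    weight_decay=train_cfg.weight_decay)
    history = _fit_loop(net, opt, G.codes[tr], y[tr], G.codes[val], y[val],
                        train_cfg)
    return net, history


TRANSFER_TRAINABLE_PREFIXES = ("fusion.f_ve", "head")


def transfer_finetune(model: MeNetNetwork, G_target: GenotypeMatrix,
                      y_target: np.ndarray, fraction: float = 0.10,
                      train_cfg: TrainConfig | None = None,
                      ) -> tuple[MeNetNetwork, TrainHistory, np.ndarray]:
    """Fine-tune a source-trained model on a small target-environment sample.

    Exactly the F_VE correction network and the prediction head are
    trainable; the RepGeno encoder, the VE trunk and F_RepGeno stay frozen
    (their tensors are bit-identical before and after).  ``fraction`` of the
    target samples is split evenly into fine-tuning train and validation
    halves; the remainder is the held-out test set, whose indices are
    returned.
    """
    if G_target.n_markers != sum(s.size for s in model.segments):
        raise ValueError("target marker set does not match the source model")
    train_cfg = train_cfg or TrainConfig()
    y_target = np.asarray(y_target, dtype=float)

    half = fraction / 2.0
    spec = SplitSpec(ratios=(half, half, 1.0 - fraction), seed=train_cfg.seed)
    tr, val, test = make_splits(G_target.n_samples, spec=spec)

    tuned = copy.deepcopy(model)
    for name, p in tuned.params():
        p.frozen = not name.startswith(TRANSFER_TRAINABLE_PREFIXES)
    opt = _nn.AdamW(tuned.trainable_params(), lr=train_cfg.lr,
                    weight_decay=train_cfg.weight_decay)
    history = _fit_loop(tuned, opt, G_target.codes[tr], y_target[tr],
                        G_target.codes[val], y_target[val], train_cfg)
    return tuned, history, test


def grid_search(G: GenotypeMatrix, y: np.ndarray, labels,
                splits: tuple[np.ndarray, np.ndarray, np.ndarray],
                margin_grid=(0.1, 0.3, 0.5), channel_grid=(4, 8),
                embed_dim: int = 64, repgeno_epochs: int = 15,
                train_cfg: TrainConfig | None = None,
                ) -> tuple[ModelConfig, TripletConfig, pd.DataFrame]:
    """Exhaustive search over (margin, channels); winner by validation R2.

    Every grid point is evaluated with the same seeds; the full results
    table is returned alongside the winning configs.
    """
    if not margin_grid or not channel_grid:
        raise ValueError("grids must be non-empty")
    train_cfg = train_cfg or TrainConfig()
    tr = splits[0]
    rows = []
    best = (-np.inf, None, None)
    for margin in margin_grid:
        tcfg = TripletConfig(margin=margin, embed_dim=embed_dim)
        G_train = GenotypeMatrix(
            samples=[G.samples[i] for i in tr], markers=G.markers,
            codes=G.codes[tr], encoded=G.encoded)
        encoder, _ = train_repgeno(
            G_train, np.asarray(y, dtype=float)[tr],
            None if labels is None else np.asarray(labels)[tr],
            tcfg, epochs=repgeno_epochs, seed=train_cfg.seed)
        for channels in channel_grid:
            mcfg = ModelConfig(ve_channels=channels, embed_dim=embed_dim)
            _, history = train_menet(G, y, encoder, splits, mcfg, train_cfg)
            val_r2 = max(history.val_r2) if history.val_r2 else -np.inf
            rows.append({"margin": margin, "channels": channels,
                         "val_r2": val_r2})
            if val_r2 > best[0]:
                best = (val_r2, mcfg, tcfg)
    table = pd.DataFrame(rows)
    return best[1], best[2], table
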