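"""Phenotype-aware genetic-relatedness embeddings (the random-effect branch).

A fully connected encoder maps each sample's {1, 0, -1} genotype vector to a
unit-norm embedding.  It is trained with a trait-aware triplet loss

    L = log(1 + exp(d+ - d- + m_gamma)),   m_gamma = D- - D+ + eps * margin,

where d+/d- are Euclidean distances between the (L2-normalized) anchor
embedding and the positive/negative embedding and D+/D- are the absolute
phenotypic differences between the anchor and the positive/negative sample.
The margin therefore widens when the negative is phenotypically distant and
narrows when the positive is, pushing embedding distances to track trait
dissimilarity on top of family separation.

Relatedness between two samples is the Euclidean embedding distance scaled
to [0, 1] (division by 2, the maximum distance between unit vectors).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from . import _nn
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TripletConfig",
    "TripletBatch",
    "RelatednessMatrix",
    "RepGenoEncoder",
    "sample_triplets",
    "triplet_loss",
    "train_repgeno",
    "relatedness_matrix",
]


@dataclass(frozen=True)
class TripletConfig:
    """Triplet-learning hyperparameters.

    margin: base margin (grid searched over {0.1, ..., 0.5} at full scale);
    epsilon: scale applied to the base margin inside m_gamma;
    embed_dim: embedding width (desk-scale default 64);
    hidden_dim: encoder hidden width.
    """

    margin: float = 0.3
    epsilon: float = 1.0
    embed_dim: int = 64
    hidden_dim: int = 128
    batch_size: int = 128

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class TripletBatch:
    """Anchor/positive/negative index triplets with phenotype deltas."""

    anchor: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    delta_pos: np.ndarray  # |pheno(anchor) - pheno(positive)|
    delta_neg: np.ndarray  # |pheno(anchor) - pheno(negative)|

    def __post_init__(self):
        n = len(self.anchor)
        for arr in (self.positive, self.negative, self.delta_pos, self.delta_neg):
            if len(arr) != n:
                raise ValueError("triplet arrays must have equal length")
        same = (self.anchor == self.positive) | (self.anchor == self.negative) \
            | (self.positive == self.negative)
        if np.any(same):
            raise ValueError("triplet indices must be distinct within a triplet")

    def __len__(self) -> int:
        return len(self.anchor)


@dataclass
class RelatednessMatrix:
    """Symmetric n x n matrix of [0, 1]-scaled embedding distances."""

    values: np.ndarray
    samples: list[str] | None = None

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relatedness matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("relatedness matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("relatedness diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("relatedness entries must lie in [0, 1]")

    def write(self, path) -> None:
        import pandas as pd
        ids = self.samples or [str(i) for i in range(self.values.shape[0])]
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(
            path, sep="\t", float_format="%.6g")


def sample_triplets(phenotypes: np.ndarray, labels: np.ndarray | None,
                    rng: np.random.Generator) -> TripletBatch:
    """One triplet per anchor for an epoch.

    With family labels present (>= 2 families): the positive is a random
    same-family sample, the negative a random other-family sample.  Without
    labels, two random candidates are drawn and the one phenotypically
    closer to the anchor serves as positive.  A single-family labeled input
    falls back to label-free mode with a warning.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    n = phenotypes.size
    if n < 3:
        raise ValueError("triplet sampling needs at least 3 samples")
    if labels is not None:
        labels = np.asarray(labels)
        if np.unique(labels).size < 2:
            warnings.warn("single-family labels: falling back to label-free "
                          "triplet sampling")
            labels = None
    anchors = np.arange(n)
    pos = np.empty(n, dtype=int)
    neg = np.empty(n, dtype=int)
    if labels is not None:
        for a in anchors:
            same = np.flatnonzero(labels == labels[a])
            same = same[same != a]
            other = np.flatnonzero(labels != labels[a])
            if same.size == 0:
                # singleton family: draw the phenotypically closest other-family
                # candidate as a stand-in positive
                cand = rng.choice(other, size=2, replace=False)
                d = np.abs(phenotypes[cand] - phenotypes[a])
                pos[a], neg[a] = (cand[0], cand[1]) if d[0] <= d[1] else (cand[1], cand[0])
                continue
            pos[a] = rng.choice(same)
            neg[a] = rng.choice(other)
    else:
        for a in anchors:
            others = np.delete(np.arange(n), a)
            cand = rng.choice(others, size=2, replace=False)
            d = np.abs(phenotypes[cand] - phenotypes[a])
            pos[a], neg[a] = (cand[0], cand[1]) if d[0] <= d[1] else (cand[1], cand[0])
    return TripletBatch(
        anchor=anchors, positive=pos, negative=neg,
        delta_pos=np.abs(phenotypes[anchors] - phenotypes[pos]),
        delta_neg=np.abs(phenotypes[anchors] - phenotypes[neg]))


def triplet_loss(d_pos, d_neg, delta_pos, delta_neg, epsilon: float,
                 margin: float):
    """Trait-aware triplet loss, elementwise over arrays.

    L = softplus(d+ - d- + m_gamma) with m_gamma = D- - D+ + epsilon*margin.
    The softplus form is numerically stable for large |argument|.
    """
    m_gamma = np.asarray(delta_neg, dtype=float) - np.asarray(delta_pos, dtype=float) \
        + epsilon * margin
    arg = np.asarray(d_pos, dtype=float) - np.asarray(d_neg, dtype=float) + m_gamma
    return _nn.softplus(arg)


class RepGenoEncoder:
    """Genotype -> unit-norm embedding encoder (MLP + L2 row normalization)."""

    def __init__(self, n_markers: int, cfg: TripletConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.n_markers = n_markers
        self.net = _nn.Sequential(
            _nn.Dense(n_markers, cfg.hidden_dim, rng),
            _nn.ReLU(),
            _nn.Dense(cfg.hidden_dim, cfg.embed_dim, rng),
        )
        self.pheno_mean = 0.0
        self.pheno_std = 1.0
        self._raw: np.ndarray | None = None
        self._norm: np.ndarray | None = None

    # -- forward / backward ------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        raw = self.net.forward(np.asarray(X, dtype=float))
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
        norms = np.maximum(norms, 1e-12)
        self._raw, self._norm = raw, norms
        return raw / norms

    def backward(self, g_embed: np.ndarray) -> np.ndarray:
        raw, norms = self._raw, self._norm
        self._raw = self._norm = None
        unit = raw / norms
        # d(v/||v||) Jacobian: (g - (g.u) u) / ||v||
        g_raw = (g_embed - (g_embed * unit).sum(axis=1, keepdims=True) * unit) / norms
        return self.net.backward(g_raw)

    def transform(self, X: np.ndarray | GenotypeMatrix) -> np.ndarray:
        if isinstance(X, GenotypeMatrix):
            X = X.codes
        raw = self.net.forward(np.asarray(X, dtype=float))
        norms = np.maximum(np.linalg.norm(raw, axis=1, keepdims=True), 1e-12)
        return raw / norms

    def params(self):
        return _nn.named_params(self.net, "repgeno")

    def freeze(self) -> None:
        for _, p in self.params():
            p.frozen = True


def train_repgeno(G: GenotypeMatrix, phenotypes: np.ndarray,
                  labels: np.ndarray | None, cfg: TripletConfig | None = None,
                  epochs: int = 30, lr: float = 1e-3, weight_decay: float = 1e-4,
                  seed: int = 0) -> tuple[RepGenoEncoder, list[float]]:
    """Train the relatedness encoder with the trait-aware triplet loss.

    Phenotypes are z-scored internally so that the phenotype deltas entering
    the adaptive margin are on a unit scale comparable with embedding
    distances.  Returns the encoder and the per-epoch mean loss history.
    """
    cfg = cfg or TripletConfig()
    X = G.codes if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    mu, sd = float(y.mean()), float(y.std())
    sd = sd if sd > 0 else 1.0
    y_std = (y - mu) / sd

    encoder = RepGenoEncoder(X.shape[1], cfg, seed=seed)
    encoder.pheno_mean, encoder.pheno_std = mu, sd
    opt = _nn.AdamW(encoder.params(), lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))

    history: list[float] = []
    n = X.shape[0]
    for _ in range(epochs):
        batch = sample_triplets(y_std, labels, rng)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            a, p_, ng = batch.anchor[idx], batch.positive[idx], batch.negative[idx]
            dp_, dn_ = batch.delta_pos[idx], batch.delta_neg[idx]
            stacked = np.concatenate([X[a], X[p_], X[ng]], axis=0)
            emb = encoder.forward(stacked)
            m = idx.size
            ea, ep, en = emb[:m], emb[m:2 * m], emb[2 * m:]
            diff_p = ea - ep
            diff_n = ea - en
            d_pos = np.maximum(np.linalg.norm(diff_p, axis=1), 1e-12)
            d_neg = np.maximum(np.linalg.norm(diff_n, axis=1), 1e-12)
            arg = d_pos - d_neg + (dn_ - dp_ + cfg.epsilon * cfg.margin)
            loss = _nn.softplus(arg)
            if not np.all(np.isfinite(loss)):
                raise FloatingPointError(
                    "non-finite triplet loss; reduce the learning rate")
            losses.append(loss.mean())
            s = _nn.sigmoid(arg) / m  # dL/darg averaged over the batch
            g_ea = s[:, None] * (diff_p / d_pos[:, None] - diff_n / d_neg[:, None])
            g_ep = -s[:, None] * diff_p / d_pos[:, None]
            g_en = s[:, None] * diff_n / d_neg[:, None]
            opt.zero_grad()
            encoder.backward(np.concatenate([g_ea, g_ep, g_en], axis=0))
            opt.step()
        history.append(float(np.mean(losses)))
    return encoder, history


def relatedness_matrix(embeddings: np.ndarray, samples: list[str] | None = None,
                       scale: str = "unit") -> RelatednessMatrix:
    """Pairwise embedding distances scaled to [0, 1].

    ``scale='unit'`` divides by 2 (the analytic maximum distance between
    unit vectors) and requires unit-norm rows; ``scale='minmax'`` rescales
    by the observed maximum instead.
    """
    E = np.asarray(embeddings, dtype=float)
    if scale == "unit":
        norms = np.linalg.norm(E, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("unit scaling requires unit-norm embeddings")
        D = squareform(pdist(E)) / 2.0
        D = np.clip(D, 0.0, 1.0)
    elif scale == "minmax":
        D = squareform(pdist(E))
        if D.max() > 0:
            D = D / D.max()
    else:
        raise ValueError("scale must be 'unit' or 'minmax'")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return RelatednessMatrix(values=D, samples=samples)
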