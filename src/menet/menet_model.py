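"""The dual-branch mixed-effect network.

Fixed-effect branch (VE): a 1-D convolutional trunk over the genotype vector
in marker order — one convolution, two residual blocks, adaptive average
pooling to a fixed length, then fully connected layers — producing an
embedding whose size is independent of the marker count.

Random-effect branch: the pre-trained relatedness encoder (see
:mod:`menet.repgeno`).

Fusion: the concatenation [z_VE; z_RepGeno] feeds two independent bottleneck
correction networks whose outputs are added back residually,

    z_VE_hat      = z_VE      + F_VE([z_VE; z_RepGeno])
    z_RepGeno_hat = z_RepGeno + F_RepGeno([z_VE; z_RepGeno]),

and the corrected pair, concatenated again, passes through a three-layer
fully connected head to the scalar prediction.

For marker counts above ``window_threshold`` the genotype is partitioned by
chromosome (and over-long chromosomes into fixed-size windows), each segment
gets its own VE instance, and the segment embeddings are merged by an
extended fusion step (each segment corrected against the concatenation of
all segments, then projected) before entering the branch fusion above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .genotype_io import GenotypeMatrix
from .repgeno import RepGenoEncoder

__all__ = [
    "ModelConfig",
    "EmbeddingPair",
    "VENetwork",
    "CrossFusion",
    "PredictionHead",
    "MeNetNetwork",
    "chromosome_partition",
]

MARGIN_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)
CHANNEL_GRID = (1, 2, 4, 8, 16, 64)
EMBED_GRID = (512, 1024, 4096, 8192)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Full-scale grids are channels {1,2,4,8,16,64} and embedding dimension
    {512,1024,4096,8192}; the defaults here are the desk-scale working
    point used throughout the synthetic studies.
    """

    ve_channels: int = 8
    embed_dim: int = 64
    pool_len: int = 64
    head_hidden: tuple[int, int] = (64, 32)
    window_threshold: int = 100_000
    bottleneck_dim: int = 0  # 0 -> embed_dim // 2
    # The unit-norm relatedness embedding has per-entry scale ~1/sqrt(E);
    # rescaling by sqrt(E) puts both branches on a comparable per-dimension
    # scale entering fusion, so neither branch is favoured at initialisation.
    rescale_repgeno: bool = True

    def __post_init__(self):
        if min(self.ve_channels, self.embed_dim, self.pool_len) < 1:
            raise ValueError("all dimensions must be positive")
        if len(self.head_hidden) != 2 or min(self.head_hidden) < 1:
            raise ValueError("head_hidden must be two positive integers")


@dataclass
class EmbeddingPair:
    """Branch embeddings before and after cross-information fusion."""

    z_ve: np.ndarray
    z_repgeno: np.ndarray
    z_ve_hat: np.ndarray | None = None
    z_repgeno_hat: np.ndarray | None = None


def chromosome_partition(G: GenotypeMatrix, threshold: int = 100_000,
                         window: int | None = None) -> list[np.ndarray]:
    """Partition marker indices for chromosome-aware window encoding.

    p <= threshold: a single segment.  Otherwise one segment per chromosome;
    a chromosome still longer than the threshold is split into fixed-size
    sliding windows of ``window`` markers (default: the threshold).
    Segments are disjoint and cover every marker.
    """
    p = G.n_markers
    if p <= threshold:
        return [np.arange(p)]
    chroms = [m.chromosome for m in G.markers]
    if any(c is None or c == "" for c in chroms):
        raise ValueError("chromosome metadata required for partitioning")
    window = window or threshold
    segments: list[np.ndarray] = []
    seen: list[str] = []
    arr = np.asarray(chroms)
    for c in chroms:
        if c in seen:
            continue
        seen.append(c)
        idx = np.flatnonzero(arr == c)
        if idx.size > threshold:
            segments.extend(idx[s:s + window] for s in range(0, idx.size, window))
        else:
            segments.append(idx)
    return segments


class VENetwork(_nn.Layer):
    """Residual-convolutional variant-effect branch for one marker segment."""

    MIN_LEN = 3  # receptive field of one kernel-3 convolution

    def __init__(self, n_markers: int, cfg: ModelConfig, rng: np.random.Generator,
                 out_dim: int | None = None):
        self.n_markers = n_markers
        if n_markers < self.MIN_LEN:
            warnings.warn("segment shorter than the convolution kernel; "
                          "inputs are zero-padded")
        c = cfg.ve_channels
        out_dim = out_dim or cfg.embed_dim
        pool_len = min(cfg.pool_len, max(n_markers, self.MIN_LEN))
        self.trunk = _nn.Sequential(
            _nn.Conv1d(1, c, rng),
            _nn.ReLU(),
            _nn.ResidualBlock1d(c, rng),
            _nn.ResidualBlock1d(c, rng),
            _nn.AdaptiveAvgPool1d(pool_len),
            _nn.Flatten(),
            _nn.Dense(c * pool_len, out_dim, rng),
            _nn.ReLU(),
            _nn.Dense(out_dim, out_dim, rng),
        )
        self._padded = max(0, self.MIN_LEN - n_markers)

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._padded:
            X = np.pad(X, ((0, 0), (0, self._padded)))
        return self.trunk.forward(X[:, None, :])

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.trunk.backward(gout)[:, 0, :]
        if self._padded:
            g = g[:, :self.n_markers]
        return g

    def params(self):
        return _nn.named_params(self.trunk, "ve")


def _bottleneck(n_in: int, hidden: int, n_out: int, rng: np.random.Generator,
                zero_out: bool = True) -> _nn.Sequential:
    """Three fully connected layers; zero-initialized output so the residual
    correction starts as the identity.  Smooth gated activations keep the
    fusion-head composition differentiable everywhere, so the integrated-
    gradients path integral converges quadratically."""
    return _nn.Sequential(
        _nn.Dense(n_in, hidden, rng),
        _nn.SmoothReLU(),
        _nn.Dense(hidden, hidden, rng),
        _nn.SmoothReLU(),
        _nn.Dense(hidden, n_out, rng, zero_init=zero_out),
    )


class CrossFusion(_nn.Layer):
    """Cross-information feature fusion: residual correction of both branches."""

    def __init__(self, embed_dim: int, rng: np.random.Generator,
                 bottleneck_dim: int = 0):
        hidden = bottleneck_dim or max(embed_dim // 2, 1)
        self.embed_dim = embed_dim
        self.f_ve = _bottleneck(2 * embed_dim, hidden, embed_dim, rng)
        self.f_repgeno = _bottleneck(2 * embed_dim, hidden, embed_dim, rng)

    def forward(self, z: np.ndarray) -> np.ndarray:
        """z is the concatenation [z_VE; z_RepGeno]; returns [z_VE_hat; z_RepGeno_hat]."""
        e = self.embed_dim
        if z.shape[1] != 2 * e:
            raise ValueError(f"fusion input width {z.shape[1]} != 2*{e}")
        corr_ve = self.f_ve.forward(z)
        corr_rg = self.f_repgeno.forward(z)
        return np.concatenate([z[:, :e] + corr_ve, z[:, e:] + corr_rg], axis=1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        e = self.embed_dim
        g_ve_hat, g_rg_hat = gout[:, :e], gout[:, e:]
        g = np.concatenate([g_ve_hat, g_rg_hat], axis=1)
        g += self.f_ve.backward(g_ve_hat)
        g += self.f_repgeno.backward(g_rg_hat)
        return g

    def params(self):
        return (_nn.named_params(self.f_ve, "fusion.f_ve") +
                _nn.named_params(self.f_repgeno, "fusion.f_repgeno"))


class PredictionHead(_nn.Layer):
    """Three fully connected layers mapping the corrected pair to a scalar."""

    def __init__(self, embed_dim: int, hidden: tuple[int, int],
                 rng: np.random.Generator):
        h1, h2 = hidden
        self.net = _nn.Sequential(
            _nn.Dense(2 * embed_dim, h1, rng),
            _nn.SmoothReLU(),
            _nn.Dense(h1, h2, rng),
            _nn.SmoothReLU(),
            _nn.Dense(h2, 1, rng),
        )

    def forward(self, z: np.ndarray) -> np.ndarray:
        return self.net.forward(z)[:, 0]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.net.backward(np.asarray(gout)[:, None])

    def params(self):
        return _nn.named_params(self.net, "head")


class _ExtendedFusion(_nn.Layer):
    """Merge per-segment VE embeddings: each segment embedding is corrected
    against the concatenation of all segment embeddings, the corrected
    segments are concatenated and projected back to embed_dim."""

    def __init__(self, n_segments: int, embed_dim: int, rng: np.random.Generator):
        self.n_segments = n_segments
        self.embed_dim = embed_dim
        hidden = max(embed_dim // 2, 1)
        self.correctors = [
            _bottleneck(n_segments * embed_dim, hidden, embed_dim, rng)
            for _ in range(n_segments)]
        self.project = _nn.Dense(n_segments * embed_dim, embed_dim, rng)

    def forward(self, z_all: np.ndarray) -> np.ndarray:
        e = self.embed_dim
        corrected = [
            z_all[:, k * e:(k + 1) * e] + self.correctors[k].forward(z_all)
            for k in range(self.n_segments)]
        return self.project.forward(np.concatenate(corrected, axis=1))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        e = self.embed_dim
        g_cat = self.project.backward(gout)
        g_all = g_cat.copy()
        for k in range(self.n_segments):
            g_all += self.correctors[k].backward(g_cat[:, k * e:(k + 1) * e])
        return g_all

    def params(self):
        out = [(f"extfusion.project.{n}", p) for n, p in self.project.params()]
        for k, c in enumerate(self.correctors):
            out += _nn.named_params(c, f"extfusion.c{k}")
        return out


class MeNetNetwork:
    """Full dual-branch network: VE segments + frozen/unfrozen RepGeno encoder,
    cross fusion, and the prediction head.

    The forward pass is a deterministic function of (parameters, input); all
    stochasticity lives in initialisation and minibatch order.
    """

    def __init__(self, G: GenotypeMatrix, encoder: RepGenoEncoder,
                 cfg: ModelConfig | None = None, seed: int = 0,
                 train_encoder: bool = False):
        cfg = cfg or ModelConfig()
        if encoder.cfg.embed_dim != cfg.embed_dim:
            raise ValueError(
                f"branch embeddings must share embed_dim "
                f"(RepGeno {encoder.cfg.embed_dim} vs VE {cfg.embed_dim})")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        self.cfg = cfg
        self.encoder = encoder
        self.train_encoder = train_encoder
        self.segments = chromosome_partition(G, cfg.window_threshold)
        self.ve_nets = [VENetwork(seg.size, cfg, rng) for seg in self.segments]
        if len(self.segments) > 1:
            self.ext_fusion = _ExtendedFusion(len(self.segments), cfg.embed_dim, rng)
        else:
            self.ext_fusion = None
        self._rg_scale = float(np.sqrt(cfg.embed_dim)) if cfg.rescale_repgeno \
            else 1.0
        self.fusion = CrossFusion(cfg.embed_dim, rng, cfg.bottleneck_dim)
        self.head = PredictionHead(cfg.embed_dim, cfg.head_hidden, rng)
        # target standardisation: the head learns on unit scale, forward
        # returns trait units (set from the training split by the trainer)
        self.y_mean = 0.0
        self.y_std = 1.0
        if not train_encoder:
            encoder.freeze()

    # ------------------------------------------------------------------
    def branch_embeddings(self, X: np.ndarray) -> EmbeddingPair:
        z_segs = [net.forward(X[:, seg]) for net, seg in
                  zip(self.ve_nets, self.segments)]
        if self.ext_fusion is not None:
            z_ve = self.ext_fusion.forward(np.concatenate(z_segs, axis=1))
        else:
            z_ve = z_segs[0]
        z_rg = self.encoder.forward(X) * self._rg_scale
        return EmbeddingPair(z_ve=z_ve, z_repgeno=z_rg)

    def forward(self, X: np.ndarray) -> np.ndarray:
        pair = self.branch_embeddings(X)
        fused = self.fusion.forward(
            np.concatenate([pair.z_ve, pair.z_repgeno], axis=1))
        return self.head.forward(fused) * self.y_std + self.y_mean

    def backward(self, g_yhat: np.ndarray) -> None:
        e = self.cfg.embed_dim
        g_fused = self.fusion.backward(self.head.backward(g_yhat * self.y_std))
        g_ve, g_rg = g_fused[:, :e], g_fused[:, e:]
        if self.ext_fusion is not None:
            g_cat = self.ext_fusion.backward(g_ve)
            for k, net in enumerate(self.ve_nets):
                net.backward(g_cat[:, k * e:(k + 1) * e])
        else:
            self.ve_nets[0].backward(g_ve)
        if self.train_encoder:
            self.encoder.backward(g_rg * self._rg_scale)
        else:
            self.encoder._raw = self.encoder._norm = None

    def predict(self, X: np.ndarray | GenotypeMatrix) -> np.ndarray:
        if isinstance(X, GenotypeMatrix):
            X = X.codes
        return self.forward(np.asarray(X, dtype=float))

    # ------------------------------------------------------------------
    def params(self) -> list[tuple[str, _nn.Param]]:
        out: list[tuple[str, _nn.Param]] = []
        for k, net in enumerate(self.ve_nets):
            out += [(f"ve{k}.{n}", p) for n, p in net.params()]
        if self.ext_fusion is not None:
            out += self.ext_fusion.params()
        out += self.fusion.params()
        out += self.head.params()
        out += self.encoder.params()
        return out

    def trainable_params(self):
        return [(n, p) for n, p in self.params() if not p.frozen]

    def state(self) -> dict[str, np.ndarray]:
        return _nn.clone_values(self.params())

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        _nn.load_values(self.params(), state)

    # ------------------------------------------------------------------
    def fused_function(self):
        """F(z): fusion + head evaluated on the fused embedding z = [z_VE; z_RepGeno].

        Returns a callable mapping an (n, 2*embed_dim) array to
        ``(values, gradients)`` — the interface consumed by integrated
        gradients.  Gradients are taken at the embedding, not the genotype.
        """
        def func(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            z = np.atleast_2d(np.asarray(z, dtype=float))
            y = self.head.forward(self.fusion.forward(z)) * self.y_std \
                + self.y_mean
            frozen = [(p, p.frozen) for _, p in
                      self.fusion.params() + self.head.params()]
            for p, _ in frozen:
                p.frozen = True
            g = self.fusion.backward(
                self.head.backward(np.full(y.shape, self.y_std)))
            for p, was in frozen:
                p.frozen = was
            return y, g
        return func

    def branch_index_sets(self) -> tuple[np.ndarray, np.ndarray]:
        """Named index sets of the fused embedding: (VE dims, RepGeno dims)."""
        e = self.cfg.embed_dim
        return np.arange(e), np.arange(e, 2 * e)
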