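"""Model/Results interface for the mixed-effect genomic predictor.

    >>> gm, labels = simulate_genotypes(PopulationSpec(seed=1))
    >>> phenos = simulate_trait(gm, labels, TraitArchitecture(...))
    >>> model = MeNet(gm, phenos, labels=labels)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    >>> res.predict(new_genotypes)

``MeNet`` holds the data and architecture choices; ``fit`` runs the
two-stage training (relatedness-encoder pre-training, then VE + fusion +
head on mean absolute error) and returns a ``MeNetResults`` carrying the
trained network, the training history, held-out metrics, branch-contribution
attribution and transfer-learning entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import Metrics, compute_metrics
from .genotype_io import GenotypeMatrix
from .interpret import AttributionReport, attribute_model
from .menet_model import MeNetNetwork, ModelConfig
from .repgeno import (RelatednessMatrix, RepGenoEncoder, TripletConfig,
                      relatedness_matrix, train_repgeno)
from .trait_sim import PhenotypeTable
from .trainer import (SplitSpec, TrainConfig, TrainHistory, make_splits,
                      train_menet, transfer_finetune)

__all__ = ["MeNet", "MeNetResults"]


class MeNet:
    """Mixed-effect dual-branch genomic prediction model.

    Parameters
    ----------
    genotypes : encoded GenotypeMatrix (codes in {1, 0, -1})
    phenotypes : PhenotypeTable, or a 1-D array aligned with the samples
    environment : which environment of the table to model (default: first)
    labels : optional family/population labels used by triplet sampling
    model_config, triplet_config : architecture hyperparameters
    """

    def __init__(self, genotypes: GenotypeMatrix,
                 phenotypes: PhenotypeTable | np.ndarray,
                 environment: str | None = None,
                 labels: np.ndarray | None = None,
                 model_config: ModelConfig | None = None,
                 triplet_config: TripletConfig | None = None):
        if not genotypes.encoded:
            raise ValueError("genotypes must be encoded ({1,0,-1}) before "
                             "modelling; run encode_and_impute")
        self.genotypes = genotypes
        if isinstance(phenotypes, PhenotypeTable):
            env = environment or phenotypes.environments[0]
            self.y = phenotypes.values_for(genotypes.samples, env)
            self.environment = env
        else:
            self.y = np.asarray(phenotypes, dtype=float)
            self.environment = environment or "E1"
        if self.y.shape != (genotypes.n_samples,):
            raise ValueError("one phenotype per sample required")
        self.labels = None if labels is None else np.asarray(labels)
        self.model_config = model_config or ModelConfig()
        self.triplet_config = triplet_config or TripletConfig(
            embed_dim=self.model_config.embed_dim)
        if self.triplet_config.embed_dim != self.model_config.embed_dim:
            raise ValueError("branch embedding dimensions must match")

    @classmethod
    def from_dataframe(cls, codes: pd.DataFrame, phenotypes: pd.DataFrame
                       | pd.Series, **kw) -> "MeNet":
        """Build from a sample x marker code DataFrame and a phenotype frame.

        ``phenotypes`` may be a Series indexed by sample or a long-format
        frame with columns sample/environment/value.
        """
        from .genotype_io import MarkerMeta
        markers = [MarkerMeta(str(c), "1", i) for i, c in enumerate(codes.columns)]
        gm = GenotypeMatrix(samples=[str(s) for s in codes.index],
                            markers=markers,
                            codes=codes.to_numpy(dtype=float), encoded=True)
        if isinstance(phenotypes, pd.Series):
            y = phenotypes.loc[codes.index].to_numpy(dtype=float)
            return cls(gm, y, **kw)
        return cls(gm, PhenotypeTable(phenotypes), **kw)

    def fit(self, split: SplitSpec | None = None,
            train_config: TrainConfig | None = None,
            repgeno_epochs: int = 30, seed: int = 0,
            train_encoder: bool = False) -> "MeNetResults":
        """Two-stage training; returns results at the best-validation-R2 checkpoint."""
        split = split or SplitSpec(seed=seed)
        train_config = train_config or TrainConfig(seed=seed)
        splits = make_splits(self.genotypes.n_samples, self.y, split)
        tr = splits[0]
        G_train = GenotypeMatrix(
            samples=[self.genotypes.samples[i] for i in tr],
            markers=self.genotypes.markers,
            codes=self.genotypes.codes[tr], encoded=True)
        encoder, rep_history = train_repgeno(
            G_train, self.y[tr],
            None if self.labels is None else self.labels[tr],
            self.triplet_config, epochs=repgeno_epochs, seed=seed)
        network, history = train_menet(
            self.genotypes, self.y, encoder, splits,
            self.model_config, train_config, train_encoder=train_encoder)
        return MeNetResults(model=self, network=network, encoder=encoder,
                            history=history, repgeno_history=rep_history,
                            splits=splits, seed=seed)


@dataclass
class MeNetResults:
    """Fitted-model container: predictions, diagnostics, transfer, attribution."""

    model: MeNet
    network: MeNetNetwork
    encoder: RepGenoEncoder
    history: TrainHistory
    repgeno_history: list[float]
    splits: tuple[np.ndarray, np.ndarray, np.ndarray]
    seed: int
    _metrics: dict[str, Metrics] = field(default_factory=dict, repr=False)

    def predict(self, genotypes: GenotypeMatrix | np.ndarray | None = None
                ) -> np.ndarray:
        X = self.model.genotypes.codes if genotypes is None else (
            genotypes.codes if isinstance(genotypes, GenotypeMatrix) else
            np.asarray(genotypes, dtype=float))
        return self.network.forward(X)

    def metrics(self, split: str = "test") -> Metrics:
        """Held-out metrics on one of the fit splits ('train'/'val'/'test')."""
        if split not in self._metrics:
            idx = dict(zip(("train", "val", "test"), self.splits))[split]
            yhat = self.network.forward(self.model.genotypes.codes[idx])
            self._metrics[split] = compute_metrics(self.model.y[idx], yhat)
        return self._metrics[split]

    def relatedness(self, genotypes: GenotypeMatrix | None = None
                    ) -> RelatednessMatrix:
        G = genotypes or self.model.genotypes
        return relatedness_matrix(self.encoder.transform(G), samples=G.samples)

    def contributions(self, split: str = "val", steps: int = 256
                      ) -> AttributionReport:
        """Integrated-gradients branch contributions on a fit split."""
        idx = dict(zip(("train", "val", "test"), self.splits))[split]
        return attribute_model(self.network,
                               self.model.genotypes.codes[idx], steps=steps)

    def transfer(self, genotypes: GenotypeMatrix, phenotypes: PhenotypeTable
                 | np.ndarray, environment: str | None = None,
                 fraction: float = 0.10,
                 train_config: TrainConfig | None = None) -> "MeNetResults":
        """Fine-tune on a fraction of a target environment (F_VE + head only)."""
        if isinstance(phenotypes, PhenotypeTable):
            y = phenotypes.values_for(genotypes.samples, environment)
        else:
            y = np.asarray(phenotypes, dtype=float)
        train_config = train_config or TrainConfig(seed=self.seed)
        tuned, history, test_idx = transfer_finetune(
            self.network, genotypes, y, fraction=fraction,
            train_cfg=train_config)
        half = fraction / 2.0
        spec = SplitSpec(ratios=(half, half, 1.0 - fraction),
                         seed=train_config.seed)
        splits = make_splits(genotypes.n_samples, spec=spec)
        target = MeNet(genotypes, y, environment=environment,
                       model_config=self.model.model_config,
                       triplet_config=self.model.triplet_config)
        return MeNetResults(model=target, network=tuned, encoder=self.encoder,
                            history=history, repgeno_history=[],
                            splits=splits, seed=train_config.seed)

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results tables."""
        m = self.metrics("test")
        v = self.metrics("val")
        cfg = self.network.cfg
        lines = [
            "                Mixed-Effect Genomic Prediction Results",
            "=" * 68,
            f"Environment:        {self.model.environment:<20} "
            f"N samples:     {self.model.genotypes.n_samples}",
            f"N markers:          {self.model.genotypes.n_markers:<20} "
            f"Embed dim:     {cfg.embed_dim}",
            f"VE channels:        {cfg.ve_channels:<20} "
            f"Segments:      {len(self.network.segments)}",
            f"Best epoch:         {self.history.best_epoch:<20} "
            f"Seed:          {self.seed}",
            "-" * 68,
            f"{'metric':<10}{'validation':>14}{'test':>14}",
            f"{'R2':<10}{v.R2:>14.4f}{m.R2:>14.4f}",
            f"{'PCC':<10}{v.PCC:>14.4f}{m.PCC:>14.4f}",
            f"{'MAE':<10}{v.MAE:>14.4f}{m.MAE:>14.4f}",
            f"{'NMSE':<10}{v.NMSE:>14.4f}{m.NMSE:>14.4f}",
            "=" * 68,
            "R2 is the squared Pearson correlation between predicted and",
            "observed phenotypes on the held-out split.",
        ]
        return "\n".join(lines)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for split in ("train", "val", "test"):
            rows += self.metrics(split).as_rows(
                environment=self.model.environment, split=split)
        return pd.DataFrame(rows, columns=["trait", "environment", "split",
                                           "metric", "value"])

    def plot_training(self, ax=None):
        """Training curve: train MAE and validation R2 per epoch."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        df = self.history.frame()
        ax.plot(df["epoch"], df["train_mae"], label="train MAE")
        ax2 = ax.twinx()
        ax2.plot(df["epoch"], df["val_r2"], color="C1", label="val R2")
        ax.set_xlabel("epoch")
        ax.set_ylabel("train MAE")
        ax2.set_ylabel("validation R2")
        ax.axvline(self.history.best_epoch, ls="--", color="grey", lw=0.8)
        return ax
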