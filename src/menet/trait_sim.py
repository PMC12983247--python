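"""Synthetic multi-family populations and quantitative traits.

The simulator produces the statistical structure a mixed-effect genomic
predictor assumes: several diverged families (recombinant-inbred-line-like,
mostly homozygous), linkage-disequilibrium blocks, a trait built from an
intercept, additive marker effects, pairwise epistatic products, a
family-level random effect, and environment-specific effect scaling plus
noise:

    y_e = b0 + s_e * (sum_i beta_i X_i + sum_{(i,j) in C} theta_ij X_i X_j)
          + Z gamma + eps_e,    eps_e ~ N(0, sigma2_env)

LD blocks are generated by copying latent founder haplotypes: each family
carries a small pool of founder haplotypes per block, every sample copies
one pool member and mutates each marker independently with a small
probability.  Correlation within a block is then controlled by the pool
size and mutation rate; blocks are independent.  Blocks of size one are
drawn i.i.d. per sample (no pool), so single-marker allele frequencies are
exactly binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MarkerMeta

__all__ = [
    "PopulationSpec",
    "EnvProfile",
    "TraitArchitecture",
    "PhenotypeTable",
    "simulate_genotypes",
    "simulate_trait",
    "random_architecture",
    "correlated_env_profiles",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Shape of the simulated panel.

    divergence is the s.d. of family-specific allele-frequency offsets;
    founder_pool controls within-block LD strength (fewer founders = more LD);
    het_rate is the residual heterozygosity of the inbred lines.
    """

    n_samples: int = 600
    n_markers: int = 500
    n_populations: int = 3
    divergence: float = 0.15
    ld_block_size: int = 10
    base_maf: float = 0.3
    founder_pool: int = 4
    mutation_rate: float = 0.03
    het_rate: float = 0.05
    # balanced founder pools pair every haplotype with its complement, making
    # the within-block genotype distribution exactly sign-symmetric (odd
    # moments vanish); requires base_maf = 0.5 to preserve allele frequency.
    symmetric_founders: bool = False
    markers_per_chromosome: int = 0  # 0 = single chromosome
    marker_spacing_bp: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_markers < 1:
            raise ValueError("n_samples and n_markers must be positive")
        if self.n_populations > self.n_samples:
            raise ValueError("n_populations must not exceed n_samples")
        if self.ld_block_size > self.n_markers:
            raise ValueError("ld_block_size must not exceed n_markers")
        if not 0.0 < self.base_maf <= 0.5:
            raise ValueError("base_maf must lie in (0, 0.5]")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.symmetric_founders and (self.base_maf != 0.5
                                        or self.divergence != 0.0):
            raise ValueError("symmetric_founders requires base_maf = 0.5 "
                             "and divergence = 0")


@dataclass(frozen=True)
class EnvProfile:
    """One environment: per-marker effect scaling and a noise variance.

    ``scaling`` of None means no rescaling (all ones).  ``noise_var`` is
    overridden when the trait architecture requests a target heritability.
    """

    name: str
    scaling: np.ndarray | None = None
    noise_var: float = 1.0


@dataclass
class TraitArchitecture:
    """Genetic architecture of a simulated trait."""

    intercept: float = 0.0
    additive_effects: dict[int, float] = field(default_factory=dict)
    epistatic_pairs: dict[tuple[int, int], float] = field(default_factory=dict)
    family_variance: float = 0.0
    target_h2: float | None = None
    env_profiles: list[EnvProfile] = field(default_factory=lambda: [EnvProfile("E1")])
    seed: int = 0

    def __post_init__(self):
        for (i, j) in self.epistatic_pairs:
            if i == j:
                raise ValueError(f"epistatic pair ({i},{j}) must have i != j")
        if self.target_h2 is not None and not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must lie in [0, 1]")


@dataclass
class PhenotypeTable:
    """Long-format trait values: one row per (sample, environment)."""

    frame: pd.DataFrame  # columns: sample, environment, value[, population]

    def __post_init__(self):
        required = {"sample", "environment", "value"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"phenotype table must have columns {sorted(required)}")
        if not np.isfinite(self.frame["value"].to_numpy(float)).all():
            raise ValueError("phenotype values must be finite")
        if self.frame.duplicated(["sample", "environment"]).any():
            raise ValueError("duplicate (sample, environment) rows")

    @property
    def environments(self) -> list[str]:
        return list(pd.unique(self.frame["environment"]))

    def values_for(self, samples: list[str], environment: str | None = None) -> np.ndarray:
        env = environment or self.environments[0]
        sub = self.frame[self.frame["environment"] == env]
        lookup = dict(zip(sub["sample"], sub["value"]))
        try:
            return np.array([lookup[s] for s in samples], dtype=float)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"no phenotype for sample {e} in environment {env}")

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str}))


def simulate_genotypes(spec: PopulationSpec) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate a multi-family panel; returns (GenotypeMatrix, family labels).

    Output codes are {1, 0, -1} (``encoded=True``); labels are integer family
    indices in [0, n_populations).
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_samples, spec.n_markers, spec.n_populations
    base_freq = np.full(p, spec.base_maf)
    # family allele-frequency offsets create between-family divergence
    fam_freq = np.clip(
        base_freq[None, :] + rng.normal(0.0, spec.divergence, size=(k, p)),
        0.02, 0.98)
    labels = np.sort(rng.integers(0, k, size=n))
    # guarantee every family non-empty
    for fam in range(k):
        if not np.any(labels == fam):
            labels[rng.integers(0, n)] = fam
    labels = np.sort(labels)

    hap1 = np.empty((n, p), dtype=np.int8)
    blocks = [np.arange(s, min(s + spec.ld_block_size, p))
              for s in range(0, p, spec.ld_block_size)]
    for fam in range(k):
        rows = np.flatnonzero(labels == fam)
        for blk in blocks:
            f = fam_freq[fam, blk]
            if blk.size == 1:
                hap1[np.ix_(rows, blk)] = (
                    rng.random((rows.size, 1)) < f).astype(np.int8)
                continue
            if spec.symmetric_founders:
                half = max(spec.founder_pool // 2, 1)
                base = (rng.random((half, blk.size)) < f).astype(np.int8)
                pool = np.concatenate([base, 1 - base], axis=0)
            else:
                pool = (rng.random((spec.founder_pool, blk.size)) < f
                        ).astype(np.int8)
            choice = rng.integers(0, pool.shape[0], size=rows.size)
            h = pool[choice]
            mutate = rng.random((rows.size, blk.size)) < spec.mutation_rate
            fresh = (rng.random((rows.size, blk.size)) < f).astype(np.int8)
            hap1[np.ix_(rows, blk)] = np.where(mutate, fresh, h)

    # inbred lines: second haplotype equals the first apart from residual het
    flip = rng.random((n, p)) < spec.het_rate
    hap2 = np.where(flip, 1 - hap1, hap1)
    codes = (hap1 + hap2 - 1).astype(np.float64)

    if spec.markers_per_chromosome and spec.markers_per_chromosome < p:
        per_chrom = spec.markers_per_chromosome
    else:
        per_chrom = p
    markers = [MarkerMeta(id=f"m{i}", chromosome=str(i // per_chrom + 1),
                          position=(i % per_chrom + 1) * spec.marker_spacing_bp)
               for i in range(p)]
    samples = [f"S{i:05d}" for i in range(n)]
    G = GenotypeMatrix(samples=samples, markers=markers, codes=codes, encoded=True)
    return G, labels


def _genetic_score(codes: np.ndarray, arch: TraitArchitecture,
                   scaling: np.ndarray | None) -> np.ndarray:
    p = codes.shape[1]
    s = np.ones(p) if scaling is None else np.asarray(scaling, dtype=float)
    if s.shape != (p,):
        raise ValueError(f"env scaling has shape {s.shape}, expected ({p},)")
    g = np.zeros(codes.shape[0])
    for i, beta in arch.additive_effects.items():
        if not 0 <= i < p:
            raise IndexError(f"additive effect index {i} out of range")
        g += s[i] * beta * codes[:, i]
    for (i, j), theta in arch.epistatic_pairs.items():
        if not (0 <= i < p and 0 <= j < p):
            raise IndexError(f"epistatic pair ({i},{j}) out of range")
        g += np.sqrt(abs(s[i] * s[j])) * np.sign(s[i] * s[j]) * theta \
            * codes[:, i] * codes[:, j]
    return g


def simulate_trait(G: GenotypeMatrix, labels: np.ndarray | None,
                   arch: TraitArchitecture) -> PhenotypeTable:
    """Simulate the trait under ``arch`` for every environment profile.

    When ``arch.target_h2`` is set, each environment's noise variance is
    solved from the realized heritable variance (genetic score plus family
    effect) so that Var(heritable)/Var(y) matches the target; the stated
    ``noise_var`` of the profiles is then ignored.
    """
    rng = np.random.default_rng(arch.seed)
    n = G.n_samples
    if labels is None:
        labels = np.zeros(n, dtype=int)
    labels = np.asarray(labels)

    fams = np.unique(labels)
    if arch.family_variance > 0:
        gamma = rng.normal(0.0, np.sqrt(arch.family_variance), size=fams.size)
        z_gamma = gamma[np.searchsorted(fams, labels)]
    else:
        z_gamma = np.zeros(n)

    rows = []
    for prof in arch.env_profiles:
        genetic = _genetic_score(G.codes, arch, prof.scaling)
        heritable = genetic + z_gamma
        var_h = float(np.var(heritable))
        if arch.target_h2 is not None:
            if arch.target_h2 >= 1.0:
                sigma2 = 0.0
            else:
                if var_h == 0.0 and arch.target_h2 > 0.0:
                    raise ValueError(
                        "target_h2 > 0 requires non-zero heritable variance")
                sigma2 = var_h * (1.0 - arch.target_h2) / arch.target_h2 \
                    if arch.target_h2 > 0 else prof.noise_var
        else:
            sigma2 = prof.noise_var
        eps = rng.normal(0.0, np.sqrt(sigma2), size=n) if sigma2 > 0 else np.zeros(n)
        y = arch.intercept + heritable + eps
        rows.append(pd.DataFrame({
            "sample": G.samples, "environment": prof.name, "value": y,
            "population": labels}))
    return PhenotypeTable(pd.concat(rows, ignore_index=True))


def random_architecture(n_markers: int, n_additive: int = 10,
                        beta_sd: float = 1.0, n_epistatic: int = 0,
                        theta_sd: float = 1.0, theta_decay: float = 1.0,
                        max_pair_distance: int = 3,
                        family_variance: float = 0.0,
                        target_h2: float | None = 0.6,
                        env_profiles: list[EnvProfile] | None = None,
                        seed: int = 0) -> TraitArchitecture:
    """Draw a random trait architecture.

    Additive loci are chosen uniformly; epistatic partners are drawn within
    ``max_pair_distance`` markers of each other, emulating interactions
    between variants on the same haplotype block (proximal epistasis).
    Effect sizes are normal with the given standard deviations; with
    ``theta_decay`` < 1 the k-th epistatic magnitude is theta_sd * decay^k
    (random sign), giving the decaying interaction spectrum in which a few
    pairs dominate the epistatic variance.
    """
    rng = np.random.default_rng(seed)
    additive = {}
    if n_additive > 0:
        idx = rng.choice(n_markers, size=min(n_additive, n_markers),
                         replace=False)
        for i in idx:
            additive[int(i)] = float(rng.normal(0.0, beta_sd))
    pairs: dict[tuple[int, int], float] = {}
    attempts = 0
    while len(pairs) < n_epistatic and attempts < 50 * max(n_epistatic, 1):
        attempts += 1
        i = int(rng.integers(0, n_markers))
        lo = max(0, i - max_pair_distance)
        hi = min(n_markers - 1, i + max_pair_distance)
        j = int(rng.integers(lo, hi + 1))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key not in pairs:
            if theta_decay < 1.0:
                k = len(pairs)
                pairs[key] = float(rng.choice([-1.0, 1.0])
                                   * theta_sd * theta_decay ** k)
            else:
                pairs[key] = float(rng.normal(0.0, theta_sd))
    return TraitArchitecture(
        intercept=float(rng.normal(0.0, 0.5)),
        additive_effects=additive, epistatic_pairs=pairs,
        family_variance=family_variance, target_h2=target_h2,
        env_profiles=env_profiles or [EnvProfile("E1")],
        seed=int(rng.integers(0, 2**31 - 1)))


def correlated_env_profiles(n_markers: int, rho: float, names=("E1", "E2"),
                            seed: int = 0) -> list[EnvProfile]:
    """Two environment profiles whose genetic values correlate at about rho.

    The first environment uses unit scaling; the second scales every marker
    effect by rho + sqrt(1-rho^2) * z_i with independent standard-normal z,
    giving an expected cross-environment genetic correlation of rho when
    per-marker effect contributions are comparable.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    s2 = rho + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(size=n_markers)
    return [EnvProfile(names[0], None), EnvProfile(names[1], s2)]
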