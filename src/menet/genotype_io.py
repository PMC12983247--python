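"""Genotype reading, quality control, and {1, 0, -1} encoding.

Two input dialects are supported:

* VCF 4.x (via :mod:`cyvcf2`) — biallelic SNP records only; multiallelic or
  non-SNP records are skipped with a warning.
* A plain text matrix: tab-separated, one row per sample, header row of
  marker IDs, first column ``sample``; a companion marker-metadata table
  (``id``, ``chrom``, ``pos``, ``ref``, ``alt``) carries positions.

Genotypes are coded 1 for homozygous-alternate, -1 for homozygous-reference,
0 for heterozygous; missing calls are imputed with 0.  Under this coding a
heterozygote and an imputed missing call are indistinguishable — that is a
property of the coding itself, not an artifact of this implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMeta",
    "GenotypeMatrix",
    "QCConfig",
    "read_genotypes",
    "write_genotypes",
    "encode_and_impute",
    "apply_qc",
    "minor_allele_frequency",
]


@dataclass(frozen=True)
class MarkerMeta:
    """Metadata for one biallelic marker."""

    id: str
    chromosome: str
    position: int
    ref_allele: str = "A"
    alt_allele: str = "T"

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"negative position for marker {self.id}")


@dataclass
class GenotypeMatrix:
    """Sample x marker genotype codes with marker metadata.

    ``codes`` holds alt-allele dosages {0, 1, 2} (NaN = missing) while
    ``encoded`` is False, and {1, 0, -1} codes afterwards.
    """

    samples: list[str]
    markers: list[MarkerMeta]
    codes: np.ndarray
    encoded: bool = False

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.float64)
        if self.codes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": [m.id for m in self.markers],
             "chrom": [m.chromosome for m in self.markers],
             "pos": [m.position for m in self.markers],
             "ref": [m.ref_allele for m in self.markers],
             "alt": [m.alt_allele for m in self.markers]})

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[i] for i in keep],
            codes=self.codes[:, keep].copy(),
            encoded=self.encoded)

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_markers),
                       key=lambda i: (self.markers[i].chromosome,
                                      self.markers[i].position))
        return self.subset_markers(np.asarray(order))


@dataclass(frozen=True)
class QCConfig:
    """Marker QC: MAF filter followed by greedy sliding-window LD pruning.

    Window/step are in base pairs by default (``window_unit='bp'``);
    ``window_unit='count'`` switches to PLINK-style marker-count windows.
    """

    maf_min: float = 0.01
    ld_window_bp: int = 2000
    ld_step_bp: int = 1000
    ld_r2_max: float = 0.5
    window_unit: str = "bp"

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not 0.0 < self.ld_r2_max <= 1.0:
            raise ValueError("ld_r2_max must lie in (0, 1]")
        if self.ld_step_bp > self.ld_window_bp:
            raise ValueError("ld_step_bp must not exceed ld_window_bp")
        if self.window_unit not in ("bp", "count"):
            raise ValueError("window_unit must be 'bp' or 'count'")


def read_genotypes(path: str | Path, format: str = "matrix",
                   marker_meta: str | Path | None = None) -> GenotypeMatrix:
    """Read a genotype file into a raw (possibly missing) :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : file path
    format : ``'vcf'`` or ``'matrix'``
    marker_meta : for the matrix dialect, path to the marker metadata table;
        defaults to ``<path>.markers.tsv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path, marker_meta)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("no samples in VCF")
    markers: list[MarkerMeta] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multiallelic record {var.CHROM}:{var.POS}")
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            warnings.warn(f"skipping non-SNP record {var.CHROM}:{var.POS}")
            continue
        col = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 0:
                col[i] = np.nan
            elif len(alleles) != 2:
                raise ValueError(
                    f"non-diploid call at {var.CHROM}:{var.POS} sample {samples[i]}")
            else:
                col[i] = alleles[0] + alleles[1]
        markers.append(MarkerMeta(
            id=var.ID or f"{var.CHROM}_{var.POS}",
            chromosome=str(var.CHROM), position=int(var.POS),
            ref_allele=var.REF, alt_allele=var.ALT[0]))
        columns.append(col)
    if not markers:
        raise ValueError("no records in VCF")
    codes = np.column_stack(columns)
    return GenotypeMatrix(samples=samples, markers=markers, codes=codes)


def _read_matrix(path: Path, marker_meta: str | Path | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError("no records: genotype matrix has zero samples")
    meta_path = Path(marker_meta) if marker_meta else path.with_suffix(
        path.suffix + ".markers.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
        lookup = {str(r.id): MarkerMeta(str(r.id), str(r.chrom), int(r.pos),
                                        str(r.ref), str(r.alt))
                  for r in meta.itertuples()}
        markers = [lookup[str(c)] for c in df.columns]
    else:
        logger.warning("no marker metadata at %s; synthesising positions", meta_path)
        markers = [MarkerMeta(str(c), "1", i) for i, c in enumerate(df.columns)]
    codes = df.to_numpy(dtype=float)
    # The matrix dialect carries encoded codes; flag accordingly.
    finite = codes[np.isfinite(codes)]
    encoded = bool(finite.size) and bool(np.isin(finite, (-1.0, 0.0, 1.0)).all())
    return GenotypeMatrix(samples=[str(s) for s in df.index], markers=markers,
                          codes=codes, encoded=encoded)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix dialect plus the companion marker-metadata table."""
    path = Path(path)
    df = pd.DataFrame(G.codes, index=G.samples,
                      columns=[m.id for m in G.markers])
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.0f")
    G.marker_frame().to_csv(path.with_suffix(path.suffix + ".markers.tsv"),
                            sep="\t", index=False)


def encode_and_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    """Map dosages to {1, 0, -1} (hom-alt, het, hom-ref) and impute missing with 0.

    Idempotent: an already-encoded matrix passes through unchanged apart from
    zero-imputation of any remaining missing entries.
    """
    codes = G.codes.copy()
    missing = ~np.isfinite(codes)
    if G.encoded:
        codes[missing] = 0.0
        return replace(G, codes=codes, encoded=True)
    observed = codes[~missing]
    if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
        raise ValueError("raw dosage matrix contains values outside {0, 1, 2}")
    codes = codes - 1.0  # 0->-1 (hom-ref), 1->0 (het), 2->1 (hom-alt)
    codes[missing] = 0.0
    return replace(G, codes=codes, encoded=True)


def minor_allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF from encoded codes: alt frequency = (mean(code)+1)/2."""
    if not G.encoded:
        raise ValueError("encode_and_impute must run before MAF computation")
    freq = (G.codes.mean(axis=0) + 1.0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 if either column is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0.0 or vy == 0.0:
        return 0.0
    r = (xc @ yc) / np.sqrt(vx * vy)
    return float(r * r)


def _prune_chromosome(codes: np.ndarray, positions: np.ndarray,
                      cfg: QCConfig) -> np.ndarray:
    """Greedy within-window pruning on one chromosome.

    Returns a boolean keep-mask over the chromosome's markers (assumed
    position-sorted).  Of every within-window pair with r^2 above the
    threshold the later-position marker is removed.
    """
    p = codes.shape[1]
    keep = np.ones(p, dtype=bool)
    if p < 2:
        return keep
    if cfg.window_unit == "bp":
        start = int(positions.min())
        stop = int(positions.max())
        win_starts = range(start, stop + 1, cfg.ld_step_bp)
        windows = (np.flatnonzero((positions >= s) &
                                  (positions < s + cfg.ld_window_bp))
                   for s in win_starts)
    else:
        step = max(cfg.ld_step_bp, 1)
        windows = (np.arange(s, min(s + cfg.ld_window_bp, p))
                   for s in range(0, p, step))
    for idx in windows:
        if idx.size < 2:
            continue
        for a_pos in range(idx.size):
            i = idx[a_pos]
            if not keep[i]:
                continue
            for b_pos in range(a_pos + 1, idx.size):
                j = idx[b_pos]
                if not keep[j]:
                    continue
                if _pairwise_r2(codes[:, i], codes[:, j]) > cfg.ld_r2_max:
                    keep[j] = False
    return keep


def apply_qc(G: GenotypeMatrix, cfg: QCConfig | None = None) -> GenotypeMatrix:
    """MAF filter then per-chromosome sliding-window LD pruning.

    Markers with MAF below ``cfg.maf_min`` are removed first; remaining
    markers are pruned greedily within sliding windows so that no surviving
    within-window pair exceeds ``cfg.ld_r2_max`` in r^2.  Chromosomes are
    pruned independently.
    """
    cfg = cfg or QCConfig()
    if not G.encoded:
        raise ValueError("apply_qc expects an encoded GenotypeMatrix")
    G = G.sorted_by_position()
    maf = minor_allele_frequency(G)
    G = G.subset_markers(maf >= cfg.maf_min)
    if G.n_markers == 0:
        warnings.warn("all markers removed by MAF filter")
        return G
    chroms = np.array([m.chromosome for m in G.markers])
    positions = np.array([m.position for m in G.markers])
    keep = np.ones(G.n_markers, dtype=bool)
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        mask = _prune_chromosome(G.codes[:, sel], positions[sel], cfg)
        keep[sel] = mask
    out = G.subset_markers(keep)
    if out.n_markers == 0:
        warnings.warn("all markers removed by LD pruning")
    return out
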