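"""Genotype containers and file I/O.

Genotypes are additive minor-allele counts (0/1/2) held in an
``n_samples x n_variants`` matrix.  Two on-disk formats are supported: a
plain tab-delimited matrix (header row of variant ids, first column of
sample ids) and VCF (biallelic records, GT converted to allele counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Additive genotype scores for ``n`` samples at ``m`` variants.

    Parameters
    ----------
    values
        ``(n, m)`` array of minor-allele counts in ``{0, 1, 2}``.
        Missing genotypes must be resolved (imputed) before construction.
    sample_ids, variant_ids
        Row and column identifiers.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)
    variant_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D (samples x variants) array")
        n, m = self.values.shape
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if self.variant_ids is None:
            self.variant_ids = [f"V{j}" for j in range(m)]
        if len(self.sample_ids) != n or len(self.variant_ids) != m:
            raise ValueError("id lists do not match matrix shape")
        vals = self.values[np.isfinite(self.values.astype(float))]
        if vals.size and not np.isin(np.unique(vals), [0, 1, 2]).all():
            raise ValueError("genotype entries must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Sample minor-allele frequency per variant, folded to <= 0.5."""
        freq = self.values.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def drop_monomorphic(self) -> "GenotypeMatrix":
        """Return a copy without zero-variance columns (count logged)."""
        keep = self.values.std(axis=0) > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d monomorphic variants", dropped)
        return GenotypeMatrix(
            self.values[:, keep],
            self.sample_ids,
            [v for v, k in zip(self.variant_ids, keep) if k],
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.variant_ids)
        df.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path) -> GenotypeMatrix:
    """Read a tab/whitespace-delimited genotype matrix.

    Header row holds variant ids; first column holds sample ids.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    values = df.to_numpy()
    if np.isnan(values.astype(float)).any():
        # column-mean imputation, rounded back to allele counts
        col_mean = np.nanmean(values.astype(float), axis=0)
        idx = np.where(np.isnan(values.astype(float)))
        values = values.astype(float)
        values[idx] = np.rint(col_mean[idx[1]])
    return GenotypeMatrix(values.astype(np.int8), list(df.index.astype(str)), list(df.columns))


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic records from a VCF into allele counts.

    Multiallelic records are skipped with a logged count.  The counted
    allele is ALT; callers needing folded frequencies use ``maf``.
    Missing genotypes are imputed to the rounded column mean.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, skipped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        g = np.asarray(rec.gt_types, dtype=float)  # 0=hom_ref,1=het,2=unknown,3=hom_alt
        col = np.where(g == 3, 2.0, np.where(g == 2, np.nan, g))
        if np.isnan(col).any():
            fill = np.nanmean(col) if np.isfinite(np.nanmean(col)) else 0.0
            col = np.where(np.isnan(col), np.rint(fill), col)
        cols.append(col)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if skipped:
        logger.info("skipped %d non-biallelic VCF records", skipped)
    if not cols:
        raise ValueError("no biallelic records found in VCF")
    return GenotypeMatrix(np.column_stack(cols).astype(np.int8), samples, ids)


def read_genotypes(path) -> GenotypeMatrix:
    """Dispatch on file extension: ``.vcf``/``.vcf.gz`` vs plain matrix."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf(p)
    return read_matrix(p)
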