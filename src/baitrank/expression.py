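"""Expression normalization and bait-gene coexpression.

Counts are normalized to transcripts per million (TPM): per-gene counts are
divided by gene length in bp, and each sample column is rescaled so the
length-normalized rates sum to one million.  Coexpression with the bait gene
is the sample Pearson correlation coefficient (PCC) of each gene's TPM vector
with the bait's, computed across all individual samples by default
(``log1p`` and ``tissue_means`` switches expose the common alternatives).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) with per-gene lengths and sample->tissue map."""

    counts: pd.DataFrame  # integer counts, index gene ids, columns sample ids
    lengths: pd.Series  # bp per gene, same index as counts
    sample_tissue: pd.Series  # tissue label per sample, index == counts.columns

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise InputError("duplicate gene ids in count matrix")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise InputError(f"genes without length: {list(missing[:5])}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise InputError(f"non-positive gene length for {bad}")
        unmapped = self.counts.columns.difference(self.sample_tissue.index)
        if len(unmapped):
            raise InputError(f"samples without tissue label: {list(unmapped[:5])}")
        self.sample_tissue = self.sample_tissue.reindex(self.counts.columns)
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise InputError("negative counts")
        if np.isnan(vals.astype(float)).any():
            raise InputError("missing values in count matrix are not allowed")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class TpmMatrix:
    """TPM values (genes x samples); non-degenerate columns sum to 1e6."""

    tpm: pd.DataFrame
    sample_tissue: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)


@dataclass
class CoexpressionResult:
    """Per-gene PCC with the bait; genes with zero variance are undefined (NaN)."""

    bait_id: str
    pcc: pd.Series  # float, NaN where undefined
    defined: pd.Series  # bool
    n_samples_used: int


def compute_tpm(cm: CountMatrix) -> TpmMatrix:
    """Normalize a count matrix to TPM.

    ``tpm[g, s] = (counts[g, s] / length[g]) / sum_g'(counts[g', s] / length[g']) * 1e6``.
    An all-zero sample column yields all-zero TPM (with a logged warning)
    rather than an error.
    """
    rate = cm.counts.div(cm.lengths, axis=0).astype(float)
    colsum = rate.sum(axis=0)
    zero_cols = colsum[colsum == 0.0].index
    if len(zero_cols):
        log.warning("all-zero sample column(s): %s — TPM set to 0", list(zero_cols))
    denom = colsum.replace(0.0, np.nan)
    tpm = rate.div(denom, axis=1).fillna(0.0) * 1e6
    return TpmMatrix(tpm=tpm, sample_tissue=cm.sample_tissue)


def tissue_mean_tpm(tm: TpmMatrix, tissue: str) -> pd.Series:
    """Per-gene arithmetic mean TPM over the replicate samples of one tissue."""
    cols = tm.sample_tissue.index[tm.sample_tissue == tissue]
    if len(cols) == 0:
        known = sorted(tm.sample_tissue.unique())
        raise InputError(f"unknown tissue label {tissue!r}; known tissues: {known}")
    return tm.tpm[cols].mean(axis=1)


def bait_pcc(
    tm: TpmMatrix,
    bait_id: str,
    *,
    log1p: bool = False,
    tissue_means: bool = False,
) -> CoexpressionResult:
    """Pearson correlation of every gene's expression vector with the bait's.

    Computed on raw TPM across all individual samples by default.  Genes with
    zero variance across samples get an undefined PCC (NaN, ``defined`` False);
    a zero-variance bait makes every result undefined, with a warning.
    """
    if bait_id not in tm.tpm.index:
        raise InputError(f"bait gene {bait_id!r} absent from expression matrix")
    X = tm.tpm
    if tissue_means:
        X = X.T.groupby(tm.sample_tissue).mean().T
    if log1p:
        X = np.log1p(X)
    n = X.shape[1]
    if n < 3:
        raise InputError(f"need >= 3 samples for correlation, have {n}")

    M = X.to_numpy(dtype=float)
    Mc = M - M.mean(axis=1, keepdims=True)
    ss = (Mc * Mc).sum(axis=1)
    bait_idx = X.index.get_loc(bait_id)
    bc = Mc[bait_idx]
    bait_ss = ss[bait_idx]

    defined = ss > 0.0
    if bait_ss == 0.0:
        log.warning("bait %s has zero variance across samples; all PCCs undefined", bait_id)
        defined = np.zeros_like(defined)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc @ bc) / np.sqrt(ss * bait_ss)
    r = np.clip(r, -1.0, 1.0)
    r[~defined] = np.nan
    return CoexpressionResult(
        bait_id=bait_id,
        pcc=pd.Series(r, index=X.index, name="pcc"),
        defined=pd.Series(defined, index=X.index, name="defined"),
        n_samples_used=n,
    )
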