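"""Marker quality control, imputation, and genomic relationship.

Genotypes are coded on the ``{-1, 0, +1}`` scale (homozygotes at the two
alleles coded -1/+1, heterozygotes 0), the convention used throughout
for inbred-line genomic selection.  Missing calls are ``NaN``.  After
imputation codes may be continuous dosages in ``[-1, 1]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "KinshipMatrix",
    "QCReport",
    "filter_markers",
    "impute_missing",
    "compute_kinship",
    "ImputationWarning",
]


class ImputationWarning(UserWarning):
    pass


@dataclass
class MarkerMatrix:
    """Lines x markers genotype matrix with missingness.

    Attributes
    ----------
    line_ids, marker_ids
        Unique identifiers for rows and columns.
    codes
        float array, values in ``[-1, 1]`` or ``NaN`` for missing.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (self.line_ids.size, self.marker_ids.size):
            raise ValueError("codes shape does not match id lengths")
        if len(set(self.line_ids)) != self.line_ids.size:
            raise ValueError("duplicated line_ids")
        finite = self.codes[np.isfinite(self.codes)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("genotype codes must lie in [-1, 1]")

    @property
    def n_lines(self) -> int:
        return self.line_ids.size

    @property
    def n_markers(self) -> int:
        return self.marker_ids.size

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.codes)

    @property
    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - self.missing_mask.mean(axis=0)

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the +1-coded allele among non-missing calls.

        Heterozygotes (code 0) contribute half a copy to each allele.
        """
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(self.codes, axis=0)
        return (mean + 1.0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def subset_lines(self, ids) -> "MarkerMatrix":
        idx = pd.Index(self.line_ids).get_indexer(list(ids))
        if np.any(idx < 0):
            raise KeyError("unknown line id in subset")
        return MarkerMatrix(np.asarray(list(ids), dtype=object), self.marker_ids.copy(), self.codes[idx].copy())

    def subset_markers(self, keep: np.ndarray) -> "MarkerMatrix":
        keep = np.asarray(keep)
        return MarkerMatrix(self.line_ids.copy(), self.marker_ids[keep].copy(), self.codes[:, keep].copy())

    # ----- IO: the TSV dialect shared with the simulator -----

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.codes, index=self.line_ids, columns=self.marker_ids)
        df.to_csv(path, sep="\t", na_rep="NA", index_label="line")

    @classmethod
    def from_tsv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object), df.to_numpy(dtype=float))

    @classmethod
    def from_vcf(cls, path) -> "MarkerMatrix":
        """Read biallelic records from a VCF (GT field, unphased).

        Mapping: 0/0 -> -1, 0/1 -> 0, 1/1 -> +1, ./. -> missing.
        Multiallelic records are skipped with a warning.
        """
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        samples = np.asarray(vcf.samples, dtype=object)
        cols, ids, n_skipped = [], [], 0
        for var in vcf:
            if len(var.ALT) != 1:
                n_skipped += 1
                continue
            gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            col = np.full(gts.size, np.nan)
            col[gts == 0] = -1.0
            col[gts == 1] = 0.0
            col[gts == 3] = 1.0
            cols.append(col)
            ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        if n_skipped:
            warnings.warn(f"skipped {n_skipped} multiallelic records", UserWarning, stacklevel=2)
        return cls(samples, np.asarray(ids, dtype=object), np.column_stack(cols))


@dataclass
class QCReport:
    """Per-rule removal counts; a marker failing several rules is counted
    once per rule but removed once."""

    n_input: int
    n_kept: int
    n_low_call_rate: int
    n_low_maf: int
    n_high_missing: int


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix (VanRaden/Endelman-Jannink form)."""

    line_ids: np.ndarray
    K: np.ndarray

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (self.line_ids.size, self.line_ids.size):
            raise ValueError("K must be square and match line_ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.K)

    def indexer(self, ids) -> np.ndarray:
        idx = pd.Index(self.line_ids).get_indexer(list(ids))
        if np.any(idx < 0):
            raise KeyError("unknown line id")
        return idx

    def submatrix(self, ids) -> "KinshipMatrix":
        idx = self.indexer(ids)
        return KinshipMatrix(np.asarray(list(ids), dtype=object), self.K[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.K, index=self.line_ids, columns=self.line_ids).to_csv(path, index_label="line")

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        K = df.to_numpy(dtype=float)
        return cls(df.index.to_numpy(dtype=object), (K + K.T) / 2.0)


def filter_markers(
    m: MarkerMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.05,
    max_missing: float = 0.10,
) -> tuple[MarkerMatrix, QCReport]:
    """Apply the three standard marker QC rules.

    Removes markers with call rate below ``min_call_rate``, minor allele
    frequency below ``min_maf``, or a missing fraction above
    ``max_missing``.  Returns the surviving submatrix together with a
    per-rule removal report.
    """
    for name, v in [("min_call_rate", min_call_rate), ("min_maf", min_maf), ("max_missing", max_missing)]:
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    cr = m.call_rate
    maf = m.maf
    miss = m.missing_mask.mean(axis=0)
    fail_cr = cr < min_call_rate
    fail_maf = ~(maf >= min_maf)  # NaN maf (no calls) fails too
    fail_miss = miss > max_missing
    keep = ~(fail_cr | fail_maf | fail_miss)
    if not keep.any():
        raise ValueError("empty marker set: all markers removed by QC")
    report = QCReport(
        n_input=m.n_markers,
        n_kept=int(keep.sum()),
        n_low_call_rate=int(fail_cr.sum()),
        n_low_maf=int(fail_maf.sum()),
        n_high_missing=int(fail_miss.sum()),
    )
    return m.subset_markers(keep), report


def impute_missing(
    m: MarkerMatrix,
    max_iter: int = 50,
    tol: float = 1e-4,
    shrinkage: float = 0.1,
) -> MarkerMatrix:
    """Impute missing genotype calls by EM under a multivariate normal.

    Each marker column is treated as a draw from ``N(mu, Sigma)`` over
    lines; the E-step replaces missing entries by their conditional
    expectation given the observed entries of the same marker and the
    current line-by-line covariance, and the M-step re-estimates ``mu``
    and ``Sigma`` (with the conditional-covariance correction).  The
    covariance is shrunk toward its diagonal to stay well conditioned
    when lines outnumber the markers they are estimated from.

    Observed entries are never altered; imputed entries are continuous
    dosages clipped to ``[-1, 1]``.
    """
    mask = m.missing_mask
    if not mask.any():
        return MarkerMatrix(m.line_ids.copy(), m.marker_ids.copy(), m.codes.copy())
    n_obs_per_marker = (~mask).sum(axis=0)
    if np.any(n_obs_per_marker < 2):
        raise ValueError("every marker needs >= 2 non-missing calls (run QC first)")

    X = m.codes.copy()
    n, M = X.shape
    row_mean = np.nanmean(m.codes, axis=1)
    X[mask] = np.take(row_mean, np.nonzero(mask)[0])

    miss_cols = np.nonzero(mask.any(axis=0))[0]
    converged = False
    Ccorr = np.zeros((n, n))  # accumulated conditional covariance from the E-step
    for _ in range(max_iter):
        mu = X.mean(axis=1)
        Xc = X - mu[:, None]
        Sigma = (Xc @ Xc.T + Ccorr) / M
        Sigma = (1.0 - shrinkage) * Sigma + shrinkage * np.diag(np.diag(Sigma))
        # partitioned-inverse E-step: invert Sigma once, then per column
        # only the small missing-by-missing block of the inverse
        Sigma_inv = np.linalg.inv(Sigma + 1e-10 * np.eye(n))
        max_change = 0.0
        Ccorr = np.zeros((n, n))
        for k in miss_cols:
            mi = np.nonzero(mask[:, k])[0]
            oi = np.nonzero(~mask[:, k])[0]
            A = Sigma_inv[np.ix_(mi, mi)]
            b = Sigma_inv[np.ix_(mi, oi)] @ (X[oi, k] - mu[oi])
            new = mu[mi] - np.linalg.solve(A, b)
            max_change = max(max_change, float(np.max(np.abs(new - X[mi, k]))))
            X[mi, k] = new
            Ccorr[np.ix_(mi, mi)] += np.linalg.inv(A)
        if max_change < tol * (1.0 + float(np.std(m.codes[~mask]))):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MVN-EM imputation did not converge in {max_iter} iterations",
            ImputationWarning,
            stacklevel=2,
        )
    out = m.codes.copy()
    out[mask] = np.clip(X[mask], -1.0, 1.0)
    return MarkerMatrix(m.line_ids.copy(), m.marker_ids.copy(), out)


def compute_kinship(m: MarkerMatrix) -> KinshipMatrix:
    """Genomic relationship matrix ``K = W W' / (2 sum_k p_k (1 - p_k))``.

    ``W`` is the marker matrix centered per column to mean zero (for
    ``{-1,0,1}`` codes this equals subtracting ``2 p_k - 1``), and
    ``p_k`` the frequency of the +1-coded allele.  Rows of ``K`` sum to
    zero by construction of the centering.
    """
    if m.missing_mask.any():
        raise ValueError("kinship requires a complete matrix: impute first")
    p = m.allele_freq
    denom = 2.0 * np.sum(p * (1.0 - p))
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic marker present: apply QC filtering first")
    W = m.codes - m.codes.mean(axis=0)
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(m.line_ids.copy(), K)
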