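"""RPKM normalisation and replicate-free differential expression calling.

Each condition has a single sequencing library, so differential expression
between two samples is assessed with the conditional exact binomial test:
given the total ``x + y`` reads observed for a gene across the two
libraries, under the null of equal relative abundance the treated-library
count is Binomial(x + y, N1 / (N1 + N2)).  The two-sided p-value doubles
the smaller tail and is capped at 1.  This is the standard test for
single-library count comparisons (equivalent to the Audic-Claverie
statistic for equal library sizes).

Genes are called differentially expressed when |log2 ratio| >= 1 and the
Benjamini-Hochberg FDR is below 0.001, with the FDR computed separately
within each comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import COMPARISONS, SAMPLES, Thresholds

__all__ = [
    "compute_rpkm",
    "two_library_test",
    "benjamini_hochberg",
    "call_degs",
    "call_all_degs",
]


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of exon model per million mapped reads.

    RPKM = 1e9 * C / (N * L) for count C, library total N and gene length
    L in nucleotides.  ``library_totals`` defaults to the per-sample count
    sums.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    if library_totals is None:
        library_totals = counts.sum(axis=0)
    library_totals = library_totals.reindex(counts.columns)
    if (library_totals <= 0).any():
        bad = library_totals.index[library_totals <= 0][0]
        raise ValueError(f"non-positive library total for sample {bad!r}")
    rpkm = counts.div(library_totals, axis=1).div(lengths, axis=0) * 1e9
    return rpkm


def two_library_test(x, y, n1, n2):
    """Two-sided exact binomial test for equal relative abundance.

    Conditional on the total ``x + y``, the count ``x`` from library 1 is
    Binomial(x + y, n1 / (n1 + n2)) under the null; the p-value is twice
    the smaller of the two tails (each including the observed count),
    capped at 1.  Accepts scalars or arrays.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative counts are not allowed")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    n = x + y
    p0 = n1 / (n1 + n2)
    lower = stats.binom.cdf(x, n, p0)
    upper = stats.binom.sf(x - 1, n, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    if p.ndim == 0:
        return float(p)
    return p


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    matrix: pd.DataFrame,
    comparison: str,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Call DEGs for one treated-vs-control comparison.

    ``matrix`` holds a ``length`` column plus the six sample count
    columns, indexed by gene id.  Returns one row per gene with columns
    gene_id, comparison, rpkm_treated, rpkm_control, log2fc, p, fdr,
    status (up/down/ns).  Ratios are formed on RPKM with a floor so genes
    absent from one library get a finite fold change; p-values come from
    the exact two-library count test and the FDR is computed across the
    genes of this comparison only, in gene-id order.
    """
    thr = thresholds or Thresholds()
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    treated, control = COMPARISONS[comparison]
    for s in (treated, control):
        if s not in matrix.columns:
            raise ValueError(f"sample {s!r} missing from expression matrix")

    matrix = matrix.sort_index()
    counts = matrix[list(SAMPLES)]
    rpkm = compute_rpkm(counts, matrix["length"])
    totals = counts.sum(axis=0)

    rt = rpkm[treated].to_numpy()
    rc = rpkm[control].to_numpy()
    log2fc = np.log2(np.maximum(rt, thr.expr_floor) / np.maximum(rc, thr.expr_floor))
    p = two_library_test(
        counts[treated].to_numpy(),
        counts[control].to_numpy(),
        float(totals[treated]),
        float(totals[control]),
    )
    fdr = benjamini_hochberg(p)

    status = np.full(len(matrix), "ns", dtype=object)
    sig = fdr < thr.deg_fdr
    status[sig & (log2fc >= thr.deg_log2fc)] = "up"
    status[sig & (log2fc <= -thr.deg_log2fc)] = "down"

    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "comparison": comparison,
            "rpkm_treated": rt,
            "rpkm_control": rc,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "status": status,
        }
    ).reset_index(drop=True)


def call_all_degs(matrix: pd.DataFrame, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """DEG results for all four comparisons, concatenated."""
    return pd.concat(
        [call_degs(matrix, c, thresholds) for c in COMPARISONS],
        ignore_index=True,
    )
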