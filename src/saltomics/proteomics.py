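"""iTRAQ proteomics: identification tiers and differential abundance.

A protein quantification table carries, per protein, the peptide tally of
each of the three biological replicates and, per treated/control
comparison, up to three replicate iTRAQ ratios.  Differentially abundant
proteins (DAPs) must have been quantified with at least one peptide among
the three replicates, a mean ratio above 1.2 or below 0.833, and a
two-sided P < 0.05 from a one-sample location test of the log2 replicate
ratios against zero.

The "average ratio" is taken as the geometric mean (the arithmetic mean
of log ratios), since iTRAQ ratios are multiplicative; the arithmetic
alternative can be selected via ``mean_kind``.  Replicate vectors with
zero variance yield a missing p-value and therefore can never be called
differentially abundant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import COMPARISONS, Thresholds

__all__ = [
    "N_REPLICATES",
    "ratio_columns",
    "peptide_columns",
    "tally_identification",
    "dap_test",
    "call_daps",
    "call_all_daps",
]

N_REPLICATES = 3


def ratio_columns(comparison: str) -> list[str]:
    return [f"ratio_{comparison}_{r}" for r in range(1, N_REPLICATES + 1)]


def peptide_columns() -> list[str]:
    return [f"peptides_{r}" for r in range(1, N_REPLICATES + 1)]


def tally_identification(quants: pd.DataFrame) -> dict[str, int]:
    """Identification-filter tier counts over a protein table.

    * ``identified``       -- at least one peptide in at least one replicate
    * ``robust``           -- at least two peptides, observed in >= 2 replicates
    * ``quantified``       -- at least one iTRAQ ratio present
    * ``quantified_all3``  -- ratios present in all three replicates of at
      least one comparison
    """
    peps = quants[peptide_columns()].to_numpy()
    identified = (peps >= 1).any(axis=1)
    robust = ((peps >= 1).sum(axis=1) >= 2) & (peps.sum(axis=1) >= 2)

    any_ratio = np.zeros(len(quants), dtype=bool)
    all3 = np.zeros(len(quants), dtype=bool)
    for comp in COMPARISONS:
        cols = [c for c in ratio_columns(comp) if c in quants.columns]
        if not cols:
            continue
        present = quants[cols].notna().to_numpy()
        any_ratio |= present.any(axis=1)
        if len(cols) == N_REPLICATES:
            all3 |= present.all(axis=1)
    return {
        "identified": int(identified.sum()),
        "robust": int(robust.sum()),
        "quantified": int(any_ratio.sum()),
        "quantified_all3": int(all3.sum()),
    }


def dap_test(ratios, mean_kind: str = "geometric") -> tuple[float, float]:
    """Mean ratio and p-value for one protein's replicate ratios.

    Missing replicates are dropped.  The p-value is a two-sided one-sample
    t-test of the log2 ratios against zero; it is NaN when fewer than two
    ratios are present or when the replicates are identical (zero
    variance).
    """
    r = np.asarray(ratios, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("all replicate ratios are missing")
    if (r <= 0).any():
        raise ValueError("ratios must be positive")
    logr = np.log2(r)
    if mean_kind == "geometric":
        mean_ratio = float(2.0 ** logr.mean())
    elif mean_kind == "arithmetic":
        mean_ratio = float(r.mean())
    else:
        raise ValueError(f"unknown mean_kind {mean_kind!r}")
    if r.size < 2 or np.ptp(logr) == 0.0:
        return mean_ratio, float("nan")
    p = float(stats.ttest_1samp(logr, 0.0).pvalue)
    return mean_ratio, p


def call_daps(
    quants: pd.DataFrame,
    comparison: str,
    thresholds: Thresholds | None = None,
    mean_kind: str = "geometric",
) -> pd.DataFrame:
    """Differential-abundance calls for one comparison.

    Returns one row per protein with columns protein_id, gene_id,
    comparison, mean_ratio, log2ratio, p, quantified, status.  Proteins
    without any ratio in this comparison, or without at least one peptide
    among the three replicates, are retained with ``quantified=False``
    and status ``ns`` so downstream joins can distinguish "quantified but
    unchanged" from "not quantified".
    """
    thr = thresholds or Thresholds()
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    cols = ratio_columns(comparison)
    peps = quants[peptide_columns()].to_numpy()
    has_peptide = (peps >= 1).any(axis=1)

    rows = []
    for i, (_, row) in enumerate(quants.iterrows()):
        ratios = row[cols].to_numpy(dtype=float) if set(cols) <= set(quants.columns) else np.array([])
        n_present = int(np.sum(~np.isnan(ratios))) if ratios.size else 0
        quantified = bool(n_present >= 1 and has_peptide[i])
        if quantified:
            mean_ratio, p = dap_test(ratios, mean_kind=mean_kind)
        else:
            mean_ratio, p = float("nan"), float("nan")
        status = "ns"
        if quantified and not np.isnan(p) and p < thr.dap_p:
            if mean_ratio > thr.dap_hi:
                status = "up"
            elif mean_ratio < thr.dap_lo:
                status = "down"
        rows.append(
            {
                "protein_id": row["protein_id"],
                "gene_id": row.get("gene_id", None),
                "comparison": comparison,
                "mean_ratio": mean_ratio,
                "log2ratio": np.log2(mean_ratio) if quantified else float("nan"),
                "p": p,
                "quantified": quantified,
                "status": status,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("protein_id", kind="stable").reset_index(drop=True)


def call_all_daps(
    quants: pd.DataFrame,
    thresholds: Thresholds | None = None,
    mean_kind: str = "geometric",
) -> pd.DataFrame:
    """DAP results for all four comparisons, concatenated."""
    return pd.concat(
        [call_daps(quants, c, thresholds, mean_kind) for c in COMPARISONS],
        ignore_index=True,
    )
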