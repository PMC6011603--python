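"""Gene-protein concordance: six-category classification and correlations.

For each comparison, every gene-protein pair (and every unmatched DE gene
or DAP) is placed in exactly one of six categories:

* **I**   gene DE and protein DAP, same direction;
* **II**  gene DE and protein DAP, opposite direction;
* **III** gene DE, protein quantified but unchanged;
* **IV**  protein DAP, gene detected but unchanged;
* **V**   gene DE, no quantified protein (unquantified or unmapped);
* **VI**  protein DAP, gene not detected in the mRNA-seq data.

Pairs where both levels are quantified but neither changes carry no
category; they still contribute to the all-pairs correlation, which uses
the gene log2 fold change against log2 of the protein mean ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import COMPARISONS

__all__ = [
    "overlap_percentage",
    "classify_pairs",
    "correlate_subsets",
    "category_counts",
]


def overlap_percentage(n_overlap: int, n_total: int, ndigits: int = 2) -> float:
    """Percentage of ``n_total`` covered by ``n_overlap`` (e.g. the share
    of the proteome also detected in the mRNA-seq data)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_overlap <= n_total:
        raise ValueError("n_overlap must lie in [0, n_total]")
    return round(100.0 * n_overlap / n_total, ndigits)


def _classify_one(gene_status, protein_status, gene_present, protein_quantified):
    gene_de = gene_present and gene_status in ("up", "down")
    prot_de = protein_quantified and protein_status in ("up", "down")
    if gene_de and prot_de:
        return "I" if gene_status == protein_status else "II"
    if gene_de and protein_quantified:
        return "III"
    if prot_de and gene_present:
        return "IV"
    if gene_de:
        return "V"
    if prot_de:
        return "VI"
    return ""


def classify_pairs(deg_results: pd.DataFrame, dap_results: pd.DataFrame) -> pd.DataFrame:
    """Join DEG and DAP results and assign categories per comparison.

    ``deg_results`` and ``dap_results`` are the concatenated outputs of
    the DEG and DAP callers (the DAP table carries the gene mapping in
    its ``gene_id`` column).  The output has one row per comparison per
    pair: every protein appears once (matched to its gene when the gene
    is in the expression universe), and every DE gene without a
    quantified protein appears once with a missing ``protein_id``.
    """
    out = []
    for comp in COMPARISONS:
        deg = deg_results[deg_results["comparison"] == comp].set_index("gene_id")
        dap = dap_results[dap_results["comparison"] == comp]
        genes_covered: set = set()
        for _, prow in dap.iterrows():
            gid = prow["gene_id"]
            gene_present = pd.notna(gid) and gid in deg.index
            if gene_present:
                grow = deg.loc[gid]
                gstat, gfc = grow["status"], float(grow["log2fc"])
            else:
                gstat, gfc = None, float("nan")
            quant = bool(prow["quantified"])
            cat = _classify_one(gstat, prow["status"], gene_present, quant)
            if cat == "" and not (gene_present and quant):
                continue  # nothing measured at either level
            if gene_present:
                genes_covered.add(gid)
            out.append(
                {
                    "comparison": comp,
                    "gene_id": gid if pd.notna(gid) else None,
                    "protein_id": prow["protein_id"],
                    "gene_log2fc": gfc,
                    "gene_status": gstat if gene_present else None,
                    "protein_log2ratio": float(prow["log2ratio"]) if quant else float("nan"),
                    "protein_status": prow["status"] if quant else None,
                    "category": cat,
                }
            )
        # DE genes with no quantified protein partner -> category V
        de_genes = deg.index[deg["status"].isin(["up", "down"])]
        for gid in de_genes:
            if gid in genes_covered:
                continue
            out.append(
                {
                    "comparison": comp,
                    "gene_id": gid,
                    "protein_id": None,
                    "gene_log2fc": float(deg.loc[gid, "log2fc"]),
                    "gene_status": deg.loc[gid, "status"],
                    "protein_log2ratio": float("nan"),
                    "protein_status": None,
                    "category": "V",
                }
            )
    pairs = pd.DataFrame(
        out,
        columns=[
            "comparison",
            "gene_id",
            "protein_id",
            "gene_log2fc",
            "gene_status",
            "protein_log2ratio",
            "protein_status",
            "category",
        ],
    )
    return pairs.sort_values(
        ["comparison", "gene_id", "protein_id"], kind="stable", na_position="last"
    ).reset_index(drop=True)


def correlate_subsets(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between gene and protein log2 changes, per comparison.

    Subsets: ``all`` (every pair measured at both levels), ``same`` (the
    same-direction category I pairs) and ``opposite`` (category II).
    Subsets with fewer than three pairs are reported with ``r`` missing.
    """
    rows = []
    for comp, grp in pairs.groupby("comparison"):
        both = grp[grp["gene_log2fc"].notna() & grp["protein_log2ratio"].notna()]
        for name, sub in (
            ("all", both),
            ("same", both[both["category"] == "I"]),
            ("opposite", both[both["category"] == "II"]),
        ):
            n = len(sub)
            if n >= 3:
                r = float(
                    stats.pearsonr(sub["gene_log2fc"], sub["protein_log2ratio"]).statistic
                )
            else:
                r = float("nan")
            rows.append({"comparison": comp, "subset": name, "n": n, "r": r})
    return pd.DataFrame(rows)


def category_counts(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison tallies of the six categories plus uncategorised."""
    rows = []
    for comp, grp in pairs.groupby("comparison"):
        counts = grp["category"].value_counts()
        row = {"comparison": comp}
        for cat in ("I", "II", "III", "IV", "V", "VI"):
            row[cat] = int(counts.get(cat, 0))
        row["both_ns"] = int(counts.get("", 0))
        rows.append(row)
    return pd.DataFrame(rows)
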