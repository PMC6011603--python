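"""Alternative-splicing event accounting and AS-DEG candidate ranking.

AS events come typed as intron retention (IR), exon skipping (ES) and
alternative 5'/3' splice sites (A5SS/A3SS).  A gene's AS status within a
sample is binary: at least one event of any type.  Salt-specific
("induced") AS genes have events at a treated time point but none in the
time-0 control of the same genotype.  AS-DEGs are DEGs of the matching
comparison that are also salt-specific AS genes; among them, tolerance
candidates are those whose absolute log2 fold change in the tolerant
comparison exceeds that of the sensitive comparison at the same time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    AS_EVENT_TYPES,
    SAMPLES,
    SENSITIVE,
    TOLERANT,
    TREATED_TIMES,
    comparison_name,
    sample_name,
)

__all__ = [
    "count_events",
    "as_gene_sets",
    "salt_specific_as_genes",
    "select_as_degs",
    "rank_as_candidates",
]


def _check_events(events: pd.DataFrame) -> None:
    bad = ~events["type"].isin(AS_EVENT_TYPES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown AS event type {events['type'].iloc[i]!r} in row {i}"
        )


def count_events(events: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-type event counts with per-type fractions.

    Returns one row per (sample, type) with columns sample, type, count,
    fraction and n_as_genes (the number of distinct genes with >= 1 event
    in the sample).  Fractions sum to 1 within any non-empty sample.
    """
    if len(events):
        _check_events(events)
    rows = []
    for sample in SAMPLES:
        sub = events[events["sample"] == sample] if len(events) else events
        total = len(sub)
        n_genes = sub["gene_id"].nunique() if total else 0
        for t in AS_EVENT_TYPES:
            c = int((sub["type"] == t).sum()) if total else 0
            rows.append(
                {
                    "sample": sample,
                    "type": t,
                    "count": c,
                    "fraction": c / total if total else 0.0,
                    "n_as_genes": n_genes,
                }
            )
    return pd.DataFrame(rows)


def as_gene_sets(events: pd.DataFrame) -> dict[str, set]:
    """The set of genes with at least one event, per sample."""
    if len(events):
        _check_events(events)
    sets: dict[str, set] = {s: set() for s in SAMPLES}
    for sample, grp in events.groupby("sample"):
        sets[str(sample)] = set(grp["gene_id"])
    return sets


def salt_specific_as_genes(
    events: pd.DataFrame, genotype: str, time: int
) -> tuple[set, set]:
    """Genes whose AS is induced (or lost) by salt for a genotype/time.

    Induced: >= 1 event at the treated time and none at time 0 for the
    genotype.  Lost: the reverse.  Returns ``(induced, lost)``.
    """
    if time not in TREATED_TIMES:
        raise ValueError(f"time must be one of {TREATED_TIMES}, got {time!r}")
    sets = as_gene_sets(events)
    control = sets[sample_name(genotype, 0)]
    treated = sets[sample_name(genotype, time)]
    return treated - control, control - treated


def select_as_degs(
    events: pd.DataFrame, deg_results: pd.DataFrame
) -> pd.DataFrame:
    """AS-DEGs: salt-specific AS genes that are DEGs of the matching
    comparison.

    One row per (genotype, time, gene) with the gene's log2 fold change
    and direction in that comparison.
    """
    rows = []
    for genotype in (TOLERANT, SENSITIVE):
        for time in TREATED_TIMES:
            comp = comparison_name(genotype, time)
            induced, _ = salt_specific_as_genes(events, genotype, time)
            deg = deg_results[
                (deg_results["comparison"] == comp)
                & deg_results["status"].isin(["up", "down"])
            ].set_index("gene_id")
            for gid in sorted(induced & set(deg.index)):
                rows.append(
                    {
                        "genotype": genotype,
                        "time": time,
                        "comparison": comp,
                        "gene_id": gid,
                        "log2fc": float(deg.loc[gid, "log2fc"]),
                        "status": deg.loc[gid, "status"],
                    }
                )
    return pd.DataFrame(
        rows, columns=["genotype", "time", "comparison", "gene_id", "log2fc", "status"]
    )


def rank_as_candidates(
    as_degs: pd.DataFrame,
    deg_results: pd.DataFrame,
    require_tolerant_as: bool = True,
) -> pd.DataFrame:
    """Salt-tolerance AS candidates.

    A tolerant-genotype AS-DEG is a candidate when its absolute tolerant
    log2 fold change exceeds the absolute sensitive log2 fold change at
    the same time point.  With ``require_tolerant_as`` (default) only
    AS-DEGs observed in the tolerant genotype are considered; otherwise
    AS in either genotype qualifies.  Candidates are ranked by the excess
    |log2 E fc| - |log2 N fc|, largest first.
    """
    rows = []
    for time in TREATED_TIMES:
        e_comp = comparison_name(TOLERANT, time)
        n_comp = comparison_name(SENSITIVE, time)
        sub = as_degs[as_degs["time"] == time]
        if require_tolerant_as:
            sub = sub[sub["genotype"] == TOLERANT]
        deg_e = deg_results[deg_results["comparison"] == e_comp].set_index("gene_id")
        deg_n = deg_results[deg_results["comparison"] == n_comp].set_index("gene_id")
        for gid in sorted(set(sub["gene_id"])):
            if gid not in deg_e.index:
                continue
            e_fc = float(deg_e.loc[gid, "log2fc"])
            n_fc = float(deg_n.loc[gid, "log2fc"]) if gid in deg_n.index else 0.0
            if abs(e_fc) > abs(n_fc):
                rows.append(
                    {
                        "gene_id": gid,
                        "time": time,
                        "log2fc_tolerant": e_fc,
                        "log2fc_sensitive": n_fc,
                        "excess": abs(e_fc) - abs(n_fc),
                    }
                )
    out = pd.DataFrame(
        rows, columns=["gene_id", "time", "log2fc_tolerant", "log2fc_sensitive", "excess"]
    )
    return out.sort_values(
        ["excess", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
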