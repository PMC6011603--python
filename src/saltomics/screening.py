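"""Stringent screening of salt-tolerance candidates.

The screen contrasts the tolerant (E) and sensitive (N) genotypes at one
time point (4 or 24 h).  Gene-level rules act on genes whose
tolerant-genotype concordance category is III ("DEG & protein ns") or I
(DE at both levels, same direction); protein-level rules act on category
IV ("DAP & gene ns") proteins:

* **i**   DE in both genotypes in the same direction with
          ``|log2 E-fc| - |log2 N-fc| >= 0.5``;
* **ii**  category III with opposite responses:
          ``log2 E-fc >= 1 and log2 N-fc <= -1`` or vice versa;
* **iii** DE only in the tolerant genotype;
* **iv**  DAP in both genotypes in the same direction with
          ``|log2 E ratio| > |log2 N ratio|``;
* **v**   DAP only in the tolerant genotype.

A separate protein-only screen (no mRNA evidence used) nominates
category VI proteins DAP only in the tolerant genotype.  Records are
de-duplicated with rule precedence i through v; every record stores the
effects it was admitted on so its rule predicate can be re-checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    SENSITIVE,
    TOLERANT,
    TREATED_TIMES,
    Thresholds,
    comparison_name,
)

__all__ = [
    "apply_rules",
    "protein_only_screen",
    "screen_all",
    "annotate_candidates",
    "check_rule_predicates",
]

_CAND_COLS = [
    "id",
    "level",
    "time",
    "rule",
    "effect_tolerant",
    "effect_sensitive",
    "as_flag",
    "osmotic_flag",
]


def _is_de(status) -> bool:
    return status in ("up", "down")


def apply_rules(
    concordance_pairs: pd.DataFrame,
    deg_results: pd.DataFrame,
    dap_results: pd.DataFrame,
    time: int,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Candidate records from rules i-v for one time point.

    Effects stored are log2 fold changes for gene-level rules and log2
    mean iTRAQ ratios for protein-level rules, tolerant then sensitive.
    """
    thr = thresholds or Thresholds()
    if time not in TREATED_TIMES:
        raise ValueError(f"time must be one of {TREATED_TIMES}, got {time!r}")
    e_comp = comparison_name(TOLERANT, time)
    n_comp = comparison_name(SENSITIVE, time)

    pairs_e = concordance_pairs[concordance_pairs["comparison"] == e_comp]
    deg_n = deg_results[deg_results["comparison"] == n_comp].set_index("gene_id")
    dap_n = dap_results[dap_results["comparison"] == n_comp].set_index("protein_id")

    records: list[dict] = []
    seen: set = set()

    def admit(ident, level, rule, eff_e, eff_n):
        if ident in seen:
            return
        seen.add(ident)
        records.append(
            {
                "id": ident,
                "level": level,
                "time": time,
                "rule": rule,
                "effect_tolerant": eff_e,
                "effect_sensitive": eff_n,
                "as_flag": False,
                "osmotic_flag": False,
            }
        )

    # gene-level rules on tolerant-genotype category I / III genes
    gene_rows = pairs_e[pairs_e["category"].isin(["I", "III"])]
    for _, row in gene_rows.iterrows():
        gid = row["gene_id"]
        cat = row["category"]
        e_fc = float(row["gene_log2fc"])
        if gid in deg_n.index:
            n_fc = float(deg_n.loc[gid, "log2fc"])
            n_de = _is_de(deg_n.loc[gid, "status"])
        else:
            n_fc, n_de = 0.0, False
        same_dir = n_de and np.sign(n_fc) == np.sign(e_fc)
        if same_dir and abs(e_fc) - abs(n_fc) >= thr.rule_i_margin:
            admit(gid, "gene", "i", e_fc, n_fc)
        elif cat == "III" and (
            (e_fc >= thr.deg_log2fc and n_fc <= -thr.deg_log2fc)
            or (e_fc <= -thr.deg_log2fc and n_fc >= thr.deg_log2fc)
        ):
            admit(gid, "gene", "ii", e_fc, n_fc)
        elif not n_de:
            admit(gid, "gene", "iii", e_fc, n_fc)

    # protein-level rules on tolerant-genotype category IV proteins
    prot_rows = pairs_e[pairs_e["category"] == "IV"]
    for _, row in prot_rows.iterrows():
        pid = row["protein_id"]
        e_lr = float(row["protein_log2ratio"])
        if pid in dap_n.index:
            n_lr = float(dap_n.loc[pid, "log2ratio"])
            n_dap = _is_de(dap_n.loc[pid, "status"])
        else:
            n_lr, n_dap = 0.0, False
        if np.isnan(n_lr):
            n_lr = 0.0
        if n_dap and np.sign(n_lr) == np.sign(e_lr) and abs(e_lr) > abs(n_lr):
            admit(pid, "protein", "iv", e_lr, n_lr)
        elif not n_dap:
            admit(pid, "protein", "v", e_lr, n_lr)

    out = pd.DataFrame(records, columns=_CAND_COLS)
    return out.sort_values(["rule", "id"], kind="stable").reset_index(drop=True)


def protein_only_screen(
    concordance_pairs: pd.DataFrame,
    dap_results: pd.DataFrame,
    time: int,
) -> pd.DataFrame:
    """Category VI proteins DAP only in the tolerant genotype (screen that
    uses no mRNA-seq evidence)."""
    if time not in TREATED_TIMES:
        raise ValueError(f"time must be one of {TREATED_TIMES}, got {time!r}")
    e_comp = comparison_name(TOLERANT, time)
    n_comp = comparison_name(SENSITIVE, time)
    pairs_e = concordance_pairs[
        (concordance_pairs["comparison"] == e_comp)
        & (concordance_pairs["category"] == "VI")
    ]
    dap_n = dap_results[dap_results["comparison"] == n_comp].set_index("protein_id")
    rows = []
    for _, row in pairs_e.iterrows():
        pid = row["protein_id"]
        if pid in dap_n.index and _is_de(dap_n.loc[pid, "status"]):
            continue
        n_lr = float(dap_n.loc[pid, "log2ratio"]) if pid in dap_n.index else float("nan")
        rows.append(
            {
                "id": pid,
                "level": "protein",
                "time": time,
                "rule": "protein_only",
                "effect_tolerant": float(row["protein_log2ratio"]),
                "effect_sensitive": n_lr,
                "as_flag": False,
                "osmotic_flag": False,
            }
        )
    out = pd.DataFrame(rows, columns=_CAND_COLS)
    return out.sort_values("id", kind="stable").reset_index(drop=True)


def screen_all(
    concordance_pairs: pd.DataFrame,
    deg_results: pd.DataFrame,
    dap_results: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Rules i-v plus the protein-only screen at both time points."""
    frames = []
    for time in TREATED_TIMES:
        frames.append(apply_rules(concordance_pairs, deg_results, dap_results, time, thresholds))
        frames.append(protein_only_screen(concordance_pairs, dap_results, time))
    return pd.concat(frames, ignore_index=True)


def annotate_candidates(
    candidates: pd.DataFrame,
    as_degs: pd.DataFrame | None = None,
    osmotic_genes: set | None = None,
) -> pd.DataFrame:
    """Set the AS and osmotic-stress flags on candidate records.

    ``as_flag`` marks gene-level candidates present in the
    tolerant-genotype AS-DEG set of the matching time point;
    ``osmotic_flag`` marks genes present in a user-supplied
    osmotic-stress annotation list.  Missing annotation inputs leave the
    flags False.
    """
    out = candidates.copy()
    if as_degs is not None and len(as_degs):
        tol = as_degs[as_degs["genotype"] == TOLERANT]
        for time in TREATED_TIMES:
            genes = set(tol.loc[tol["time"] == time, "gene_id"])
            mask = (out["time"] == time) & out["id"].isin(genes)
            out.loc[mask, "as_flag"] = True
    if osmotic_genes:
        out.loc[out["id"].isin(set(osmotic_genes)), "osmotic_flag"] = True
    return out


def check_rule_predicates(
    candidates: pd.DataFrame, thresholds: Thresholds | None = None
) -> pd.Series:
    """Re-evaluate each record's rule predicate from its stored effects.

    Returns a boolean Series; every record of a valid screen is True.
    Only the effect-based part of each rule is re-checkable from the
    stored values (status conditions were consumed at admission time).
    """
    thr = thresholds or Thresholds()
    oks = []
    for _, row in candidates.iterrows():
        e, n = row["effect_tolerant"], row["effect_sensitive"]
        rule = row["rule"]
        if rule == "i":
            ok = np.sign(e) == np.sign(n) and abs(e) - abs(n) >= thr.rule_i_margin
        elif rule == "ii":
            ok = (e >= thr.deg_log2fc and n <= -thr.deg_log2fc) or (
                e <= -thr.deg_log2fc and n >= thr.deg_log2fc
            )
        elif rule == "iii":
            ok = abs(e) >= thr.deg_log2fc
        elif rule == "iv":
            ok = np.sign(e) == np.sign(n) and abs(e) > abs(n)
        elif rule == "v":
            ok = abs(e) > min(np.log2(thr.dap_hi), -np.log2(thr.dap_lo))
        elif rule == "protein_only":
            ok = abs(e) > min(np.log2(thr.dap_hi), -np.log2(thr.dap_lo))
        else:
            ok = False
        oks.append(bool(ok))
    return pd.Series(oks, index=candidates.index)
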