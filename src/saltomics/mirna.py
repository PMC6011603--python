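"""miRNA differential expression, target scanning and regulatory chains.

Small-RNA abundance is normalised to reads per million (RPM).  A miRNA
is eligible for differential testing when it reaches RPM >= 10 in a
compared sample and its six-sample RPM sum exceeds 60; it is called DE
when the exact two-library count test gives P < 0.05 with
|log2 fold change| > 1 on the RPM ratio.

Target scanning follows the plant convention of near-perfect
complementarity: the reverse complement of the miRNA slides gaplessly
along each coding sequence and every offset is scored as
``mismatches + 0.5 * wobbles`` where a G:U pair counts as a wobble;
offsets scoring below 3 are reported.

Regulatory chains join DE miRNAs to anticorrelated targets: gene-level
chains (transcript degradation) require the target gene DE in the
opposite direction in the same comparison; protein-level chains
(candidate translational repression) require the target's protein DAP in
the opposite direction while the gene itself is unchanged or undetected
(concordance categories IV/VI).  miRNAs DE only in the sensitive
genotype are removed before chain building.  A triple satisfying both
levels is reported once, at gene level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .config import COMPARISONS, SAMPLES, TOLERANT, Thresholds, comparison_genotype
from .diffexpr import two_library_test

__all__ = [
    "compute_rpm",
    "filter_and_call_de_mirnas",
    "call_all_de_mirnas",
    "scan_targets",
    "scan_all_targets",
    "anticorrelated_pairs",
    "protein_level_chains",
]

# nucleotide encoding: T and U are equivalent
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


def _encode(seq: str, name: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        code = _CODE.get(ch)
        if code is None:
            raise ValueError(
                f"non-nucleotide character {ch!r} at position {i + 1} of {name}"
            )
        out[i] = code
    return out


def compute_rpm(counts: pd.DataFrame, library_totals: pd.Series | None = None) -> pd.DataFrame:
    """Reads per million: count / library total * 1e6."""
    if library_totals is None:
        library_totals = counts.sum(axis=0)
    library_totals = library_totals.reindex(counts.columns)
    if (library_totals <= 0).any():
        bad = library_totals.index[library_totals <= 0][0]
        raise ValueError(f"non-positive library total for sample {bad!r}")
    return counts.div(library_totals, axis=1) * 1e6


def filter_and_call_de_mirnas(
    counts: pd.DataFrame,
    comparison: str,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Eligibility filtering plus DE calling for one comparison.

    ``counts`` is indexed by miRNA id with the six sample columns.
    Returns one row per miRNA with columns mirna_id, comparison,
    eligible, log2fc, p, status.  Ineligible miRNAs keep status ``ns``
    with missing p.
    """
    thr = thresholds or Thresholds()
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    treated, control = COMPARISONS[comparison]
    counts = counts.sort_index()
    rpm = compute_rpm(counts[list(SAMPLES)])
    totals = counts[list(SAMPLES)].sum(axis=0)

    rt = rpm[treated].to_numpy()
    rc = rpm[control].to_numpy()
    if thr.mirna_rpm_rule == "either":
        reach = np.maximum(rt, rc) >= thr.mirna_rpm_min
    elif thr.mirna_rpm_rule == "both":
        reach = np.minimum(rt, rc) >= thr.mirna_rpm_min
    else:
        raise ValueError(f"unknown mirna_rpm_rule {thr.mirna_rpm_rule!r}")
    eligible = reach & (rpm.sum(axis=1).to_numpy() > thr.mirna_rpm_sum)

    log2fc = np.log2(np.maximum(rt, thr.expr_floor) / np.maximum(rc, thr.expr_floor))
    p = np.full(len(counts), np.nan)
    if eligible.any():
        p[eligible] = two_library_test(
            counts.loc[eligible, treated].to_numpy(),
            counts.loc[eligible, control].to_numpy(),
            float(totals[treated]),
            float(totals[control]),
        )
    status = np.full(len(counts), "ns", dtype=object)
    de = eligible & (p < thr.mirna_p) & (np.abs(log2fc) > thr.mirna_log2fc)
    status[de & (log2fc > 0)] = "up"
    status[de & (log2fc < 0)] = "down"
    return pd.DataFrame(
        {
            "mirna_id": counts.index,
            "comparison": comparison,
            "eligible": eligible,
            "log2fc": log2fc,
            "p": p,
            "status": status,
        }
    ).reset_index(drop=True)


def call_all_de_mirnas(counts: pd.DataFrame, thresholds: Thresholds | None = None) -> pd.DataFrame:
    return pd.concat(
        [filter_and_call_de_mirnas(counts, c, thresholds) for c in COMPARISONS],
        ignore_index=True,
    )


def scan_targets(
    mirna_id: str,
    mirna_seq: str,
    cds_seqs: dict[str, str],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Scan one miRNA against a CDS library.

    At each offset the site is the gapless antiparallel pairing of the
    miRNA with the transcript window; the penalty counts non-paired
    positions, with G:U wobbles weighted by ``wobble_weight`` (default
    0.5).  Offsets with penalty below ``target_penalty_max`` (default 3)
    are reported, 1-based.
    """
    thr = thresholds or Thresholds()
    if not 19 <= len(mirna_seq) <= 24:
        raise ValueError(f"miRNA {mirna_id!r} length {len(mirna_seq)} outside 19-24 nt")
    q = _encode(mirna_seq, mirna_id)
    rc = _COMP[q][::-1]  # reverse complement, codes
    m = len(rc)
    rows = []
    for tid in sorted(cds_seqs):
        t = _encode(cds_seqs[tid], tid)
        if len(t) < m:
            continue
        win = sliding_window_view(t, m)
        neq = win != rc
        # in reverse-complement space a G:U wobble is (rc=C, site=T) for a
        # miRNA G opposite a transcript U, or (rc=A, site=G) for a miRNA U
        # opposite a transcript G
        wob = ((rc == 1) & (win == 3)) | ((rc == 0) & (win == 2))
        penalty = neq.sum(axis=1) - (1.0 - thr.wobble_weight) * (wob & neq).sum(axis=1)
        hits = np.flatnonzero(penalty < thr.target_penalty_max)
        for off in hits:
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "transcript_id": tid,
                    "offset": int(off) + 1,
                    "penalty": float(penalty[off]),
                }
            )
    return pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "offset", "penalty"])


def scan_all_targets(
    mirna_seqs: dict[str, str],
    cds_seqs: dict[str, str],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Scan every miRNA against every CDS; concatenated hit table."""
    frames = [
        f
        for mid in sorted(mirna_seqs)
        if len(f := scan_targets(mid, mirna_seqs[mid], cds_seqs, thresholds))
    ]
    if not frames:
        return pd.DataFrame(columns=["mirna_id", "transcript_id", "offset", "penalty"])
    return pd.concat(frames, ignore_index=True)


def _tolerant_de_mirnas(de_mirnas: pd.DataFrame) -> pd.DataFrame:
    """DE calls restricted to miRNAs DE in at least one tolerant-genotype
    comparison (removes miRNAs DE only in the sensitive genotype)."""
    de = de_mirnas[de_mirnas["status"].isin(["up", "down"])]
    keep = set(
        de.loc[
            de["comparison"].map(comparison_genotype) == TOLERANT, "mirna_id"
        ]
    )
    return de[de["mirna_id"].isin(keep)]


def anticorrelated_pairs(
    de_mirnas: pd.DataFrame,
    target_hits: pd.DataFrame,
    deg_results: pd.DataFrame,
) -> pd.DataFrame:
    """Gene-level chains: miRNA and target gene DE in opposite directions
    in the same tolerant-genotype comparison."""
    de = _tolerant_de_mirnas(de_mirnas)
    de = de[de["comparison"].map(comparison_genotype) == TOLERANT]
    targets = target_hits.groupby("mirna_id")["transcript_id"].agg(set)
    deg = deg_results.set_index(["comparison", "gene_id"])
    opposite = {"up": "down", "down": "up"}
    rows = []
    for _, mrow in de.iterrows():
        mid, comp, mdir = mrow["mirna_id"], mrow["comparison"], mrow["status"]
        for gid in sorted(targets.get(mid, set())):
            key = (comp, gid)
            if key not in deg.index:
                continue
            gdir = deg.loc[key, "status"]
            if gdir == opposite[mdir]:
                rows.append(
                    {
                        "mirna_id": mid,
                        "gene_id": gid,
                        "protein_id": None,
                        "comparison": comp,
                        "mirna_direction": mdir,
                        "gene_direction": gdir,
                        "protein_direction": None,
                        "level": "gene",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "gene_id",
            "protein_id",
            "comparison",
            "mirna_direction",
            "gene_direction",
            "protein_direction",
            "level",
        ],
    )


def protein_level_chains(
    de_mirnas: pd.DataFrame,
    target_hits: pd.DataFrame,
    concordance_pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Protein-level chains (candidate translational repression).

    The miRNA must be DE in a tolerant-genotype comparison and the
    target's protein DAP in the opposite direction while the gene is
    unchanged or undetected (concordance categories IV or VI).
    """
    de = _tolerant_de_mirnas(de_mirnas)
    de = de[de["comparison"].map(comparison_genotype) == TOLERANT]
    targets = target_hits.groupby("mirna_id")["transcript_id"].agg(set)
    cat46 = concordance_pairs[concordance_pairs["category"].isin(["IV", "VI"])]
    opposite = {"up": "down", "down": "up"}
    rows = []
    for _, mrow in de.iterrows():
        mid, comp, mdir = mrow["mirna_id"], mrow["comparison"], mrow["status"]
        tset = targets.get(mid, set())
        sub = cat46[(cat46["comparison"] == comp) & cat46["gene_id"].isin(tset)]
        for _, prow in sub.iterrows():
            if prow["protein_status"] == opposite[mdir]:
                rows.append(
                    {
                        "mirna_id": mid,
                        "gene_id": prow["gene_id"],
                        "protein_id": prow["protein_id"],
                        "comparison": comp,
                        "mirna_direction": mdir,
                        "gene_direction": prow["gene_status"],
                        "protein_direction": prow["protein_status"],
                        "level": "protein",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "gene_id",
            "protein_id",
            "comparison",
            "mirna_direction",
            "gene_direction",
            "protein_direction",
            "level",
        ],
    )
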