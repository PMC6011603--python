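"""Synthetic multi-omics data with a known planted truth.

The generator emulates the study design end to end: two genotypes
(salt-tolerant E, salt-sensitive N) sampled at 0/4/24 h, a single
mRNA-seq and small-RNA library per sample, three iTRAQ replicates per
sample, plus AS event tables, ortholog/PPI tables and miRNA/CDS
sequences.  Differential structure is planted with known effects so that
every downstream stage can be tested by recovery:

* mRNA counts are independent Poisson draws around an expected abundance
  (one library per condition means no replicate dispersion is
  identifiable, matching the real design); DE genes carry a planted log2
  effect in the treated samples of their comparison.
* A protein-mapped subset of genes receives gene-protein concordance
  categories I-VI; category semantics fix which level changes
  (I same-direction, II opposite, III mRNA only, IV protein only,
  V mRNA DE with no quantified protein, VI protein DE with no mRNA).
* Replicate iTRAQ ratios scatter log-normally around the category-implied
  true ratio; peptide tallies populate all identification tiers.
* miRNAs are 21-nt random sequences; planted targets carry the reverse
  complement of their miRNA in the target CDS with 0-2 injected
  mismatches and anticorrelated planted expression.
* AS events are per-gene Bernoulli draws with the tolerant treated rate
  above and the sensitive treated rate below the control rate.
* The PPI table wires two planted hub nodes to candidate orthologs with
  scores above the edge cutoff, over a scored background.

The truth table stores the noise-free planted effects; "true" result
frames derived from it apply the published thresholds to those effects
at face value, so recovery comparisons are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import concordance, mirna as mirna_mod, screening
from .config import (
    AS_EVENT_TYPES,
    COMPARISONS,
    SAMPLES,
    SENSITIVE,
    TOLERANT,
    TREATED_TIMES,
    Thresholds,
    comparison_name,
)
from .proteomics import N_REPLICATES, peptide_columns, ratio_columns

__all__ = [
    "SimConfig",
    "TruthTable",
    "SyntheticDataset",
    "null_config",
    "noise_free_config",
    "simulate_counts",
    "simulate_proteome",
    "simulate_mirnas_and_targets",
    "simulate_as_events",
    "simulate_ppi",
    "simulate_all",
]

_FC_COLS = {c: f"log2fc_{c}" for c in COMPARISONS}
_LR_COLS = {c: f"log2ratio_{c}" for c in COMPARISONS}

_DEFAULT_RULE_HITS: Mapping[str, int] = {
    "i": 5, "ii": 4, "iii": 6, "iv": 5, "v": 5, "protein_only": 6,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale version of the design: 2000 genes, a
    400-protein mapped subset, 60 miRNAs, 10% planted differential
    structure per comparison with 4- to 16-fold effects, Poisson count
    noise at 5M mRNA reads per library, log-normal iTRAQ replicate
    scatter, and IR-dominant AS with the tolerant treated rate above and
    the sensitive treated rate below the control rate.
    """

    n_genes: int = 2000
    n_proteins: int = 400
    n_mirnas: int = 60
    frac_deg: float = 0.1
    #: probability of categories I..VI for the protein-mapped non-null genes
    category_probs: tuple = (0.12, 0.08, 0.30, 0.20, 0.15, 0.15)
    effect_log2fc_range: tuple = (2.0, 4.0)
    mrna_library_size: int = 5_000_000
    protein_replicates: int = 3
    #: sd of the natural-log replicate ratio noise (~CV of the ratio)
    protein_cv: float = 0.10
    mirna_library_size: int = 2_000_000
    #: fraction of tolerant-DE miRNAs given an anticorrelated gene target
    frac_planted_targets: float = 0.5
    as_event_rate_control: float = 0.05
    as_event_rate_treated_tolerant: float = 0.09
    as_event_rate_treated_sensitive: float = 0.03
    n_planted_rule_hits: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_RULE_HITS)
    )
    seed: int = 0
    # --- distributional choices (documented artifact parameters) ---
    #: 'poisson' count noise, or 'none' for rounded expected counts
    noise: str = "poisson"
    baseline_median: float = 200.0
    baseline_sigma: float = 1.2
    baseline_min: float = 10.0
    #: log2 range of planted protein effects
    protein_effect_log2_range: tuple = (0.5, 1.5)
    cds_length_range: tuple = (300, 1500)
    mirna_length: int = 21
    as_type_probs: tuple = (0.55, 0.20, 0.13, 0.12)  # IR, ES, A5SS, A3SS
    #: extra events per AS-positive gene-sample (Poisson mean)
    as_extra_events: float = 0.7
    #: probability a category I/II/III/V gene is also DE in the sensitive
    #: genotype (same direction and magnitude)
    frac_n_effect: float = 0.6
    #: probability a category IV/VI protein is also DAP in the sensitive
    #: genotype
    frac_iv_shared: float = 0.5
    n_protein_level_targets: int = 3

    def validate(self) -> None:
        for name in ("n_genes", "n_proteins", "n_mirnas"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins cannot exceed n_genes")
        for name in ("frac_deg", "frac_planted_targets", "frac_n_effect", "frac_iv_shared"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if len(self.category_probs) != 6:
            raise ValueError("category_probs must have six entries (categories I-VI)")
        if any(p < 0 for p in self.category_probs):
            raise ValueError("category_probs must be non-negative")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1 within 1e-9")
        lo, hi = self.effect_log2fc_range
        if not (0 < lo <= hi):
            raise ValueError("effect_log2fc_range must be a positive interval")
        for name in ("mrna_library_size", "mirna_library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.protein_replicates != N_REPLICATES:
            raise ValueError(
                f"protein_replicates: the iTRAQ design uses {N_REPLICATES} biological replicates"
            )
        if self.protein_cv < 0:
            raise ValueError("protein_cv must be non-negative")
        for name in (
            "as_event_rate_control",
            "as_event_rate_treated_tolerant",
            "as_event_rate_treated_sensitive",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for rule, n in self.n_planted_rule_hits.items():
            if rule not in _DEFAULT_RULE_HITS:
                raise ValueError(f"n_planted_rule_hits: unknown rule {rule!r}")
            if n < 0:
                raise ValueError(f"n_planted_rule_hits[{rule!r}] must be non-negative")
        n_rule_prot = sum(self.n_planted_rule_hits.values())
        if self.n_proteins and n_rule_prot > self.n_proteins:
            raise ValueError("n_planted_rule_hits exceed n_proteins")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"noise must be 'poisson' or 'none', got {self.noise!r}")
        if self.mirna_length != 21:
            raise ValueError("mirna_length is fixed at 21 nt")

    def asdict(self) -> dict:
        return asdict(self)


def null_config(n_genes: int = 5000, seed: int = 0, **kwargs) -> SimConfig:
    """A configuration with no planted structure at all (for null
    calibration of the DEG caller)."""
    return SimConfig(
        n_genes=n_genes,
        n_proteins=0,
        n_mirnas=0,
        frac_deg=0.0,
        n_planted_rule_hits={k: 0 for k in _DEFAULT_RULE_HITS},
        seed=seed,
        **kwargs,
    )


def noise_free_config(seed: int = 0, **kwargs) -> SimConfig:
    """The noise-free limit of the default configuration.

    Counts equal their expectations (rounded) and the iTRAQ replicate
    scatter is vanishingly small (1e-3 rather than exactly zero, because
    identical replicates carry no degrees of freedom for the replicate
    location test).  The expression floor is raised so every planted
    effect is unambiguous at the simulated depth.
    """
    kwargs.setdefault("noise", "none")
    kwargs.setdefault("protein_cv", 1e-3)
    kwargs.setdefault("baseline_min", 100.0)
    return SimConfig(seed=seed, **kwargs)


@dataclass
class TruthTable:
    """Noise-free planted effects for every molecule, plus derived
    'true' result frames in the same shapes the callers emit."""

    gene_effects: pd.DataFrame  # index gene_id; baseline, length, log2fc per comparison
    protein_truth: pd.DataFrame  # protein_id, gene_id, category, role, quantified, log2ratio per comparison
    mirna_truth: pd.DataFrame | None = None
    as_events: pd.DataFrame | None = None
    ppi_hubs: list | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    def true_deg_results(self) -> pd.DataFrame:
        thr = self.thresholds
        rows = []
        for comp in COMPARISONS:
            fc = self.gene_effects[_FC_COLS[comp]]
            status = np.where(
                fc >= thr.deg_log2fc, "up", np.where(fc <= -thr.deg_log2fc, "down", "ns")
            )
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": self.gene_effects.index,
                        "comparison": comp,
                        "log2fc": fc.to_numpy(),
                        "status": status,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def true_dap_results(self) -> pd.DataFrame:
        thr = self.thresholds
        lo, hi = np.log2(thr.dap_lo), np.log2(thr.dap_hi)
        rows = []
        for comp in COMPARISONS:
            for _, p in self.protein_truth.iterrows():
                quant = bool(p["quantified"])
                lr = float(p[_LR_COLS[comp]]) if quant else float("nan")
                status = "ns"
                if quant and (lr > hi or lr < lo):
                    status = "up" if lr > 0 else "down"
                rows.append(
                    {
                        "protein_id": p["protein_id"],
                        "gene_id": p["gene_id"],
                        "comparison": comp,
                        "mean_ratio": 2.0 ** lr if quant else float("nan"),
                        "log2ratio": lr,
                        "p": 0.0 if status != "ns" else float("nan"),
                        "quantified": quant,
                        "status": status,
                    }
                )
        return pd.DataFrame(rows)

    def true_pairs(self) -> pd.DataFrame:
        return concordance.classify_pairs(self.true_deg_results(), self.true_dap_results())

    def true_candidates(self) -> pd.DataFrame:
        return screening.screen_all(
            self.true_pairs(), self.true_deg_results(), self.true_dap_results(), self.thresholds
        )

    def true_de_mirna_results(self) -> pd.DataFrame:
        thr = self.thresholds
        if self.mirna_truth is None or not len(self.mirna_truth):
            return pd.DataFrame(columns=["mirna_id", "comparison", "eligible", "log2fc", "p", "status"])
        rows = []
        for comp in COMPARISONS:
            for _, m in self.mirna_truth.iterrows():
                fc = float(m[_FC_COLS[comp]])
                status = "ns"
                if abs(fc) > thr.mirna_log2fc:
                    status = "up" if fc > 0 else "down"
                rows.append(
                    {
                        "mirna_id": m["mirna_id"],
                        "comparison": comp,
                        "eligible": True,
                        "log2fc": fc,
                        "p": 0.0 if status != "ns" else 1.0,
                        "status": status,
                    }
                )
        return pd.DataFrame(rows)

    def true_target_hits(self) -> pd.DataFrame:
        if self.mirna_truth is None or not len(self.mirna_truth):
            return pd.DataFrame(columns=["mirna_id", "transcript_id", "offset", "penalty"])
        planted = self.mirna_truth[self.mirna_truth["target_gene"].notna()]
        return pd.DataFrame(
            {
                "mirna_id": planted["mirna_id"].to_numpy(),
                "transcript_id": planted["target_gene"].to_numpy(),
                "offset": planted["site_offset"].to_numpy(dtype=int),
                "penalty": planted["injected_mismatches"].to_numpy(dtype=float),
            }
        ).reset_index(drop=True)

    def true_gene_chains(self) -> pd.DataFrame:
        return mirna_mod.anticorrelated_pairs(
            self.true_de_mirna_results(), self.true_target_hits(), self.true_deg_results()
        )

    def true_protein_chains(self) -> pd.DataFrame:
        return mirna_mod.protein_level_chains(
            self.true_de_mirna_results(), self.true_target_hits(), self.true_pairs()
        )


@dataclass
class SyntheticDataset:
    config: SimConfig
    expression: pd.DataFrame
    proteins: pd.DataFrame
    mirna_counts: pd.DataFrame
    mirna_seqs: dict
    cds_seqs: dict
    as_events: pd.DataFrame
    ortholog_map: pd.DataFrame
    ppi_edges: pd.DataFrame
    truth: TruthTable


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(6)
    return np.random.default_rng(children[stream])


def _draw_counts(rng, expected, noise: str):
    if noise == "poisson":
        return rng.poisson(expected)
    return np.rint(expected).astype(np.int64)


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Generate the gene expression matrix and the planted truth.

    Gene roles (screening-rule plants, concordance categories, background
    DE) are assigned here because the mRNA effects of protein-mapped
    genes are dictated by their category; the proteome generator then
    reads the same truth.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    n = cfg.n_genes
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n)])
    lengths = rng.integers(500, 3001, size=n)
    baseline = np.exp(rng.normal(np.log(cfg.baseline_median), cfg.baseline_sigma, size=n))
    baseline = np.clip(baseline, cfg.baseline_min, 1e5)

    fc = {comp: np.zeros(n) for comp in COMPARISONS}

    perm = rng.permutation(n)
    pool = list(perm[: cfg.n_proteins])  # gene indices mapped to proteins
    lo, hi = cfg.effect_log2fc_range
    qlo, qhi = cfg.protein_effect_log2_range

    protein_rows: list[dict] = []

    def new_protein(gene_idx, category, role, quantified, lr_e, lr_n):
        gid = gene_ids[gene_idx] if gene_idx is not None else None
        row = {"gene_idx": gene_idx, "gene_id": gid, "category": category,
               "role": role, "quantified": quantified}
        for comp in COMPARISONS:
            is_e = comp.startswith(TOLERANT)
            row[_LR_COLS[comp]] = lr_e if is_e else lr_n
        protein_rows.append(row)

    take = 0

    def next_genes(k):
        nonlocal take
        sel = pool[take : take + k]
        take += k
        return sel

    hits = dict(_DEFAULT_RULE_HITS)
    hits.update(cfg.n_planted_rule_hits)

    # --- screening-rule plants (effects chosen to satisfy each predicate) ---
    for gi in next_genes(hits["i"]):
        s = rng.choice([-1.0, 1.0])
        for t in TREATED_TIMES:
            fc[comparison_name(TOLERANT, t)][gi] = s * 3.0
            fc[comparison_name(SENSITIVE, t)][gi] = s * 1.5
        new_protein(gi, "III", "rule_i", True, 0.0, 0.0)
    for gi in next_genes(hits["ii"]):
        s = rng.choice([-1.0, 1.0])
        for t in TREATED_TIMES:
            fc[comparison_name(TOLERANT, t)][gi] = s * 2.0
            fc[comparison_name(SENSITIVE, t)][gi] = -s * 2.0
        new_protein(gi, "III", "rule_ii", True, 0.0, 0.0)
    for gi in next_genes(hits["iii"]):
        s = rng.choice([-1.0, 1.0])
        for t in TREATED_TIMES:
            fc[comparison_name(TOLERANT, t)][gi] = s * 2.5
        new_protein(gi, "III", "rule_iii", True, 0.0, 0.0)
    for gi in next_genes(hits["iv"]):
        s = rng.choice([-1.0, 1.0])
        new_protein(gi, "IV", "rule_iv", True, s * 1.2, s * 0.5)
    for gi in next_genes(hits["v"]):
        s = rng.choice([-1.0, 1.0])
        new_protein(gi, "IV", "rule_v", True, s * 1.0, 0.0)
    for k in range(hits["protein_only"]):
        s = rng.choice([-1.0, 1.0])
        next_genes(1)  # consumes a pool slot; the gene stays a plain background gene
        row_lr_n = 0.0  # tolerant-only by construction
        protein_rows.append(
            {
                "gene_idx": None,
                "gene_id": f"GX{k + 1:04d}",  # phantom gene, absent from the matrix
                "category": "VI",
                "role": "protein_only",
                "quantified": True,
                **{
                    _LR_COLS[c]: (s * 1.0 if c.startswith(TOLERANT) else row_lr_n)
                    for c in COMPARISONS
                },
            }
        )

    # --- concordance-category plants on the remaining protein pool ---
    n_cat = min(int(round(cfg.frac_deg * cfg.n_proteins)), cfg.n_proteins - take)
    cat_labels = np.array(["I", "II", "III", "IV", "V", "VI"])
    cats = rng.choice(6, size=n_cat, p=np.asarray(cfg.category_probs, dtype=float))
    vi_extra = 0
    for j, ci in enumerate(cats):
        cat = cat_labels[ci]
        s = rng.choice([-1.0, 1.0])
        m = rng.uniform(lo, hi)
        q = rng.uniform(qlo, qhi)
        gi = next_genes(1)[0]
        if cat in ("I", "II", "III", "V"):
            n_too = rng.random() < cfg.frac_n_effect
            for t in TREATED_TIMES:
                fc[comparison_name(TOLERANT, t)][gi] = s * m
                if n_too:
                    fc[comparison_name(SENSITIVE, t)][gi] = s * m
        if cat == "I":
            new_protein(gi, cat, "category", True, s * q, 0.0)
        elif cat == "II":
            new_protein(gi, cat, "category", True, -s * q, 0.0)
        elif cat == "III":
            new_protein(gi, cat, "category", True, 0.0, 0.0)
        elif cat == "IV":
            # shared responders change at least as strongly in the sensitive
            # genotype, so they are not tolerant-specific under rule iv
            shared = rng.random() < cfg.frac_iv_shared
            new_protein(gi, cat, "category", True, s * q, s * (q + 0.4) if shared else 0.0)
        elif cat == "V":
            new_protein(gi, cat, "category", False, float("nan"), float("nan"))
        else:  # VI: protein maps to a phantom gene; the pool gene stays background
            vi_extra += 1
            shared = rng.random() < cfg.frac_iv_shared
            protein_rows.append(
                {
                    "gene_idx": None,
                    "gene_id": f"GX{hits['protein_only'] + vi_extra:04d}",
                    "category": "VI",
                    "role": "category",
                    "quantified": True,
                    **{
                        _LR_COLS[c]: (
                            s * q if c.startswith(TOLERANT) else (s * q if shared else 0.0)
                        )
                        for c in COMPARISONS
                    },
                }
            )

    # remaining pool slots: null proteins (quantified, ratio 1)
    for gi in pool[take:]:
        new_protein(gi, "null", "null", True, 0.0, 0.0)

    # --- background DE genes, independently per comparison ---
    pool_set = set(pool)
    bg = np.array([i for i in range(n) if i not in pool_set])
    if cfg.frac_deg > 0 and len(bg):
        for comp in COMPARISONS:
            mask = rng.random(len(bg)) < cfg.frac_deg
            sel = bg[mask]
            signs = rng.choice([-1.0, 1.0], size=len(sel))
            mags = rng.uniform(lo, hi, size=len(sel))
            fc[comp][sel] = signs * mags

    # --- expected abundance and counts ---
    scale = cfg.mrna_library_size / (cfg.n_genes * cfg.baseline_median)
    expected = {s: baseline * scale for s in SAMPLES}
    for comp, (treated, _control) in COMPARISONS.items():
        expected[treated] = expected[treated] * 2.0 ** fc[comp]
    counts = {s: _draw_counts(rng, expected[s], cfg.noise) for s in SAMPLES}

    matrix = pd.DataFrame({"length": lengths, **counts}, index=pd.Index(gene_ids, name="gene_id"))

    gene_truth = pd.DataFrame(
        {
            "length": lengths,
            "baseline": baseline,
            **{_FC_COLS[c]: fc[c] for c in COMPARISONS},
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    prot = pd.DataFrame(protein_rows)
    if len(prot):
        prot = prot.sort_values("gene_id", na_position="last", kind="stable").reset_index(drop=True)
        prot.insert(0, "protein_id", [f"P{i + 1:05d}" for i in range(len(prot))])
        prot = prot.drop(columns=["gene_idx"])
    else:
        prot = pd.DataFrame(
            columns=["protein_id", "gene_id", "category", "role", "quantified"]
            + [_LR_COLS[c] for c in COMPARISONS]
        )

    truth = TruthTable(gene_effects=gene_truth, protein_truth=prot)
    return matrix, truth


# peptide tally distribution: populates every identification tier
_PEPTIDE_VALUES = np.array([0, 1, 2, 3, 4])
_PEPTIDE_PROBS = np.array([0.15, 0.35, 0.30, 0.15, 0.05])


def simulate_proteome(cfg: SimConfig, truth: TruthTable) -> pd.DataFrame:
    """Per-replicate iTRAQ ratios and peptide tallies from the truth.

    Replicate ratios are the true ratio times exp(N(0, protein_cv)).
    Planted non-null proteins are quantified in all three replicates so
    their differential status is testable; null proteins draw a
    replicate-presence pattern that also populates the partial tiers.
    Category V proteins are identified (peptides only) but never
    quantified.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    prot = truth.protein_truth
    rows = []
    for _, p in prot.iterrows():
        peps = rng.choice(_PEPTIDE_VALUES, size=N_REPLICATES, p=_PEPTIDE_PROBS)
        if peps.sum() == 0:
            peps[0] = 1
        row = {"protein_id": p["protein_id"], "gene_id": p["gene_id"]}
        for r, v in zip(peptide_columns(), peps):
            row[r] = int(v)
        if p["quantified"]:
            if p["role"] == "null":
                n_present = rng.choice([3, 2, 1], p=[0.5, 0.3, 0.2])
                present = np.zeros(N_REPLICATES, dtype=bool)
                present[rng.choice(N_REPLICATES, size=n_present, replace=False)] = True
            else:
                present = np.ones(N_REPLICATES, dtype=bool)
            for comp in COMPARISONS:
                true_ratio = 2.0 ** float(p[_LR_COLS[comp]])
                noise = np.exp(rng.normal(0.0, cfg.protein_cv, size=N_REPLICATES))
                ratios = true_ratio * noise
                for col, ok, val in zip(ratio_columns(comp), present, ratios):
                    row[col] = float(val) if ok else float("nan")
        else:
            for comp in COMPARISONS:
                for col in ratio_columns(comp):
                    row[col] = float("nan")
        rows.append(row)
    cols = (
        ["protein_id", "gene_id"]
        + peptide_columns()
        + [c for comp in COMPARISONS for c in ratio_columns(comp)]
    )
    return pd.DataFrame(rows, columns=cols)


_DNA = np.array(list("ACGT"))
_RNA = np.array(list("ACGU"))
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def _rc_dna(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def simulate_mirnas_and_targets(
    cfg: SimConfig, truth: TruthTable
) -> tuple[pd.DataFrame, dict, dict, TruthTable]:
    """miRNA counts + sequences, CDS sequences, and planted target sites.

    20% of the miRNAs are DE in the tolerant comparisons, 10% only in the
    sensitive comparisons (these must be removed by the chain builder),
    15% sit below the RPM eligibility filters, and the rest are
    abundance-matched nulls.  Planted gene-level targets point at
    category III genes DE in the opposite direction; a few
    protein-level targets point at category IV proteins with the
    opposite protein direction.  Each planted site is the reverse
    complement of its miRNA with 0-2 injected mismatches.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    n = cfg.n_mirnas
    ids = [f"mir{i + 1:04d}" for i in range(n)]
    seqs = {mid: "".join(rng.choice(_RNA, size=cfg.mirna_length)) for mid in ids}

    gene_ids = list(truth.gene_effects.index)
    clo, chi = cfg.cds_length_range
    cds = {
        gid: "".join(rng.choice(_DNA, size=int(rng.integers(clo, chi + 1))))
        for gid in gene_ids
    }

    n_tol = int(round(0.2 * n))
    n_sens = int(round(0.1 * n))
    n_low = int(round(0.15 * n))

    fc = {comp: np.zeros(n) for comp in COMPARISONS}
    # abundances are designed in count space so that the per-sample column
    # total approximates the library depth; RPM is later recomputed against
    # that total, which keeps the low-abundance plants below the RPM filters
    mean_count = cfg.mirna_library_size / max(1, n - n_low)
    baseline_count = np.empty(n)
    baseline_count[:] = rng.uniform(0.2 * mean_count, 1.8 * mean_count, size=n)
    baseline_count[n_tol + n_sens : n_tol + n_sens + n_low] = rng.uniform(
        2.0, 0.35 * cfg.mirna_library_size * 60e-6 / 6.0, size=n_low
    )
    baseline_rpm = baseline_count / (cfg.mirna_library_size / 1e6)

    signs = rng.choice([-1.0, 1.0], size=n)
    mags = rng.uniform(1.5, 3.0, size=n)
    for i in range(n_tol):
        for t in TREATED_TIMES:
            fc[comparison_name(TOLERANT, t)][i] = signs[i] * mags[i]
    for i in range(n_tol, n_tol + n_sens):
        for t in TREATED_TIMES:
            fc[comparison_name(SENSITIVE, t)][i] = signs[i] * mags[i]

    expected = {s: baseline_count.copy() for s in SAMPLES}
    for comp, (treated, _c) in COMPARISONS.items():
        expected[treated] = expected[treated] * 2.0 ** fc[comp]
    counts = pd.DataFrame(
        {s: _draw_counts(rng, expected[s], cfg.noise) for s in SAMPLES},
        index=pd.Index(ids, name="mirna_id"),
    )

    # --- target planting ---
    target_gene = [None] * n
    target_protein = [None] * n
    target_level = [None] * n
    site_offset = np.full(n, -1)
    injected = np.full(n, -1)

    prot = truth.protein_truth
    e4 = _FC_COLS[comparison_name(TOLERANT, 4)]
    lr_e4 = _LR_COLS[comparison_name(TOLERANT, 4)]
    cat3 = prot[(prot["category"] == "III") & (prot["role"] == "category")]
    cat4 = prot[(prot["category"] == "IV")]

    def inject(mirna_idx, gid, k):
        site = list(_rc_dna(seqs[ids[mirna_idx]]))
        pos = rng.choice(len(site), size=k, replace=False)
        for pidx in pos:
            choices = [b for b in "ACGT" if b != site[pidx]]
            site[pidx] = choices[rng.integers(len(choices))]
        seq = cds[gid]
        off = int(rng.integers(0, len(seq) - len(site) + 1))
        cds[gid] = seq[:off] + "".join(site) + seq[off + len(site):]
        site_offset[mirna_idx] = off + 1
        injected[mirna_idx] = k

    n_gene_targets = int(round(cfg.frac_planted_targets * n_tol))
    used_genes: set = set()
    gi_pool = [
        (row["gene_id"], float(truth.gene_effects.loc[row["gene_id"], e4]))
        for _, row in cat3.iterrows()
    ]
    planted_gene_targets = 0
    for i in range(n_tol):
        if planted_gene_targets >= n_gene_targets:
            break
        want = -signs[i]  # gene direction opposite the miRNA
        match = next(
            (g for g, gfc in gi_pool if g not in used_genes and np.sign(gfc) == want),
            None,
        )
        if match is None:
            continue
        used_genes.add(match)
        inject(i, match, int(rng.integers(0, 3)))
        target_gene[i] = match
        target_level[i] = "gene"
        planted_gene_targets += 1

    n_prot_targets = cfg.n_protein_level_targets
    planted_prot_targets = 0
    pi_pool = [
        (row["protein_id"], row["gene_id"], float(row[lr_e4]))
        for _, row in cat4.iterrows()
        if row["gene_id"] is not None and pd.notna(row["gene_id"]) and row["gene_id"] in cds
    ]
    for i in range(n_tol):
        if planted_prot_targets >= n_prot_targets:
            break
        if target_level[i] is not None:
            continue
        want = -signs[i]  # protein direction opposite the miRNA
        match = next(
            (
                (pid, gid)
                for pid, gid, plr in pi_pool
                if gid not in used_genes and np.sign(plr) == want
            ),
            None,
        )
        if match is None:
            continue
        pid, gid = match
        used_genes.add(gid)
        inject(i, gid, int(rng.integers(0, 3)))
        target_gene[i] = gid
        target_protein[i] = pid
        target_level[i] = "protein"
        planted_prot_targets += 1

    mirna_truth = pd.DataFrame(
        {
            "mirna_id": ids,
            "sequence": [seqs[m] for m in ids],
            "baseline_rpm": baseline_rpm,
            **{_FC_COLS[c]: fc[c] for c in COMPARISONS},
            "target_gene": target_gene,
            "target_protein": target_protein,
            "target_level": target_level,
            "site_offset": site_offset,
            "injected_mismatches": injected,
        }
    )
    truth.mirna_truth = mirna_truth
    return counts, seqs, cds, truth


def simulate_as_events(cfg: SimConfig, truth: TruthTable) -> tuple[pd.DataFrame, TruthTable]:
    """Per-sample AS events with configurable per-gene rates.

    Treated tolerant samples use a rate above the control rate and
    treated sensitive samples a rate below it, so tolerant event counts
    rise under salt while sensitive counts fall.  Event types are
    IR-dominant by default.  The drawn events themselves are the truth.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    rates = {
        "SE0": cfg.as_event_rate_control,
        "SN0": cfg.as_event_rate_control,
        "SE4": cfg.as_event_rate_treated_tolerant,
        "SE24": cfg.as_event_rate_treated_tolerant,
        "SN4": cfg.as_event_rate_treated_sensitive,
        "SN24": cfg.as_event_rate_treated_sensitive,
    }
    gene_ids = truth.gene_effects.index.to_numpy()
    lengths = truth.gene_effects["length"].to_numpy()
    rows = []
    for sample in SAMPLES:
        has = rng.random(len(gene_ids)) < rates[sample]
        for gi in np.flatnonzero(has):
            n_ev = 1 + rng.poisson(cfg.as_extra_events)
            for _ in range(n_ev):
                t = AS_EVENT_TYPES[
                    rng.choice(len(AS_EVENT_TYPES), p=np.asarray(cfg.as_type_probs))
                ]
                length = int(lengths[gi])
                start = int(rng.integers(1, max(2, length - 50)))
                end = min(length, start + int(rng.integers(20, 201)))
                rows.append(
                    {
                        "gene_id": gene_ids[gi],
                        "sample": sample,
                        "type": t,
                        "start": start,
                        "end": end,
                    }
                )
    events = pd.DataFrame(rows, columns=["gene_id", "sample", "type", "start", "end"])
    truth.as_events = events
    return events, truth


def simulate_ppi(
    cfg: SimConfig, truth: TruthTable
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Ortholog map and scored PPI edges with two planted hubs.

    Every true screening candidate gets an ortholog id; the two hub nodes
    are wired to disjoint halves of the candidates with scores above the
    edge cutoff, over a sparse scored background that straddles the
    cutoff.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    cand = truth.true_candidates()
    cand_ids = sorted(set(cand["id"]))
    orth = {cid: f"AT{i + 1:05d}" for i, cid in enumerate(cand_ids)}
    ortholog_map = pd.DataFrame({"id": cand_ids, "ortholog": [orth[c] for c in cand_ids]})

    hubs = ["AT_HUB1", "AT_HUB2"]
    edges = []
    orth_ids = [orth[c] for c in cand_ids]
    half = (len(orth_ids) + 1) // 2
    for hub, members in zip(hubs, (orth_ids[:half], orth_ids[half:])):
        for node in members:
            edges.append(
                {
                    "node_a": hub,
                    "node_b": node,
                    "combined_score": int(rng.integers(200, 900)),
                }
            )
    bg_nodes = [f"AT_BG{i + 1:03d}" for i in range(30)]
    for node in bg_nodes:
        for _ in range(int(rng.integers(1, 3))):
            other = bg_nodes[rng.integers(len(bg_nodes))]
            if other == node:
                continue
            edges.append(
                {
                    "node_a": node,
                    "node_b": other,
                    "combined_score": int(rng.integers(50, 400)),
                }
            )
    # a few background-candidate edges straddling the cutoff
    for _ in range(min(10, len(orth_ids))):
        edges.append(
            {
                "node_a": bg_nodes[rng.integers(len(bg_nodes))],
                "node_b": orth_ids[rng.integers(len(orth_ids))],
                "combined_score": int(rng.integers(50, 400)),
            }
        )
    edge_df = pd.DataFrame(edges, columns=["node_a", "node_b", "combined_score"])
    truth.ppi_hubs = hubs
    return ortholog_map, edge_df, truth


def simulate_all(cfg: SimConfig) -> SyntheticDataset:
    """Run every generator stage and bundle the dataset."""
    matrix, truth = simulate_counts(cfg)
    proteins = simulate_proteome(cfg, truth)
    mirna_counts, mirna_seqs, cds_seqs, truth = simulate_mirnas_and_targets(cfg, truth)
    as_events, truth = simulate_as_events(cfg, truth)
    ortholog_map, ppi_edges, truth = simulate_ppi(cfg, truth)
    return SyntheticDataset(
        config=cfg,
        expression=matrix,
        proteins=proteins,
        mirna_counts=mirna_counts,
        mirna_seqs=mirna_seqs,
        cds_seqs=cds_seqs,
        as_events=as_events,
        ortholog_map=ortholog_map,
        ppi_edges=ppi_edges,
        truth=truth,
    )
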