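"""The synthetic generator: determinism, null limits and truth consistency."""

import numpy as np
import pandas as pd
import pytest

from saltomics.config import COMPARISONS
from saltomics.mirna import scan_targets
from saltomics.proteomics import ratio_columns
from saltomics.synthetic import (
    SimConfig,
    noise_free_config,
    null_config,
    simulate_all,
    simulate_counts,
    simulate_mirnas_and_targets,
    simulate_proteome,
)

ZERO_HITS = {k: 0 for k in ("i", "ii", "iii", "iv", "v", "protein_only")}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_genes", 0),
            ("frac_deg", 1.5),
            ("category_probs", (0.5, 0.5, 0.0, 0.0, 0.0, 0.1)),
            ("effect_log2fc_range", (0.0, 2.0)),
            ("mrna_library_size", -1),
            ("protein_cv", -0.1),
            ("as_event_rate_control", 2.0),
            ("noise", "gauss"),
        ],
    )
    def test_invalid_fields_rejected_by_name(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            cfg.validate()

    def test_rule_hits_cannot_exceed_proteins(self):
        cfg = SimConfig(n_proteins=3)
        with pytest.raises(ValueError):
            cfg.validate()


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        a = simulate_all(SimConfig(seed=123, n_genes=300, n_proteins=40, n_mirnas=20))
        b = simulate_all(SimConfig(seed=123, n_genes=300, n_proteins=40, n_mirnas=20))
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.proteins, b.proteins)
        pd.testing.assert_frame_equal(a.mirna_counts, b.mirna_counts)
        pd.testing.assert_frame_equal(a.as_events, b.as_events)
        pd.testing.assert_frame_equal(a.ppi_edges, b.ppi_edges)
        assert a.mirna_seqs == b.mirna_seqs and a.cds_seqs == b.cds_seqs

    def test_different_seed_differs(self):
        a = simulate_all(SimConfig(seed=1, n_genes=300, n_proteins=40, n_mirnas=20))
        b = simulate_all(SimConfig(seed=2, n_genes=300, n_proteins=40, n_mirnas=20))
        assert not a.expression.equals(b.expression)


class TestNullLimits:
    def test_frac_deg_zero_no_expected_differences(self):
        cfg = null_config(n_genes=500, seed=4)
        _, truth = simulate_counts(cfg)
        for comp in COMPARISONS:
            assert (truth.gene_effects[f"log2fc_{comp}"] == 0).all()

    def test_zero_protein_cv_replicates_equal_truth(self):
        cfg = SimConfig(n_genes=400, n_proteins=60, protein_cv=0.0, seed=6,
                        n_planted_rule_hits=dict(i=1, ii=1, iii=1, iv=1, v=1, protein_only=1))
        _, truth = simulate_counts(cfg)
        prot = simulate_proteome(cfg, truth)
        merged = prot.merge(truth.protein_truth, on="protein_id", suffixes=("", "_t"))
        for comp in COMPARISONS:
            true_ratio = 2.0 ** merged[f"log2ratio_{comp}"]
            for col in ratio_columns(comp):
                obs = merged[col]
                ok = obs.notna()
                assert np.allclose(obs[ok], true_ratio[ok])

    def test_category_iii_protein_is_null_with_de_gene(self, default_dataset):
        truth = default_dataset.truth
        cat3 = truth.protein_truth.query("category == 'III'")
        assert len(cat3) > 0
        assert (cat3["log2ratio_E4/E0"] == 0).all()
        fc = truth.gene_effects.loc[cat3["gene_id"], "log2fc_E4/E0"]
        assert (fc.abs() >= 1).all()

    def test_no_planted_targets_when_fraction_zero(self):
        cfg = SimConfig(n_genes=300, n_proteins=40, n_mirnas=20,
                        frac_planted_targets=0.0, n_protein_level_targets=0, seed=8)
        _, truth = simulate_counts(cfg)
        _, _, _, truth = simulate_mirnas_and_targets(cfg, truth)
        assert truth.mirna_truth["target_gene"].isna().all()
        assert len(truth.true_gene_chains()) == 0


class TestPlantedSites:
    def test_perfect_site_scores_zero_at_planted_offset(self, default_dataset):
        truth = default_dataset.truth.mirna_truth
        planted = truth[truth["injected_mismatches"] == 0]
        assert len(planted) > 0
        row = planted.iloc[0]
        hits = scan_targets(
            row["mirna_id"],
            row["sequence"],
            {row["target_gene"]: default_dataset.cds_seqs[row["target_gene"]]},
        )
        at = hits[hits["offset"] == row["site_offset"]]
        assert len(at) == 1 and at.iloc[0]["penalty"] == 0.0

    def test_injected_sites_all_detected(self, default_dataset):
        truth = default_dataset.truth.mirna_truth
        planted = truth[truth["target_gene"].notna()]
        for _, row in planted.iterrows():
            hits = scan_targets(
                row["mirna_id"],
                row["sequence"],
                {row["target_gene"]: default_dataset.cds_seqs[row["target_gene"]]},
            )
            at = hits[hits["offset"] == row["site_offset"]]
            # wobble-weighted penalty never exceeds the injected mismatch count
            assert len(at) == 1
            assert at.iloc[0]["penalty"] <= row["injected_mismatches"]

    def test_no_spurious_hits_on_random_cds(self):
        rng = np.random.default_rng(55)
        mirna = "".join(rng.choice(list("ACGU"), 21))
        cds = {"bg": "".join(rng.choice(list("ACGT"), 300))}
        assert len(scan_targets("m", mirna, cds)) == 0


def test_truth_rule_membership_consistent_with_predicates(default_dataset):
    """Screening the noise-free truth reproduces planted rule membership."""
    from saltomics.screening import check_rule_predicates

    cands = default_dataset.truth.true_candidates()
    cfg = default_dataset.config
    for rule, n in cfg.n_planted_rule_hits.items():
        # planted hits appear at both time points, plus category-derived members
        assert (cands["rule"] == rule).sum() >= 2 * n
    assert check_rule_predicates(cands).all()


def test_mirna_rpm_filters_have_planted_ineligible_mirnas(default_dataset):
    from saltomics.mirna import call_all_de_mirnas

    res = call_all_de_mirnas(default_dataset.mirna_counts)
    assert (~res["eligible"]).any() and res["eligible"].any()
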