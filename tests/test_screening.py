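"""Stringent screening rules i-v, the protein-only screen and annotation."""

import numpy as np
import pandas as pd
import pytest

from saltomics.config import Thresholds
from saltomics.screening import (
    annotate_candidates,
    apply_rules,
    check_rule_predicates,
    protein_only_screen,
    screen_all,
)


def pairs_frame(rows):
    return pd.DataFrame(
        [
            {"comparison": comp, "gene_id": g, "protein_id": p, "gene_log2fc": gfc,
             "gene_status": gs, "protein_log2ratio": plr, "protein_status": ps,
             "category": cat}
            for comp, g, p, gfc, gs, plr, ps, cat in rows
        ]
    )


def deg_frame(rows):
    return pd.DataFrame(
        [{"gene_id": g, "comparison": c, "log2fc": fc, "status": s} for g, c, fc, s in rows],
        columns=["gene_id", "comparison", "log2fc", "status"],
    )


def dap_frame(rows):
    return pd.DataFrame(
        [
            {"protein_id": p, "gene_id": None, "comparison": c, "mean_ratio": 2.0 ** lr,
             "log2ratio": lr, "p": 0.0, "quantified": True, "status": s}
            for p, c, lr, s in rows
        ],
        columns=["protein_id", "gene_id", "comparison", "mean_ratio", "log2ratio", "p",
                 "quantified", "status"],
    )


class TestRules:
    def _run(self, pairs, deg, dap, **thr):
        return apply_rules(pairs, deg, dap, 4, Thresholds(**thr))

    def test_rule_i_margin(self):
        pairs = pairs_frame([("E4/E0", "g1", "p1", 2.0, "up", 0.0, "ns", "III")])
        deg = deg_frame([("g1", "N4/N0", 1.2, "up")])
        res = self._run(pairs, deg, dap_frame([]))
        assert list(res["rule"]) == ["i"]
        # margin 0.8 >= 0.5; raising the margin beyond it drops the candidate
        res2 = self._run(pairs, deg, dap_frame([]), rule_i_margin=0.9)
        assert "i" not in set(res2["rule"])

    def test_rule_ii_opposite_responses(self):
        pairs = pairs_frame([("E4/E0", "g1", "p1", 1.5, "up", 0.0, "ns", "III")])
        deg = deg_frame([("g1", "N4/N0", -1.5, "down")])
        res = self._run(pairs, deg, dap_frame([]))
        assert list(res["rule"]) == ["ii"]

    def test_rule_iii_tolerant_only(self):
        pairs = pairs_frame([("E4/E0", "g1", "p1", 2.5, "up", 0.0, "ns", "III")])
        deg = deg_frame([("g1", "N4/N0", 0.3, "ns")])
        res = self._run(pairs, deg, dap_frame([]))
        assert list(res["rule"]) == ["iii"]

    def test_rule_iv_common_daps_with_stronger_tolerant_effect(self):
        pairs = pairs_frame([("E4/E0", "g1", "p1", 0.1, "ns", 1.0, "up", "IV")])
        dap = dap_frame([("p1", "N4/N0", 0.4, "up")])
        res = self._run(pairs, deg_frame([]), dap)
        assert list(res["rule"]) == ["iv"]

    def test_rule_v_tolerant_only_dap(self):
        pairs = pairs_frame([("E4/E0", "g1", "p1", 0.1, "ns", 1.0, "up", "IV")])
        dap = dap_frame([("p1", "N4/N0", 0.05, "ns")])
        res = self._run(pairs, deg_frame([]), dap)
        assert list(res["rule"]) == ["v"]

    def test_shared_equal_direction_without_margin_is_not_a_candidate(self):
        pairs = pairs_frame([("E4/E0", "g1", "p1", 2.0, "up", 0.0, "ns", "III")])
        deg = deg_frame([("g1", "N4/N0", 2.0, "up")])
        res = self._run(pairs, deg, dap_frame([]))
        assert len(res) == 0

    def test_margin_monotonicity(self, noise_free_result, noise_free_dataset):
        """Raising the rule-i margin never admits new candidates."""
        pairs = noise_free_result.pairs
        deg = noise_free_result.deg_results
        dap = noise_free_result.dap_results
        prev = None
        for margin in (0.5, 1.0, 2.0, 4.0):
            res = apply_rules(pairs, deg, dap, 4, Thresholds(rule_i_margin=margin))
            ids = set(res["id"])
            if prev is not None:
                assert ids <= prev
            prev = ids


class TestProteinOnly:
    def test_tolerant_only_vi_protein_admitted(self):
        pairs = pairs_frame(
            [("E4/E0", "gx", "p1", np.nan, None, 1.0, "up", "VI"),
             ("E4/E0", "gy", "p2", np.nan, None, 0.9, "up", "VI")]
        )
        dap = dap_frame([("p2", "N4/N0", 0.9, "up")])
        res = protein_only_screen(pairs, dap, 4)
        assert list(res["id"]) == ["p1"]
        assert set(res["rule"]) == {"protein_only"}


class TestAnnotation:
    def test_flags_from_lists(self):
        cands = pd.DataFrame(
            {
                "id": [f"g{i}" for i in range(10)],
                "level": "gene",
                "time": 4,
                "rule": "iii",
                "effect_tolerant": 2.0,
                "effect_sensitive": 0.0,
                "as_flag": False,
                "osmotic_flag": False,
            }
        )
        as_degs = pd.DataFrame(
            {"genotype": "E", "time": 4, "comparison": "E4/E0",
             "gene_id": ["g1", "g3", "g5"], "log2fc": 2.0, "status": "up"}
        )
        out = annotate_candidates(cands, as_degs, {"g1", "g3", "g5"})
        assert out["as_flag"].sum() == 3 and out["osmotic_flag"].sum() == 3

    def test_empty_lists_leave_flags_false(self):
        cands = pd.DataFrame(
            {"id": ["g1"], "level": "gene", "time": 4, "rule": "iii",
             "effect_tolerant": 2.0, "effect_sensitive": 0.0,
             "as_flag": False, "osmotic_flag": False}
        )
        out = annotate_candidates(cands, None, set())
        assert not out["as_flag"].any() and not out["osmotic_flag"].any()


def test_all_records_satisfy_their_rule_predicates(noise_free_result):
    cands = noise_free_result.candidates
    assert len(cands) > 0
    assert check_rule_predicates(cands).all()


def test_every_rule_populated_on_default_synthetic_data(default_result):
    rules = set(default_result.candidates["rule"])
    assert rules == {"i", "ii", "iii", "iv", "v", "protein_only"}
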