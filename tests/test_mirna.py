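"""miRNA filters, DE calls, target scanning and regulatory chains."""

import numpy as np
import pandas as pd
import pytest

from saltomics.config import SAMPLES, Thresholds
from saltomics.mirna import (
    anticorrelated_pairs,
    compute_rpm,
    filter_and_call_de_mirnas,
    protein_level_chains,
    scan_targets,
)

RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rc_rna(seq):
    return "".join(RC[b] for b in reversed(seq))


def counts_frame(rows):
    return pd.DataFrame(rows, columns=SAMPLES, index=[f"m{i}" for i in range(len(rows))])


class TestEligibility:
    def test_rpm_normalisation(self):
        c = counts_frame([[10, 0, 0, 0, 0, 0], [90, 100, 100, 100, 100, 100]])
        rpm = compute_rpm(c)
        assert rpm.iloc[0, 0] == pytest.approx(10 / 100 * 1e6)

    def test_sum_filter_is_strict(self):
        # six-sample RPM sum exactly 60 -> ineligible; 70 -> eligible
        base = counts_frame([[12, 1, 12, 12, 12, 11], [12, 11, 12, 12, 12, 11]])
        # make library totals 1e6 per sample so counts are RPM
        filler = pd.DataFrame(
            [[1e6 - base[s].sum() for s in SAMPLES]], columns=SAMPLES, index=["bulk"]
        )
        counts = pd.concat([base, filler])
        res = filter_and_call_de_mirnas(counts, "E4/E0").set_index("mirna_id")
        assert float(compute_rpm(counts).loc["m0"].sum()) == pytest.approx(60.0)
        assert not res.loc["m0", "eligible"]
        assert res.loc["m1", "eligible"]

    def test_rpm_min_rule_either_vs_both(self):
        rows = [[12, 1, 0, 0, 0, 60]]
        filler = [[1e6 - sum(r[i] for r in rows) for i in range(6)]]
        counts = pd.concat(
            [counts_frame(rows), pd.DataFrame(filler, columns=SAMPLES, index=["bulk"])]
        )
        either = filter_and_call_de_mirnas(counts, "E4/E0").set_index("mirna_id")
        assert either.loc["m0", "eligible"]
        both = filter_and_call_de_mirnas(
            counts, "E4/E0", Thresholds(mirna_rpm_rule="both")
        ).set_index("mirna_id")
        assert not both.loc["m0", "eligible"]

    def test_equal_counts_not_de(self):
        counts = counts_frame([[500, 500, 500, 500, 500, 500]])
        res = filter_and_call_de_mirnas(counts, "N4/N0").set_index("mirna_id")
        assert res.loc["m0", "p"] == 1.0 and res.loc["m0", "status"] == "ns"


class TestScan:
    MIRNA = "UGACCUAGGCUAAGCUAGGCU"  # 21 nt

    @staticmethod
    def _dna(seq):
        return seq.replace("U", "T")

    def test_perfect_complement_site(self):
        site = self._dna(rc_rna(self.MIRNA))
        cds = {"t1": "A" * 40 + site + "C" * 40}
        hits = scan_targets("m", self.MIRNA, cds)
        exact = hits[hits["penalty"] == 0.0]
        assert len(exact) == 1
        assert exact.iloc[0]["offset"] == 41

    def test_three_substitutions_blocked(self):
        site = list(self._dna(rc_rna(self.MIRNA)))
        # three transversion-style substitutions that are full mismatches
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for i in (2, 9, 16):
            site[i] = swap[site[i]]
        cds = {"t1": "A" * 30 + "".join(site) + "C" * 30}
        hits = scan_targets("m", self.MIRNA, cds)
        assert (np.abs(hits["offset"] - 31) > 0).all() or len(hits) == 0

    def test_wobble_scores_half(self):
        # replace a site base so the miRNA G faces a U: penalty 0.5
        mirna = self.MIRNA
        gpos = mirna.index("G")
        site = list(self._dna(rc_rna(mirna)))
        site_pos = len(mirna) - 1 - gpos  # antiparallel pairing position
        assert site[site_pos] == "C"
        site[site_pos] = "T"
        cds = {"t1": "".join(site)}
        hits = scan_targets("m", mirna, cds)
        assert len(hits) == 1 and hits.iloc[0]["penalty"] == 0.5
        # with wobble weight 1.0 the same site scores a full mismatch
        hits_full = scan_targets("m", mirna, cds, Thresholds(wobble_weight=1.0))
        assert hits_full.iloc[0]["penalty"] == 1.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        mirna = "".join(rng.choice(list("ACGU"), 21))
        cds = {
            f"t{i}": "".join(rng.choice(list("ACGT"), 500)) for i in range(10)
        }
        # plant one near-perfect site so the comparison is non-vacuous
        site = list(self._dna(rc_rna(mirna)))
        site[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[5]]
        cds["t0"] = cds["t0"][:100] + "".join(site) + cds["t0"][121:]

        def brute(mirna, seq):
            out = []
            m = len(mirna)
            for off in range(len(seq) - m + 1):
                window = seq[off : off + m]
                pen = 0.0
                for i, mb in enumerate(mirna):
                    tb = window[m - 1 - i].replace("T", "U")
                    pair = mb + tb
                    if pair in ("AU", "UA", "GC", "CG"):
                        continue
                    elif pair in ("GU", "UG"):
                        pen += 0.5
                    else:
                        pen += 1.0
                if pen < 3.0:
                    out.append((off + 1, pen))
            return out

        hits = scan_targets("m", mirna, cds)
        for tid, seq in cds.items():
            expected = brute(mirna, seq)
            got = [
                (int(r["offset"]), float(r["penalty"]))
                for _, r in hits[hits["transcript_id"] == tid].iterrows()
            ]
            assert sorted(got) == sorted(expected)

    def test_bad_character_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            scan_targets("m", self.MIRNA, {"t": "ACXGT" * 10})

    def test_bad_mirna_length(self):
        with pytest.raises(ValueError):
            scan_targets("m", "ACGU", {"t": "ACGT" * 20})


def de_mirna_frame(rows):
    return pd.DataFrame(
        [
            {"mirna_id": m, "comparison": c, "eligible": True, "log2fc": fc, "p": 0.001,
             "status": s}
            for m, c, fc, s in rows
        ]
    )


def hits_frame(pairs):
    return pd.DataFrame(
        [{"mirna_id": m, "transcript_id": t, "offset": 1, "penalty": 0.0} for m, t in pairs]
    )


class TestChains:
    DEG = pd.DataFrame(
        [
            {"gene_id": "gd", "comparison": "E4/E0", "log2fc": -2.0, "status": "down"},
            {"gene_id": "gu", "comparison": "E4/E0", "log2fc": 2.0, "status": "up"},
        ]
    )

    def test_opposite_direction_emits_chain(self):
        de = de_mirna_frame([("m1", "E4/E0", 2.0, "up")])
        chains = anticorrelated_pairs(de, hits_frame([("m1", "gd")]), self.DEG)
        assert len(chains) == 1
        assert chains.iloc[0]["gene_direction"] == "down"

    def test_same_direction_no_chain(self):
        de = de_mirna_frame([("m1", "E4/E0", 2.0, "up")])
        chains = anticorrelated_pairs(de, hits_frame([("m1", "gu")]), self.DEG)
        assert len(chains) == 0

    def test_sensitive_only_mirnas_removed(self):
        de = de_mirna_frame([("m1", "N4/N0", 2.0, "up")])
        chains = anticorrelated_pairs(de, hits_frame([("m1", "gd")]), self.DEG)
        assert len(chains) == 0

    def test_protein_level_chain_requires_category_iv(self):
        de = de_mirna_frame([("m1", "E4/E0", 2.0, "up")])
        pairs = pd.DataFrame(
            [
                {"comparison": "E4/E0", "gene_id": "giv", "protein_id": "p1",
                 "gene_log2fc": 0.1, "gene_status": "ns", "protein_log2ratio": -0.6,
                 "protein_status": "down", "category": "IV"},
                {"comparison": "E4/E0", "gene_id": "gi", "protein_id": "p2",
                 "gene_log2fc": -2.0, "gene_status": "down", "protein_log2ratio": -0.6,
                 "protein_status": "down", "category": "I"},
            ]
        )
        chains = protein_level_chains(de, hits_frame([("m1", "giv"), ("m1", "gi")]), pairs)
        # the category I triple is gene-level territory, not reported here
        assert list(chains["protein_id"]) == ["p1"]
        assert chains.iloc[0]["level"] == "protein"

    def test_every_chain_has_a_sequence_hit(self, noise_free_result):
        res = noise_free_result
        hit_pairs = set(
            map(tuple, res.target_hits[["mirna_id", "transcript_id"]].itertuples(index=False))
        )
        for df in (res.gene_chains, res.protein_chains):
            for _, row in df.iterrows():
                assert (row["mirna_id"], row["gene_id"]) in hit_pairs
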