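"""Clumping hand-traces, replication rules and instrument selection."""

import numpy as np
import pandas as pd
import pytest

from protmr.instruments import LDSource, ld_clump, replicate_leads, select_instruments


def stats_frame(rows):
    df = pd.DataFrame(rows)
    df["chrom"] = df.get("chrom", 1)
    df["a1"], df["a0"] = "A", "G"
    df["trait_id"] = "P"
    for col, default in (("n", 900), ("freq1", 0.3), ("info", 1.0), ("beta1", 0.1), ("se", 0.01)):
        if col not in df:
            df[col] = default
    return df


def ld_from_pairs(ids, pairs):
    r = np.eye(len(ids))
    idx = {v: i for i, v in enumerate(ids)}
    for a, b, val in pairs:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = val
    return LDSource(r, ids)


class TestClump:
    def test_single_significant_snp_is_its_own_lead(self):
        df = stats_frame([{"rsid": "A", "pos": 100, "p": 1e-10}])
        clumps = ld_clump(df, ld_from_pairs(["A"], []))
        assert len(clumps) == 1 and clumps[0].lead["rsid"] == "A"
        assert clumps[0].members == ["A"]

    def test_hand_trace_three_snps(self):
        # A absorbs B (200 kb, r2=0.5); C is 8 Mb away so outside the +/-5 Mb
        # window regardless of its r2 and founds its own clump
        df = stats_frame(
            [
                {"rsid": "A", "pos": 1_000_000, "p": 1e-12},
                {"rsid": "B", "pos": 1_200_000, "p": 1e-9},
                {"rsid": "C", "pos": 9_000_000, "p": 1e-8},
            ]
        )
        ld = ld_from_pairs(
            ["A", "B", "C"], [("A", "B", np.sqrt(0.5)), ("A", "C", np.sqrt(0.9))]
        )
        clumps = ld_clump(df, ld)
        got = {c.lead["rsid"]: sorted(c.members) for c in clumps}
        assert got == {"A": ["A", "B"], "C": ["C"]}

    def test_hand_trace_low_r2_partner_is_independent_lead(self):
        df = stats_frame(
            [
                {"rsid": "A", "pos": 1_000_000, "p": 1e-12},
                {"rsid": "B", "pos": 1_200_000, "p": 1e-9},
                {"rsid": "C", "pos": 9_000_000, "p": 1e-8},
            ]
        )
        ld = ld_from_pairs(["A", "B", "C"], [("A", "B", np.sqrt(0.1))])
        clumps = ld_clump(df, ld)
        got = {c.lead["rsid"] for c in clumps}
        assert got == {"A", "B", "C"}  # r2 = 0.1 <= 0.2: B not absorbed

    def test_nonsignificant_variants_absorbed_but_never_lead(self):
        df = stats_frame(
            [
                {"rsid": "A", "pos": 100, "p": 1e-9},
                {"rsid": "B", "pos": 200, "p": 0.5},
            ]
        )
        clumps = ld_clump(df, ld_from_pairs(["A", "B"], [("A", "B", 0.9)]))
        assert len(clumps) == 1 and sorted(clumps[0].members) == ["A", "B"]

    def test_significant_variants_form_a_partition(self):
        rng = np.random.default_rng(0)
        m = 60
        ids = [f"v{i}" for i in range(m)]
        df = stats_frame(
            [{"rsid": ids[i], "pos": 1000 * i, "p": rng.uniform(1e-12, 1e-4)} for i in range(m)]
        )
        r = np.linalg.qr(rng.normal(size=(m, m)))[0]
        r = r @ r.T  # orthonormal -> identity; perturb with structure instead
        r = 0.5 * np.eye(m) + 0.5 * np.ones((m, m)) * 0.3
        np.fill_diagonal(r, 1.0)
        clumps = ld_clump(df, LDSource(r, ids), p_max=1e-6)
        sig = set(df.loc[df["p"] <= 1e-6, "rsid"])
        seen = [v for c in clumps for v in c.members if v in sig]
        assert sorted(seen) == sorted(sig)  # each significant variant exactly once

    def test_missing_ld_variant_treated_as_zero(self, caplog):
        df = stats_frame(
            [
                {"rsid": "A", "pos": 100, "p": 1e-10},
                {"rsid": "X", "pos": 200, "p": 1e-9},
            ]
        )
        clumps = ld_clump(df, ld_from_pairs(["A"], []))
        assert {c.lead["rsid"] for c in clumps} == {"A", "X"}


class TestReplication:
    def test_bonferroni_threshold_over_209_leads(self):
        leads = stats_frame(
            [{"rsid": f"v{i}", "pos": i, "p": 1e-10} for i in range(209)]
        )
        rep = leads.copy()
        rep["p"] = 1e-5
        out = replicate_leads(leads, rep)
        assert np.isclose(out["replication_threshold"].iloc[0], 0.05 / 209)
        assert out["replicated"].all()  # 1e-5 < 2.39e-4, same sign

    def test_opposite_sign_not_replicated(self):
        leads = stats_frame([{"rsid": "A", "pos": 1, "p": 1e-10, "beta1": 0.5}])
        rep = stats_frame([{"rsid": "A", "pos": 1, "p": 1e-6, "beta1": -0.5}])
        out = replicate_leads(leads, rep)
        assert not out["replicated"].iloc[0]

    def test_missing_lead_flagged_unreplicable(self):
        leads = stats_frame([{"rsid": "A", "pos": 1, "p": 1e-10}])
        rep = stats_frame([{"rsid": "B", "pos": 2, "p": 1e-10}])
        out = replicate_leads(leads, rep)
        assert out["unreplicable"].iloc[0] and not out["replicated"].iloc[0]

    def test_empty_leads_no_division_error(self):
        leads = stats_frame([{"rsid": "A", "pos": 1, "p": 1e-10}]).iloc[:0]
        out = replicate_leads(leads, stats_frame([{"rsid": "A", "pos": 1, "p": 1.0}]))
        assert len(out) == 0


def _leads_with_rep(rows):
    df = stats_frame(rows)
    df["beta1_rep"] = df["beta1"]
    df["se_rep"] = df["se"]
    df["p_rep"] = df["p"]
    df["freq1_rep"] = df["freq1"]
    df["info_rep"] = df["info"]
    df["n_rep"] = df["n"]
    df["replicated"] = df.pop("replicated_flag") if "replicated_flag" in df else True
    return df


GENES = pd.DataFrame(
    [{"protein_id": "P", "gene_id": "ENSG1", "chrom": 1, "start": 1_000_000, "end": 1_050_000}]
)


class TestSelection:
    def test_distal_lead_yields_no_instrument(self):
        leads = _leads_with_rep([{"rsid": "A", "pos": 5_000_000, "p": 1e-10}])
        out = select_instruments(leads, GENES)
        assert len(out) == 0

    def test_lowest_discovery_p_wins(self):
        leads = _leads_with_rep(
            [
                {"rsid": "A", "pos": 1_010_000, "p": 1e-20},
                {"rsid": "B", "pos": 1_020_000, "p": 1e-9},
            ]
        )
        out = select_instruments(leads, GENES)
        primary = out[out["is_primary"]]
        assert list(primary["rsid"]) == ["A"]
        # the second qualifying independent lead is retained for sensitivity MR
        assert set(out["rsid"]) == {"A", "B"}

    def test_flank_boundary_inclusive(self):
        leads = _leads_with_rep(
            [
                {"rsid": "edge", "pos": 1_050_000 + 150_000, "p": 1e-10},
                {"rsid": "beyond", "pos": 1_050_000 + 150_001, "p": 1e-12},
            ]
        )
        out = select_instruments(leads, GENES)
        assert list(out["rsid"]) == ["edge"]

    def test_maf_and_info_filters_apply_to_both_cohorts(self):
        rows = [{"rsid": "A", "pos": 1_010_000, "p": 1e-10}]
        leads = _leads_with_rep(rows)
        leads.loc[0, "freq1_rep"] = 0.005  # rare in replication only
        assert len(select_instruments(leads, GENES)) == 0
        leads = _leads_with_rep(rows)
        leads.loc[0, "info"] = 0.9  # poorly imputed in discovery only
        assert len(select_instruments(leads, GENES)) == 0

    def test_unmapped_protein_skipped(self):
        leads = _leads_with_rep([{"rsid": "A", "pos": 1_010_000, "p": 1e-10}])
        out = select_instruments(leads, GENES[GENES["protein_id"] != "P"])
        assert len(out) == 0

    def test_locality_ignores_allele_labels(self):
        leads = _leads_with_rep([{"rsid": "A", "pos": 1_010_000, "p": 1e-10}])
        flipped = leads.copy()
        flipped["a1"], flipped["a0"] = leads["a0"], leads["a1"]
        assert select_instruments(leads, GENES)["is_local"].equals(
            select_instruments(flipped, GENES)["is_local"]
        )
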