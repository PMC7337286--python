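"""Schema IO round-trips, screen counting and supplement re-verification logic.

All supplementary-style fixtures here are synthetic stand-ins built in code;
they exercise the schemas and the counting/recomputation rules, not the
original study's values.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protmr.io import read_dosage_vcf, write_dosage_vcf
from protmr.mr import bh_fdr, mr_delta
from protmr.tables import (
    count_replicated_from_s1,
    read_supp_table,
    recompute_screen_from_s6,
    screen_report,
    verify_p_consistency,
    write_supp_table,
)


def synthetic_s7(n=6, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "snpid": [f"1_{1000 + i}" for i in range(n)],
            "exposure": [f"Q{i:05d}" for i in range(n)],
            "hgnc_symbol": [f"GENE{i}" for i in range(n)],
            "outcome": [f"T{i}" for i in range(n)],
            "outcome_description": "trait",
            "p_HEIDI": rng.uniform(0.001, 1.0, n).round(4),
            "nsnp_HEIDI": rng.integers(3, 21, n),
            "CLPP": rng.uniform(0, 1, n).round(4),
        }
    )


def synthetic_s6(n=40, seed=1):
    """Internally consistent external-study MR table built from the estimator."""
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.5, 0.1, n)
    sx = np.full(n, 0.04)
    by = np.where(rng.uniform(size=n) < 0.3, rng.normal(0.15, 0.02, n), rng.normal(0, 0.01, n))
    sy = np.full(n, 0.012)
    b, s, p = mr_delta(bx, sx, by, sy)
    q, sig = bh_fdr(p)
    return pd.DataFrame(
        {
            "hgnc_symbol": [f"G{i}" for i in range(n)],
            "trait": "trait", "snp": [f"chr1:{i}" for i in range(n)],
            "rsid": [f"rs{i}" for i in range(n)], "chr": 1, "pos": np.arange(n) + 1000,
            "a1": "A", "a0": "G", "exposure": [f"Q{i}" for i in range(n)],
            "n_exposure_pri": 900, "freq1_exposure_pri": 0.3,
            "beta1_exposure_pri": bx, "se_exposure_pri": sx,
            "p_exposure_pri": 2 * stats.norm.sf(np.abs(bx / sx)),
            "info_exposure_pri": 1.0,
            "n_exposure_sec": 1000, "freq1_exposure_sec": 0.3,
            "beta1_exposure_sec": bx, "se_exposure_sec": sx,
            "p_exposure_sec": 2 * stats.norm.sf(np.abs(bx / sx)),
            "info_exposure_sec": 1.0,
            "ensembl_gene_id": "ENSG0", "study": "meta", "pmid": 1, "ancestry": "EUR",
            "year": 2018, "beta1_outcome": by, "se_outcome": sy,
            "p_outcome": 2 * stats.norm.sf(np.abs(by / sy)),
            "n_outcome": 100000, "n_cases_outcome": 20000, "n_controls_outcome": 80000,
            "n_studies_meta_outcome": 5, "units_outcome": "log(OR)", "dataset": "d1",
            "beta1_outcome_flipped": False,
            "beta_mr_delta_sec": b, "se_mr_delta_sec": s, "p_mr_delta_sec": p,
            "fdr_sig_mr_delta_sec": sig,
        }
    )


class TestSchemaIO:
    def test_s7_round_trip(self, tmp_path):
        df = synthetic_s7()
        path = tmp_path / "s7.tsv"
        write_supp_table(df, path, "s007")
        back = read_supp_table(path, "s007")
        assert len(back) == len(df)
        assert np.allclose(back["p_HEIDI"], df["p_HEIDI"])

    def test_boolean_flags_round_trip(self, tmp_path):
        df = synthetic_s6(8)
        path = tmp_path / "s6.tsv"
        write_supp_table(df, path, "s006")
        back = read_supp_table(path, "s006")
        assert back["fdr_sig_mr_delta_sec"].tolist() == df["fdr_sig_mr_delta_sec"].tolist()

    def test_missing_schema_column_named(self, tmp_path):
        df = synthetic_s7().drop(columns=["CLPP"])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="CLPP"):
            read_supp_table(path, "s007")

    def test_unparseable_boolean_cell_located(self, tmp_path):
        df = synthetic_s6(3)
        df["fdr_sig_mr_delta_sec"] = ["TRUE", "maybe", "FALSE"]
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="row 1"):
            read_supp_table(path, "s006")

    def test_out_of_range_p_rejected(self, tmp_path):
        df = synthetic_s7(3)
        df.loc[1, "p_HEIDI"] = 1.5
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="p_HEIDI"):
            read_supp_table(path, "s007")


class TestScreenReport:
    def _inputs(self):
        mr = pd.DataFrame(
            {
                "protein_id": ["a", "b", "c", "d"],
                "outcome_id": ["x"] * 4,
                "source_group": ["g"] * 4,
                "significant": [True, True, True, False],
            }
        )
        heidi = pd.DataFrame(
            {"protein_id": ["a", "b", "c"], "outcome_id": ["x"] * 3,
             "p_heidi": [0.5, 0.01, 0.2]}
        )
        clpp = pd.DataFrame(
            {"protein_id": ["a", "b", "c"], "outcome_id": ["x"] * 3,
             "clpp": [0.5, 0.2, 0.001]}
        )
        return mr, heidi, clpp

    def test_counts_and_intersection(self):
        mr, heidi, clpp = self._inputs()
        rep = screen_report(mr, heidi, clpp, heidi_n_tests=3)
        assert rep["n_significant"] == {"g": 3}
        assert rep["n_heidi_nominal"] == 2  # a, c
        assert rep["n_clpp"] == 2  # a, b
        assert rep["intersect"] == {("a", "x")}

    def test_disjoint_survivor_sets_intersect_zero(self):
        mr, heidi, clpp = self._inputs()
        heidi["p_heidi"] = [0.5, 0.001, 0.001]  # survivor: a
        clpp["clpp"] = [0.001, 0.5, 0.5]  # survivors: b, c
        assert screen_report(mr, heidi, clpp)["n_intersect"] == 0

    def test_duplicate_keys_rejected(self):
        mr, heidi, clpp = self._inputs()
        heidi = pd.concat([heidi, heidi.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            screen_report(mr, heidi, clpp)

    def test_row_order_invariance(self):
        mr, heidi, clpp = self._inputs()
        a = screen_report(mr, heidi, clpp, heidi_n_tests=3)
        b = screen_report(
            mr.sample(frac=1, random_state=1),
            heidi.sample(frac=1, random_state=2),
            clpp.sample(frac=1, random_state=3),
            heidi_n_tests=3,
        )
        assert {k: v for k, v in a.items() if k.startswith("n_")} == {
            k: v for k, v in b.items() if k.startswith("n_")
        }


class TestRecomputeS6:
    def test_self_consistent_table_has_no_mismatches(self):
        s6 = synthetic_s6(60)
        out = recompute_screen_from_s6(s6)
        assert out["n_value_mismatches"] == 0
        assert out["n_flag_mismatches"] == 0
        assert out["n_significant"] == int(s6["fdr_sig_mr_delta_sec"].sum())

    def test_hand_example_row_recomputed(self):
        s6 = synthetic_s6(1)
        s6.loc[0, ["beta1_exposure_sec", "se_exposure_sec", "beta1_outcome", "se_outcome"]] = (
            0.5, 0.05, 0.2, 0.05
        )
        out = recompute_screen_from_s6(s6)
        assert np.isclose(out["results"]["beta_mr_recomputed"].iloc[0], 0.404)
        assert np.isclose(out["results"]["se_mr_recomputed"].iloc[0], np.sqrt(0.0116))

    def test_zero_exposure_beta_excluded_with_reason(self):
        s6 = synthetic_s6(5)
        s6.loc[2, "beta1_exposure_sec"] = 0.0
        out = recompute_screen_from_s6(s6)
        assert len(out["excluded"]) == 1 and len(out["results"]) == 4

    def test_tampered_value_detected(self):
        s6 = synthetic_s6(10)
        s6.loc[3, "beta_mr_delta_sec"] *= 1.5
        out = recompute_screen_from_s6(s6)
        assert out["n_value_mismatches"] == 1


class TestS1Counting:
    def _s1(self):
        n = 10
        df = pd.DataFrame(
            {
                "hgnc_symbol": [f"G{i // 2}" for i in range(n)],  # two leads per protein
                "p_pri": [1e-10] * 8 + [1e-4] * 2,  # 8 significant discovery leads
                "p_sec": [1e-6] * 6 + [0.5] * 2 + [1e-6] * 2,
                "beta1_pri": 0.5,
                "beta1_sec": [0.5] * 5 + [-0.5] + [0.5] * 4,
                "chr": 1, "chromosome_name": 1,
                "pos": 1_000_000,
                "start_position": [990_000] * 6 + [5_000_000] * 4,
                "end_position": [1_010_000] * 6 + [5_020_000] * 4,
            }
        )
        return df

    def test_bonferroni_sign_and_local_counts(self):
        out = count_replicated_from_s1(self._s1())
        # 8 discovery leads -> threshold 0.05/8; rows 0-5 pass p_sec, row 5 flips sign
        assert out["n_discovery_leads"] == 8
        assert out["n_replicated"] == 5
        # replicated & local rows 0-4 cover proteins G0, G1, G2
        assert out["n_local_proteins"] == 3

    def test_empty_discovery(self):
        s1 = self._s1()
        s1["p_pri"] = 0.5
        assert count_replicated_from_s1(s1)["n_replicated"] == 0


class TestVCF:
    def test_dosage_round_trip(self, tmp_path):
        from conftest import make_variants

        rng = np.random.default_rng(0)
        dos = rng.uniform(0, 2, size=(5, 4)).round(3)
        var = make_variants(4)
        path = tmp_path / "geno.vcf"
        write_dosage_vcf(dos, var, path, seed=42)
        back_dos, back_var = read_dosage_vcf(path)
        assert np.allclose(back_dos, dos)
        assert list(back_var["rsid"]) == list(var["rsid"])
        assert "simulation_seed=42" in path.read_text()


def test_p_consistency_checker():
    df = pd.DataFrame({"b": [0.2, 0.3], "s": [0.05, 0.05]})
    df["p"] = 2 * stats.norm.sf(np.abs(df["b"] / df["s"]))
    assert verify_p_consistency(df, "b", "s", "p") == 0
    df.loc[0, "p"] *= 3
    assert verify_p_consistency(df, "b", "s", "p") == 1
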