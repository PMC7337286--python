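"""Supplementary-table schemas, screen-level counting, and re-verification.

Table ids follow the source study's supplement numbering: ``s001`` (clumped
pQTL leads with replication flags), ``s005`` (biobank-atlas MR results),
``s006`` (external meta-analysis MR results, all rows), ``s007`` (HEIDI and
colocalization results for the significant biobank pairs).  Readers validate
the full column vocabulary and types; extra columns are preserved verbatim.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mr import bh_fdr, mr_delta

__all__ = [
    "SCHEMAS",
    "read_supp_table",
    "write_supp_table",
    "screen_report",
    "recompute_screen_from_s6",
    "count_replicated_from_s1",
    "verify_p_consistency",
]

_S1_COLUMNS = [
    "hgnc_symbol", "snpid", "rsid", "chr", "pos", "a1", "a0",
    "n_pri", "freq1_pri", "beta1_pri", "se_pri", "p_pri", "info_pri", "r2_pri",
    "n_sec", "freq1_sec", "beta1_sec", "se_sec", "p_sec", "info_sec", "r2_sec",
    "uniprot_swissprot", "ensembl_gene_id", "chromosome_name",
    "start_position", "end_position", "description",
    "replicated_pqtl", "within_gene_plus_flank_tol",
]
_S5_COLUMNS = [
    "hgnc_symbol", "outcome_description", "rsid", "snpid", "chr", "pos", "a1", "a0",
    "exposure", "ensembl_gene_id",
    "n_exposure_pri", "freq1_exposure_pri", "beta1_exposure_pri",
    "se_exposure_pri", "p_exposure_pri", "info_exposure_pri",
    "n_exposure_sec", "freq1_exposure_sec", "beta1_exposure_sec",
    "se_exposure_sec", "p_exposure_sec", "info_exposure_sec",
    "outcome", "beta1_outcome", "se_outcome", "p_outcome",
    "info_outcome", "freq1_outcome",
    "beta_mr_delta_sec", "se_mr_delta_sec", "p_mr_delta_sec", "fdr_sig_mr_delta_sec",
]
_S6_COLUMNS = [
    "hgnc_symbol", "trait", "snp", "rsid", "chr", "pos", "a1", "a0", "exposure",
    "n_exposure_pri", "freq1_exposure_pri", "beta1_exposure_pri",
    "se_exposure_pri", "p_exposure_pri", "info_exposure_pri",
    "n_exposure_sec", "freq1_exposure_sec", "beta1_exposure_sec",
    "se_exposure_sec", "p_exposure_sec", "info_exposure_sec",
    "ensembl_gene_id", "study", "pmid", "ancestry", "year",
    "beta1_outcome", "se_outcome", "p_outcome",
    "n_outcome", "n_cases_outcome", "n_controls_outcome",
    "n_studies_meta_outcome", "units_outcome", "dataset", "beta1_outcome_flipped",
    "beta_mr_delta_sec", "se_mr_delta_sec", "p_mr_delta_sec", "fdr_sig_mr_delta_sec",
]
_S7_COLUMNS = [
    "snpid", "exposure", "hgnc_symbol", "outcome", "outcome_description",
    "p_HEIDI", "nsnp_HEIDI", "CLPP",
]

SCHEMAS: dict[str, dict] = {
    "s001": {
        "columns": _S1_COLUMNS,
        "p_cols": ["p_pri", "p_sec"],
        "bool_cols": ["replicated_pqtl", "within_gene_plus_flank_tol"],
    },
    "s005": {
        "columns": _S5_COLUMNS,
        "p_cols": ["p_exposure_pri", "p_exposure_sec", "p_outcome", "p_mr_delta_sec"],
        "bool_cols": ["fdr_sig_mr_delta_sec"],
    },
    "s006": {
        "columns": _S6_COLUMNS,
        "p_cols": ["p_exposure_pri", "p_exposure_sec", "p_outcome", "p_mr_delta_sec"],
        "bool_cols": ["beta1_outcome_flipped", "fdr_sig_mr_delta_sec"],
    },
    "s007": {
        "columns": _S7_COLUMNS,
        "p_cols": ["p_HEIDI"],
        "bool_cols": [],
    },
}

_TRUE_TOKENS = {"TRUE", "True", "true", "T", "1"}
_FALSE_TOKENS = {"FALSE", "False", "false", "F", "0"}


def _parse_bool(series: pd.Series, col: str) -> pd.Series:
    out = []
    for i, v in enumerate(series):
        s = str(v).strip()
        if s in _TRUE_TOKENS:
            out.append(True)
        elif s in _FALSE_TOKENS:
            out.append(False)
        else:
            raise ValueError(f"unparseable boolean {v!r} at row {i}, column {col!r}")
    return pd.Series(out, index=series.index)


def read_supp_table(path, table_id: str) -> pd.DataFrame:
    """Read and validate a supplementary-schema TSV."""
    if table_id not in SCHEMAS:
        raise ValueError(f"unknown table id {table_id!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[table_id]
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"table {table_id} is missing schema columns: {missing}")
    for col in df.columns:
        if col in schema["bool_cols"]:
            df[col] = _parse_bool(df[col], col)
        else:
            converted = pd.to_numeric(df[col], errors="coerce")
            # keep text columns as text; numeric columns must convert cleanly
            if converted.notna().sum() >= df[col].notna().sum() and df[col].notna().any():
                if converted.isna().sum() == df[col].isna().sum():
                    df[col] = converted
    for col in schema["p_cols"]:
        p = pd.to_numeric(df[col], errors="coerce")
        bad = p.notna() & ((p <= 0) | (p > 1))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"p-value out of (0,1] at row {i}, column {col!r}: {p.iloc[i]}"
            )
        df[col] = p
    return df


def write_supp_table(df: pd.DataFrame, path, table_id: str) -> None:
    """Write a supplementary-schema TSV (booleans serialized TRUE/FALSE)."""
    schema = SCHEMAS[table_id]
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"table {table_id} is missing schema columns: {missing}")
    out = df.copy()
    for col in schema["bool_cols"]:
        out[col] = out[col].map({True: "TRUE", False: "FALSE"})
    out.to_csv(path, sep="\t", index=False)


def _keyset(df: pd.DataFrame) -> set:
    keys = list(zip(df["protein_id"], df["outcome_id"]))
    if len(keys) != len(set(keys)):
        dup = pd.Series(keys).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise ValueError(f"duplicate (protein_id, outcome_id) keys: {dup}")
    return set(keys)


def screen_report(
    mr_results: pd.DataFrame,
    heidi_results: pd.DataFrame,
    clpp_results: pd.DataFrame,
    heidi_alpha: float = 0.05,
    clpp_threshold: float = 0.01,
    heidi_n_tests: int | None = None,
) -> dict:
    """Step-3 summary counts over the screen, keyed by (protein_id, outcome_id).

    Returns significant counts per source group, HEIDI nominal/Bonferroni
    survivor counts, the colocalization survivor count, the intersection of
    nominal-HEIDI and colocalization survivors, and the underlying key sets.
    Counts are set-based, hence invariant to row order.
    """
    n_sig_per_source = {
        str(src): int(grp["significant"].sum())
        for src, grp in mr_results.groupby("source_group")
    }
    _keyset(heidi_results)
    _keyset(clpp_results)

    p = pd.to_numeric(heidi_results["p_heidi"], errors="coerce")
    n_tests = heidi_n_tests if heidi_n_tests is not None else max(int(p.notna().sum()), 1)
    heidi_nominal = set(
        zip(
            heidi_results.loc[p > heidi_alpha, "protein_id"],
            heidi_results.loc[p > heidi_alpha, "outcome_id"],
        )
    )
    bonf = p > heidi_alpha / n_tests
    clpp_vals = pd.to_numeric(clpp_results["clpp"], errors="coerce")
    clpp_surv = set(
        zip(
            clpp_results.loc[clpp_vals > clpp_threshold, "protein_id"],
            clpp_results.loc[clpp_vals > clpp_threshold, "outcome_id"],
        )
    )
    return {
        "n_significant": n_sig_per_source,
        "n_heidi_nominal": len(heidi_nominal),
        "n_heidi_bonferroni": int(bonf.sum()),
        "n_clpp": len(clpp_surv),
        "n_intersect": len(heidi_nominal & clpp_surv),
        "heidi_survivors": heidi_nominal,
        "clpp_survivors": clpp_surv,
        "intersect": heidi_nominal & clpp_surv,
    }


def _match_sigfigs(a: float, b: float, sig: int = 4) -> bool:
    if not (np.isfinite(a) and np.isfinite(b)):
        return False
    if a == b:
        return True
    scale = max(abs(a), abs(b))
    if scale == 0:
        return True
    return abs(a - b) <= scale * 10.0 ** (1 - sig) * 0.5 * 10


def recompute_screen_from_s6(s6: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Re-derive the delta-method MR columns and FDR flags of an s006 table.

    Recomputes beta/se/p from the four summary-statistic columns row by row,
    re-runs Benjamini-Hochberg across all rows, and reports the number of
    rows whose stored values disagree beyond 4 significant figures.
    """
    usable = s6["beta1_exposure_sec"] != 0
    excluded = s6.loc[~usable].copy()
    df = s6.loc[usable].copy()
    b, s, p = mr_delta(
        df["beta1_exposure_sec"].to_numpy(),
        df["se_exposure_sec"].to_numpy(),
        df["beta1_outcome"].to_numpy(),
        df["se_outcome"].to_numpy(),
    )
    q, sig = bh_fdr(np.clip(p, np.finfo(float).tiny, 1.0), alpha=alpha)
    df["beta_mr_recomputed"] = b
    df["se_mr_recomputed"] = s
    df["p_mr_recomputed"] = p
    df["fdr_q_recomputed"] = q
    df["fdr_sig_recomputed"] = sig

    mismatch = 0
    for stored_col, new in (
        ("beta_mr_delta_sec", b),
        ("se_mr_delta_sec", s),
        ("p_mr_delta_sec", p),
    ):
        stored = pd.to_numeric(df[stored_col], errors="coerce").to_numpy()
        mismatch += int(
            sum(not _match_sigfigs(x, y) for x, y in zip(stored, new))
        )
    flag_mismatch = int((df["fdr_sig_mr_delta_sec"].astype(bool) != sig).sum())
    return {
        "results": df,
        "excluded": excluded,
        "n_significant": int(sig.sum()),
        "n_value_mismatches": mismatch,
        "n_flag_mismatches": flag_mismatch,
    }


def count_replicated_from_s1(
    s1: pd.DataFrame,
    p_discovery_max: float = 5e-8,
    alpha: float = 0.05,
    flank_bp: int = 150_000,
) -> dict:
    """Replication counting over an s001-style lead table.

    Applies the discovery significance threshold, the Bonferroni replication
    rule over the number of significant discovery leads, and the
    direction-of-effect requirement; counts replicated leads and the proteins
    with a replicated lead within the gene +/- ``flank_bp`` window.
    """
    disc = s1[pd.to_numeric(s1["p_pri"]) < p_discovery_max].copy()
    n_leads = len(disc)
    if n_leads == 0:
        return {"n_discovery_leads": 0, "n_replicated": 0, "n_local_proteins": 0,
                "threshold": np.nan}
    thr = alpha / n_leads
    rep = (
        (pd.to_numeric(disc["p_sec"]) < thr)
        & (np.sign(pd.to_numeric(disc["beta1_sec"])) == np.sign(pd.to_numeric(disc["beta1_pri"])))
    )
    local = (
        (disc["chr"] == disc["chromosome_name"])
        & (pd.to_numeric(disc["pos"]) >= pd.to_numeric(disc["start_position"]) - flank_bp)
        & (pd.to_numeric(disc["pos"]) <= pd.to_numeric(disc["end_position"]) + flank_bp)
    )
    n_local_proteins = disc.loc[rep & local, "hgnc_symbol"].nunique()
    return {
        "n_discovery_leads": n_leads,
        "n_replicated": int(rep.sum()),
        "n_local_proteins": int(n_local_proteins),
        "threshold": thr,
    }


def verify_p_consistency(
    df: pd.DataFrame, beta_col: str, se_col: str, p_col: str, sig: int = 4
) -> int:
    """Number of rows whose stored p disagrees (beyond ``sig`` significant
    figures) with the two-sided normal p recomputed from beta and se."""
    from scipy import stats

    b = pd.to_numeric(df[beta_col]).to_numpy()
    s = pd.to_numeric(df[se_col]).to_numpy()
    p = pd.to_numeric(df[p_col]).to_numpy()
    p_new = 2.0 * stats.norm.sf(np.abs(b / s))
    return int(sum(not _match_sigfigs(x, y, sig) for x, y in zip(p, p_new)))
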