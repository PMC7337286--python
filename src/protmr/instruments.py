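"""LD clumping, discovery/replication logic and instrument selection.

Clumping follows PLINK semantics: only genome-wide-significant variants may
found a clump, but any unassigned biallelic variant within the physical window
and above the r-squared floor is absorbed, so leads are mutually un-clumpable.
Replication applies a Bonferroni correction over the number of significant
discovery leads and requires a consistent direction of effect.  An instrument
for a protein is the replicated local lead (within +/-150 kb of the encoding
gene) with the lowest discovery p-value that passes MAF and imputation-info
filters in both cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["LDSource", "ClumpedLocus", "ld_clump", "replicate_leads", "select_instruments"]


class LDSource:
    """r-squared lookups over a signed correlation matrix keyed by variant id.

    A missing variant pair is treated as r2=0 with a logged warning (the
    paper's LD reference also lacked some variants); set ``strict=True`` to
    hard-error instead.
    """

    def __init__(self, r: np.ndarray, ids: list[str], strict: bool = False):
        self.r = np.asarray(r, dtype=float)
        self.idx = {v: i for i, v in enumerate(ids)}
        self.strict = strict
        self._warned: set[str] = set()

    def r2(self, id_a: str, id_b: str) -> float:
        ia, ib = self.idx.get(id_a), self.idx.get(id_b)
        if ia is None or ib is None:
            missing = id_a if ia is None else id_b
            if self.strict:
                raise KeyError(f"variant {missing} absent from LD source")
            if missing not in self._warned:
                logger.warning("variant %s absent from LD source; treating r2 as 0", missing)
                self._warned.add(missing)
            return 0.0
        return float(self.r[ia, ib] ** 2)


@dataclass
class ClumpedLocus:
    lead: pd.Series
    members: list[str] = field(default_factory=list)
    protein_id: str | None = None


def _order_candidates(stats: pd.DataFrame) -> pd.DataFrame:
    # deterministic tie-break: p, then position, then rsid
    return stats.sort_values(["p", "pos", "rsid"], kind="mergesort")


def ld_clump(
    stats: pd.DataFrame,
    ld: LDSource,
    window_bp: int = 5_000_000,
    r2_min: float = 0.2,
    p_max: float = 5e-8,
) -> list[ClumpedLocus]:
    """Greedy LD clumping of an association scan.

    Repeatedly takes the smallest-p unassigned variant with p <= ``p_max`` as a
    lead and absorbs every unassigned variant on the same chromosome within
    ``window_bp`` of it with r2 > ``r2_min``.  Window and r2 floor default to
    the +/-5 Mb, r2 > 0.2 clumping rule.
    """
    df = stats.dropna(subset=["p"]).reset_index(drop=True)
    protein = df["trait_id"].iloc[0] if "trait_id" in df and len(df) else None
    rsid = df["rsid"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    assigned = np.zeros(len(df), dtype=bool)
    clumps: list[ClumpedLocus] = []
    candidates = _order_candidates(df[df["p"] <= p_max])
    for lead_idx in candidates.index:
        if assigned[lead_idx]:
            continue
        lead = df.loc[lead_idx]
        in_window = (
            (chrom == lead["chrom"])
            & (np.abs(pos - lead["pos"]) <= window_bp)
            & ~assigned
        )
        members = [lead["rsid"]]
        assigned[lead_idx] = True
        for j in np.flatnonzero(in_window):
            if j == lead_idx:
                continue
            if ld.r2(lead["rsid"], rsid[j]) > r2_min:
                members.append(rsid[j])
                assigned[j] = True
        clumps.append(ClumpedLocus(lead=lead, members=members, protein_id=protein))
    return clumps


def replicate_leads(
    discovery_leads: pd.DataFrame,
    replication_stats: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Annotate discovery leads with Bonferroni-corrected replication flags.

    ``replicated`` is True when the replication p-value is below
    ``alpha / n_discovery_leads`` *and* the direction of effect agrees.  Leads
    absent from the replication scan are flagged unreplicable (not replicated).
    Keys are (trait_id, rsid) so the correction is per protein screen-wide.
    """
    out = discovery_leads.copy()
    n_leads = len(out)
    if n_leads == 0:
        out["replicated"] = pd.Series(dtype=bool)
        out["replication_threshold"] = pd.Series(dtype=float)
        return out
    threshold = alpha / n_leads

    rep = replication_stats.set_index(["trait_id", "rsid"]) if "trait_id" in replication_stats else replication_stats.set_index("rsid")
    rep_cols = ["n", "freq1", "beta1", "se", "p", "info"]
    flags, rows = [], []
    for _, lead in out.iterrows():
        key = (lead["trait_id"], lead["rsid"]) if "trait_id" in replication_stats else lead["rsid"]
        if key not in rep.index:
            flags.append(False)
            rows.append({f"{c}_rep": np.nan for c in rep_cols} | {"unreplicable": True})
            continue
        r = rep.loc[key]
        ok = (r["p"] < threshold) and (np.sign(r["beta1"]) == np.sign(lead["beta1"]))
        flags.append(bool(ok))
        rows.append({f"{c}_rep": r[c] for c in rep_cols} | {"unreplicable": False})
    out = pd.concat([out.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    out["replicated"] = flags
    out["replication_threshold"] = threshold
    return out


def select_instruments(
    leads: pd.DataFrame,
    gene_table: pd.DataFrame,
    maf_min: float = 0.01,
    info_min: float = 0.95,
    flank_bp: int = 150_000,
) -> pd.DataFrame:
    """Select instrumental variables from replicated leads.

    Per protein, among replicated leads that are local (within ``flank_bp`` of
    the encoding gene, inclusive, same chromosome) and pass the MAF and
    imputation-info filters in both cohorts, the lead with the lowest discovery
    p-value is the primary instrument (``is_primary``); further qualifying
    leads are retained as independent sensitivity instruments (clump leads are
    mutually un-clumpable, hence r2 <= 0.2 by construction).  Proteins without
    gene coordinates are skipped with a log entry.

    ``leads`` must carry discovery columns (freq1, info, p, beta1, pos, chrom)
    plus the ``*_rep`` replication columns and ``replicated`` flag.
    ``gene_table`` columns: protein_id, gene_id, chrom, start, end.
    """
    genes = gene_table.set_index("protein_id")
    rows = []
    for protein, grp in leads.groupby("trait_id"):
        if protein not in genes.index:
            logger.info("protein %s has no mapped gene; skipped", protein)
            continue
        gene = genes.loc[protein]
        for _, lead in grp.iterrows():
            maf_d = min(lead["freq1"], 1.0 - lead["freq1"])
            maf_r = min(lead["freq1_rep"], 1.0 - lead["freq1_rep"])
            is_local = bool(
                lead["chrom"] == gene["chrom"]
                and gene["start"] - flank_bp <= lead["pos"] <= gene["end"] + flank_bp
            )
            qualifies = bool(
                lead["replicated"]
                and is_local
                and maf_d > maf_min
                and maf_r > maf_min
                and lead["info"] > info_min
                and lead["info_rep"] > info_min
            )
            rows.append(
                dict(lead)
                | {
                    "protein_id": protein,
                    "gene_id": gene["gene_id"],
                    "gene_chrom": gene["chrom"],
                    "gene_start": gene["start"],
                    "gene_end": gene["end"],
                    "is_local": is_local,
                    "qualifies": qualifies,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["protein_id", "rsid", "is_local", "qualifies", "is_primary"]
        )
    df = pd.DataFrame(rows)
    df = df[df["qualifies"]].copy()
    df = df.sort_values(["protein_id", "p", "pos", "rsid"], kind="mergesort")
    df["is_primary"] = ~df.duplicated(subset="protein_id", keep="first")
    return df.reset_index(drop=True)
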