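"""Heterogeneity (HEIDI) and colocalization (CLPP) screening of significant pairs.

For every FDR-significant protein-trait pair, tests whether the locus is
consistent with a single shared causal variant (HEIDI; small p means
heterogeneity/linkage) and computes the colocalization posterior probability
at the instrument.  Writes results/step3_results.tsv.
"""

import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from protmr import clpp as clpp_mod
from protmr import heidi as heidi_mod
from protmr.io import read_summary_tsv

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    with open(ROOT / "scratch" / "world.pkl", "rb") as fh:
        world = pickle.load(fh)
    cfg, panel = world["cfg"], world["panel"]
    mr_results = pd.read_csv(ROOT / "results" / "mr_results.tsv", sep="\t")
    scan_rep = read_summary_tsv(ROOT / "scratch" / "sumstats_replication.tsv")
    outcomes = pd.read_csv(ROOT / "scratch" / "outcome_sumstats.tsv", sep="\t")

    ids_all = list(panel.variants["rsid"])
    by_trait = {t: g.reset_index(drop=True) for t, g in outcomes.groupby("trait_id")}
    by_protein = {p: g.reset_index(drop=True) for p, g in scan_rep.groupby("trait_id")}

    rows = []
    for _, row in mr_results[mr_results["significant"]].iterrows():
        inst_rs = row["rsid"]
        block = int(panel.variants.loc[panel.variants["rsid"] == inst_rs, "block"].iloc[0])
        mask = (panel.variants["block"] == block).to_numpy()
        ids = [i for i, m in zip(ids_all, mask) if m]
        exp = by_protein[row["protein_id"]].loc[mask].reset_index(drop=True)
        out = by_trait[row["outcome_id"]].loc[mask].reset_index(drop=True)
        ld = panel.ld[np.ix_(mask, mask)]

        locus = heidi_mod.LocusStats(
            instrument=inst_rs, ids=ids,
            beta_x=exp["beta1"].to_numpy(), se_x=exp["se"].to_numpy(),
            beta_y=out["beta1"].to_numpy(), se_y=out["se"].to_numpy(), ld=ld,
        )
        sub, insuff = heidi_mod.heidi_select(locus, max_snps=cfg.heidi_max_snps)
        hres = heidi_mod.heidi_test(sub) if sub is not None else insuff

        coloc = clpp_mod.make_locus(exp, out, ld, inst_rs, flank_snps=cfg.clpp_flank_snps)
        cres = clpp_mod.clpp_locus(coloc, max_causal=cfg.clpp_max_causal)
        rows.append(
            {
                "protein_id": row["protein_id"], "outcome_id": row["outcome_id"],
                "snpid": f"{int(panel.variants.loc[panel.variants['rsid'] == inst_rs, 'chrom'].iloc[0])}_"
                         f"{int(panel.variants.loc[panel.variants['rsid'] == inst_rs, 'pos'].iloc[0])}",
                "p_heidi": hres.p_heidi, "nsnp_heidi": hres.n_snps_used,
                "status": hres.status, "clpp": cres.clpp_at_instrument,
            }
        )
    step3 = pd.DataFrame(rows)
    step3.to_csv(ROOT / "results" / "step3_results.tsv", sep="\t", index=False)
    n = len(step3)
    ok = step3["status"] == "ok"
    print(
        f"{n} significant pairs tested: "
        f"{int((step3.loc[ok, 'p_heidi'] > 0.05).sum())} survive HEIDI (p > 0.05), "
        f"{int((step3['clpp'] > 0.01).sum())} have CLPP > 1%"
    )


if __name__ == "__main__":
    main()
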