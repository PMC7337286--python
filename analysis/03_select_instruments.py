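"""LD clumping, replication and instrument selection.

Reads the two cohort scans, clumps the discovery scan per protein against the
analytic LD reference, applies the Bonferroni replication rule with sign
consistency, and selects one primary local instrument per protein (plus any
independent sensitivity instruments).  Writes results/instruments.tsv.
"""

import pickle
from pathlib import Path

import pandas as pd

from protmr.instruments import LDSource, ld_clump, replicate_leads, select_instruments
from protmr.io import read_summary_tsv

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    with open(ROOT / "scratch" / "world.pkl", "rb") as fh:
        world = pickle.load(fh)
    panel = world["panel"]
    scan_disc = read_summary_tsv(ROOT / "scratch" / "sumstats_discovery.tsv")
    scan_rep = read_summary_tsv(ROOT / "scratch" / "sumstats_replication.tsv")

    ld_ref = LDSource(panel.ld, list(panel.variants["rsid"]))
    leads = []
    for pid, grp in scan_disc.groupby("trait_id"):
        for clump in ld_clump(grp, ld_ref):
            leads.append(clump.lead)
    leads_df = pd.DataFrame(leads).reset_index(drop=True)
    print(f"{len(leads_df)} discovery lead SNPs across {leads_df['trait_id'].nunique()} proteins")

    leads_df = replicate_leads(leads_df, scan_rep)
    n_rep = int(leads_df["replicated"].sum())
    print(
        f"{n_rep} replicated at p < 0.05/{len(leads_df)} with sign consistency"
    )

    instruments = select_instruments(leads_df, world["gene_table"])
    primary = instruments[instruments["is_primary"]]
    print(
        f"{len(primary)} proteins with a replicated local (+/-150 kb) instrument; "
        f"{len(instruments) - len(primary)} secondary sensitivity instruments"
    )
    leads_df.to_csv(ROOT / "results" / "leads.tsv", sep="\t", index=False)
    instruments.to_csv(ROOT / "results" / "instruments.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
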