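"""Step-3 summary counts and recovery against the simulator's ground truth.

Assembles the screen report (significant pairs per source, HEIDI nominal and
Bonferroni survivors, CLPP survivors, and their intersection) and scores each
filter against the known scenario labels.  Writes results/report.json.
"""

import json
import pickle
from pathlib import Path

import pandas as pd

from protmr.tables import screen_report

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    with open(ROOT / "scratch" / "world.pkl", "rb") as fh:
        world = pickle.load(fh)
    mr_results = pd.read_csv(ROOT / "results" / "mr_results.tsv", sep="\t")
    step3 = pd.read_csv(ROOT / "results" / "step3_results.tsv", sep="\t")

    heidi = step3[["protein_id", "outcome_id", "p_heidi"]]
    clpp = step3[["protein_id", "outcome_id", "clpp"]]
    report = screen_report(mr_results, heidi, clpp)

    truth = world["truth"].set_index("protein_id")
    own = step3[
        step3.apply(lambda r: truth.loc[r["protein_id"], "outcome_id"] == r["outcome_id"], axis=1)
    ].copy()
    own["scenario"] = [truth.loc[p, "scenario"] for p in own["protein_id"]]
    recovery = {}
    for scen, grp in own.groupby("scenario"):
        recovery[scen] = {
            "n_significant_pairs": len(grp),
            "heidi_survive_frac": float((grp["p_heidi"] > 0.05).mean()),
            "clpp_survive_frac": float((grp["clpp"] > 0.01).mean()),
        }

    out = {
        "n_significant": report["n_significant"],
        "n_heidi_nominal": report["n_heidi_nominal"],
        "n_heidi_bonferroni": report["n_heidi_bonferroni"],
        "n_clpp": report["n_clpp"],
        "n_intersect": report["n_intersect"],
        "recovery_by_scenario": recovery,
        "seed": world["seed"],
    }
    with open(ROOT / "results" / "report.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
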