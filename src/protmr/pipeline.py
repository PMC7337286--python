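"""End-to-end orchestration of the three-step screen on synthetic cohorts.

This is the glue the numbered analysis drivers and the acceptance script call:
simulate a stated world (cohort pair + outcome GWAS), run the three-stage pQTL
scan in both cohorts, clump, replicate and select instruments, run the
delta-method MR screen with per-source FDR, then HEIDI and colocalization on
every significant pair, and report the step-3 counts.

The default stated world is a desk-scale version of the real design: two
cohorts of 909 and 998 individuals, one LD block (AR-correlated, 21 variants)
per protein, a local pQTL explaining 20% of protein variance, polygenic
heritability 0.1, age and sex covariates, and outcome GWAS of 100,000
individuals per trait with protein-causal, linkage (r2 ~ 0.6) and null
architectures in equal parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clpp as clpp_mod
from . import heidi as heidi_mod
from .gwas import (
    assoc_scan,
    grm_eigendecomposition,
    preprocess_proteins,
    stage1_covariate_residualize,
    stage2_grammar_residualize,
)
from .instruments import LDSource, ld_clump, replicate_leads, select_instruments
from .mr import run_mr_screen
from .simulate import (
    LDBlockSpec,
    TruthRecord,
    ar1_corr,
    simulate_cohort_pair,
    simulate_ld_panel,
    simulate_outcome_gwas,
)
from .tables import screen_report

__all__ = ["PipelineConfig", "default_world", "run_pipeline"]


@dataclass
class PipelineConfig:
    n_proteins: int = 30
    snps_per_block: int = 21
    ld_rho: float = 0.9
    pqtl_var: float = 0.20  # protein variance explained by the local pQTL
    beta_yx: float = 0.3  # causal protein -> outcome effect (sd/sd)
    linkage_beta_yz: float = 0.10  # direct effect of the linkage variant
    n_discovery: int = 909
    n_replication: int = 998
    n_outcome: int = 100_000
    h2_polygenic: float = 0.1
    flank_bp: int = 150_000
    heidi_max_snps: int = 20
    clpp_flank_snps: int = 50
    clpp_max_causal: int = 2
    scenarios: tuple[str, ...] = ("causal", "linkage", "null")


def default_world(cfg: PipelineConfig, seed: int) -> tuple[list[LDBlockSpec], list[TruthRecord], pd.DataFrame]:
    """Block specs, ground-truth architecture and gene table for the stated world."""
    rng = np.random.default_rng(seed)
    specs, truths, genes = [], [], []
    R = ar1_corr(cfg.snps_per_block, cfg.ld_rho)
    causal_pos = cfg.snps_per_block // 2
    # variant with r2 ~ 0.6 to the pQTL for the linkage architecture
    link_pos = int(np.argmin(np.abs(R[causal_pos] ** 2 - 0.6)))
    beta_xz = float(np.sqrt(cfg.pqtl_var))
    span = 400_000
    for i in range(cfg.n_proteins):
        specs.append(
            LDBlockSpec(
                cfg.snps_per_block, R, block_span_bp=span, chrom=i + 1, start_bp=1_000_000
            )
        )
        scenario = cfg.scenarios[i % len(cfg.scenarios)]
        first_rs = i * cfg.snps_per_block + 1
        causal_id = f"rs{first_rs + causal_pos}"
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        kw = {}
        if scenario == "linkage":
            kw = dict(
                outcome_causal_variant_id=f"rs{first_rs + link_pos}",
                beta_yz_direct=cfg.linkage_beta_yz * (1.0 if rng.uniform() < 0.5 else -1.0),
            )
        truths.append(
            TruthRecord(
                protein_id=f"PROT{i + 1:03d}",
                causal_variant_ids=[causal_id],
                beta_xz_true=[sign * beta_xz],
                scenario=scenario,
                beta_yx_true=cfg.beta_yx if scenario == "causal" else 0.0,
                outcome_id=f"TRAIT{i + 1:03d}",
                **kw,
            )
        )
        causal_bp = 1_000_000 + int(span * causal_pos / (cfg.snps_per_block - 1))
        genes.append(
            {
                "protein_id": f"PROT{i + 1:03d}",
                "gene_id": f"ENSG{i + 1:011d}",
                "chrom": i + 1,
                "start": causal_bp - 20_000,
                "end": causal_bp + 20_000,
            }
        )
    return specs, truths, pd.DataFrame(genes)


def _scan_cohort(cohort, grm_eig) -> pd.DataFrame:
    """Three-stage scan of every protein in a cohort; returns stacked stats."""
    proteins, _ = preprocess_proteins(cohort.proteins, cohort.lod_flags)
    scans = []
    for pid in proteins.columns:
        r = stage1_covariate_residualize(proteins[pid].to_numpy(), cohort.covariates)
        g = stage2_grammar_residualize(r, cohort.grm, grm_eig=grm_eig)
        scans.append(
            assoc_scan(g.residuals, cohort.dosages[g.kept], cohort.variants, trait_id=pid)
        )
    return pd.concat(scans, ignore_index=True)


def run_pipeline(cfg: PipelineConfig | None = None, seed: int = 0) -> dict:
    """Simulate the stated world and run the full three-step screen.

    Returns a dict with the cohorts, scans, instruments, MR results,
    HEIDI/CLPP results, the step-3 report, and the ground truth.
    """
    cfg = cfg or PipelineConfig()
    specs, truths, gene_table = default_world(cfg, seed)

    discovery, replication, truth = simulate_cohort_pair(
        specs,
        truths,
        n_discovery=cfg.n_discovery,
        n_replication=cfg.n_replication,
        heritability_polygenic=cfg.h2_polygenic,
        seed=seed,
    )
    # LD reference: analytic correlation of the shared generating process
    panel = simulate_ld_panel(specs, n_samples=2, seed=seed)
    ld_ref = LDSource(panel.ld, list(panel.variants["rsid"]))

    scan_disc = _scan_cohort(discovery, grm_eigendecomposition(discovery.grm))
    scan_rep = _scan_cohort(replication, grm_eigendecomposition(replication.grm))

    # clump per protein in the discovery cohort, pool the leads
    leads = []
    for pid, grp in scan_disc.groupby("trait_id"):
        for clump in ld_clump(grp, ld_ref):
            leads.append(clump.lead)
    leads_df = pd.DataFrame(leads).reset_index(drop=True)
    leads_df = replicate_leads(leads_df, scan_rep)
    instruments = select_instruments(leads_df, gene_table, flank_bp=cfg.flank_bp)
    primary = instruments[instruments["is_primary"]].copy()

    # outcome GWAS over the whole variant set, one trait per truth record
    outcome_stats = []
    for i, t in enumerate(truths):
        outcome_stats.append(
            simulate_outcome_gwas(panel, t, n_outcome=cfg.n_outcome, seed=seed + 7919 + i)
        )
    outcomes = pd.concat(outcome_stats, ignore_index=True)

    mr_results, exclusions = run_mr_screen(primary, {"geneatlas": outcomes})

    # step 3 on the significant pairs
    ids_all = list(panel.variants["rsid"])
    by_trait = {t: g.reset_index(drop=True) for t, g in outcomes.groupby("trait_id")}
    exp_by_protein = {p: g.reset_index(drop=True) for p, g in scan_rep.groupby("trait_id")}
    heidi_rows, clpp_rows = [], []
    for _, row in mr_results[mr_results["significant"]].iterrows():
        inst_rs = row["rsid"]
        block = int(panel.variants.loc[panel.variants["rsid"] == inst_rs, "block"].iloc[0])
        mask = (panel.variants["block"] == block).to_numpy()
        ids = [i for i, m in zip(ids_all, mask) if m]
        exp = exp_by_protein[row["protein_id"]].loc[mask].reset_index(drop=True)
        out = by_trait[row["outcome_id"]].loc[mask].reset_index(drop=True)
        ld = panel.ld[np.ix_(mask, mask)]

        locus = heidi_mod.LocusStats(
            instrument=inst_rs,
            ids=ids,
            beta_x=exp["beta1"].to_numpy(),
            se_x=exp["se"].to_numpy(),
            beta_y=out["beta1"].to_numpy(),
            se_y=out["se"].to_numpy(),
            ld=ld,
        )
        sub, insuff = heidi_mod.heidi_select(locus, max_snps=cfg.heidi_max_snps)
        hres = heidi_mod.heidi_test(sub) if sub is not None else insuff
        heidi_rows.append(
            {
                "protein_id": row["protein_id"],
                "outcome_id": row["outcome_id"],
                "p_heidi": hres.p_heidi,
                "nsnp_heidi": hres.n_snps_used,
                "status": hres.status,
            }
        )

        coloc = clpp_mod.make_locus(exp, out, ld, inst_rs, flank_snps=cfg.clpp_flank_snps)
        cres = clpp_mod.clpp_locus(coloc, max_causal=cfg.clpp_max_causal)
        clpp_rows.append(
            {
                "protein_id": row["protein_id"],
                "outcome_id": row["outcome_id"],
                "clpp": cres.clpp_at_instrument,
            }
        )

    heidi_results = pd.DataFrame(heidi_rows, columns=["protein_id", "outcome_id", "p_heidi", "nsnp_heidi", "status"])
    clpp_results = pd.DataFrame(clpp_rows, columns=["protein_id", "outcome_id", "clpp"])
    report = screen_report(mr_results, heidi_results, clpp_results)

    return {
        "config": cfg,
        "truth": truth,
        "gene_table": gene_table,
        "discovery": discovery,
        "replication": replication,
        "panel": panel,
        "scan_discovery": scan_disc,
        "scan_replication": scan_rep,
        "leads": leads_df,
        "instruments": instruments,
        "mr_results": mr_results,
        "exclusions": exclusions,
        "heidi_results": heidi_results,
        "clpp_results": clpp_results,
        "report": report,
    }
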