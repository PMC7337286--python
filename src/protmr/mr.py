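"""Allele harmonization, delta-method Wald-ratio MR, and the FDR screen.

The causal effect of protein X on outcome Y through instrument Z is estimated
from summary statistics as a ratio of expectations with a second-order Taylor
correction for the effect size and a first-order (delta-method) standard
error::

    beta_YX = (beta_YZ / beta_XZ) * (1 + se_XZ**2 / beta_XZ**2)
    se_YX   = sqrt(se_YZ**2 / beta_XZ**2 + beta_YZ**2 * se_XZ**2 / beta_XZ**4)
    p_YX    = 2 * Phi(-|beta_YX| / se_YX)

To avoid winner's curse the exposure effect sizes come from the replication
cohort (lead selection used the discovery cohort); the screen refuses
discovery-cohort exposure statistics unless explicitly overridden.  FDR is
Benjamini-Hochberg, run separately within each outcome source group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["HarmonizedPair", "harmonize", "mr_delta", "bh_fdr", "run_mr_screen"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class HarmonizedPair:
    variant: str
    beta_xz: float
    se_xz: float
    beta_yz: float
    se_yz: float
    flipped: bool
    ambiguous_palindrome: bool
    ok: bool = True
    reason: str = ""


def harmonize(exposure_stat, outcome_stat) -> HarmonizedPair:
    """Align the outcome record's effect allele to the exposure's.

    Swapped allele order flips the outcome beta; non-palindromic records on the
    opposite strand are complemented then matched.  Palindromic (A/T, C/G)
    pairs are retained with ``ambiguous_palindrome=True`` and no
    frequency-based resolution is attempted.  Allele sets sharing no resolution
    yield an exclusion record (``ok=False``), never a silent drop.
    """
    ea1, ea0 = str(exposure_stat["a1"]).upper(), str(exposure_stat["a0"]).upper()
    oa1, oa0 = str(outcome_stat["a1"]).upper(), str(outcome_stat["a0"]).upper()
    ambiguous = (ea1, ea0) in _PALINDROMES
    variant = str(exposure_stat.get("rsid", exposure_stat.get("snpid", "")))

    def pair(flip: bool, beta_yz: float) -> HarmonizedPair:
        return HarmonizedPair(
            variant=variant,
            beta_xz=float(exposure_stat["beta1"]),
            se_xz=float(exposure_stat["se"]),
            beta_yz=beta_yz,
            se_yz=float(outcome_stat["se"]),
            flipped=flip,
            ambiguous_palindrome=ambiguous,
        )

    b = float(outcome_stat["beta1"])
    if (oa1, oa0) == (ea1, ea0):
        return pair(False, b)
    if (oa1, oa0) == (ea0, ea1):
        return pair(True, -b)
    if not ambiguous and {oa1, oa0} <= set(_COMPLEMENT):
        ca1, ca0 = _COMPLEMENT[oa1], _COMPLEMENT[oa0]
        if (ca1, ca0) == (ea1, ea0):
            return pair(False, b)
        if (ca1, ca0) == (ea0, ea1):
            return pair(True, -b)
    out = pair(False, b)
    out.ok = False
    out.reason = f"alleles unresolvable: exposure {ea1}/{ea0} vs outcome {oa1}/{oa0}"
    return out


def mr_delta(beta_xz, se_xz, beta_yz, se_yz):
    """Delta-method Wald-ratio estimate (second-order beta, first-order se).

    Accepts scalars or arrays; returns (beta_mr, se_mr, p_mr).
    """
    bx = np.asarray(beta_xz, dtype=float)
    sx = np.asarray(se_xz, dtype=float)
    by = np.asarray(beta_yz, dtype=float)
    sy = np.asarray(se_yz, dtype=float)
    if np.any(bx == 0):
        raise ValueError("beta_xz = 0: instrument has no exposure effect; estimate undefined")
    beta_mr = (by / bx) * (1.0 + sx**2 / bx**2)
    se_mr = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_mr = 2.0 * stats.norm.sf(np.abs(beta_mr) / se_mr)
    if np.ndim(beta_xz) == 0 and np.ndim(beta_yz) == 0:
        return float(beta_mr), float(se_mr), float(p_mr)
    return beta_mr, se_mr, p_mr


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, significant flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    sig, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, sig


def run_mr_screen(
    instruments: pd.DataFrame,
    outcome_tables: dict[str, pd.DataFrame],
    exposure: str = "replication",
    allow_discovery: bool = False,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delta-method MR of every instrument against every outcome per source.

    ``instruments`` rows carry discovery stats (beta1, se, ...) and ``*_rep``
    replication stats from :func:`protmr.instruments.select_instruments`.
    ``outcome_tables`` maps a source-group name (e.g. ``geneatlas``) to a
    summary-statistic table with one row per (trait_id, variant).  FDR is run
    separately within each source group.  Returns (results, exclusions).
    """
    if exposure == "discovery" and not allow_discovery:
        raise ValueError(
            "discovery-cohort exposure statistics re-use the selection data "
            "(winner's curse); pass allow_discovery=True to override"
        )
    if exposure not in ("replication", "discovery"):
        raise ValueError(f"unknown exposure cohort {exposure!r}")

    results, exclusions = [], []
    for source, table in outcome_tables.items():
        out_idx = table.set_index(["trait_id", "rsid"])
        traits = table["trait_id"].unique()
        rows = []
        for _, inst in instruments.iterrows():
            if exposure == "replication":
                exp_stat = {
                    "rsid": inst["rsid"], "a1": inst["a1"], "a0": inst["a0"],
                    "beta1": inst["beta1_rep"], "se": inst["se_rep"],
                }
            else:
                exp_stat = {
                    "rsid": inst["rsid"], "a1": inst["a1"], "a0": inst["a0"],
                    "beta1": inst["beta1"], "se": inst["se"],
                }
            for trait in traits:
                key = (trait, inst["rsid"])
                if key not in out_idx.index:
                    exclusions.append(
                        {
                            "protein_id": inst["protein_id"], "outcome_id": trait,
                            "source_group": source, "rsid": inst["rsid"],
                            "reason": "instrument absent from outcome study",
                        }
                    )
                    continue
                orec = out_idx.loc[key]
                hp = harmonize(exp_stat, orec)
                if not hp.ok:
                    exclusions.append(
                        {
                            "protein_id": inst["protein_id"], "outcome_id": trait,
                            "source_group": source, "rsid": inst["rsid"],
                            "reason": hp.reason,
                        }
                    )
                    continue
                if hp.beta_xz == 0:
                    exclusions.append(
                        {
                            "protein_id": inst["protein_id"], "outcome_id": trait,
                            "source_group": source, "rsid": inst["rsid"],
                            "reason": "exposure beta is zero",
                        }
                    )
                    continue
                b, s, p = mr_delta(hp.beta_xz, hp.se_xz, hp.beta_yz, hp.se_yz)
                rows.append(
                    {
                        "protein_id": inst["protein_id"], "outcome_id": trait,
                        "source_group": source, "rsid": inst["rsid"],
                        "beta_xz": hp.beta_xz, "se_xz": hp.se_xz,
                        "beta_yz": hp.beta_yz, "se_yz": hp.se_yz,
                        "flipped": hp.flipped,
                        "ambiguous_palindrome": hp.ambiguous_palindrome,
                        "beta_mr": b, "se_mr": s, "p_mr": p,
                    }
                )
        if rows:
            df = pd.DataFrame(rows)
            q, sig = bh_fdr(df["p_mr"].to_numpy(), alpha=alpha)
            df["fdr_q"] = q
            df["significant"] = sig
            results.append(df)
    res = (
        pd.concat(results, ignore_index=True)
        if results
        else pd.DataFrame(
            columns=["protein_id", "outcome_id", "source_group", "rsid",
                     "beta_mr", "se_mr", "p_mr", "fdr_q", "significant"]
        )
    )
    excl = pd.DataFrame(
        exclusions,
        columns=["protein_id", "outcome_id", "source_group", "rsid", "reason"],
    )
    return res, excl
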