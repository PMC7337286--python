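"""Synthetic cohorts, LD reference panels and outcome GWAS summary statistics.

The generator emulates the statistical structure that a proteome-by-phenome
Mendelian-randomization screen assumes: two genotyped cohorts (discovery and
replication) measured on a shared plasma-protein panel, where each protein is
driven by zero or more local pQTLs plus covariates, a polygenic (kinship)
component and noise; an external LD reference panel; and outcome-trait GWAS
summary statistics generated under three architectures —

* ``causal``  — the protein mediates the variant's effect on the outcome, so
  every variant's outcome effect is ``beta_yx * beta_xz`` (a causal chain);
* ``linkage`` — the outcome has its own causal variant, distinct from the
  pQTL but in LD with it (the confounded case heterogeneity tests target);
* ``null``    — no variant affects the outcome.

Genotypes are produced from a Gaussian copula: latent MVN haplotypes are
thresholded at allele-frequency quantiles and a dosage is the sum of two
haplotypes.  Because thresholding attenuates correlation, the latent
correlation is calibrated per variant pair (bivariate-normal CDF root-find)
so that the *dosage* correlation converges to the requested ``target_r``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LDBlockSpec",
    "LDPanel",
    "CohortData",
    "TruthRecord",
    "ar1_corr",
    "simulate_ld_panel",
    "simulate_cohort_pair",
    "simulate_exposure_gwas",
    "simulate_outcome_gwas",
    "truth_table",
]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


def ar1_corr(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix, r_ij = rho^|i-j|."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class LDBlockSpec:
    """One LD block of the synthetic genome.

    ``target_r`` is the pairwise dosage-correlation profile: a scalar gives an
    exchangeable block (every pair at that r), a square matrix gives the full
    signed correlation structure (e.g. from :func:`ar1_corr`).
    """

    n_variants: int
    target_r: float | np.ndarray = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_span_bp: int = 1_000_000
    chrom: int | None = None
    start_bp: int = 1_000_000

    def corr_matrix(self) -> np.ndarray:
        if np.ndim(self.target_r) == 0:
            r = float(self.target_r)
            m = np.full((self.n_variants, self.n_variants), r)
            np.fill_diagonal(m, 1.0)
            return m
        m = np.asarray(self.target_r, dtype=float)
        if m.shape != (self.n_variants, self.n_variants):
            raise ValueError(
                f"target_r matrix shape {m.shape} does not match n_variants={self.n_variants}"
            )
        return m


@dataclass
class LDPanel:
    """Reference genotype panel plus its generating correlation structure."""

    dosages: np.ndarray  # n_samples x n_variants, values in [0, 2]
    variants: pd.DataFrame  # chrom, pos, rsid, a1, a0, info, maf
    ld: np.ndarray  # analytic (target) dosage correlation matrix
    latent: np.ndarray  # calibrated latent Gaussian correlation
    freqs: np.ndarray  # generating a1 allele frequencies

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["rsid"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return int(idx[0])


@dataclass
class CohortData:
    """Individual-level data for one simulated cohort."""

    dosages: np.ndarray
    variants: pd.DataFrame
    proteins: pd.DataFrame  # individuals x proteins
    lod_flags: pd.DataFrame  # True where measurement is above the limit of detection
    covariates: pd.DataFrame
    grm: np.ndarray
    name: str = "cohort"


@dataclass
class TruthRecord:
    """Simulator ground truth for one protein (and optionally one outcome)."""

    protein_id: str
    causal_variant_ids: list[str]
    beta_xz_true: list[float]
    scenario: str = "null"  # causal | linkage | null
    beta_yx_true: float = 0.0
    outcome_id: str | None = None
    # linkage scenario only: the outcome's own causal variant and its direct effect
    outcome_causal_variant_id: str | None = None
    beta_yz_direct: float = 0.0

    def __post_init__(self) -> None:
        if self.scenario not in ("causal", "linkage", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "null" and self.beta_yx_true != 0.0:
            raise ValueError("scenario='null' requires beta_yx_true == 0")
        if self.scenario == "linkage" and self.outcome_causal_variant_id is None:
            raise ValueError("scenario='linkage' requires outcome_causal_variant_id")
        if len(self.causal_variant_ids) != len(self.beta_xz_true):
            raise ValueError("causal_variant_ids and beta_xz_true must align")


def truth_table(records: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in records:
        rows.append(
            {
                "protein_id": t.protein_id,
                "causal_variant_ids": ",".join(t.causal_variant_ids),
                "beta_xz_true": ",".join(f"{b:g}" for b in t.beta_xz_true),
                "scenario": t.scenario,
                "beta_yx_true": t.beta_yx_true,
                "outcome_id": t.outcome_id if t.outcome_id is not None else "",
                "outcome_causal_variant_id": t.outcome_causal_variant_id or "",
                "beta_yz_direct": t.beta_yz_direct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Latent-correlation calibration


def _binary_corr(rho: float, q1: float, q2: float, f1: float, f2: float) -> float:
    """Point correlation of threshold indicators 1{z1<q1}, 1{z2<q2} at latent rho."""
    if rho >= 1.0:
        p11 = min(f1, f2)
    elif rho <= -1.0:
        p11 = max(f1 + f2 - 1.0, 0.0)
    else:
        p11 = stats.multivariate_normal.cdf(
            [q1, q2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
    denom = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
    return (p11 - f1 * f2) / denom


def _calibrate_latent(r_target: float, f1: float, f2: float, cache: dict) -> float:
    """Latent Gaussian correlation giving dosage correlation ``r_target``."""
    if r_target == 0.0:
        return 0.0
    key = (round(r_target, 6), round(min(f1, f2), 6), round(max(f1, f2), 6))
    if key in cache:
        return cache[key]
    q1, q2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    r_max = _binary_corr(1.0, q1, q2, f1, f2)
    r_min = _binary_corr(-1.0, q1, q2, f1, f2)
    if not (r_min < r_target < r_max):
        raise ValueError(
            f"target r={r_target:.3f} unattainable for allele frequencies "
            f"({f1:.3f}, {f2:.3f}); attainable range is ({r_min:.3f}, {r_max:.3f})"
        )
    rho = optimize.brentq(
        lambda x: _binary_corr(x, q1, q2, f1, f2) - r_target,
        -0.9999,
        0.9999,
        xtol=1e-6,
    )
    cache[key] = rho
    return rho


def _nearest_psd_corr(m: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    if w.min() >= floor:
        return m
    w = np.clip(w, floor, None)
    m2 = (v * w) @ v.T
    d = np.sqrt(np.diag(m2))
    return m2 / np.outer(d, d)


def _build_block(
    spec: LDBlockSpec, block_index: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (target dosage corr, calibrated latent corr, allele freqs)."""
    target = spec.corr_matrix()
    w = np.linalg.eigvalsh(target)
    if w.min() < -1e-8:
        raise ValueError(
            f"target LD correlation for block {block_index} is not positive "
            f"semi-definite (min eigenvalue {w.min():.3g})"
        )
    lo, hi = spec.maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range for block {block_index} must lie in (0, 0.5]")
    # Variants in strong LD carry similar allele frequencies (and the point
    # correlation of threshold indicators is frequency-bounded), so within a
    # block frequencies scatter around a shared base, tighter the stronger the LD.
    off = target[~np.eye(spec.n_variants, dtype=bool)]
    r_abs_max = float(np.abs(off).max()) if off.size else 0.0
    base = rng.uniform(lo, hi)
    spread = base * 0.25 * (1.0 - r_abs_max)
    freqs = np.clip(
        base + rng.uniform(-spread, spread, size=spec.n_variants), lo, hi
    )
    cache: dict = {}
    latent = np.eye(spec.n_variants)
    for i, j in itertools.combinations(range(spec.n_variants), 2):
        if target[i, j] != 0.0:
            latent[i, j] = latent[j, i] = _calibrate_latent(
                target[i, j], freqs[i], freqs[j], cache
            )
    latent = _nearest_psd_corr(latent)
    return target, latent, freqs


def _haplotypes_to_dosage(
    latent_chol: np.ndarray, quantiles: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    z = rng.standard_normal((2 * n, latent_chol.shape[0])) @ latent_chol.T
    hap = (z < quantiles).astype(np.float64)
    return hap[:n] + hap[n:]


def simulate_ld_panel(
    specs: list[LDBlockSpec], n_samples: int, seed: int
) -> LDPanel:
    """Simulate a block-LD reference genotype panel.

    Blocks are mutually independent (each lives on its own chromosome unless a
    chromosome is set explicitly).  Returns the dosage panel together with the
    analytic dosage-correlation matrix the empirical LD converges to.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not specs:
        raise ValueError("at least one LD block spec is required")
    rng = np.random.default_rng(seed)

    dosage_parts, var_rows = [], []
    ld_blocks, latent_blocks, freq_parts = [], [], []
    rs_counter = 1
    for b, spec in enumerate(specs):
        target, latent, freqs = _build_block(spec, b, rng)
        chol = np.linalg.cholesky(latent + 1e-10 * np.eye(spec.n_variants))
        quantiles = stats.norm.ppf(freqs)
        dosage_parts.append(_haplotypes_to_dosage(chol, quantiles, n_samples, rng))
        ld_blocks.append(target)
        latent_blocks.append(latent)
        freq_parts.append(freqs)
        chrom = spec.chrom if spec.chrom is not None else b + 1
        positions = spec.start_bp + np.linspace(
            0, spec.block_span_bp, spec.n_variants, dtype=int
        )
        for k in range(spec.n_variants):
            a1, a0 = _ALLELE_PAIRS[(rs_counter - 1) % len(_ALLELE_PAIRS)]
            var_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(positions[k]),
                    "rsid": f"rs{rs_counter}",
                    "a1": a1,
                    "a0": a0,
                    "info": 1.0,
                    "maf": min(freqs[k], 1 - freqs[k]),
                    "block": b,
                }
            )
            rs_counter += 1

    from scipy.linalg import block_diag

    variants = pd.DataFrame(var_rows)
    return LDPanel(
        dosages=np.hstack(dosage_parts),
        variants=variants,
        ld=block_diag(*ld_blocks),
        latent=block_diag(*latent_blocks),
        freqs=np.concatenate(freq_parts),
    )


# ---------------------------------------------------------------------------
# Cohort pair


def _grm_from_dosages(dosages: np.ndarray) -> np.ndarray:
    p = dosages.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1 - p))
    ok = sd > 0
    x = (dosages[:, ok] - 2.0 * p[ok]) / sd[ok]
    grm = x @ x.T / ok.sum()
    return grm


def _default_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    # age and sex, the two covariates every pQTL GWAS adjusts for
    return pd.DataFrame(
        {
            "age": rng.normal(55.0, 12.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
        }
    )


def simulate_cohort_pair(
    specs: list[LDBlockSpec],
    architecture: list[TruthRecord],
    n_discovery: int = 909,
    n_replication: int = 998,
    heritability_polygenic: float = 0.1,
    covariate_effects: dict[str, float] | None = None,
    ld_mismatch: float = 0.0,
    info_degrade: bool = False,
    lod_below_frac: float = 0.0,
    n_grm_markers: int = 500,
    seed: int = 0,
) -> tuple[CohortData, CohortData, pd.DataFrame]:
    """Simulate a matched discovery/replication cohort pair plus ground truth.

    Each protein is ``sum(beta_xz * standardized dosage) + covariates +
    polygenic(h2 * GRM) + noise`` on a unit-variance scale.  Cohort sizes
    default to the 909 / 998 of the two island cohorts the design emulates.
    ``ld_mismatch`` (epsilon in [0,1]) blends the replication cohort's latent
    LD toward a random perturbation to emulate cross-population LD differences.
    """
    if not (0.0 <= heritability_polygenic < 1.0):
        raise ValueError("heritability_polygenic must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if covariate_effects is None:
        covariate_effects = {"age": 0.1, "sex": 0.1}

    # One shared generating process: build latent structure once.
    panel = simulate_ld_panel(specs, n_samples=2, seed=seed)  # structure only
    variants, freqs = panel.variants, panel.freqs
    latent_disc = panel.latent
    if ld_mismatch > 0.0:
        pert = _nearest_psd_corr(
            np.corrcoef(rng.standard_normal((panel.n_variants + 5, panel.n_variants)).T)
        )
        latent_rep = _nearest_psd_corr(
            (1.0 - ld_mismatch) * latent_disc + ld_mismatch * pert
        )
    else:
        latent_rep = latent_disc

    id_to_idx = {r: i for i, r in enumerate(variants["rsid"])}
    for t in architecture:
        for vid in t.causal_variant_ids:
            if vid not in id_to_idx:
                raise ValueError(
                    f"protein {t.protein_id}: causal variant {vid} absent from panel"
                )

    quantiles = stats.norm.ppf(freqs)

    def make_cohort(n: int, latent: np.ndarray, name: str) -> CohortData:
        chol = np.linalg.cholesky(latent + 1e-10 * np.eye(latent.shape[0]))
        dos = _haplotypes_to_dosage(chol, quantiles, n, rng)
        # GRM from independent genome-wide background markers: in real data a
        # single locus is a negligible fraction of the relationship matrix, so
        # the kinship correction must not absorb the local pQTL signal.
        f_bg = rng.uniform(0.05, 0.5, size=n_grm_markers)
        bg = rng.binomial(2, f_bg, size=(n, n_grm_markers)).astype(float)
        grm = _grm_from_dosages(bg)
        cov = _default_covariates(n, rng)
        cov_std = (cov - cov.mean()) / cov.std(ddof=0).replace(0.0, 1.0)

        # polygenic component shared covariance h2 * GRM
        h2 = heritability_polygenic
        if h2 > 0:
            w, v = np.linalg.eigh(grm)
            w = np.clip(w, 0.0, None)
            poly_chol = v * np.sqrt(w)
        p_mean = dos.mean(axis=0) / 2.0
        p_sd = np.sqrt(2.0 * p_mean * (1 - p_mean))
        p_sd[p_sd == 0] = 1.0
        dos_std = (dos - 2.0 * p_mean) / p_sd

        prot, lod = {}, {}
        for t in architecture:
            idx = [id_to_idx[v] for v in t.causal_variant_ids]
            b = np.asarray(t.beta_xz_true, dtype=float)
            g = dos_std[:, idx] @ b if idx else np.zeros(n)
            var_g = float(b @ panel.ld[np.ix_(idx, idx)] @ b) if idx else 0.0
            c = sum(
                covariate_effects.get(k, 0.0) * cov_std[k].to_numpy()
                for k in cov.columns
            )
            var_c = sum(covariate_effects.get(k, 0.0) ** 2 for k in cov.columns)
            var_e = max(1.0 - var_g - var_c - h2, 0.02)
            y = g + c + rng.standard_normal(n) * np.sqrt(var_e)
            if h2 > 0:
                y = y + poly_chol @ rng.standard_normal(n) * np.sqrt(h2)
            prot[t.protein_id] = y
            if lod_below_frac > 0:
                thr = np.quantile(y, lod_below_frac)
                lod[t.protein_id] = y > thr
            else:
                lod[t.protein_id] = np.ones(n, dtype=bool)

        var_df = variants.copy()
        if info_degrade:
            var_df["info"] = rng.uniform(0.9, 1.0, size=len(var_df))
        return CohortData(
            dosages=dos,
            variants=var_df,
            proteins=pd.DataFrame(prot),
            lod_flags=pd.DataFrame(lod),
            covariates=cov,
            grm=grm,
            name=name,
        )

    discovery = make_cohort(n_discovery, latent_disc, "discovery")
    replication = make_cohort(n_replication, latent_rep, "replication")
    return discovery, replication, truth_table(architecture)


# ---------------------------------------------------------------------------
# Outcome GWAS summary statistics


def simulate_exposure_gwas(
    panel: LDPanel | np.ndarray,
    truth: TruthRecord,
    n_exposure: int = 998,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Protein (exposure) GWAS summary statistics over a locus.

    Same sampling model as :func:`simulate_outcome_gwas` but the direct
    effects are the protein's own pQTL effects ``beta_xz_true`` on the
    standardized scale, regardless of scenario.
    """
    proxy = TruthRecord(
        protein_id=truth.protein_id,
        causal_variant_ids=truth.causal_variant_ids,
        beta_xz_true=truth.beta_xz_true,
        scenario="causal",
        beta_yx_true=1.0,
        outcome_id=truth.protein_id,
    )
    return simulate_outcome_gwas(panel, proxy, n_exposure, seed=seed, variants=variants)


def simulate_outcome_gwas(
    panel: LDPanel | np.ndarray,
    truth: TruthRecord,
    n_outcome: int = 100_000,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Outcome-trait GWAS summary statistics over a locus.

    Marginal effects on the standardized-genotype scale are ``R @ b_direct``
    where ``b_direct`` encodes the scenario: under ``causal`` every pQTL
    causal variant carries ``beta_yx * beta_xz``; under ``linkage`` only the
    outcome's own causal variant carries ``beta_yz_direct``; under ``null``
    all are zero.  Estimates are ``z / sqrt(n)`` with LD-correlated sampling
    noise, i.e. ``z ~ MVN(sqrt(n) R b, R)``.
    """
    if isinstance(panel, LDPanel):
        R = panel.ld
        variants = panel.variants if variants is None else variants
    else:
        R = np.asarray(panel, dtype=float)
        if variants is None:
            raise ValueError("variants table required when passing a bare LD matrix")
    m = R.shape[0]
    rng = np.random.default_rng(seed)
    id_to_idx = {r: i for i, r in enumerate(variants["rsid"])}

    b = np.zeros(m)
    if truth.scenario == "causal":
        for vid, bxz in zip(truth.causal_variant_ids, truth.beta_xz_true):
            b[id_to_idx[vid]] += truth.beta_yx_true * bxz
    elif truth.scenario == "linkage":
        b[id_to_idx[truth.outcome_causal_variant_id]] = truth.beta_yz_direct
    elif truth.scenario != "null":
        raise ValueError(f"unknown scenario {truth.scenario!r}")

    chol = np.linalg.cholesky(_nearest_psd_corr(R) + 1e-10 * np.eye(m))
    z = np.sqrt(n_outcome) * (R @ b) + chol @ rng.standard_normal(m)
    se = np.full(m, 1.0 / np.sqrt(n_outcome))
    beta = z * se
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = variants[["chrom", "pos", "rsid", "a1", "a0"]].copy()
    out.insert(0, "snpid", out["chrom"].astype(str) + "_" + out["pos"].astype(str))
    out["trait_id"] = truth.outcome_id or "outcome"
    out["n"] = n_outcome
    out["freq1"] = (
        panel.freqs if isinstance(panel, LDPanel) else np.full(m, np.nan)
    )
    out["beta1"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["info"] = variants["info"].to_numpy() if "info" in variants else 1.0
    return out
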