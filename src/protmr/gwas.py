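"""Protein preprocessing and the three-stage pQTL genome-wide association scan.

Stage 1 regresses each rank-normalized protein on measured covariates and keeps
the residuals.  Stage 2 fits a single-GRM variance-component model by REML and
removes the genetic BLUP (GRAMMAR-style environmental residuals), drops gross
outliers (|z| > 4) and rank-normalizes the remainder.  Stage 3 runs simple
per-SNP linear regression of the transformed trait on allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "rank_inverse_normal",
    "preprocess_proteins",
    "stage1_covariate_residualize",
    "stage2_grammar_residualize",
    "assoc_scan",
    "grm_eigendecomposition",
    "GrammarResult",
]


def rank_inverse_normal(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x, method="average")
    n = len(x)
    return stats.norm.ppf((r - c) / (n + 1.0 - 2.0 * c))


def preprocess_proteins(
    proteins: pd.DataFrame,
    lod_flags: pd.DataFrame,
    min_above_lod: int = 200,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop under-detected proteins and rank-inverse-normal transform the rest.

    A protein is excluded when fewer than ``min_above_lod`` samples have a
    measurement above the assay's limit of detection.  Returns the transformed
    panel and the list of excluded protein ids.
    """
    if proteins.shape != lod_flags.shape:
        raise ValueError("proteins and lod_flags must be conformable")
    counts = lod_flags.sum(axis=0)
    dropped = [str(c) for c in proteins.columns if counts[c] < min_above_lod]
    kept = [c for c in proteins.columns if c not in set(dropped)]
    if not kept:
        raise ValueError(
            f"all {proteins.shape[1]} proteins excluded: none has >= "
            f"{min_above_lod} measurements above the limit of detection"
        )
    out = proteins[kept].apply(lambda col: rank_inverse_normal(col.to_numpy()))
    return out, dropped


def stage1_covariate_residualize(
    protein_column: np.ndarray, covariates: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Least-squares residuals of a protein on covariates (intercept added)."""
    y = np.asarray(protein_column, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    X = np.column_stack([np.ones(len(y)), c])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = (
            list(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else [f"col{i}" for i in range(c.shape[1])]
        )
        # identify columns that do not increase rank when added one at a time
        bad, kept = [], np.ones((len(y), 1))
        for j, nm in enumerate(names):
            trial = np.column_stack([kept, c[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(nm)
            else:
                kept = trial
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def grm_eigendecomposition(grm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a GRM, validated symmetric PSD (small negatives clipped)."""
    grm = np.asarray(grm, dtype=float)
    if not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    w, v = np.linalg.eigh(grm)
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ValueError(f"GRM is not positive semi-definite (min eigenvalue {w.min():.3g})")
    return np.clip(w, 0.0, None), v


@dataclass
class GrammarResult:
    residuals: np.ndarray  # transformed residuals on the kept samples
    kept: np.ndarray  # boolean mask of retained samples
    h2: float
    sigma_g2: float
    sigma_e2: float
    n_removed: int


def _reml_h2(yt: np.ndarray, xt: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Profiled REML for y = mu + g + e with cov(g) = sigma_g^2 K, in the GRM eigenbasis.

    ``yt = U'y``, ``xt = U'1``, ``w`` the GRM eigenvalues.  Returns (h2, sigma_total^2).
    """
    n = len(yt)

    def neg_reml(h2: float) -> float:
        d = h2 * w + (1.0 - h2)
        xdx = np.sum(xt * xt / d)
        bhat = np.sum(xt * yt / d) / xdx
        r = yt - bhat * xt
        rss = np.sum(r * r / d)
        s2 = rss / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2) + np.sum(np.log(d)) + np.log(xdx))

    res = optimize.minimize_scalar(
        neg_reml, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(
            f"REML did not converge; last bracket value h2={res.x:.6f}, "
            f"objective={res.fun:.6f}"
        )
    h2 = float(res.x)
    d = h2 * w + (1.0 - h2)
    xdx = np.sum(xt * xt / d)
    bhat = np.sum(xt * yt / d) / xdx
    r = yt - bhat * xt
    s2 = float(np.sum(r * r / d) / (n - 1))
    return h2, s2


def stage2_grammar_residualize(
    residuals: np.ndarray,
    grm: np.ndarray,
    outlier_z: float = 4.0,
    grm_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> GrammarResult:
    """REML-BLUP environmental residuals, outlier removal, rank-normal transform.

    Fits the one-GRM variance-component model by REML via eigendecomposition,
    subtracts the genetic BLUP, removes samples with residual |z| > ``outlier_z``
    and rank-inverse-normal transforms the remainder.  When the GRM is the
    identity the split is unidentifiable; by contract h2=0 is returned and the
    residuals are the z-scored input.
    """
    y = np.asarray(residuals, dtype=float)
    grm = np.asarray(grm, dtype=float)
    n = len(y)

    if np.abs(grm - np.eye(n)).max() < 1e-10:
        e = (y - y.mean()) / y.std(ddof=0)
        kept = np.abs(e) <= outlier_z
        out = rank_inverse_normal(e[kept])
        s2 = float(y.var(ddof=1))
        return GrammarResult(out, kept, 0.0, 0.0, s2, int((~kept).sum()))

    w, v = grm_eig if grm_eig is not None else grm_eigendecomposition(grm)
    yt = v.T @ y
    xt = v.T @ np.ones(n)
    h2, s2 = _reml_h2(yt, xt, w)

    d = h2 * w + (1.0 - h2)
    bhat = np.sum(xt * yt / d) / np.sum(xt * xt / d)
    rt = yt - bhat * xt
    # environmental residual e = sigma_e^2 V^{-1} (y - mu); in eigenbasis (1-h2)/d
    e = v @ ((1.0 - h2) / d * rt)

    z = (e - e.mean()) / e.std(ddof=0)
    kept = np.abs(z) <= outlier_z
    out = rank_inverse_normal(e[kept])
    return GrammarResult(
        residuals=out,
        kept=kept,
        h2=h2,
        sigma_g2=h2 * s2,
        sigma_e2=(1.0 - h2) * s2,
        n_removed=int((~kept).sum()),
    )


def assoc_scan(
    transformed_trait: np.ndarray,
    dosages: np.ndarray,
    variants: pd.DataFrame,
    trait_id: str = "trait",
    use_t: bool = False,
) -> pd.DataFrame:
    """Per-SNP simple linear regression of the trait on allele dosage.

    Vectorized closed-form OLS per variant.  Monomorphic variants are emitted
    with NaN estimates and ``undefined=True`` rather than dropped, so a
    genome-wide scan never aborts.
    """
    y = np.asarray(transformed_trait, dtype=float)
    g = np.asarray(dosages, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("at least 3 samples required")
    if g.shape[0] != n:
        raise ValueError("trait and dosage matrix are not conformable")
    if np.isnan(y).any() or np.isnan(g).any():
        raise ValueError("missing values are not supported")

    yc = y - y.mean()
    gm = g.mean(axis=0)
    gc = g - gm
    sxx = (gc * gc).sum(axis=0)
    syy = float(yc @ yc)
    sxy = gc.T @ yc

    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe
    rss = syy - beta * sxy
    dof = n - 2
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
        if use_t:
            p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        else:
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        r2 = np.where(syy > 0, beta * sxy / syy, np.nan)

    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)
    p = np.where(mono, np.nan, p)

    out = variants[["chrom", "pos", "rsid", "a1", "a0"]].copy().reset_index(drop=True)
    out.insert(0, "snpid", out["chrom"].astype(str) + "_" + out["pos"].astype(str))
    out["trait_id"] = trait_id
    out["n"] = n
    out["freq1"] = gm / 2.0
    out["beta1"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["info"] = variants["info"].to_numpy() if "info" in variants else 1.0
    out["r2"] = r2
    out["undefined"] = mono
    return out
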