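"""Motif-activity inference by multiple linear regression.

For each pair of consecutive timepoints, the log2 expression change of every
gene is regressed on the standardized binding affinities of its promoter (or
enhancer) for each motif:

    delta_{g,t} = c_t + sum_m  Ntilde_{g,m} A_{m,t} + eps_{g,t}

The coefficient A_{m,t} is the *motif activity* over interval t: positive
means genes carrying the motif's sites were coordinately up-regulated across
that interval, negative means coordinate repression, zero means no change.
Promoter and enhancer region classes are fitted independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import TimepointDesign


def log_fold_changes(
    means: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Promoters x (T-1) matrix of consecutive log2 fold changes.

    ``delta_{g,t} = log2((E_{g,t+1} + d) / (E_{g,t} + d))`` with pseudocount
    ``d`` guarding zero-expression ratios.  Columns are labelled by the
    interval, e.g. ``E11->E12``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if means.shape[1] < 2:
        raise ValueError("need at least 2 timepoints for fold changes")
    m = means.to_numpy() + pseudocount
    delta = np.log2(m[:, 1:]) - np.log2(m[:, :-1])
    labels = [f"{a}->{b}" for a, b in zip(means.columns[:-1], means.columns[1:])]
    return pd.DataFrame(delta, index=means.index, columns=labels)


@dataclass(frozen=True)
class ScalingRecord:
    """Column means/scales used to standardize a design matrix."""

    means: pd.Series
    scales: pd.Series
    dropped: tuple[str, ...] = ()


def standardize_design(affinities: pd.DataFrame) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center each motif column to mean 0, variance 1 (population SD).

    Constant columns carry no regression information and are dropped with a
    warning naming the motif; the scaling record allows back-transformation
    of coefficients to the raw-affinity scale.
    """
    if len(affinities) < 2:
        raise ValueError("need at least 2 regions to standardize")
    mu = affinities.mean(axis=0)
    sd = affinities.std(axis=0, ddof=0)
    constant = sd[sd == 0].index
    if len(constant) == len(affinities.columns):
        raise ValueError("all affinity columns are constant")
    if len(constant):
        warnings.warn(
            f"dropping constant affinity column(s): {list(constant)}", stacklevel=2
        )
    kept = affinities.columns.difference(constant, sort=False)
    z = (affinities[kept] - mu[kept]) / sd[kept]
    record = ScalingRecord(mu[kept], sd[kept], tuple(constant))
    return z, record


@dataclass
class ActivityFit:
    """Per-interval motif activities with intercepts, SEs and fit quality."""

    activities: pd.DataFrame  # motifs x intervals
    intercepts: pd.Series  # per interval
    standard_errors: pd.DataFrame  # motifs x intervals
    r_squared: pd.Series  # per interval
    ridge_lambda: float
    region_class: str = "promoter"

    @property
    def motif_ids(self) -> list[str]:
        return list(self.activities.index)


def fit_activities(
    delta: pd.DataFrame,
    design: pd.DataFrame,
    ridge_lambda: float = 0.0,
    region_class: str = "promoter",
) -> ActivityFit:
    """Fit per-interval activities by (optionally ridge-penalised) least
    squares of expression changes on the standardized design.

    The intercept is never penalised.  With ``ridge_lambda = 0`` the design
    must have more rows than columns and full column rank; otherwise a
    positive ridge penalty is required.  Standard errors come from the OLS
    covariance at ``lambda = 0`` and from the ridge sandwich
    ``(X'X + lI)^-1 X'X (X'X + lI)^-1 s^2`` otherwise.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    if not delta.index.equals(design.index):
        design = design.reindex(delta.index)
        if design.isna().any().any():
            raise ValueError("delta and design rows are not aligned")
    G, K = design.shape
    X = design.to_numpy()
    Y = delta.to_numpy()
    n_int = Y.shape[1]
    if ridge_lambda == 0 and K >= G:
        raise ValueError(
            f"{K} motifs >= {G} genes: ordinary least squares is underdetermined; "
            "use a positive ridge_lambda"
        )
    # center X and Y: the unpenalised intercept separates out exactly
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    XtX = Xc.T @ Xc
    if ridge_lambda == 0:
        eigvals = np.linalg.eigvalsh(XtX)
        if eigvals[0] <= max(G, K) * np.finfo(float).eps * max(eigvals[-1], 1.0):
            raise ValueError(
                "design matrix is rank deficient; use a positive ridge_lambda"
            )
        XtX_pen = XtX
    else:
        XtX_pen = XtX + ridge_lambda * np.eye(K)
    A = np.linalg.solve(XtX_pen, Xc.T @ Yc)  # K x n_int
    intercepts = y_mean - x_mean @ A

    resid = Yc - Xc @ A
    rss = (resid**2).sum(axis=0)
    tss = (Yc**2).sum(axis=0)
    dof = max(G - K - 1, 1)
    sigma2 = rss / dof
    inv_pen = np.linalg.inv(XtX_pen)
    if ridge_lambda == 0:
        cov_unit = inv_pen
    else:
        cov_unit = inv_pen @ XtX @ inv_pen
    se = np.sqrt(np.outer(np.diag(cov_unit), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)

    cols = list(delta.columns)
    motifs = list(design.columns)
    return ActivityFit(
        activities=pd.DataFrame(A, index=motifs, columns=cols),
        intercepts=pd.Series(intercepts, index=cols),
        standard_errors=pd.DataFrame(se, index=motifs, columns=cols),
        r_squared=pd.Series(r2, index=cols),
        ridge_lambda=ridge_lambda,
        region_class=region_class,
    )


def default_ridge_lambda(n_genes: int, n_motifs: int) -> float:
    """0 when genes comfortably outnumber motifs (G > 5K), else a small ridge."""
    return 0.0 if n_genes > 5 * n_motifs else 1.0


def map_enhancers_to_genes(
    enhancer_affinities: pd.DataFrame, links: Mapping[str, str]
) -> tuple[pd.DataFrame, int]:
    """Aggregate enhancer rows to their linked genes (affinities add over a
    gene's enhancers).  Returns the gene-level matrix and the number of
    unmapped enhancers that were dropped."""
    mapped = enhancer_affinities.index.to_series().map(dict(links))
    unmapped = int(mapped.isna().sum())
    kept = enhancer_affinities[mapped.notna()]
    gene_level = kept.groupby(mapped.dropna().to_numpy()).sum()
    return gene_level, unmapped


def fit_both_region_classes(
    delta: pd.DataFrame,
    promoter_affinities: pd.DataFrame,
    enhancer_affinities: pd.DataFrame | None,
    ridge_lambda: float = 0.0,
    enhancer_gene_links: Mapping[str, str] | None = None,
) -> tuple[ActivityFit, ActivityFit | None]:
    """Fit promoter and enhancer activities as two independent regressions.

    Enhancers are mapped to genes via ``enhancer_gene_links`` when their row
    index is not already gene-keyed; genes without any enhancer are excluded
    from the enhancer fit (zero affinity is a statement about sequence, not
    missingness).  An empty enhancer set yields a promoter fit only.
    """
    z_prom, _ = standardize_design(promoter_affinities.reindex(delta.index))
    prom_fit = fit_activities(delta, z_prom, ridge_lambda, "promoter")

    if enhancer_affinities is None or enhancer_affinities.empty:
        warnings.warn("no enhancer regions; returning promoter fit only", stacklevel=2)
        return prom_fit, None

    enh = enhancer_affinities
    if enhancer_gene_links is not None:
        enh, unmapped = map_enhancers_to_genes(enh, enhancer_gene_links)
        if unmapped:
            warnings.warn(f"excluded {unmapped} unmapped enhancer(s)", stacklevel=2)
    common = delta.index.intersection(enh.index)
    if len(common) < 2:
        warnings.warn(
            "fewer than 2 genes with enhancers; returning promoter fit only",
            stacklevel=2,
        )
        return prom_fit, None
    z_enh, _ = standardize_design(enh.loc[common])
    enh_fit = fit_activities(delta.loc[common], z_enh, ridge_lambda, "enhancer")
    return prom_fit, enh_fit


def activity_zscores(
    fit: ActivityFit, z_min: float = 2.0
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cell z = A / SE and the motifs "activated" anywhere (|z| >= z_min).

    Motifs with a zero standard error in any interval are excluded from the
    activated set with a warning (their z is undefined there).
    """
    se = fit.standard_errors
    zero_se = se.index[(se == 0).any(axis=1)]
    if len(zero_se):
        warnings.warn(
            f"zero standard error, z undefined for: {list(zero_se)}", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.activities / se
    z = z.replace([np.inf, -np.inf], np.nan)
    usable = z.drop(index=zero_se)
    activated = list(usable.index[(usable.abs() >= z_min).any(axis=1)])
    return z, activated
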