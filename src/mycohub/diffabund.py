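"""Negative-binomial Wald test for two-group differential abundance.

A deliberately transparent pipeline: median-of-ratios size factors,
method-of-moments per-ASV dispersion pooled within groups, an NB log-link GLM
with a group indicator fit by IRLS at fixed dispersion, a Wald z-test on the
group coefficient, and Benjamini-Hochberg adjustment. No dispersion
shrinkage, outlier refitting or fold-change shrinkage is applied; the
significance rule is padj < 0.01 and |log2FC| > 2 by default. Positive
log2 fold change means more abundant in the second-named group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import AsvCountTable, SampleMetadata

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class DiffAbundResult:
    """Per-ASV records plus the contrast and thresholds used."""

    table: pd.DataFrame  # index asv_id; base_mean, log2fc, se, wald, p, padj, ...
    group1: str
    group2: str
    padj_max: float
    lfc_min: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def direction_counts(self) -> dict[str, int]:
        sig = self.significant()
        return {
            f"up_in_{self.group2}": int((sig["log2fc"] > 0).sum()),
            f"up_in_{self.group1}": int((sig["log2fc"] < 0).sum()),
        }


def size_factors_median_ratios(
    table: AsvCountTable, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    By default ASVs with a zero in any sample are excluded from the
    reference and at least one all-nonzero ASV is required. With
    ``pseudo_reference`` the reference is instead the per-ASV geometric mean
    over the samples where the ASV is present, and each sample's median is
    taken over its own nonzero ASVs — usable when the two groups share no
    ASVs at all (e.g. a cross-species contrast).
    """
    counts = table.counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(counts), np.nan)
        log_ref = np.nanmean(logs, axis=0)  # geometric mean over nonzero samples
        ratios = logs - log_ref[None, :]
        factors = np.exp(np.nanmedian(ratios, axis=1))
        if not np.isfinite(factors).all():
            raise ValueError("a sample has no nonzero ASV; cannot size it")
        return pd.Series(factors, index=table.counts.index, name="size_factor")
    nonzero = (counts > 0).all(axis=0)
    if not nonzero.any():
        raise ValueError(
            "no ASV is nonzero in every sample; cannot form the geometric-mean "
            "reference (set pseudo_reference=True for a presence-restricted one)"
        )
    sub = counts[:, nonzero]
    log_ref = np.log(sub).mean(axis=0)  # per-ASV log geometric mean
    ratios = np.log(sub) - log_ref[None, :]
    factors = np.exp(np.median(ratios, axis=1))
    return pd.Series(factors, index=table.counts.index, name="size_factor")


def estimate_dispersion(
    table: AsvCountTable,
    size_factors: pd.Series,
    groups: pd.Series,
    moderate: bool = True,
) -> pd.Series:
    """Method-of-moments dispersion alpha per ASV, pooled within groups.

    The raw estimate is alpha = (s^2 - m) / m^2 on size-factor-normalized
    counts, df-weighted across groups and floored at 1e-8. With ``moderate``
    (the default) each ASV's dispersion is additionally bounded below by the
    across-ASV mean of the clipped (non-negative) raw estimates — a crude
    common-dispersion moderation that protects the Wald test from the
    anti-conservative bias of per-ASV underestimates. For Poisson-like data
    the common value is ~0 and moderation is nearly a no-op.
    """
    norm = table.counts.div(size_factors, axis=0)
    labels = groups.loc[norm.index]
    weight_total = 0.0
    acc = np.zeros(norm.shape[1])
    for g, sub in norm.groupby(labels):
        n = len(sub)
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        m = sub.mean(axis=0).to_numpy()
        v = sub.var(axis=0, ddof=1).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / m**2, 0.0)
        acc += (n - 1) * np.nan_to_num(a)
        weight_total += n - 1
    alphas = acc / weight_total
    if moderate and alphas.size:
        # common-dispersion lower bound; the mean of the clipped raw
        # estimates is less downward-biased than the median for skewed MoM
        common = float(np.mean(np.maximum(alphas, 0.0)))
        alphas = np.maximum(alphas, common)
    alphas = np.maximum(DISPERSION_FLOOR, alphas)
    return pd.Series(alphas, index=table.counts.columns, name="dispersion")


def _fit_one(
    y: np.ndarray, design: np.ndarray, offset: np.ndarray, alpha: float
) -> tuple[float, float, bool]:
    """NB log-link GLM at fixed dispersion; returns (coef, se, converged)."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
    model = sm.GLM(y, design, family=fam, offset=offset)
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception:  # noqa: BLE001 - any numerical failure marks non-convergence
        return np.nan, np.nan, False
    converged = bool(getattr(res, "converged", True))
    return float(res.params[1]), float(res.bse[1]), converged


def nb_wald_test(
    table: AsvCountTable,
    groups: pd.Series,
    size_factors: pd.Series,
    dispersions: pd.Series,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-ASV Wald test of the group coefficient in an NB log-link GLM.

    log2fc is the group coefficient / ln 2, positive when the second group is
    more abundant. When one group has zero counts for an ASV, the estimate
    falls back to a +0.5 pseudo-fraction contrast of normalized means and the
    record is flagged ``pseudo``.
    """
    labels = groups.loc[table.counts.index]
    uniq = list(group_order) if group_order else sorted(pd.unique(labels))
    if len(pd.unique(labels)) != 2 or len(uniq) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = uniq
    if min((labels == g1).sum(), (labels == g2).sum()) < 2:
        raise ValueError("each group needs at least 2 samples")
    indicator = (labels == g2).to_numpy().astype(float)
    design = np.column_stack([np.ones_like(indicator), indicator])
    sf = size_factors.loc[table.counts.index].to_numpy()
    offset = np.log(sf)
    norm = table.counts.to_numpy(dtype=float) / sf[:, None]
    base_mean = norm.mean(axis=0)
    ln2 = np.log(2.0)
    rows = []
    for j, asv in enumerate(table.counts.columns):
        y = table.counts.iloc[:, j].to_numpy(dtype=float)
        zero_group = (
            y[indicator == 0].sum() == 0 or y[indicator == 1].sum() == 0
        )
        pseudo = False
        if zero_group:
            # +0.5 pseudo-fraction fallback on normalized means
            m1 = norm[indicator == 0, j].mean() + 0.5
            m2 = norm[indicator == 1, j].mean() + 0.5
            coef, se, converged = np.log(m2 / m1), np.nan, True
            pseudo = True
        else:
            coef, se, converged = _fit_one(y, design, offset, dispersions.iloc[j])
        if not converged or not np.isfinite(coef):
            rows.append(
                {"asv_id": asv, "base_mean": base_mean[j], "log2fc": np.nan,
                 "se": np.nan, "wald": np.nan, "p": np.nan,
                 "converged": False, "pseudo": pseudo}
            )
            continue
        log2fc = coef / ln2
        if pseudo or not np.isfinite(se) or se == 0:
            wald, p = np.nan, np.nan
        else:
            wald = coef / se
            from scipy.stats import norm as norm_dist

            p = 2.0 * norm_dist.sf(abs(wald))
        rows.append(
            {"asv_id": asv, "base_mean": base_mean[j], "log2fc": log2fc,
             "se": se / ln2 if np.isfinite(se) else np.nan,
             "wald": wald, "p": p, "converged": converged, "pseudo": pseudo}
        )
    return pd.DataFrame(rows).set_index("asv_id")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def differential_abundance(
    table: AsvCountTable,
    meta: SampleMetadata,
    contrast: tuple[str, str],
    contrast_on: str = "species",
    tissue: str | None = None,
    padj_max: float = 0.01,
    lfc_min: float = 2.0,
) -> DiffAbundResult:
    """Full two-group pipeline: size factors, dispersion, Wald test, BH, thresholds."""
    md = meta.table.loc[[s for s in table.counts.index if s in meta.table.index]]
    if tissue is not None:
        md = md[md["tissue"] == tissue]
    g1, g2 = contrast
    md = md[md[contrast_on].isin([g1, g2])]
    if md.empty:
        raise ValueError("contrast selects no samples")
    sub = table.counts.loc[md.index]
    sub = sub.loc[:, sub.sum(axis=0) > 0]
    sub_table = AsvCountTable(sub.copy())
    groups = md[contrast_on]
    if bool((sub > 0).all(axis=0).any()):
        sf = size_factors_median_ratios(sub_table)
    else:
        logger.warning(
            "no ASV present in every sample; falling back to the "
            "presence-restricted pseudo-reference for size factors"
        )
        sf = size_factors_median_ratios(sub_table, pseudo_reference=True)
    disp = estimate_dispersion(sub_table, sf, groups)
    records = nb_wald_test(sub_table, groups, sf, disp, group_order=(g1, g2))
    records["padj"] = bh_adjust(records["p"].to_numpy())
    records["significant"] = (
        (records["padj"] < padj_max) & (records["log2fc"].abs() > lfc_min)
    ).fillna(False)
    return DiffAbundResult(records, group1=g1, group2=g2,
                           padj_max=padj_max, lfc_min=lfc_min)
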