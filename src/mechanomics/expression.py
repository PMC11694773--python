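"""Strain- and group-stratified expression statistics for spot-level counts.

The count model throughout is the negative binomial with mean/dispersion
parameterisation: a count ``y`` with mean ``mu`` and dispersion ``phi`` has

    Var(y) = mu + phi * mu**2,        r = 1/phi (NB "size").

Spots differ in capture efficiency; per-spot size factors are estimated by
the median-of-ratios method against a geometric-mean pseudo-reference (a
pool-and-deconvolve variant is available for sparse data) and rescaled to
geometric mean one. Differential expression between two spot groups is a
per-gene NB generalised linear model with log link and log-size-factor
offsets; the full model has an intercept and a group term, the null only an
intercept, and significance comes from the likelihood-ratio test against
chi-square(1). Gene-wise dispersions are maximum-likelihood estimates
shrunk toward a log-linear mean-dispersion trend (moderation for small
samples). A gene is called differentially expressed when its BH-adjusted
p-value is below 0.05 *and* its absolute log2 fold change exceeds 0.5.

Two lighter-weight summaries complete the module: a coefficient-of-variation
ranking that surfaces the most consistently expressed genes within a strain
region, and a gene-set score that compares per-gene log2 mean-expression
ratios of a set against the background with a two-sample t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import special, stats

from .errors import (
    DesignError,
    FormatError,
    GroupSizeError,
    NormalizationError,
)

_R_MIN, _R_MAX = 1e-2, 1e8  # NB size bounds (phi in [1e-8, 100])
_MU_FLOOR = 1e-10


@dataclass
class CountMatrix:
    """Genes x spots UMI counts with optional per-spot size factors."""

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    barcodes: list[str]
    size_factors: np.ndarray | None = None

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.barcodes = list(self.barcodes)
        n_genes, n_spots = self.counts.shape
        if n_genes != len(self.gene_ids) or n_spots != len(self.barcodes):
            raise FormatError("count matrix dimensions do not match id lists")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes must be unique")
        dense = self.dense()
        if (dense < 0).any() or not np.allclose(dense, np.round(dense)):
            raise FormatError("counts must be non-negative integers")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if self.size_factors.shape != (n_spots,) or (self.size_factors <= 0).any():
                raise FormatError("size factors must be positive, one per spot")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def normalized(self) -> np.ndarray:
        """Counts divided by size factors (requires estimated factors)."""
        if self.size_factors is None:
            raise NormalizationError("size factors not estimated yet")
        return self.dense() / self.size_factors[None, :]

    def spot_index(self, barcodes) -> np.ndarray:
        col = {b: i for i, b in enumerate(self.barcodes)}
        try:
            return np.array([col[b] for b in barcodes], dtype=int)
        except KeyError as exc:
            raise NormalizationError(f"unknown barcode {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Normalisation


def estimate_size_factors(
    cm: CountMatrix, method: str = "median_ratio", pool_size: int = 8
) -> CountMatrix:
    """Estimate per-spot size factors, rescaled to geometric mean one.

    ``method='median_ratio'``: for each spot, the median over genes (nonzero
    in all spots) of the ratio of its count to the geometric-mean
    pseudo-reference. ``method='pooled'``: ring pools of spots are
    normalised against the average profile and the per-spot factors are
    deconvolved from the pooled ones by least squares — more stable when
    few genes are expressed in every spot.
    """
    mat = cm.dense()
    n_genes, n_spots = mat.shape
    if method == "median_ratio":
        ref_genes = (mat > 0).all(axis=1)
        if not ref_genes.any():
            raise NormalizationError(
                "no gene is expressed in every spot; try method='pooled'"
            )
        logs = np.log(mat[ref_genes])
        log_ref = logs.mean(axis=1)
        sf = np.exp(np.median(logs - log_ref[:, None], axis=0))
    elif method == "pooled":
        if n_spots < 2:
            raise NormalizationError("pooled estimation needs >= 2 spots")
        lib = mat.sum(axis=0)
        if (lib == 0).any():
            raise NormalizationError("spot with zero total counts")
        order = np.argsort(lib)
        pseudo = mat.mean(axis=1)
        rows, targets = [], []
        sizes = {min(pool_size, n_spots), max(min(pool_size, n_spots) // 2, 2)}
        for size in sorted(sizes):
            for start in range(n_spots):
                members = order[(start + np.arange(size)) % n_spots]
                pooled = mat[:, members].sum(axis=1)
                ok = (pooled > 0) & (pseudo > 0)
                if not ok.any():
                    raise NormalizationError("pool shares no genes with reference")
                factor = np.median(pooled[ok] / pseudo[ok])
                row = np.zeros(n_spots)
                row[members] = 1.0
                rows.append(row)
                targets.append(factor)
        # Low-weight per-spot anchor rows pin the components the smooth ring
        # pools determine poorly, without reintroducing single-spot noise.
        anchor_w = 0.1
        for s in range(n_spots):
            ok = (mat[:, s] > 0) & (pseudo > 0)
            if ok.any():
                row = np.zeros(n_spots)
                row[s] = anchor_w
                rows.append(row)
                targets.append(anchor_w * np.median(mat[ok, s] / pseudo[ok]))
        a = np.asarray(rows)
        b = np.asarray(targets)
        sf, *_ = np.linalg.lstsq(a, b, rcond=None)
        if (sf <= 0).any():
            raise NormalizationError("deconvolved a non-positive size factor")
    else:
        raise NormalizationError(f"unknown method {method!r}")
    sf = sf / np.exp(np.mean(np.log(sf)))
    return replace(cm, size_factors=sf)


def filter_low_expression(
    cm: CountMatrix, min_total: int = 10, min_frac_detected: float = 0.05
) -> np.ndarray:
    """Gene eligibility flags for DE testing (both thresholds inclusive).

    A gene is eligible iff its total count is >= ``min_total`` and it is
    detected (count > 0) in at least ``min_frac_detected`` of spots.
    """
    mat = cm.dense()
    total = mat.sum(axis=1)
    frac = (mat > 0).mean(axis=1)
    return (total >= min_total) & (frac >= min_frac_detected - 1e-12)


# ---------------------------------------------------------------------------
# Negative-binomial likelihood machinery (vectorised over genes)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """NB log-likelihood summed over spots, per gene. y, mu: (G, S); r: (G,)."""
    mu = np.maximum(mu, _MU_FLOOR)
    rr = r[:, None]
    return (
        special.gammaln(y + rr)
        - special.gammaln(rr)
        - special.gammaln(y + 1.0)
        + rr * np.log(rr / (rr + mu))
        + y * np.log(mu / (rr + mu))
    ).sum(axis=1)


def _fit_group_mean(
    y: np.ndarray, sf: np.ndarray, r: np.ndarray, max_iter: int = 60, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of the NB group mean with size-factor offsets, per gene.

    Solves sum_s r (y - mu_s) / (r + mu_s) = 0 for mu_s = sf_s * m by Newton
    iteration on theta = log m (the score is monotone in theta). Returns the
    fitted means m (G,) and a convergence flag per gene.
    """
    y = np.asarray(y, float)
    total = y.sum(axis=1)
    theta = np.log(np.maximum(total, 0.5) / sf.sum())
    converged = np.zeros(len(y), dtype=bool)
    rr = r[:, None]
    for _ in range(max_iter):
        mu = np.maximum(sf[None, :] * np.exp(theta)[:, None], _MU_FLOOR)
        score = (rr * (y - mu) / (rr + mu)).sum(axis=1)
        info = (rr * mu * (rr + y) / (rr + mu) ** 2).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        theta = theta + step
        converged |= np.abs(step) < tol
        if converged.all():
            break
    # All-zero groups drive theta to -inf; clamp to a tiny positive mean.
    theta = np.maximum(theta, np.log(_MU_FLOOR))
    converged |= total == 0
    return np.exp(theta), converged


def _fit_dispersion(
    y: np.ndarray, mu: np.ndarray, r0: np.ndarray, max_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene ML dispersion given fitted means, Newton on log r.

    Returns NB sizes r (G,) clipped to the admissible range and a flag per
    gene; genes whose Newton stalls keep their method-of-moments start.
    """
    mu = np.maximum(mu, _MU_FLOOR)
    t = np.log(np.clip(r0, _R_MIN, _R_MAX))
    converged = np.zeros(len(y), dtype=bool)
    for _ in range(max_iter):
        r = np.exp(t)[:, None]
        g = (
            special.digamma(y + r)
            - special.digamma(r)
            + np.log(r)
            - np.log(r + mu)
            + (mu - y) / (r + mu)
        ).sum(axis=1)
        h = (
            special.polygamma(1, y + r)
            - special.polygamma(1, r)
            + 1.0 / r
            - 1.0 / (r + mu)
            + (y - mu) / (r + mu) ** 2
        ).sum(axis=1)
        rf = np.exp(t)
        g_t = rf * g
        h_t = rf**2 * h + rf * g
        step = np.where(h_t < 0, -g_t / np.where(h_t < 0, h_t, -1.0), np.sign(g_t) * 0.5)
        step = np.clip(step, -2.0, 2.0)
        hit_bound = ((t >= np.log(_R_MAX)) & (step > 0)) | (
            (t <= np.log(_R_MIN)) & (step < 0)
        )
        step = np.where(hit_bound, 0.0, step)
        t = np.clip(t + step, np.log(_R_MIN), np.log(_R_MAX))
        converged |= (np.abs(step) < tol) | hit_bound
        if converged.all():
            break
    return np.exp(t), converged


def _mom_dispersion(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion phi = sum((y-mu)^2 - mu) / sum(mu^2)."""
    mu = np.maximum(mu, _MU_FLOOR)
    phi = ((y - mu) ** 2 - mu).sum(axis=1) / (mu**2).sum(axis=1)
    return np.clip(phi, 1.0 / _R_MAX, 1.0 / _R_MIN)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def nb_lrt_de(
    cm: CountMatrix,
    group_labels,
    eligibility: np.ndarray | None = None,
    *,
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 0.5,
    prior_df: float = 10.0,
    n_outer: int = 3,
    groups: tuple | None = None,
) -> pd.DataFrame:
    """NB likelihood-ratio differential expression between two spot groups.

    Per eligible gene: fit the NB GLM with log link and log-size-factor
    offsets under the full model (per-group means) and the null model
    (common mean); estimate the gene-wise dispersion by alternating maximum
    likelihood and shrink it toward a log-linear mean-dispersion trend with
    ``prior_df`` pseudo-observations; the deviance difference is referred to
    chi-square(1). Log2 fold changes are ratios of fitted group means
    (group2 over group1; ``groups=(group1, group2)`` sets the contrast
    orientation, defaulting to sorted label order); no fold-change
    shrinkage is applied. BH adjustment runs over eligible, converged genes
    and a gene is flagged ``is_deg`` when ``fdr < fdr_cutoff`` and
    ``|log2fc| > lfc_cutoff``.

    Returns a DataFrame with one row per gene of the matrix (including
    filtered genes, flagged and never called).
    """
    labels = np.asarray(group_labels)
    if labels.shape != (cm.shape[1],):
        raise DesignError("need one group label per spot")
    uniq = _resolve_groups(labels, groups)
    idx1 = np.flatnonzero(labels == uniq[0])
    idx2 = np.flatnonzero(labels == uniq[1])
    if len(idx1) < 2 or len(idx2) < 2:
        raise DesignError("each group needs at least 2 spots")

    if cm.size_factors is None:
        cm = estimate_size_factors(cm)
    sf = cm.size_factors
    if eligibility is None:
        eligibility = filter_low_expression(cm)
    eligibility = np.asarray(eligibility, dtype=bool)

    mat = cm.dense()
    y = mat[eligibility]
    y1, y2 = y[:, idx1], y[:, idx2]
    sf1, sf2 = sf[idx1], sf[idx2]
    n_el, n_spots = y.shape

    # Alternate mean and dispersion fits.
    m_null, _ = _fit_group_mean(y, sf, np.full(n_el, 1.0 / 0.1))
    mu0 = sf[None, :] * m_null[:, None]
    r = 1.0 / _mom_dispersion(y, mu0)
    ok = np.ones(n_el, dtype=bool)
    for _ in range(n_outer):
        m1, c1 = _fit_group_mean(y1, sf1, r)
        m2, c2 = _fit_group_mean(y2, sf2, r)
        mu = np.empty_like(y)
        mu[:, idx1] = sf1[None, :] * m1[:, None]
        mu[:, idx2] = sf2[None, :] * m2[:, None]
        r, cd = _fit_dispersion(y, mu, r)
        ok &= c1 & c2

    # Trend shrinkage: log phi ~ a + b log(base mean), moderated average.
    base_mean = (y / sf[None, :]).mean(axis=1)
    phi = 1.0 / r
    interior = (phi > 1.05 / _R_MAX) & (phi < 0.95 / _R_MIN) & (base_mean > 0)
    log_phi = np.log(phi)
    if interior.sum() >= 10:
        x = np.log(base_mean[interior])
        coef = np.polyfit(x, log_phi[interior], 1)
        trend = np.polyval(coef, np.log(np.maximum(base_mean, _MU_FLOOR)))
    else:
        trend = np.full(n_el, np.median(log_phi))
    df_resid = max(n_spots - 2, 1)
    log_phi_shrunk = (df_resid * log_phi + prior_df * trend) / (df_resid + prior_df)
    r = np.clip(1.0 / np.exp(log_phi_shrunk), _R_MIN, _R_MAX)

    # Final fits and LRT with the moderated dispersions.
    m1, c1 = _fit_group_mean(y1, sf1, r)
    m2, c2 = _fit_group_mean(y2, sf2, r)
    m0, c0 = _fit_group_mean(y, sf, r)
    ok &= c1 & c2 & c0
    ll_full = _nb_loglik(y1, sf1[None, :] * m1[:, None], r) + _nb_loglik(
        y2, sf2[None, :] * m2[:, None], r
    )
    ll_null = _nb_loglik(y, sf[None, :] * m0[:, None], r)
    dev = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pval = stats.chi2.sf(dev, df=1)
    pval[~ok] = np.nan
    lfc = np.log2(np.maximum(m2, _MU_FLOOR) / np.maximum(m1, _MU_FLOOR))
    fdr = bh_adjust(pval)

    out = pd.DataFrame(
        {
            "gene": cm.gene_ids,
            "filtered": ~eligibility,
            "base_mean": np.nan,
            "log2fc": np.nan,
            "lrt_stat": np.nan,
            "pvalue": np.nan,
            "fdr": np.nan,
            "dispersion": np.nan,
            "converged": False,
            "is_deg": False,
        }
    )
    el = np.flatnonzero(eligibility)
    out.loc[el, "base_mean"] = base_mean
    out.loc[el, "log2fc"] = lfc
    out.loc[el, "lrt_stat"] = dev
    out.loc[el, "pvalue"] = pval
    out.loc[el, "fdr"] = fdr
    out.loc[el, "dispersion"] = 1.0 / r
    out.loc[el, "converged"] = ok
    with pd.option_context("mode.chained_assignment", None):
        call = (out["fdr"] < fdr_cutoff) & (out["log2fc"].abs() > lfc_cutoff)
    out["is_deg"] = call.fillna(False) & ~out["filtered"] & out["converged"]
    out.attrs["groups"] = (str(uniq[0]), str(uniq[1]))
    return out


def _resolve_groups(labels: np.ndarray, groups: tuple | None) -> np.ndarray:
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise DesignError(f"exactly two groups required, got {list(uniq)}")
    if groups is None:
        return uniq
    if sorted(map(str, groups)) != sorted(map(str, uniq)):
        raise DesignError(f"groups {groups} do not match labels {list(uniq)}")
    return np.asarray(groups)


# ---------------------------------------------------------------------------
# CV ranking and gene-set scoring


def cv_ranking(
    cm: CountMatrix,
    region_barcodes,
    top_k: int | None = 25,
    min_detect_frac: float = 0.5,
    ascending: bool = True,
) -> pd.DataFrame:
    """Rank genes within a region by coefficient of variation.

    On size-factor-normalised counts restricted to the region's spots,
    ``cv = sd / mean`` (sample sd) is computed for genes detected in at
    least ``min_detect_frac`` of the region's spots; genes with zero mean
    are excluded. The default ranking is ascending (rank 1 = most
    consistently expressed); ties break by higher mean, then gene id.
    """
    idx = cm.spot_index(region_barcodes)
    if len(idx) < 3:
        raise GroupSizeError(f"region has {len(idx)} spots; need >= 3")
    if cm.size_factors is None:
        cm = estimate_size_factors(cm)
    norm = cm.normalized()[:, idx]
    detect = (norm > 0).mean(axis=1)
    mean = norm.mean(axis=1)
    keep = (detect >= min_detect_frac - 1e-12) & (mean > 0)
    sd = norm.std(axis=1, ddof=1)
    cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    tab = pd.DataFrame(
        {
            "gene": np.asarray(cm.gene_ids)[keep],
            "mean": mean[keep],
            "sd": sd[keep],
            "cv": cv[keep],
        }
    )
    tab = tab.sort_values(
        ["cv", "mean", "gene"], ascending=[ascending, False, True]
    ).reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    if top_k is not None:
        tab = tab.head(top_k).reset_index(drop=True)
    return tab


def gene_set_score(
    cm: CountMatrix,
    group_labels,
    gene_sets: dict[str, list[str]],
    *,
    pseudocount: float = 0.5,
    groups: tuple | None = None,
) -> pd.DataFrame:
    """Score gene sets on log2 mean-expression ratios between two groups.

    Per gene, ``r_g = log2((mean normalised expression in group2 + c) /
    (mean in group1 + c))`` with pseudo-count ``c`` (``groups=(group1,
    group2)`` fixes the orientation, defaulting to sorted label order); per set, the two-sample
    t statistic (Welch) of member ratios against non-member ratios, with a
    two-sided p-value, BH adjustment across sets, and a direction given by
    the sign of the set-vs-background mean difference. Sets with fewer than
    2 genes present are skipped with a warning.
    """
    labels = np.asarray(group_labels)
    uniq = _resolve_groups(labels, groups)
    if cm.size_factors is None:
        cm = estimate_size_factors(cm)
    norm = cm.normalized()
    mean1 = norm[:, labels == uniq[0]].mean(axis=1)
    mean2 = norm[:, labels == uniq[1]].mean(axis=1)
    ratios = np.log2((mean2 + pseudocount) / (mean1 + pseudocount))
    gene_pos = {g: i for i, g in enumerate(cm.gene_ids)}

    rows = []
    for name, members in gene_sets.items():
        pos = [gene_pos[g] for g in members if g in gene_pos]
        if len(pos) < 2:
            warnings.warn(f"gene set {name!r} has <2 genes present; skipped")
            continue
        in_set = np.zeros(len(ratios), dtype=bool)
        in_set[pos] = True
        res = stats.ttest_ind(ratios[in_set], ratios[~in_set], equal_var=False)
        diff = ratios[in_set].mean() - ratios[~in_set].mean()
        rows.append(
            {
                "set": name,
                "n_genes": int(in_set.sum()),
                "stat": float(res.statistic),
                "pvalue": float(res.pvalue),
                "direction": "up" if diff > 0 else "down",
            }
        )
    out = pd.DataFrame(rows, columns=["set", "n_genes", "stat", "pvalue", "direction"])
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    out.attrs["groups"] = (str(uniq[0]), str(uniq[1]))
    return out
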