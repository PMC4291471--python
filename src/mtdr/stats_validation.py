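"""Validation statistics for the MTDR index.

Implements the statistical protocols used to validate the index:

* Spearman correlation (Pearson on average ranks, p from the
  t-approximation) and first-order partial Spearman correlation
  (partial Pearson on ranks, controlling for a third variable).
* The protein-abundance regression PA~ = c + w1*MTDR + w2*tAI + w3*CAI
  with 95% coefficient confidence intervals; a coefficient "contributes"
  when its CI excludes zero.
* Held-out ribosomal-load prediction: estimate decoding times on a
  random half of the filtered (highly expressed) genes, score the other
  half, and correlate MTDR with mean footprint count.
* Two-condition comparison: Spearman of per-gene MTDR ratios against
  ribosomal-load ratios, plus t and Wilcoxon rank-sum tests comparing
  MTDR ratios of the top vs bottom load-ratio quantile groups.

Raw p-values are reported throughout (no multiple-testing correction by
default); :func:`benjamini_hochberg` is available for users who want one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .emg_model import FitOptions, fit_codon_table
from .io_formats import GeneProfile, ORFRecord
from .mtdr_index import rates_from_times, score_batch
from .preprocess import FilterConfig, build_nfc_table, filter_genes

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "ConditionComparison",
    "spearman",
    "partial_spearman",
    "fit_pa_regression",
    "ribosomal_load_validation",
    "condition_comparison",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    kind: str = "spearman"
    defined: bool = True
    note: str = ""


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of PA~ = c + w1*MTDR + w2*tAI + w3*CAI."""

    coefficients: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    contributes: dict[str, bool]
    n: int
    r2: float


def _ranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        return float("nan")
    return float(xc @ yc) / denom


def _t_pvalue(rho: float, n: int, df: int | None = None) -> float:
    df = (n - 2) if df is None else df
    if df < 1 or not math.isfinite(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rho as Pearson correlation of average ranks; two-sided p
    from the t-approximation with n-2 df. A constant input vector yields
    an undefined (flagged) result instead of an exception."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rho = _pearson(_ranks(x), _ranks(y))
    if not math.isfinite(rho):
        return CorrelationResult(float("nan"), float("nan"), x.size,
                                 defined=False, note="constant input vector")
    return CorrelationResult(rho, _t_pvalue(rho, x.size), x.size)


def partial_spearman(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> CorrelationResult:
    """Partial Spearman correlation of x and y given z: rank all three,
    then apply the first-order partial-Pearson formula
    (r_xy - r_xz*r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)). Degenerate when
    |r_xz| or |r_yz| is 1 (flagged, not raised). p uses n-3 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be 1-D and equal length")
    if x.size < 4:
        raise ValueError("need n >= 4")
    rx, ry, rz = _ranks(x), _ranks(y), _ranks(z)
    r_xy, r_xz, r_yz = _pearson(rx, ry), _pearson(rx, rz), _pearson(ry, rz)
    if any(not math.isfinite(r) for r in (r_xy, r_xz, r_yz)):
        return CorrelationResult(float("nan"), float("nan"), x.size,
                                 kind="partial_spearman", defined=False,
                                 note="constant input vector")
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        return CorrelationResult(float("nan"), float("nan"), x.size,
                                 kind="partial_spearman", defined=False,
                                 note="control variable collinear with x or y")
    rho = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    return CorrelationResult(rho, _t_pvalue(rho, x.size, df=x.size - 3),
                             x.size, kind="partial_spearman")


def fit_pa_regression(
    pa: Sequence[float],
    mtdr: Sequence[float],
    tai: Sequence[float],
    cai: Sequence[float],
) -> RegressionResult:
    """OLS of protein abundance on (MTDR, tAI, CAI) with intercept c;
    95% CIs from the t-distribution with n-4 df. Raises on a
    rank-deficient design (reporting its condition number)."""
    arrays = [np.asarray(v, dtype=float) for v in (pa, mtdr, tai, cai)]
    if len({a.shape for a in arrays}) != 1 or arrays[0].ndim != 1:
        raise ValueError("all inputs must be 1-D and equal length")
    mask = np.all(np.isfinite(np.vstack(arrays)), axis=0)
    pa_v, mtdr_v, tai_v, cai_v = (a[mask] for a in arrays)
    n = int(pa_v.size)
    if n <= 10:
        raise ValueError(f"need more than 10 complete cases, got {n}")
    design = np.column_stack([np.ones(n), mtdr_v, tai_v, cai_v])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        cond = np.linalg.cond(design)
        raise ValueError(
            f"rank-deficient design (rank {rank} < 4, condition number {cond:.3g})"
        )
    res = sm.OLS(pa_v, design).fit()
    names = ("c", "w1", "w2", "w3")
    ci = res.conf_int(alpha=0.05)
    coefficients = dict(zip(names, map(float, res.params)))
    ci95 = {name: (float(ci[i][0]), float(ci[i][1])) for i, name in enumerate(names)}
    contributes = {name: (lo > 0 or hi < 0) for name, (lo, hi) in ci95.items()}
    return RegressionResult(coefficients, ci95, contributes, n, float(res.rsquared))


def ribosomal_load_validation(
    profiles: Sequence[GeneProfile],
    orfs: Sequence[ORFRecord],
    cfg: FilterConfig | None = None,
    split_seed: int = 0,
    fit_options: FitOptions | None = None,
    min_genes_per_half: int = 10,
    shuffle_loads: bool = False,
) -> CorrelationResult:
    """Held-out prediction of ribosomal load.

    Genes passing the gene filter (the operational definition of "highly
    expressed") are split 50/50 with a seeded permutation; codon decoding
    times are estimated on half A, the MTDR of half B's ORFs is scored
    against half B's mean footprint count with a Spearman correlation.
    ``shuffle_loads=True`` permutes half B's load vector (null control).
    """
    cfg = cfg or FilterConfig()
    kept, _ = filter_genes(profiles, cfg)
    if len(kept) < 2 * min_genes_per_half:
        raise ValueError(
            f"need at least {2 * min_genes_per_half} genes passing the filter, got {len(kept)}"
        )
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(kept))
    half = len(kept) // 2
    half_a = [kept[i] for i in order[:half]]
    half_b = [kept[i] for i in order[half:]]

    table, _ = build_nfc_table(half_a, orfs, cfg)
    fits = fit_codon_table(table.arrays(), fit_options)
    rate_table = rates_from_times(fits)

    orf_map = {o.gene_id: o for o in orfs}
    scorable = [p for p in half_b if p.gene_id in orf_map]
    scores = score_batch([orf_map[p.gene_id] for p in scorable], rate_table, policy="skip")
    pairs = [
        (s.mtdr, float(np.mean(p.counts)))
        for s, p in zip(scores, scorable)
        if math.isfinite(s.mtdr)
    ]
    if len(pairs) < min_genes_per_half:
        raise ValueError("too few scorable held-out genes")
    mtdr_b = np.array([v for v, _ in pairs])
    load_b = np.array([v for _, v in pairs])
    if shuffle_loads:
        load_b = rng.permutation(load_b)
    return spearman(mtdr_b, load_b)


@dataclass
class ConditionComparison:
    """Two-condition comparison report."""

    ratio_correlation: CorrelationResult
    t_p: float
    wilcoxon_p: float
    n: int
    n_top: int
    n_bottom: int
    degenerate: bool = False
    note: str = ""


def condition_comparison(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    load_a: Mapping[str, float],
    load_b: Mapping[str, float],
    q: float = 0.30,
) -> ConditionComparison:
    """Compare two conditions via per-gene MTDR and load ratios.

    On the genes present with positive values in all four tables,
    computes Spearman(MTDR_A/MTDR_B, load_A/load_B) and compares the
    MTDR ratios of the top-q vs bottom-q genes ranked by load ratio with
    a two-sample t test and a Wilcoxon rank-sum test (normal
    approximation with continuity correction).
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must be in (0, 0.5]")
    genes = sorted(
        g
        for g in set(scores_a) & set(scores_b) & set(load_a) & set(load_b)
        if scores_a[g] > 0 and scores_b[g] > 0 and load_a[g] > 0 and load_b[g] > 0
    )
    n = len(genes)
    if n < 10:
        raise ValueError(f"need at least 10 shared genes with positive values, got {n}")
    mtdr_ratio = np.array([scores_a[g] / scores_b[g] for g in genes])
    load_ratio = np.array([load_a[g] / load_b[g] for g in genes])

    corr = spearman(mtdr_ratio, load_ratio)
    order = np.argsort(load_ratio, kind="stable")
    n_bottom = int(math.floor(q * n))
    n_top = int(math.ceil(q * n))
    bottom = mtdr_ratio[order[:n_bottom]]
    top = mtdr_ratio[order[n - n_top :]]

    if np.ptp(mtdr_ratio) == 0 or (np.ptp(top) == 0 and np.ptp(bottom) == 0
                                   and top[0] == bottom[0]):
        return ConditionComparison(
            ratio_correlation=corr, t_p=1.0, wilcoxon_p=1.0,
            n=n, n_top=n_top, n_bottom=n_bottom,
            degenerate=True, note="identical group distributions",
        )
    t_p = float(sps.ttest_ind(top, bottom, equal_var=False).pvalue)
    w_p = float(
        sps.mannwhitneyu(top, bottom, alternative="two-sided", method="asymptotic").pvalue
    )
    return ConditionComparison(
        ratio_correlation=corr, t_p=t_p, wilcoxon_p=w_p,
        n=n, n_top=n_top, n_bottom=n_bottom,
    )


def benjamini_hochberg(pvalues: Sequence[float], alpha: float = 0.05):
    """BH-adjusted q-values and rejection flags (off by default everywhere)."""
    reject, qvals, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return qvals, reject
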