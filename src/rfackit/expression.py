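"""Microarray expression statistics: probe filtering, multivariate
permutation tests with FDR-and-confidence control, pairwise t-tests with
fold-change gates, and quantitative-trait correlation screens.

The significance machinery controls the false discovery *proportion* with
stated confidence rather than its expectation: genes are ranked by p-value
and, for a candidate list of size k with p-value cutoff p(k), the permutation
distribution of the number of null genes falling below p(k) estimates the
false-discovery count; the procedure returns the largest k whose estimated
false-discovery proportion is below the FDR bound in at least a ``conf``
fraction of permutations (e.g. FDR < 10% with 80% confidence).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "ExpressionMatrix",
    "FilterAudit",
    "PermTestResult",
    "filter_probes",
    "multivariate_permutation_f",
    "pairwise_fc_filter",
    "quantitative_trait_corr",
    "read_series_matrix",
]


@dataclass
class ExpressionMatrix:
    """Probes x samples intensities with annotation.

    ``intensity``: DataFrame (index probe IDs, columns sample IDs) on the
    post-normalization linear scale (non-negative); ``genes``: probe -> gene
    symbol; ``classes``: sample -> class label; ``trait``: optional numeric
    per-sample trait (e.g. ipRFAC).
    """

    intensity: pd.DataFrame
    genes: pd.Series
    classes: pd.Series
    trait: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        missing = set(self.intensity.columns) - set(self.classes.index)
        if missing:
            raise ValueError(f"samples without class labels: {sorted(missing)}")
        if self.trait is not None:
            missing = set(self.intensity.columns) - set(self.trait.index)
            if missing:
                raise ValueError(f"samples without trait values: {sorted(missing)}")

    @property
    def n_probes(self) -> int:
        return self.intensity.shape[0]

    @property
    def samples(self):
        return list(self.intensity.columns)

    def subset(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensity=self.intensity.loc[probes],
            genes=self.genes.loc[probes],
            classes=self.classes,
            trait=self.trait,
            metadata=self.metadata,
        )


def read_series_matrix(path, classes: pd.Series | None = None,
                       genes: pd.Series | None = None,
                       trait: pd.Series | None = None) -> ExpressionMatrix:
    """Read a GEO series-matrix style TSV (metadata lines start with '!')."""
    df = pd.read_csv(path, sep="\t", comment="!", index_col=0)
    if classes is None:
        classes = pd.Series("unknown", index=df.columns)
    if genes is None:
        genes = pd.Series(df.index, index=df.index)
    return ExpressionMatrix(intensity=df, genes=genes, classes=classes, trait=trait)


@dataclass
class FilterAudit:
    """Per-rule record of the probe filter."""

    n_input: int
    n_after_intensity: int
    n_after_variance: int
    n_after_collapse: int
    sigma0: float  # null log2-variance used by the variance test
    dropped_intensity: list = field(default_factory=list)
    dropped_variance: list = field(default_factory=list)


def filter_probes(
    m: ExpressionMatrix,
    intensity_cut: float = 125.0,
    pct: float = 33.0,
    logvar_alpha: float = 0.05,
    sigma0: float | None = None,
    drop_unannotated: bool = False,
) -> tuple:
    """Three-rule probe filter; returns (filtered matrix, audit).

    (a) a probe is excluded when the ``pct``-th percentile of its intensities
    falls below ``intensity_cut`` (below-detection probes); (b) a probe is
    excluded when a chi-square test of its log2-intensity variance against
    the median probe variance gives p > ``logvar_alpha`` (uninformative, flat
    probes); (c) multiple probes per gene symbol collapse to the one with the
    largest interquartile range.  ``sigma0`` overrides the null variance of
    rule (b) (by default the median over the input matrix; reuse the audit's
    value to make refiltering a no-op).  Unannotated probes are retained
    under their probe ID unless ``drop_unannotated``.
    """
    x = m.intensity.to_numpy(dtype=float)
    n = x.shape[1]
    # (a) percentile-intensity rule
    p33 = np.percentile(x, pct, axis=1)
    keep_a = p33 >= intensity_cut
    # (b) log-variation rule: variance above the typical (median) probe
    logx = np.log2(np.maximum(x, 1e-12))
    s2 = logx.var(axis=1, ddof=1)
    if sigma0 is None:
        sigma0 = float(np.median(s2))
    if sigma0 <= 0:
        raise ValueError("null variance sigma0 must be positive")
    stat = (n - 1) * s2 / sigma0
    p_var = sps.chi2.sf(stat, df=n - 1)
    keep_b = p_var <= logvar_alpha
    keep = keep_a & keep_b
    probes = m.intensity.index
    dropped_a = list(probes[~keep_a])
    dropped_b = list(probes[keep_a & ~keep_b])
    kept = probes[keep]
    # (c) collapse to the most-variable probe per gene symbol
    gene_of = m.genes.reindex(kept)
    if drop_unannotated:
        kept = kept[gene_of.notna().to_numpy()]
        gene_of = gene_of.loc[kept]
    gene_of = gene_of.fillna(pd.Series(kept, index=kept))
    iqr = pd.Series(
        sps.iqr(m.intensity.loc[kept].to_numpy(dtype=float), axis=1), index=kept
    )
    order = pd.DataFrame({"gene": gene_of, "iqr": iqr}).sort_values(
        ["gene", "iqr"], ascending=[True, False], kind="mergesort"
    )
    winners = order.groupby("gene", sort=False).head(1).index
    out = m.subset(winners)
    audit = FilterAudit(
        n_input=len(probes),
        n_after_intensity=int(keep_a.sum()),
        n_after_variance=int(keep.sum()),
        n_after_collapse=len(winners),
        sigma0=sigma0,
        dropped_intensity=dropped_a,
        dropped_variance=dropped_b,
    )
    return out, audit


# ---------------------------------------------------------------------------
# FDR-with-confidence permutation machinery


@dataclass
class PermTestResult:
    """Outcome of an FDR-with-confidence permutation screen."""

    genes: list  # selected gene symbols, ranked by p
    stats: pd.DataFrame  # per gene: statistic, p (and r for trait mode)
    k: int  # selected list size
    cutoff: float  # p-value cutoff of the selected list (NaN if empty)
    n_perm_used: int
    exhaustive: bool


def _select_list_size(p_obs_sorted: np.ndarray, perm_p: np.ndarray,
                      fdr: float, conf: float) -> int:
    """Largest k whose false-discovery proportion is <= fdr with prob >= conf.

    ``perm_p`` holds the per-permutation null p-values (B x G); for cutoff
    p(k) the false-discovery count in permutation b is the number of its
    p-values <= p(k).
    """
    perm_sorted = np.sort(perm_p, axis=1)
    n_b, n_g = perm_sorted.shape
    counts = np.empty((n_b, p_obs_sorted.size), dtype=np.int64)
    for b in range(n_b):
        counts[b] = np.searchsorted(perm_sorted[b], p_obs_sorted, side="right")
    for k in range(p_obs_sorted.size, 0, -1):
        ok = np.mean(counts[:, k - 1] <= fdr * k)
        if ok >= conf:
            return k
    return 0


def _f_pvalues(x: np.ndarray, labels: np.ndarray) -> tuple:
    """Vectorized one-way F statistic and p per row of ``x``."""
    groups = np.unique(labels)
    n = x.shape[1]
    grand = x.mean(axis=1, keepdims=True)
    ss_b = np.zeros(x.shape[0])
    ss_w = np.zeros(x.shape[0])
    for g in groups:
        sel = x[:, labels == g]
        mg = sel.mean(axis=1, keepdims=True)
        ss_b += sel.shape[1] * (mg[:, 0] - grand[:, 0]) ** 2
        ss_w += ((sel - mg) ** 2).sum(axis=1)
    df_b = groups.size - 1
    df_w = n - groups.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_b / df_b) / (ss_w / df_w)
    p = sps.f.sf(f, df_b, df_w)
    p = np.where(np.isfinite(f), p, 0.0)  # infinite F => p -> 0
    return f, p


def _class_permutations(labels: np.ndarray, n_perm: int, rng) -> tuple:
    """Label permutations: exhaustive when the multiset space is small."""
    total = math.factorial(labels.size)
    for _, cnt in zip(*np.unique(labels, return_counts=True)):
        total //= math.factorial(cnt)
    if total <= n_perm:
        perms = np.array(list(multiset_permutations(list(labels))))
        return perms, True
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    return perms, False


def multivariate_permutation_f(
    m: ExpressionMatrix,
    fdr: float = 0.10,
    conf: float = 0.80,
    n_perm: int = 1000,
    seed: int | None = None,
    log_transform: bool = True,
) -> PermTestResult:
    """Class-comparison screen controlling the FDP with confidence.

    Per-gene one-way F p-values across the sample classes are ranked; class
    labels are permuted (exhaustively when the label multiset admits at most
    ``n_perm`` distinct arrangements, otherwise ``n_perm`` random draws) and
    the largest list whose false-discovery proportion stays below ``fdr``
    with probability >= ``conf`` is returned.
    """
    labels = m.classes.reindex(m.intensity.columns).to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 classes with >= 2 samples each")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse confidence estimate")
    x = m.intensity.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(np.maximum(x, 1e-12))
    f_obs, p_obs = _f_pvalues(x, labels)
    order = np.argsort(p_obs, kind="mergesort")
    rng = np.random.default_rng(seed)
    perms, exhaustive = _class_permutations(labels, n_perm, rng)
    perm_p = np.empty((perms.shape[0], x.shape[0]))
    for b, lab in enumerate(perms):
        perm_p[b] = _f_pvalues(x, lab)[1]
    k = _select_list_size(p_obs[order], perm_p, fdr, conf)
    sel = order[:k]
    genes = list(m.genes.reindex(m.intensity.index).iloc[sel])
    table = pd.DataFrame(
        {"gene": m.genes.reindex(m.intensity.index).to_numpy(),
         "F": f_obs, "p": p_obs},
        index=m.intensity.index,
    )
    return PermTestResult(
        genes=genes, stats=table, k=k,
        cutoff=float(p_obs[order[k - 1]]) if k else float("nan"),
        n_perm_used=perms.shape[0], exhaustive=exhaustive,
    )


def pairwise_fc_filter(
    m: ExpressionMatrix,
    comparisons=(("MI", "sham"), ("MI", "MI+Val")),
    alpha: float = 0.01,
    fc: float = 1.2,
    direction_comparison: tuple = ("MI+Val", "MI"),
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise t-tests with a signed fold-change gate.

    For each comparison (A, B) a two-sample t-test is run per gene (on log2
    intensities by default) together with the signed linear-scale fold change
    mean(A)/mean(B) (folded to -mean(B)/mean(A) when below 1).  A gene
    survives when p < ``alpha`` and |FC| >= ``fc`` in at least one
    comparison.  The returned frame has per-comparison p and FC columns, a
    ``significant`` flag, and an up/down ``direction`` in the
    ``direction_comparison`` sense (default: MI+Val relative to MI).
    """
    if fc < 1:
        raise ValueError("fold-change threshold must be >= 1")
    labels = m.classes.reindex(m.intensity.columns).to_numpy()
    x_lin = m.intensity.to_numpy(dtype=float)
    x_t = np.log2(np.maximum(x_lin, 1e-12)) if log_transform else x_lin

    def signed_fc(a_mean, b_mean):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = a_mean / b_mean
        return np.where(ratio >= 1.0, ratio, -1.0 / ratio)

    out = pd.DataFrame(index=m.intensity.index)
    out["gene"] = m.genes.reindex(m.intensity.index).to_numpy()
    gate = np.zeros(x_lin.shape[0], dtype=bool)
    for a, b in comparisons:
        sel_a, sel_b = labels == a, labels == b
        if sel_a.sum() < 2 or sel_b.sum() < 2:
            raise ValueError(f"comparison ({a}, {b}) lacks samples")
        _, p = sps.ttest_ind(x_t[:, sel_a], x_t[:, sel_b], axis=1)
        fc_ab = signed_fc(x_lin[:, sel_a].mean(axis=1), x_lin[:, sel_b].mean(axis=1))
        out[f"p {a} vs {b}"] = p
        out[f"FC {a} vs {b}"] = fc_ab
        gate |= (p < alpha) & (np.abs(fc_ab) >= fc)
    a, b = direction_comparison
    dir_fc = signed_fc(
        x_lin[:, labels == a].mean(axis=1), x_lin[:, labels == b].mean(axis=1)
    )
    out["direction"] = np.where(dir_fc >= 1.0, "up", "down")
    out["significant"] = gate
    return out


def quantitative_trait_corr(
    m: ExpressionMatrix,
    fdr: float = 0.10,
    conf: float = 0.80,
    n_perm: int = 1000,
    seed: int | None = None,
    log_transform: bool = True,
) -> PermTestResult:
    """Trait-correlation screen with FDR-and-confidence control.

    Per-gene Pearson r against the trait with the parametric t-based p-value;
    trait values are permuted across samples (exhaustively when the sample
    count admits at most ``n_perm`` orderings) and list size is chosen by the
    same false-discovery-proportion rule as the class screen.
    """
    if m.trait is None:
        raise ValueError("matrix has no trait values")
    trait = m.trait.reindex(m.intensity.columns).to_numpy(dtype=float)
    n = trait.size
    if n < 4:
        raise ValueError("need >= 4 samples for a trait screen")
    if trait.std() == 0:
        raise ValueError("trait has zero variance")
    x = m.intensity.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(np.maximum(x, 1e-12))

    def corr_p(t):
        tz = (t - t.mean()) / t.std()
        xc = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ tz) / (n * sd)
        r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
        with np.errstate(divide="ignore"):
            tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * sps.t.sf(np.abs(tstat), n - 2)
        return r, p

    r_obs, p_obs = corr_p(trait)
    order = np.argsort(p_obs, kind="mergesort")
    rng = np.random.default_rng(seed)
    if math.factorial(n) <= n_perm:
        perm_idx = np.array(list(itertools.permutations(range(n))))
        exhaustive = True
    else:
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        exhaustive = False
    perm_p = np.empty((perm_idx.shape[0], x.shape[0]))
    for b, idx in enumerate(perm_idx):
        perm_p[b] = corr_p(trait[idx])[1]
    k = _select_list_size(p_obs[order], perm_p, fdr, conf)
    sel = order[:k]
    genes = list(m.genes.reindex(m.intensity.index).iloc[sel])
    table = pd.DataFrame(
        {"gene": m.genes.reindex(m.intensity.index).to_numpy(),
         "r": r_obs, "p": p_obs},
        index=m.intensity.index,
    )
    return PermTestResult(
        genes=genes, stats=table, k=k,
        cutoff=float(p_obs[order[k - 1]]) if k else float("nan"),
        n_perm_used=perm_idx.shape[0], exhaustive=exhaustive,
    )
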