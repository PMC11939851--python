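"""Patient-profile clustering and cluster-level statistics.

Four pieces, mirroring the clustering half of the analysis:

* Ward-D2 agglomerative clustering of patients on their (log-scale)
  marker profiles, with Euclidean distances and dendrogram heights on the
  distance scale;
* outlier removal by cutting the dendrogram at a height threshold and
  discarding patients that only join the tree above it;
* exact r x c contingency testing (Freeman-Halton generalisation of
  Fisher's exact test) to associate cluster membership with clinical
  labels;
* a moderated two-group t-test with empirical-Bayes variance shrinkage
  and Benjamini-Hochberg FDR control for differential marker expression
  between clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import t as t_dist

from .cohort_io import ClinicalTable, ImmuneProfileMatrix
from .errors import ConfigError, DegenerateMarkerError, SizeError, ValidationError

__all__ = [
    "ClusterConfig", "ClusterResult", "DEResult",
    "hierarchical_cluster", "remove_outliers",
    "fisher_exact_rxc", "moderated_ttest", "bh_fdr", "associate_clusters",
]


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterConfig:
    """Ward-D2/Euclidean clustering configuration.

    Exactly one of ``n_clusters`` and ``cut_height`` selects the partition;
    ``outlier_cut_height`` feeds :func:`remove_outliers` when set.
    """

    distance: str = "euclidean"
    linkage: str = "ward_d2"
    n_clusters: int | None = None
    cut_height: float | None = None
    outlier_cut_height: float | None = None

    def __post_init__(self) -> None:
        if self.distance != "euclidean":
            raise ConfigError(f"unsupported distance {self.distance!r}")
        if self.linkage != "ward_d2":
            raise ConfigError(f"unsupported linkage {self.linkage!r}")
        if (self.n_clusters is None) == (self.cut_height is None):
            raise ConfigError("set exactly one of n_clusters and cut_height")
        if self.n_clusters is not None and self.n_clusters < 2:
            raise ConfigError("n_clusters must be >= 2")
        if self.cut_height is not None and self.cut_height <= 0:
            raise ConfigError("cut_height must be positive")
        if self.outlier_cut_height is not None and self.outlier_cut_height <= 0:
            raise ConfigError("outlier_cut_height must be positive")


@dataclass
class ClusterResult:
    """Merge tree (scipy linkage matrix, heights on the Euclidean-distance
    scale), patient -> cluster labels, and the list of removed outliers."""

    merge_tree: np.ndarray
    labels: dict[str, int]
    outliers: list[str] = field(default_factory=list)

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes


def _patient_matrix(m: ImmuneProfileMatrix) -> np.ndarray:
    x = m.values.T.to_numpy(dtype=float)  # patients x markers
    if np.isnan(x).any():
        raise ValidationError("missing values present; impute or drop before clustering")
    return x


def ward_tree(m: ImmuneProfileMatrix) -> np.ndarray:
    """Ward-D2 merge tree over patients (Lance-Williams update on squared
    Euclidean distances; reported heights are on the distance scale)."""
    x = _patient_matrix(m)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 patients to build a tree")
    return linkage(x, method="ward")


def hierarchical_cluster(m: ImmuneProfileMatrix, cfg: ClusterConfig) -> ClusterResult:
    """Cluster patients by their marker profiles and cut the tree."""
    x = _patient_matrix(m)
    n = x.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 patients to cluster")
    if cfg.n_clusters is not None and cfg.n_clusters > n:
        raise ConfigError(f"{cfg.n_clusters} clusters requested for {n} patients")
    z = linkage(x, method="ward")
    if cfg.n_clusters is not None:
        flat = fcluster(z, t=cfg.n_clusters, criterion="maxclust")
    else:
        flat = fcluster(z, t=cfg.cut_height, criterion="distance")
    labels = dict(zip(m.patient_ids, (int(c) for c in flat)))
    return ClusterResult(merge_tree=z, labels=labels)


def remove_outliers(m: ImmuneProfileMatrix, cut_height: float, *,
                    max_branch_size: int = 1, max_fraction: float = 0.5,
                    ) -> tuple[ImmuneProfileMatrix, list[str]]:
    """Drop patients sitting on small branches that only join the dendrogram
    above ``cut_height``.

    Cutting the tree at ``cut_height`` yields branches whose internal merges
    all lie below the threshold; members of branches of size at most
    ``max_branch_size`` (default: singletons) are declared outliers. Refuses
    to remove more than ``max_fraction`` of the cohort.
    """
    z = ward_tree(m)
    flat = fcluster(z, t=cut_height, criterion="distance")
    sizes = np.bincount(flat)
    outlier_mask = sizes[flat] <= max_branch_size
    outliers = [p for p, o in zip(m.patient_ids, outlier_mask) if o]
    if len(outliers) > max_fraction * m.n_patients:
        raise ValidationError(
            f"cut height {cut_height} would remove {len(outliers)} of "
            f"{m.n_patients} patients (> {max_fraction:.0%}); refusing")
    retained = [p for p in m.patient_ids if p not in outliers]
    return m.subset_patients(retained), outliers


# ---------------------------------------------------------------------------
# exact r x c contingency test (Freeman-Halton)
# ---------------------------------------------------------------------------

def fisher_exact_rxc(table, *, enumeration_budget: int = 60,
                     tie_tol: float = 1e-9) -> float:
    """Exact two-sided p-value for independence in an r x c count table.

    Freeman-Halton generalisation of Fisher's exact test: enumerate every
    table with the observed row and column margins; the p-value is the sum
    of the (multivariate hypergeometric) probabilities of all tables no more
    probable than the observed one, with ties admitted within a relative
    tolerance of ``tie_tol``.

    The grand total must not exceed ``enumeration_budget`` (default 60, safe
    for cohort-scale tables); larger tables are refused with a suggestion to
    fall back to Monte Carlo.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValidationError("need a table with at least 2 rows and 2 columns")
    if (np.asarray(table, dtype=float) != tab).any():
        raise ValidationError("table cells must be integers")
    if (tab < 0).any():
        raise ValidationError("negative cell count")
    total = int(tab.sum())
    if total == 0:
        raise ValidationError("table grand total must be positive")
    if total > enumeration_budget:
        raise SizeError(
            f"grand total {total} exceeds enumeration budget "
            f"{enumeration_budget}; consider a Monte Carlo approximation")

    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    # log prefactor: prod(r_i!) prod(c_j!) / N!
    log_pref = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(total + 1)

    def log_prob(cells_lgamma_sum: float) -> float:
        return log_pref - cells_lgamma_sum

    p_obs = math.exp(log_prob(gammaln(tab + 1).sum()))

    r, c = tab.shape
    p_sum = 0.0
    p_total = 0.0  # for an internal sanity check by callers/tests
    cols_list = cols.tolist()

    def rec_rows(i: int, col_rem: list[int], acc_lgam: float) -> None:
        nonlocal p_sum, p_total
        if i == r - 1:
            # last row forced by column remainders
            lg = acc_lgam + sum(gammaln(v + 1) for v in col_rem)
            p = math.exp(log_prob(lg))
            p_total += p
            if p <= p_obs * (1.0 + tie_tol):
                p_sum += p
            return
        row_total = int(rows[i])

        def rec_cells(j: int, rem_row: int, col_rem2: list[int], lgam: float) -> None:
            if j == c - 1:
                if rem_row > col_rem2[j]:
                    return
                nxt = col_rem2.copy()
                nxt[j] -= rem_row
                rec_rows(i + 1, nxt, lgam + gammaln(rem_row + 1))
                return
            # cell value bounded by remaining row and column mass
            hi = min(rem_row, col_rem2[j])
            lo = max(0, rem_row - sum(col_rem2[j + 1:]))
            for v in range(lo, hi + 1):
                nxt = col_rem2.copy()
                nxt[j] -= v
                rec_cells(j + 1, rem_row - v, nxt, lgam + gammaln(v + 1))

        rec_cells(0, row_total, col_rem, acc_lgam)

    rec_rows(0, cols_list, 0.0)
    # degenerate margins (a zero row/column) admit exactly one table -> p = 1
    return min(p_sum, 1.0)


def associate_clusters(labels: dict[str, int], clin: ClinicalTable,
                       variable: str) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate cluster labels against a clinical variable and test
    the association exactly.

    Returns the contingency grid (clinical categories x clusters) and the
    Freeman-Halton p-value.
    """
    patients = list(labels)
    clin.check_covers(patients)
    clin_labels = clin.labels(variable).loc[patients]
    grid = pd.crosstab(clin_labels, pd.Series(labels, name="cluster"))
    p = fisher_exact_rxc(grid.to_numpy())
    return grid, p


# ---------------------------------------------------------------------------
# moderated differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-marker differential-expression table plus the shrinkage
    hyperparameters: prior degrees of freedom ``d0`` and prior variance
    ``s0_sq`` of the empirical-Bayes model."""

    table: pd.DataFrame  # columns: log2_fold_change, moderated_t, raw_p, fdr_q
    d0: float
    s0_sq: float


def _trigamma_inverse(y: float, *, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed sample
    variances.

    Each sample variance s_g^2 with ``df`` degrees of freedom is modelled as
    s0^2 * F(df, d0); matching the mean and variance of log s_g^2 (via the
    digamma/trigamma moments of the log chi-square) yields the prior
    degrees of freedom d0 and prior variance s0^2. When the observed spread
    of log-variances does not exceed its sampling floor, d0 = inf (fully
    pooled prior).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise DegenerateMarkerError([], "all markers have zero pooled variance")
    e = np.log(s2[ok]) - digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    if ok.sum() < 2:
        return math.inf, math.exp(e_mean)
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(polygamma(1, df / 2.0))
    if excess <= 0:
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_ttest(group_a: pd.DataFrame, group_b: pd.DataFrame, *,
                    d0: float | None = None, s0_sq: float | None = None,
                    ) -> DEResult:
    """Two-group moderated t-test with empirical-Bayes variance shrinkage.

    Both arguments are markers x patients slices on the log2 scale. For each
    marker, the pooled sample variance s_g^2 (d_g = n_A + n_B - 2 df) is
    shrunk toward a prior variance s0^2 estimated across markers:

        s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

    and the moderated t = (mean_A - mean_B) / (s_post * sqrt(1/n_A + 1/n_B))
    is referred to a t distribution with d0 + d_g degrees of freedom.
    ``d0``/``s0_sq`` may be forced (0 recovers the ordinary equal-variance
    t; inf fully pools to the common variance). Q-values are
    Benjamini-Hochberg.
    """
    if list(group_a.index) != list(group_b.index):
        raise ValidationError("group slices must share the same marker index")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs at least 2 patients")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("missing values not supported in moderated_ttest")

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    dg = n_a + n_b - 2
    s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / dg
    if (s2 == 0).all():
        raise DegenerateMarkerError(list(group_a.index),
                                    "zero variance on all markers in both groups")

    if d0 is None or (s0_sq is None and d0 != 0):
        est_d0, est_s0 = estimate_prior_variance(s2, dg)
        if d0 is None:
            d0 = est_d0
        if s0_sq is None:
            s0_sq = est_s0
    if d0 is None or not (d0 >= 0):
        warnings.warn("non-finite prior df estimate; falling back to fully "
                      "pooled prior (d0 = inf)", RuntimeWarning, stacklevel=2)
        d0 = math.inf
    if s0_sq is None:
        s0_sq = 0.0  # unused when d0 == 0

    if math.isinf(d0):
        s_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    delta = mean_a - mean_b
    denom = np.sqrt(s_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = delta / denom
    raw_p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    q = bh_fdr(raw_p)
    table = pd.DataFrame({
        "log2_fold_change": delta,
        "moderated_t": t_mod,
        "raw_p": raw_p,
        "fdr_q": q,
    }, index=group_a.index)
    return DEResult(table=table, d0=float(d0), s0_sq=float(s0_sq))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order kept."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("expected a 1-d sequence of p-values")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
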