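"""Differential correlation of marker pairs between two clinical conditions.

For every unordered pair of markers the Pearson (or Spearman) correlation
is computed separately in the two patient groups of a clinical contrast.
Each correlation r with n complete pairs is Fisher-transformed,

    z = atanh(r),    se_z = 1 / sqrt(n - 3),

which approximately normalises and variance-stabilises the sampling
distribution of r. The contrast statistic is the standardised difference

    z_diff = (z_A - z_B) / sqrt(1/(n_A - 3) + 1/(n_B - 3)),

referred to a standard normal. A pair is called differentially correlated
either when |z_diff| exceeds a fixed threshold (default 1.64, the upper-5%
normal quantile) or when the two-sided normal p falls below alpha
(``sided="two_sided_p"``). Note the default pairs a one-sided critical
value with a two-sided rejection region, so its null rate is ~0.10, not
0.05; both modes are provided.

Each pair is additionally classified by the ordered pair of per-condition
correlation states from {+, 0, -} ("+" = significantly positive at
``alpha_condition``, "-" = significantly negative, "0" = not significant),
giving the nine edge classes +/+, +/0, +/-, 0/+, 0/0, 0/-, -/+, -/0, -/-.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ClinicalTable, ContrastSpec, ImmuneProfileMatrix
from .errors import (
    ConfigError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)

EDGE_CLASSES = ("+/+", "+/0", "+/-", "0/+", "0/0", "0/-", "-/+", "-/0", "-/-")

#: classes whose correlation keeps the same sign in both conditions; these
#: carry no differential signal and are dropped from networks by default
SAME_SIGN_CLASSES = frozenset({"+/+", "-/-"})

_SATURATION_EPS = 1e-12


@dataclass(frozen=True)
class DiffCorrConfig:
    """Tuning knobs of the differential-correlation scan.

    ``alpha_condition`` is the per-condition significance level used for the
    edge-class symbols; ``z_diff_threshold``/``alpha_diff`` govern the
    significance of the *difference* under the ``abs_threshold`` and
    ``two_sided_p`` modes respectively; ``clip_r`` is the shrinkage applied
    to saturated |r| = 1 before atanh.
    """

    method: str = "pearson"
    alpha_condition: float = 0.05
    z_diff_threshold: float = 1.64
    sided: str = "abs_threshold"
    alpha_diff: float = 0.05
    clip_r: float = 0.999999

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman"):
            raise ConfigError(f"unknown correlation method {self.method!r}")
        if not 0 < self.alpha_condition < 1:
            raise ConfigError("alpha_condition must be in (0, 1)")
        if not 0 < self.alpha_diff < 1:
            raise ConfigError("alpha_diff must be in (0, 1)")
        if self.z_diff_threshold <= 0:
            raise ConfigError("z_diff_threshold must be positive")
        if self.sided not in ("abs_threshold", "two_sided_p"):
            raise ConfigError(f"unknown sided mode {self.sided!r}")

    def is_significant(self, z_diff: float, p_diff: float) -> bool:
        if self.sided == "abs_threshold":
            return abs(z_diff) > self.z_diff_threshold
        return p_diff < self.alpha_diff


@dataclass
class CorrelationEstimate:
    """One condition's correlation for one marker pair."""

    r: float
    n: int
    p: float
    z: float
    se_z: float
    saturated: bool = False


@dataclass
class DiffCorrRecord:
    """One marker pair's per-condition correlations, difference statistic
    and edge class. ``error`` is set (and the statistics NaN) when the pair
    could not be evaluated in one of the conditions."""

    marker_i: str
    marker_j: str
    est_A: CorrelationEstimate | None
    est_B: CorrelationEstimate | None
    z_diff: float = float("nan")
    p_diff: float = float("nan")
    edge_class: str | None = None
    significant: bool = False
    error: str | None = None


# ---------------------------------------------------------------------------
# pair-level statistics
# ---------------------------------------------------------------------------

def fisher_z(r: float, n: int, *, clip: float | None = 0.999999,
             ) -> tuple[float, float]:
    """Fisher transform z = atanh(r) and its standard error 1/sqrt(n-3).

    Saturated correlations (|r| = 1) have an infinite transform; with
    ``clip`` set they are shrunk to +/-clip first, with ``clip=None`` a
    :class:`UndefinedCorrelationError` cousin is raised instead.
    """
    if n < 4:
        raise InsufficientDataError(f"n = {n} < 4 leaves no variance for z (needs n-3 > 0)")
    if abs(r) > 1 + 1e-12:
        raise ValidationError(f"|r| = {abs(r)} > 1")
    if abs(r) >= 1 - _SATURATION_EPS:
        if clip is None:
            from .errors import SaturationError
            raise SaturationError(
                "|r| = 1: Fisher z is infinite; set a shrinkage epsilon "
                "(clip_r) to proceed")
        r = clip if r > 0 else -clip
    z = float(np.arctanh(r))
    se = 1.0 / np.sqrt(n - 3)
    return z, float(se)


def _pearson_p(r: float, n: int) -> float:
    if abs(r) >= 1 - _SATURATION_EPS:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def pair_correlation(x, y, method: str = "pearson", *,
                     clip_r: float = 0.999999) -> CorrelationEstimate:
    """Correlation of two marker vectors over pairwise-complete patients.

    Pearson r with a two-sided p from the t distribution on n-2 df, or the
    same machinery on ranks for Spearman. Requires >= 4 complete pairs and
    nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 4:
        raise InsufficientDataError(f"only {n} complete pairs (need >= 4)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ConfigError(f"unknown correlation method {method!r}")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    p = _pearson_p(r, n)
    saturated = abs(r) >= 1 - _SATURATION_EPS
    z, se = fisher_z(r, n, clip=clip_r)
    return CorrelationEstimate(r=r, n=n, p=p, z=z, se_z=se, saturated=saturated)


def z_difference(est_a: CorrelationEstimate, est_b: CorrelationEstimate,
                 ) -> tuple[float, float]:
    """Standardised difference of two Fisher z-scores and its two-sided
    standard-normal p-value."""
    if est_a.n < 4 or est_b.n < 4:
        raise InsufficientDataError("both conditions need n >= 4")
    se = np.sqrt(1.0 / (est_a.n - 3) + 1.0 / (est_b.n - 3))
    z_diff = (est_a.z - est_b.z) / se
    p_diff = float(2.0 * stats.norm.sf(abs(z_diff)))
    return float(z_diff), p_diff


def classify_edge(est_a: CorrelationEstimate, est_b: CorrelationEstimate,
                  alpha: float = 0.05) -> str:
    """Ordered pair of per-condition correlation states from {+, 0, -}."""
    def symbol(est: CorrelationEstimate) -> str:
        if est.p < alpha and est.r > 0:
            return "+"
        if est.p < alpha and est.r < 0:
            return "-"
        return "0"
    return f"{symbol(est_a)}/{symbol(est_b)}"


# ---------------------------------------------------------------------------
# cohort-level scan
# ---------------------------------------------------------------------------

def differential_correlation_scan(m: ImmuneProfileMatrix, clin: ClinicalTable,
                                  contrast: ContrastSpec,
                                  cfg: DiffCorrConfig = DiffCorrConfig(),
                                  ) -> list[DiffCorrRecord]:
    """Evaluate every unordered marker pair under one clinical contrast.

    M markers yield M(M-1)/2 records, in lexicographic marker-index order.
    Pairs that cannot be evaluated (too few complete observations, zero
    variance) are returned as flagged records rather than aborting the scan.
    """
    group_a, group_b = contrast.split(clin, m.patient_ids)
    a = m.values[group_a].to_numpy(dtype=float)
    b = m.values[group_b].to_numpy(dtype=float)
    markers = m.marker_ids

    records: list[DiffCorrRecord] = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            rec = DiffCorrRecord(marker_i=markers[i], marker_j=markers[j],
                                 est_A=None, est_B=None)
            try:
                rec.est_A = pair_correlation(a[i], a[j], cfg.method,
                                             clip_r=cfg.clip_r)
                rec.est_B = pair_correlation(b[i], b[j], cfg.method,
                                             clip_r=cfg.clip_r)
                rec.z_diff, rec.p_diff = z_difference(rec.est_A, rec.est_B)
                rec.edge_class = classify_edge(rec.est_A, rec.est_B,
                                               cfg.alpha_condition)
                rec.significant = cfg.is_significant(rec.z_diff, rec.p_diff)
            except (InsufficientDataError, UndefinedCorrelationError) as exc:
                rec.error = f"{type(exc).__name__}: {exc}"
            records.append(rec)
    return records


_SCAN_COLUMNS = ["marker_i", "marker_j", "r_A", "n_A", "p_A", "r_B", "n_B",
                 "p_B", "z_diff", "p_diff", "class", "significant", "error"]


def scan_to_frame(records: list[DiffCorrRecord]) -> pd.DataFrame:
    """Flatten scan records into the TSV-ready table."""
    rows = []
    for r in records:
        rows.append({
            "marker_i": r.marker_i, "marker_j": r.marker_j,
            "r_A": r.est_A.r if r.est_A else np.nan,
            "n_A": r.est_A.n if r.est_A else 0,
            "p_A": r.est_A.p if r.est_A else np.nan,
            "r_B": r.est_B.r if r.est_B else np.nan,
            "n_B": r.est_B.n if r.est_B else 0,
            "p_B": r.est_B.p if r.est_B else np.nan,
            "z_diff": r.z_diff, "p_diff": r.p_diff,
            "class": r.edge_class, "significant": r.significant,
            "error": r.error,
        })
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[DiffCorrRecord]:
    """Rebuild scan records from a table written by :func:`scan_to_frame`."""
    records = []
    for _, row in df.iterrows():
        err = row["error"]
        err = None if (pd.isna(err) or err == "") else str(err)
        est_a = est_b = None
        if err is None:
            za, sea = fisher_z(float(row["r_A"]), int(row["n_A"]))
            zb, seb = fisher_z(float(row["r_B"]), int(row["n_B"]))
            est_a = CorrelationEstimate(r=float(row["r_A"]), n=int(row["n_A"]),
                                        p=float(row["p_A"]), z=za, se_z=sea)
            est_b = CorrelationEstimate(r=float(row["r_B"]), n=int(row["n_B"]),
                                        p=float(row["p_B"]), z=zb, se_z=seb)
        cls = row["class"]
        rec = DiffCorrRecord(
            marker_i=str(row["marker_i"]), marker_j=str(row["marker_j"]),
            est_A=est_a, est_B=est_b,
            z_diff=float(row["z_diff"]) if not pd.isna(row["z_diff"]) else float("nan"),
            p_diff=float(row["p_diff"]) if not pd.isna(row["p_diff"]) else float("nan"),
            edge_class=None if (not isinstance(cls, str)) else cls,
            significant=bool(row["significant"]), error=err)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# permutation oracle
# ---------------------------------------------------------------------------

def permutation_null(x_a, x_b, y_a, y_b, n_perm: int, seed: int,
                     method: str = "pearson") -> tuple[float, float]:
    """Empirical p-value for the z-difference by condition-label permutation.

    Pools both conditions' observations of the pair (x, y), permutes the
    condition labels jointly, recomputes z_diff each time, and returns

        p = (1 + #{|z*| >= |z_obs|}) / (n_perm + 1)

    together with the observed z_diff. A seed is required: the oracle must
    be reproducible.
    """
    if seed is None:
        raise ValidationError("permutation_null requires an explicit seed")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    x_a, x_b = np.asarray(x_a, float), np.asarray(x_b, float)
    y_a, y_b = np.asarray(y_a, float), np.asarray(y_b, float)
    n_a, n_b = x_a.size, x_b.size

    def zd(xa, ya, xb, yb) -> float:
        ea = pair_correlation(xa, ya, method)
        eb = pair_correlation(xb, yb, method)
        return z_difference(ea, eb)[0]

    z_obs = zd(x_a, y_a, x_b, y_b)
    x_pool = np.concatenate([x_a, x_b])
    y_pool = np.concatenate([y_a, y_b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_a + n_b)
        ia, ib = perm[:n_a], perm[n_a:]
        z_star = zd(x_pool[ia], y_pool[ia], x_pool[ib], y_pool[ib])
        if abs(z_star) >= abs(z_obs):
            count += 1
    p_emp = (1 + count) / (n_perm + 1)
    return p_emp, z_obs
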