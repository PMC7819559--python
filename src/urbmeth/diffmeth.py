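"""Differential methylation between habitats.

Per CpG unit, methylation counts are compared between urban and forest birds
with a logistic regression of read-level methylation status on habitat. With
a single binary covariate the maximum-likelihood fit is available in closed
form (fitted group probabilities are the pooled group fractions), so the
likelihood-ratio chi-square(1) statistic is computed vectorised across all
sites. P-values are adjusted to q-values with a sliding-linear-model (SLIM)
estimate of the null proportion pi0 scaling a Benjamini-Hochberg adjustment.
A site is a DMS when |difference| > 25 percentage points (strict) and
q < 0.01 (strict). Significance of the genome-wide result is assessed by
permuting habitat labels and recomputing the full analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import MethylationMatrix


# ---------------------------------------------------------------------------
# per-site test
# ---------------------------------------------------------------------------

def _binom_ll(m: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Profile binomial log-likelihood at the MLE p = m/t (0*log0 = 0)."""
    m = m.astype(float)
    t = t.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(t > 0, m / np.maximum(t, 1.0), 0.0)
        a = np.where(m > 0, m * np.log(np.where(p > 0, p, 1.0)), 0.0)
        b = np.where(t - m > 0, (t - m) * np.log(np.where(p < 1, 1 - p, 1.0)), 0.0)
    return a + b


def site_test(meth: np.ndarray, total: np.ndarray, is_urban: np.ndarray,
              test: str = "logistic") -> tuple[np.ndarray, np.ndarray]:
    """LRT p-value and methylation difference per site.

    ``meth``/``total`` are (n_sites, n_samples); ``is_urban`` a boolean
    sample mask. The difference is the gap of group means of per-sample
    methylation fractions, in percentage points (urban minus forest).
    ``test="fisher"`` switches to a two-sided Fisher exact test on the pooled
    group counts (sensitivity alternative).
    """
    meth = np.atleast_2d(meth)
    total = np.atleast_2d(total)
    is_urban = np.asarray(is_urban, dtype=bool)
    if is_urban.sum() < 2 or (~is_urban).sum() < 2:
        raise ValueError("need at least two samples per group")
    if (total < 1).any():
        raise ValueError("all per-sample totals must be >= 1 in the united matrix")

    frac = meth / total
    diff = 100.0 * (frac[:, is_urban].mean(axis=1) - frac[:, ~is_urban].mean(axis=1))

    m_u, t_u = meth[:, is_urban].sum(axis=1), total[:, is_urban].sum(axis=1)
    m_f, t_f = meth[:, ~is_urban].sum(axis=1), total[:, ~is_urban].sum(axis=1)
    if test == "logistic":
        lr = 2.0 * (_binom_ll(m_u, t_u) + _binom_ll(m_f, t_f) - _binom_ll(m_u + m_f, t_u + t_f))
        p = stats.chi2.sf(np.maximum(lr, 0.0), df=1)
        # no information (all unmethylated or all methylated in both groups)
        degenerate = ((m_u + m_f) == 0) | ((m_u + m_f) == (t_u + t_f))
        p = np.where(degenerate, 1.0, p)
    elif test == "fisher":
        p = np.array([stats.fisher_exact([[mu, tu - mu], [mf, tf - mf]])[1]
                      for mu, tu, mf, tf in zip(m_u, t_u, m_f, t_f)])
    else:
        raise ValueError(f"unknown test {test!r}")
    return p, diff


# ---------------------------------------------------------------------------
# SLIM q-values
# ---------------------------------------------------------------------------

def slim_pi0(p_values: np.ndarray, lambdas: np.ndarray | None = None,
             window: int = 5) -> float:
    """Sliding-linear-model estimate of the null proportion pi0.

    The empirical CDF of the p-values is evaluated on a lambda grid
    (default 0.05..0.95, step 0.05). A straight line is fitted to every
    ``window``-point segment; in the region where only null p-values remain
    the CDF is linear with slope pi0, so the segment with the smallest
    residual variance (the most stable one) supplies the estimate, clipped
    to (0, 1]. Degenerate fits (slope <= 0) fall back to a tail-based
    estimate at lambda = 0.5.
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    F = np.array([(p <= lam).mean() for lam in lambdas])
    best_slope, best_var = None, np.inf
    for i in range(len(lambdas) - window + 1):
        x = lambdas[i:i + window]
        y = F[i:i + window]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        v = float(resid.var())
        if v < best_var:
            best_var, best_slope = v, float(slope)
    if best_slope is None or best_slope <= 1e-3:
        tail = (p > 0.5).mean() / 0.5  # Storey-style fallback
        best_slope = tail if tail > 0 else 1.0
    return float(min(best_slope, 1.0))


def slim_qvalues(p_values: np.ndarray, min_n: int = 100) -> np.ndarray:
    """q = pi0 x BH-adjusted p, monotone non-decreasing in p.

    With fewer than ``min_n`` p-values pi0 estimation is unreliable and the
    adjustment falls back to plain BH (pi0 = 1) with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < min_n:
        warnings.warn(f"only {p.size} p-values; using pi0 = 1 (plain BH)")
        pi0 = 1.0
    else:
        pi0 = slim_pi0(p)
    bh = multipletests(p, method="fdr_bh")[1]
    q = np.minimum(pi0 * bh, 1.0)
    # BH output is already monotone in p; enforce explicitly for safety
    order = np.argsort(p, kind="stable")
    q_sorted = np.maximum.accumulate(q[order])
    out = np.empty_like(q)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_statistic: float
    null_statistics: np.ndarray
    p_value: float
    n_iter: int
    seed: int
    statistic: str = "n_dms"


@dataclass
class DifferentialMethylationResults:
    """Per-site statistics and the called DMS set."""

    table: pd.DataFrame     # chrom,pos,meth_urban,meth_forest,meth_diff,p_value,q_value
    dms: pd.DataFrame       # called subset + direction
    diff_threshold: float
    q_threshold: float
    pi0: float
    model: "DifferentialMethylation" = field(repr=False, default=None)

    @property
    def n_dms(self) -> int:
        return len(self.dms)

    def direction_counts(self) -> pd.Series:
        return self.dms.direction.value_counts()

    def permutation_test(self, n_iter: int = 1000, seed: int = 0,
                         statistic: str = "n_dms") -> PermutationResult:
        return self.model.permutation_test(n_iter=n_iter, seed=seed, statistic=statistic)

    def summary(self) -> str:
        lines = [
            "Differential methylation (urban vs forest)",
            f"  sites tested            {len(self.table)}",
            f"  estimated pi0 (SLIM)    {self.pi0:.3f}",
            f"  DMS (|diff|>{self.diff_threshold:g}, q<{self.q_threshold:g})"
            f"   {self.n_dms}",
        ]
        if self.n_dms:
            hyper = int((self.dms.direction == "hyper").sum())
            lines.append(f"  hypermethylated in urban {hyper} "
                         f"({100.0 * hyper / self.n_dms:.1f}%)")
        return "\n".join(lines)


class DifferentialMethylation:
    """Site-level urban-vs-forest methylation model over a united matrix."""

    def __init__(self, matrix: MethylationMatrix, test: str = "logistic"):
        self.matrix = matrix
        self.test = test
        self.is_urban = matrix.habitat_mask("urban")

    def _site_stats(self, meth: np.ndarray, total: np.ndarray,
                    is_urban: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p, diff = site_test(meth, total, is_urban, test=self.test)
        q = slim_qvalues(p) if p.size else p
        return p, diff, q

    def fit(self, diff_threshold: float = 25.0, q_threshold: float = 0.01
            ) -> DifferentialMethylationResults:
        m = self.matrix
        if m.n_sites == 0:
            empty = pd.DataFrame(columns=["chrom", "pos", "meth_urban", "meth_forest",
                                          "meth_diff", "p_value", "q_value"])
            return DifferentialMethylationResults(empty, empty.assign(direction=[]),
                                                  diff_threshold, q_threshold, 1.0, self)
        p, diff, q = self._site_stats(m.meth, m.total, self.is_urban)
        frac = m.fractions()
        table = m.sites.copy()
        table["meth_urban"] = 100.0 * frac[:, self.is_urban].mean(axis=1)
        table["meth_forest"] = 100.0 * frac[:, ~self.is_urban].mean(axis=1)
        table["meth_diff"] = diff
        table["p_value"] = p
        table["q_value"] = q
        called = table[(table.meth_diff.abs() > diff_threshold)
                       & (table.q_value < q_threshold)].copy()
        called["direction"] = np.where(called.meth_diff > 0, "hyper", "hypo")
        called = called.sort_values(["chrom", "pos"]).reset_index(drop=True)
        pi0 = slim_pi0(p) if p.size >= 100 else 1.0
        return DifferentialMethylationResults(table.reset_index(drop=True), called,
                                              diff_threshold, q_threshold, pi0, self)

    def _count_dms(self, is_urban: np.ndarray, diff_threshold: float,
                   q_threshold: float) -> int:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, diff, q = self._site_stats(self.matrix.meth, self.matrix.total, is_urban)
        return int(((np.abs(diff) > diff_threshold) & (q < q_threshold)).sum())

    def permutation_test(self, n_iter: int = 1000, seed: int = 0,
                         diff_threshold: float = 25.0, q_threshold: float = 0.01,
                         statistic: str = "n_dms") -> PermutationResult:
        """Permute habitat labels (balanced reassignments, sampled with
        replacement) and rerun the full DMS analysis each iteration.

        The statistic is the number of called DMSs (default) or the mean
        |difference| at called sites (``statistic="mean_abs_diff"``);
        p = (1 + #{null >= observed}) / (n_iter + 1), never exactly 0.
        """
        if n_iter < 100:
            raise ValueError("n_iter must be at least 100")
        rng = np.random.default_rng(seed)

        def stat(mask: np.ndarray) -> float:
            if statistic == "n_dms":
                return float(self._count_dms(mask, diff_threshold, q_threshold))
            if statistic == "mean_abs_diff":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p, diff, q = self._site_stats(self.matrix.meth, self.matrix.total, mask)
                sel = (np.abs(diff) > diff_threshold) & (q < q_threshold)
                return float(np.abs(diff[sel]).mean()) if sel.any() else 0.0
            raise ValueError(f"unknown statistic {statistic!r}")

        observed = stat(self.is_urban)
        null = np.empty(n_iter)
        for i in range(n_iter):
            null[i] = stat(rng.permutation(self.is_urban))
        p_value = (1.0 + (null >= observed).sum()) / (n_iter + 1.0)
        return PermutationResult(observed_statistic=observed, null_statistics=null,
                                 p_value=p_value, n_iter=n_iter, seed=seed,
                                 statistic=statistic)


def call_dms(matrix: MethylationMatrix, diff_threshold: float = 25.0,
             q_threshold: float = 0.01, test: str = "logistic") -> pd.DataFrame:
    """Functional wrapper: fit and return the called DMS table."""
    return DifferentialMethylation(matrix, test=test).fit(diff_threshold, q_threshold).dms
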