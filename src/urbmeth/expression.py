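"""Methylation-expression modelling.

Expression (size-factor normalised log2 counts) is regressed on methylation
level at DMSs, the genomic feature carrying the DMS (gene body, promoter or
TSS), and their interaction, with a random intercept per individual. When the
estimated individual variance is numerically zero the model is refit as a
fixed-effects linear model. Per-feature marginal slopes are reported with 95%
CIs and pairwise slope differences are Tukey-adjusted via the studentized
range over the three features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .coverage import MethylationMatrix

MODEL_FEATURES = ("gene_body", "promoter", "tss")


# ---------------------------------------------------------------------------
# count transform
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (computed on genes with no zero count)."""
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts; size factor undefined")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        return pd.Series(1.0, index=counts.columns)
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


def transform_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalised log2(count + 1): log2(count / size_factor + 1).

    A light-weight variance-stabilising transform standing in for a
    regularized-log transform; adequate here because the downstream model
    concerns slopes on the log scale, not shrinkage of low counts.
    """
    sf = size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)


# ---------------------------------------------------------------------------
# observation table
# ---------------------------------------------------------------------------

def build_observations(dms: pd.DataFrame, annotation: pd.DataFrame,
                       matrix: MethylationMatrix, expression: pd.DataFrame
                       ) -> pd.DataFrame:
    """One row per (DMS, gene, feature, sample).

    Only DMSs overlapping the gene body, promoter or TSS of a gene with
    quantified expression contribute; a DMS lying in several features of one
    gene contributes one row per feature. Methylation is the per-sample
    fraction (%) at the site; expression the transformed count of the gene in
    that sample.
    """
    frac = 100.0 * matrix.fractions()
    site_index = {(c, p): i for i, (c, p) in
                  enumerate(zip(matrix.sites.chrom, matrix.sites.pos))}
    ann_index = {(c, p): row for (c, p), (_, row) in
                 zip(zip(annotation.chrom, annotation.pos), annotation.iterrows())}
    individual = matrix.samples.sample_id.to_numpy()
    rows = []
    for rec in dms.itertuples(index=False):
        key = (rec.chrom, rec.pos)
        ann = ann_index.get(key)
        if ann is None or key not in site_index:
            continue
        si = site_index[key]
        for feature in MODEL_FEATURES:
            for gene in ann[f"genes_{feature}"]:
                if gene not in expression.index:
                    continue
                for j, sid in enumerate(individual):
                    rows.append((rec.chrom, rec.pos, gene, feature, sid,
                                 frac[si, j], expression.loc[gene, sid]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "feature",
                                       "sample_id", "methylation", "expression"])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class SlopeReport:
    slopes: pd.DataFrame            # feature, slope, se, ci_low, ci_high
    interaction_F: float
    interaction_df: tuple[int, int]
    interaction_p: float
    pairwise: pd.DataFrame          # feature_a, feature_b, estimate, se, p_tukey
    random_effect_variance: float
    used_mixed: bool
    n_obs: int

    def summary(self) -> str:
        lines = [
            "Expression ~ methylation x feature",
            f"  observations        {self.n_obs}",
            f"  individual variance {self.random_effect_variance:.3g}"
            f" ({'mixed model kept' if self.used_mixed else 'refit as fixed effects'})",
            f"  interaction F({self.interaction_df[0]},{self.interaction_df[1]})"
            f" = {self.interaction_F:.2f}, p = {self.interaction_p:.3g}",
            "  per-feature slopes (log2 expression per methylation %):",
        ]
        for r in self.slopes.itertuples(index=False):
            lines.append(f"    {r.feature:10s} {r.slope:+.2e}"
                         f"  [{r.ci_low:+.2e}, {r.ci_high:+.2e}]")
        for r in self.pairwise.itertuples(index=False):
            lines.append(f"    {r.feature_a} vs {r.feature_b}: "
                         f"diff {r.estimate:+.2e}, Tukey p = {r.p_tukey:.3g}")
        return "\n".join(lines)


class MethylationExpressionModel:
    """expression ~ methylation * feature (+ random intercept per individual)."""

    def __init__(self, observations: pd.DataFrame, variance_tol: float = 1e-2):
        if observations.empty:
            raise ValueError("no observations")
        self.observations = observations.copy()
        self.variance_tol = variance_tol

    def fit(self) -> SlopeReport:
        obs = self.observations
        features = [f for f in MODEL_FEATURES if (obs.feature == f).any()]
        if len(features) < 2 or any((obs.feature == f).sum() < 3 for f in features):
            return self._slopes_only(features)

        re_var = 0.0
        used_mixed = False
        if obs.sample_id.nunique() > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    md = smf.mixedlm("expression ~ methylation * C(feature)", obs,
                                     groups=obs.sample_id)
                    mfit = md.fit(reml=True, method="lbfgs")
                    re_var = float(mfit.cov_re.iloc[0, 0])
                except Exception:
                    re_var = 0.0
        ols = smf.ols("expression ~ methylation * C(feature)", obs).fit()
        resid_var = float(ols.mse_resid) if ols.df_resid > 0 else 1.0
        if re_var > self.variance_tol * resid_var:
            used_mixed = True
            fit, resid_df = mfit, float(obs.shape[0] - len(mfit.fe_params))
            params, cov = mfit.fe_params, mfit.cov_params().loc[
                mfit.fe_params.index, mfit.fe_params.index]
        else:
            fit, resid_df = ols, float(ols.df_resid)
            params, cov = ols.params, ols.cov_params()

        # interaction F test from the OLS ANOVA (identical when re_var ~ 0)
        reduced = smf.ols("expression ~ methylation + C(feature)", obs).fit()
        if ols.ssr <= 1e-12:  # perfect fit (e.g. constant response): no evidence
            f_res = (0.0, 1.0, len(features) - 1)
        else:
            f_res = ols.compare_f_test(reduced)
        interaction_F, interaction_p = float(f_res[0]), float(f_res[1])
        df_num = int(round(f_res[2]))
        df_den = int(ols.df_resid)

        slopes_rows, contrasts = [], {}
        ref = features[0]  # patsy reference level (alphabetical: gene_body)
        names = list(params.index)
        for f in features:
            vec = np.zeros(len(names))
            vec[names.index("methylation")] = 1.0
            if f != ref:
                key = f"methylation:C(feature)[T.{f}]"
                vec[names.index(key)] = 1.0
            contrasts[f] = vec
            est = float(vec @ params.to_numpy())
            se = float(np.sqrt(max(vec @ cov.to_numpy() @ vec, 0.0)))
            tcrit = stats.t.ppf(0.975, resid_df)
            slopes_rows.append((f, est, se, est - tcrit * se, est + tcrit * se))
        slopes = pd.DataFrame(slopes_rows,
                              columns=["feature", "slope", "se", "ci_low", "ci_high"])

        pair_rows = []
        k = len(features)
        for fa, fb in itertools.combinations(features, 2):
            vec = contrasts[fa] - contrasts[fb]
            est = float(vec @ params.to_numpy())
            se = float(np.sqrt(max(vec @ cov.to_numpy() @ vec, 0.0)))
            t = abs(est) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(np.sqrt(2.0) * t, k, resid_df))
            pair_rows.append((fa, fb, est, se, p))
        pairwise = pd.DataFrame(pair_rows, columns=["feature_a", "feature_b",
                                                    "estimate", "se", "p_tukey"])
        return SlopeReport(slopes=slopes, interaction_F=interaction_F,
                           interaction_df=(df_num, df_den), interaction_p=interaction_p,
                           pairwise=pairwise, random_effect_variance=re_var,
                           used_mixed=used_mixed, n_obs=len(obs))

    def _slopes_only(self, features) -> SlopeReport:
        """Singular design (one feature, or too few rows): slopes without
        comparisons."""
        rows = []
        for f in features:
            sub = self.observations[self.observations.feature == f]
            if len(sub) < 3 or sub.methylation.nunique() < 2:
                continue
            ols = sm.OLS(sub.expression.to_numpy(),
                         sm.add_constant(sub.methylation.to_numpy())).fit()
            est, se = float(ols.params[1]), float(ols.bse[1])
            tcrit = stats.t.ppf(0.975, ols.df_resid) if ols.df_resid > 0 else np.nan
            rows.append((f, est, se, est - tcrit * se, est + tcrit * se))
        slopes = pd.DataFrame(rows, columns=["feature", "slope", "se", "ci_low", "ci_high"])
        empty = pd.DataFrame(columns=["feature_a", "feature_b", "estimate", "se", "p_tukey"])
        return SlopeReport(slopes=slopes, interaction_F=np.nan, interaction_df=(0, 0),
                           interaction_p=np.nan, pairwise=empty,
                           random_effect_variance=0.0, used_mixed=False,
                           n_obs=len(self.observations))
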