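"""Cohort-level association and survival analysis.

Survival data are right-censored at a fixed horizon (default 10 years)
before modeling.  Kaplan–Meier curves use the product-limit estimator; Cox
proportional-hazards models maximize the partial likelihood with the Efron
tie correction and report Wald hazard ratios, 95% CIs, and p-values against
the stated reference levels (stage 1, age < 65, endometrioid histology,
dTLS absent).  Two-group comparisons use the Mann-Whitney U test (or the
Wilcoxon signed-rank test when paired); correlations use Spearman's rank
coefficient.  No multiple-testing adjustment is applied; p-values are
reported unadjusted.

Model fitting is delegated to lifelines and scipy.stats behind this module's
surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import AnalysisError


@dataclass
class CoxResult:
    table: pd.DataFrame  # index: covariate; columns: hr, ci_lower, ci_upper, p
    n: int
    events: int

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def censor_at(
    df: pd.DataFrame,
    horizon_years: Optional[float] = None,
    time_col: str = "os_years",
    event_col: str = "os_event",
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Administratively censor at the horizon: times beyond it are clamped
    to the horizon with the event flag cleared.  Idempotent."""
    horizon = config.censor_years if horizon_years is None else horizon_years
    if horizon <= 0:
        raise AnalysisError("censoring horizon must be > 0")
    out = df.copy()
    over = out[time_col] > horizon
    out.loc[over, time_col] = horizon
    out.loc[over, event_col] = 0
    return out


def km_estimate(
    df: pd.DataFrame,
    time_col: str = "os_years",
    event_col: str = "os_event",
    group_by: Optional[str] = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group: columns time, survival.

    Curves start at S(0) = 1 and step at observed event times.  Empty groups
    are omitted.
    """
    groups = {"all": df} if group_by is None else {
        str(k): g for k, g in df.groupby(group_by) if len(g)
    }
    out = {}
    for name, g in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(g[time_col], event_observed=g[event_col])
        sf = kmf.survival_function_
        out[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def prepare_covariates(
    df: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Expand clinical columns into the model design used throughout.

    stage → indicator columns stage_2/3/4 against reference stage 1;
    age → ``age_ge_65`` (cutoff configurable); histology → ``histology_other``
    against endometrioid; dtls_positive → ``dtls_present``.  Columns absent
    from the input are skipped.
    """
    out = pd.DataFrame(index=df.index)
    if "stage" in df:
        stage = df["stage"].astype(int)
        for s in (2, 3, 4):
            out[f"stage_{s}"] = (stage == s).astype(float)
    if "age" in df:
        out[f"age_ge_{int(config.age_cutoff)}"] = (
            df["age"] >= config.age_cutoff
        ).astype(float)
    if "histology" in df:
        out["histology_other"] = (df["histology"] != "endometrioid").astype(float)
    if "dtls_positive" in df:
        out["dtls_present"] = df["dtls_positive"].astype(float)
    return out


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "os_years",
    event_col: str = "os_event",
) -> CoxResult:
    """Multivariable Cox PH fit (Efron ties) over pre-expanded covariates.

    ``covariates`` are numeric columns of ``df`` (see
    :func:`prepare_covariates`).  Raises :class:`AnalysisError` on zero
    events or non-identifiable (separated / constant-covariate) data.
    """
    covariates = list(covariates)
    events = int(df[event_col].sum())
    if events == 0:
        raise AnalysisError("no observed events; Cox model not identifiable")
    sub = df[[time_col, event_col, *covariates]].astype(float)
    for c in covariates:
        if sub[c].nunique() < 2:
            raise AnalysisError(f"covariate {c} is constant; not identifiable")
    cph = CoxPHFitter()
    try:
        # tight Newton tolerance: partial-likelihood optimum to ~1e-9
        cph.fit(sub, duration_col=time_col, event_col=event_col,
                fit_options={"precision": 1e-9})
    except ConvergenceError as exc:
        raise AnalysisError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_lower": np.exp(summ["coef lower 95%"]),
            "ci_upper": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    return CoxResult(table=table, n=len(sub), events=events)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
    alternative: str = "two-sided",
    exact_limit: int = 25,
) -> tuple[float, float]:
    """Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired): (statistic, p).

    Exact null distribution for small samples without ties; normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise AnalysisError("paired comparison requires equal lengths")
        res = stats.wilcoxon(a, b, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    method = "exact" if max(len(a), len(b)) <= exact_limit else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    except ValueError:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def cohort_summary(values: pd.Series, name: str = "variable") -> pd.DataFrame:
    """Counts and percentages (1 decimal) per level of a categorical variable.

    Missing values form their own ``NA`` level so levels always sum to N.
    """
    v = values.astype("object").where(values.notna(), "NA")
    counts = v.value_counts(dropna=False)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "variable": name,
            "level": counts.index.astype(str),
            "n": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    ).reset_index(drop=True)


def summary_from_counts(counts: dict[str, int], name: str = "variable") -> pd.DataFrame:
    """Same report as :func:`cohort_summary` from pre-tabulated level counts."""
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "variable": name,
            "level": list(counts),
            "n": list(counts.values()),
            "percent": [round(100.0 * n / total, 1) for n in counts.values()],
        }
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties: (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise AnalysisError("spearman_corr requires equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise AnalysisError("spearman correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
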