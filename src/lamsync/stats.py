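"""Inferential layer: dose-stepped Kaplan–Meier with log-rank,
factorial ANOVA with Holm–Šidák post hoc, t-tests, Pearson correlation.

The incidence of burst/suppression is analysed as a survival problem on a
*discrete ordered dose axis*: isoflurane steps 3.0→2.0→1.0→0.5% play the
role of time (steps 1–4), the "event" is the first appearance of
burst/suppression while the dose is lowered, and animals that never show
it by 0.5% are censored at the last step.  The standard log-rank test
with its discrete ties correction applies unchanged.

Unbalanced factorial designs use Type-III sums of squares (with sum
contrasts), documented here so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .core import ISOFLURANE_LEVELS

#: dose % → ordered step (the survival "time" axis)
DOSE_STEP = {dose: i + 1 for i, dose in enumerate(ISOFLURANE_LEVELS)}
STEP_DOSE = {v: k for k, v in DOSE_STEP.items()}


@dataclass
class SurvivalResult:
    """Per-group burst/suppression-free step functions + log-rank test."""

    step_functions: dict        # group → (steps, fraction event-free)
    median_onset_level: dict    # group → dose % or None
    logrank_chi2: float | None
    logrank_p: float | None
    flagged: str | None = None  # set when the test is undefined


@dataclass
class AnovaResult:
    table: pd.DataFrame         # effect → F, df, p
    posthoc: pd.DataFrame | None = None

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def pearson(x, y) -> dict:
    """Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n ≥ 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = sstats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue),
            "n": len(x)}


def ttest(a, b, equal_var: bool = True) -> dict:
    """Two-sample Student t-test (two-sided)."""
    res = sstats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=equal_var)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "df": float(res.df)}


def holm_sidak(pvalues, alpha: float = 0.05) -> dict:
    """Step-down Holm–Šidák procedure.

    Sorted ascending, the hypothesis at rank i of m is tested at
    ``1 − (1 − α)^{1/(m−i+1)}``; rejection stops at the first failure.
    Adjusted p-values are the monotone ``1 − (1 − p)^{m−i+1}``.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha,
                                        method="holm-sidak")
    return {"reject": reject, "p_adjusted": p_adj, "alpha": alpha}


def kaplan_meier_logrank(records) -> SurvivalResult:
    """Kaplan–Meier estimates per group over dose steps + log-rank test.

    ``records`` are :class:`~lamsync.bursts.IncidenceRecord`-like objects
    with ``group``, ``onset_level`` and ``event`` attributes.
    """
    rows = []
    for r in records:
        step = DOSE_STEP[r.onset_level] if r.event else max(DOSE_STEP.values())
        rows.append({"group": r.group, "step": step, "event": bool(r.event)})
    df = pd.DataFrame(rows)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (df["group"] == g).sum() < 1:
            raise ValueError(f"group {g!r} has no records")

    step_functions, medians = {}, {}
    for g in groups:
        sub = df[df["group"] == g]
        km = KaplanMeierFitter()
        km.fit(sub["step"], event_observed=sub["event"])
        steps = np.array(sorted(DOSE_STEP.values()))
        surv = np.array([float(km.predict(s)) for s in steps])
        step_functions[g] = (steps, surv)
        below = steps[surv <= 0.5]
        medians[g] = STEP_DOSE[int(below[0])] if len(below) else None

    if not df["event"].any():
        return SurvivalResult(step_functions, medians, None, None,
                              flagged="no events observed; test undefined")
    res = multivariate_logrank_test(df["step"], df["group"], df["event"])
    return SurvivalResult(step_functions, medians,
                          float(res.test_statistic), float(res.p_value))


def factorial_anova(data: pd.DataFrame, response: str,
                    factors: list[str]) -> AnovaResult:
    """Fixed-effects factorial ANOVA (Type-III SS, sum contrasts).

    All main effects and interactions among ``factors`` are estimated.
    Raises when a cell of the full factorial cross is empty, naming it.
    """
    df = data.copy()
    for f in factors:
        levels = df[f].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} needs ≥2 levels")
    counts = df.groupby(factors, observed=True).size()
    full = pd.MultiIndex.from_product(
        [df[f].unique() for f in factors], names=factors) \
        if len(factors) > 1 else pd.Index(df[factors[0]].unique(),
                                          name=factors[0])
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"empty design cell(s): {list(missing)[:5]}")

    if np.std(df[response].to_numpy(dtype=float)) == 0:
        effects = _effect_names(factors)
        table = pd.DataFrame({"F": 0.0, "df": np.nan, "p": 1.0},
                             index=effects)
        return AnovaResult(table=table)

    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    model = ols(f"{response} ~ {terms}", data=df).fit()
    aov = anova_lm(model, typ=3)
    aov = aov.drop(index=[i for i in ("Intercept", "Residual")
                          if i in aov.index])
    clean_index = [i.replace("C(", "").replace(", Sum)", "")
                   for i in aov.index]
    table = pd.DataFrame({"F": aov["F"].to_numpy(),
                          "df": aov["df"].to_numpy(),
                          "p": aov["PR(>F)"].to_numpy()},
                         index=clean_index)
    return AnovaResult(table=table)


def _effect_names(factors: list[str]) -> list[str]:
    from itertools import combinations
    names = []
    for k in range(1, len(factors) + 1):
        for combo in combinations(factors, k):
            names.append(":".join(combo))
    return names


def logrank_by_hand(records) -> float:
    """Independent O−E log-rank chi-square for exactly two groups.

    Textbook discrete computation (hypergeometric variance with ties);
    kept as a cross-check of the packaged test, not a replacement.
    """
    rows = []
    for r in records:
        step = DOSE_STEP[r.onset_level] if r.event else max(DOSE_STEP.values())
        rows.append((r.group, step, bool(r.event)))
    groups = sorted({g for g, _, _ in rows})
    if len(groups) != 2:
        raise ValueError("hand computation covers two groups")
    g0 = groups[0]
    steps = sorted({s for _, s, e in rows if e})
    o_minus_e, var = 0.0, 0.0
    for s in steps:
        n_at = sum(1 for _, t, _ in rows if t >= s)
        n0_at = sum(1 for g, t, _ in rows if t >= s and g == g0)
        d = sum(1 for _, t, e in rows if t == s and e)
        d0 = sum(1 for g, t, e in rows if t == s and e and g == g0)
        if n_at == 0:
            continue
        e0 = d * n0_at / n_at
        o_minus_e += d0 - e0
        if n_at > 1:
            var += (d * (n0_at / n_at) * (1 - n0_at / n_at)
                    * (n_at - d) / (n_at - 1))
    if var == 0:
        return 0.0
    return float(o_minus_e ** 2 / var)
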