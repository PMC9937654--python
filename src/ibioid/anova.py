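"""Two-factor ANOVA with Bonferroni post-hoc comparisons.

The category summaries are compared across genotype × bait with a factorial
two-way ANOVA (interaction included). The fit goes through statsmodels
(OLS + Type II sums of squares — identical to the textbook decomposition on
balanced designs, deterministic on the near-balanced designs the analysis
produces). Post-hoc tests compare each mutant genotype to control within
each bait with two-sample t-tests, multiplying p by the number of
comparisons performed (Bonferroni, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import ValidationError


class DegenerateDataError(ValueError):
    """All observations identical — no variance to decompose."""


@dataclass
class AnovaResult:
    """F and p per effect, plus Bonferroni-adjusted post-hoc p-values."""

    effects: pd.DataFrame  # index: genotype, bait, interaction; cols F, p, df
    posthoc: pd.DataFrame  # genotype, bait, t, p_raw, p_adj, skipped
    ss_type: int = 2
    n_comparisons: int = 0


def two_way_anova_bonferroni(
    obs: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "bait",
    control_level: str = "CONTROL",
) -> AnovaResult:
    """Factorial two-way ANOVA on a tidy observation frame.

    ``obs`` needs columns ``value``, ``factor_a``, ``factor_b`` with ≥2
    levels per factor. Returns F/p for both main effects and the
    interaction, and per-(mutant, bait) Bonferroni-adjusted comparisons
    against ``control_level``. Cells with fewer than two observations on
    either side are skipped and flagged.
    """
    df = obs[[value, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} needs >= 2 levels")
    if np.ptp(df[value].to_numpy()) == 0.0:
        raise DegenerateDataError("all observations are identical")

    df = df.rename(columns={value: "y", factor_a: "A", factor_b: "B"})
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)

    effects = pd.DataFrame(
        {
            "F": [
                tab.loc["C(A)", "F"],
                tab.loc["C(B)", "F"],
                tab.loc["C(A):C(B)", "F"],
            ],
            "p": [
                tab.loc["C(A)", "PR(>F)"],
                tab.loc["C(B)", "PR(>F)"],
                tab.loc["C(A):C(B)", "PR(>F)"],
            ],
            "df": [
                tab.loc["C(A)", "df"],
                tab.loc["C(B)", "df"],
                tab.loc["C(A):C(B)", "df"],
            ],
        },
        index=[factor_a, factor_b, "interaction"],
    )

    mutants = sorted(set(df["A"]) - {control_level})
    baits = sorted(set(df["B"]))
    comparisons = []
    for mut in mutants:
        for b in baits:
            x = df.loc[(df["A"] == control_level) & (df["B"] == b), "y"].to_numpy()
            y = df.loc[(df["A"] == mut) & (df["B"] == b), "y"].to_numpy()
            skipped = len(x) < 2 or len(y) < 2
            if skipped:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(x, y, equal_var=True)
            comparisons.append(
                {
                    "genotype": mut,
                    "bait": b,
                    "t": float(t) if not skipped else np.nan,
                    "p_raw": float(p) if not skipped else np.nan,
                    "skipped": skipped,
                }
            )
    posthoc = pd.DataFrame(comparisons)
    m = int((~posthoc["skipped"]).sum()) if len(posthoc) else 0
    posthoc["p_adj"] = np.minimum(posthoc["p_raw"] * m, 1.0)
    return AnovaResult(effects=effects, posthoc=posthoc, ss_type=2, n_comparisons=m)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Adjusted p-values: raw p × family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    return np.minimum(p * m, 1.0)
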