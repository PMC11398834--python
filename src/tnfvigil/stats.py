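"""Disproportionality statistics: ROR with Woolf CI, BCPNN information
component with its lower credible bound, association p-values and the
composite signal verdict.

Conventions
-----------
ROR
    (a*d)/(b*c) with the 95% CI on the log scale,
    exp(ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d)).  If any cell is zero,
    the Haldane-Anscombe +0.5 continuity correction is applied to all
    four cells and the row is flagged ``corrected``.

IC (information component)
    With expected count E = (a+b)(a+c)/N, the shrunk observed-to-expected
    log-ratio IC = log2((a + 0.5) / (E + 0.5)).  The default lower 2.5%
    credible bound uses the closed-form approximation
    IC025 = IC - 3.3 (a+0.5)^{-1/2} - 2 (a+0.5)^{-3/2}; an exact
    Gamma-posterior quantile and the classical Beta-prior normal
    approximation are available as variants.

Signal
    ROR025 > 1 AND a > count_threshold AND IC025 > 0 (optionally also
    Bonferroni-adjusted p < 0.05, off by default).  The Bonferroni family
    is the number of distinct events tested for the same drug and stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ror_with_ci",
    "bcpnn_ic",
    "pvalue",
    "classify_signal",
    "evaluate_signals",
    "top_k_by_ror",
]


def ror_with_ci(a, b, c, d, alpha: float = 0.05):
    """Reporting odds ratio and Woolf (log-scale) CI; vectorized.

    Returns ``(ror, lo, hi, corrected)`` where ``corrected`` marks rows
    on which the Haldane-Anscombe +0.5 correction was applied because of
    a zero cell.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    corrected = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    aa = np.where(corrected, a + 0.5, a)
    bb = np.where(corrected, b + 0.5, b)
    cc = np.where(corrected, c + 0.5, c)
    dd = np.where(corrected, d + 0.5, d)
    ror = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = sps.norm.ppf(1 - alpha / 2)
    lo = ror * np.exp(-z * se)
    hi = ror * np.exp(z * se)
    return ror, lo, hi, corrected


def bcpnn_ic(a, b, c, d, variant: str = "noren"):
    """BCPNN information component and its lower 2.5% credible bound.

    ``variant``:

    * ``"noren"`` — shrunk IC with the closed-form IC025 approximation
      (deterministic, the default).
    * ``"gamma"`` — same shrunk IC, IC025 as the exact 2.5% quantile of
      the Gamma(a + 0.5, 1) posterior of the observed-count intensity
      divided by E + 0.5.
    * ``"bate"`` — classical Beta-prior formulation: posterior mean and
      a normal approximation of the 2.5% bound from the posterior
      variance.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    if np.any(n <= 0):
        raise ValueError("N must be positive")
    e = (a + b) * (a + c) / n
    if variant in ("noren", "gamma"):
        ic = np.log2((a + 0.5) / (e + 0.5))
        if variant == "noren":
            ic_lo = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
        else:
            q = sps.gamma.ppf(0.025, a + 0.5)
            ic_lo = np.log2(q / (e + 0.5))
        return ic, ic_lo
    if variant == "bate":
        # Bate et al. Beta-prior posterior moments of the IC
        alpha1 = beta1 = 1.0
        alpha = beta = 2.0
        gamma11 = 1.0
        gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
        ln2 = np.log(2.0)
        e_ic = (
            np.log((a + gamma11) * (n + alpha) * (n + beta))
            - np.log((n + gamma) * (a + b + alpha1) * (a + c + beta1))
        ) / ln2
        v_ic = (
            (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
            + (n - (a + b) + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha))
            + (n - (a + c) + beta - beta1) / ((a + c + beta1) * (1 + n + beta))
        ) / (ln2**2)
        ic_lo = e_ic - sps.norm.ppf(0.975) * np.sqrt(v_ic)
        return e_ic, ic_lo
    raise ValueError(f"unknown IC variant {variant!r}")


def expected_count(a, b, c, d):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    return (a + b) * (a + c) / (a + b + c + d)


def pvalue(a, b, c, d, method: str = "auto"):
    """Two-sided association p-value for one 2x2 table.

    ``method="chi2_yates"`` forces the Yates-corrected chi-square,
    ``"fisher_exact"`` forces Fisher's exact test, ``"auto"`` (default)
    uses chi-square and falls back to Fisher whenever any expected cell
    is below 5.  Degenerate margins (no drug reports or no event reports)
    give p = 1.
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0 or (a + b) == 0 or (a + c) == 0 or (c + d) == 0 or (b + d) == 0:
        return 1.0
    table = [[a, b], [c, d]]
    if method == "auto":
        expected = np.outer([a + b, c + d], [a + c, b + d]) / n
        method = "fisher_exact" if expected.min() < 5 else "chi2_yates"
    if method == "chi2_yates":
        _, p, _, _ = sps.chi2_contingency(table, correction=True)
        return float(p)
    if method == "fisher_exact":
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return float(p)
    raise ValueError(f"unknown p-value method {method!r}")


def classify_signal(
    ror_lo,
    a,
    ic_lo,
    p_adj=None,
    count_threshold: int = 3,
    require_significance: bool = False,
):
    """Composite signal verdict; vectorized.

    True iff ROR025 > 1 and the report count a is strictly greater than
    ``count_threshold`` and IC025 > 0; when ``require_significance`` is
    set, additionally the Bonferroni-adjusted p must be below 0.05.
    """
    ror_lo = np.asarray(ror_lo, dtype=float)
    a = np.asarray(a, dtype=float)
    ic_lo = np.asarray(ic_lo, dtype=float)
    verdict = (ror_lo > 1.0) & (a > count_threshold) & (ic_lo > 0.0)
    if require_significance:
        if p_adj is None:
            raise ValueError("require_significance needs p_adj")
        verdict = verdict & (np.asarray(p_adj, dtype=float) < 0.05)
    return verdict


def evaluate_signals(
    tables: pd.DataFrame,
    count_threshold: int = 3,
    alpha: float = 0.05,
    ic_variant: str = "noren",
    require_significance: bool = False,
    p_method: str = "auto",
) -> pd.DataFrame:
    """Score every 2x2 table and attach the composite verdict.

    Input is the tidy table frame from :func:`tnfvigil.contingency.build_tables`.
    The Bonferroni ``family_size`` is the number of distinct events tested
    for the same (drug, stratum), matching per-drug signal lists.
    """
    df = tables.copy()
    ror, lo, hi, corrected = ror_with_ci(df["a"], df["b"], df["c"], df["d"], alpha)
    ic, ic_lo = bcpnn_ic(df["a"], df["b"], df["c"], df["d"], variant=ic_variant)
    df["ror"], df["ror_lo"], df["ror_hi"] = ror, lo, hi
    df["ic"], df["ic_lo"] = ic, ic_lo
    df["corrected"] = corrected
    df["expected"] = expected_count(df["a"], df["b"], df["c"], df["d"])
    df["p_raw"] = [
        pvalue(a, b, c, d, method=p_method)
        for a, b, c, d in zip(df["a"], df["b"], df["c"], df["d"])
    ]
    df["family_size"] = df.groupby(["drug", "stratum"])["event"].transform("size")
    df["p_adj"] = np.minimum(1.0, df["p_raw"] * df["family_size"])
    df["is_signal"] = classify_signal(
        df["ror_lo"],
        df["a"],
        df["ic_lo"],
        df["p_adj"],
        count_threshold=count_threshold,
        require_significance=require_significance,
    )
    return df


def top_k_by_ror(signals: pd.DataFrame, k: int = 30, stratum: str = "all") -> pd.DataFrame:
    """Forest-plot-ready per-drug top-k positive signals ranked by ROR."""
    sub = signals[(signals["stratum"] == stratum) & signals["is_signal"]]
    return (
        sub.sort_values(["drug", "ror"], ascending=[True, False], kind="stable")
        .groupby("drug", sort=False)
        .head(k)
        .reset_index(drop=True)
    )
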