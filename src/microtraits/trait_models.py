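"""Linear and smooth additive trait-environment models.

The headline models are penalized-regression-spline additive models
(Gaussian family, identity link): soil pH regressed on smooths of
organic matter and the community-weighted trait means, and community
niche breadth (``ave.snb``) regressed on smooths of organic matter, pH
and the trait means.  Smoothing parameters are chosen by generalized
cross-validation; each smooth term is scored by an approximate F test
obtained by refitting without the term at the selected penalties.
Simple ordinary-least-squares fits cover the scatter-plot relationships
(pH~OM, ave.gs~ave.rrna, simpson~pH, ave.snb~ave.gs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import logger

DEFAULT_BASIS_DF = 10

#: the two headline additive-model formulas: response -> smooth terms
MODEL_FORMULAS = {
    "pH": ["Organic_Matter_LOI", "ave.gs", "ave.rrna", "ave.gc"],
    "ave.snb": ["Organic_Matter_LOI", "pH", "ave.gs", "ave.rrna", "ave.gc"],
}

#: the figure-style linear regressions: (x, y)
LINEAR_PAIRS = [
    ("pH", "Organic_Matter_LOI"),
    ("ave.rrna", "ave.gs"),
    ("pH", "simpson"),
    ("ave.gs", "ave.snb"),
]


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


@dataclass
class LinearFitSummary:
    slope: float
    intercept: float
    r_squared: float
    r_squared_adj: float
    p_value: float
    n: int


@dataclass
class SmoothModelSummary:
    response: str
    terms: pd.DataFrame          # per-smooth: edf, ref_df, F, p, stars
    intercept: float
    intercept_se: float
    r_squared_adj: float
    deviance_explained: float    # percent
    gcv: float
    scale: float
    n: int
    alphas: list = field(default_factory=list, repr=False)
    fitted: pd.Series = field(default=None, repr=False)


def linear_fit(x: pd.Series, y: pd.Series) -> LinearFitSummary:
    """Ordinary least squares of y on x with a two-sided slope t-test."""
    df = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(df["x"].to_numpy()) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(df["x"], df["y"])
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return LinearFitSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        r_squared_adj=float(r2_adj),
        p_value=float(res.pvalue),
        n=n,
    )


def _make_splines(x: np.ndarray, k: int, basis_df: int):
    from statsmodels.gam.api import BSplines

    return BSplines(x, df=[basis_df] * k, degree=[3] * k, include_intercept=False)


def fit_additive_model(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    basis_df: int = DEFAULT_BASIS_DF,
    alphas: list[float] | None = None,
    min_n: int = 30,
) -> SmoothModelSummary:
    """Penalized-regression-spline additive model with GCV smoothing.

    Each smooth term's effective degrees of freedom come from the
    influence matrix at the selected penalties; its approximate F test
    compares the residual sums of squares with and without the term,
    holding the other penalties fixed.  ``alphas`` overrides the GCV
    search (useful to force maximal smoothing).
    """
    from statsmodels.gam.api import GLMGam

    if len(set(terms)) != len(terms):
        raise ValueError("duplicate smooth terms")
    missing = [c for c in [response, *terms] if c not in data.columns]
    if missing:
        raise ValueError(f"missing model columns: {missing}")
    sub = data[[response, *terms]].dropna()
    n = len(sub)
    if n < min_n:
        raise ValueError(f"need at least {min_n} complete cases, got {n}")
    for t in terms:
        if np.ptp(sub[t].to_numpy()) == 0:
            raise ValueError(f"term {t!r} is constant")
    y = sub[response].to_numpy(dtype=float)
    xmat = sub[terms].to_numpy(dtype=float)
    k = len(terms)
    bs = _make_splines(xmat, k, basis_df)
    exog = np.ones((n, 1))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alphas is None:
            gam = GLMGam(y, exog, smoother=bs, alpha=[1.0] * k)
            try:
                gam.fit()
                # fixed internal seed: the basinhopping search must not
                # couple fits to the caller's global random state
                alphas = list(
                    gam.select_penweight(criterion="gcv", seed=0)[0]
                )
            except Exception as exc:
                raise RuntimeError(
                    f"smoothing-parameter selection failed for {response!r}: {exc}"
                ) from exc
        res = GLMGam(y, exog, smoother=bs, alpha=alphas).fit()

    edf = np.asarray(res.edf)
    edf_total = float(edf.sum())
    fitted = np.asarray(res.fittedvalues)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    scale = rss / (n - edf_total)
    gcv = n * rss / (n - edf_total) ** 2
    r2_adj = 1.0 - (rss / (n - edf_total)) / (tss / (n - 1))
    dev_expl = 100.0 * (1.0 - rss / tss)

    # column block of each smooth inside the parameter vector
    starts = [1]
    for j in range(k):
        starts.append(starts[-1] + bs.smoothers[j].basis.shape[1])

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, term in enumerate(terms):
            edf_j = float(edf[starts[j]:starts[j + 1]].sum())
            others = [i for i in range(k) if i != j]
            if others:
                bs_red = _make_splines(xmat[:, others], len(others), basis_df)
                res_red = GLMGam(
                    y, exog, smoother=bs_red, alpha=[alphas[i] for i in others]
                ).fit()
                rss_red = float(np.sum((y - np.asarray(res_red.fittedvalues)) ** 2))
            else:
                rss_red = tss
            df_test = max(edf_j, 0.5)
            fstat = max(rss_red - rss, 0.0) / df_test / scale
            p = float(stats.f.sf(fstat, df_test, n - edf_total))
            rows.append(
                {
                    "term": f"s({term})",
                    "edf": edf_j,
                    "ref_df": df_test,
                    "F": fstat,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    term_table = pd.DataFrame(rows).set_index("term")
    summary = SmoothModelSummary(
        response=response,
        terms=term_table,
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        r_squared_adj=float(r2_adj),
        deviance_explained=float(dev_expl),
        gcv=float(gcv),
        scale=float(scale),
        n=n,
        alphas=list(alphas),
        fitted=pd.Series(fitted, index=sub.index),
    )
    logger.info(
        "fit_additive_model: %s ~ %s  adj-R2=%.3f dev=%.1f%% n=%d",
        response,
        " + ".join(f"s({t})" for t in terms),
        r2_adj,
        dev_expl,
        n,
    )
    return summary


def merge_model_table(
    profiles: pd.DataFrame,
    meta: pd.DataFrame,
    coverage: pd.DataFrame | None = None,
    coverage_floor: float = 0.5,
) -> pd.DataFrame:
    """Join per-sample trait profiles with metadata for modelling.

    Samples whose annotated-read fraction falls below ``coverage_floor``
    for any assigned trait are refused (dropped with a warning).
    """
    table = profiles.join(meta, how="inner")
    table = table.rename(columns={"om_loi": "Organic_Matter_LOI"})
    if coverage is not None:
        cov_cols = [c for c in ("ave.gs", "ave.rrna", "ave.gc") if c in coverage]
        ok = (coverage[cov_cols] >= coverage_floor).all(axis=1)
        dropped = ok.index[~ok.reindex(table.index, fill_value=False)]
        low = [s for s in table.index if s in dropped]
        if low:
            logger.warning(
                "merge_model_table: refused %d samples below %.0f%% trait "
                "read coverage",
                len(low),
                100 * coverage_floor,
            )
            table = table.drop(index=low)
    return table


def model_battery(
    profiles: pd.DataFrame,
    meta: pd.DataFrame,
    coverage: pd.DataFrame | None = None,
    coverage_floor: float = 0.5,
    basis_df: int = DEFAULT_BASIS_DF,
) -> dict:
    """Fit the two headline additive models plus the four figure
    regressions and collect one machine-readable report.

    Term p-values additionally get a Benjamini-Hochberg adjustment across
    the terms of each model (the ``p_adj`` column).
    """
    from statsmodels.stats.multitest import multipletests

    table = merge_model_table(profiles, meta, coverage, coverage_floor)
    required = {"pH", "Organic_Matter_LOI", "ave.gs", "ave.rrna", "ave.gc",
                "ave.snb", "simpson"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"missing model columns: {missing}")

    gams: dict[str, SmoothModelSummary] = {}
    report_rows = []
    for response, terms in MODEL_FORMULAS.items():
        summary = fit_additive_model(table, response, terms, basis_df=basis_df)
        padj = multipletests(summary.terms["p"], method="fdr_bh")[1]
        summary.terms["p_adj"] = padj
        gams[response] = summary
        for term, row in summary.terms.iterrows():
            report_rows.append(
                {
                    "model": f"gam:{response}",
                    "term": term,
                    "estimate": np.nan,
                    "edf": row["edf"],
                    "F": row["F"],
                    "p": row["p"],
                    "p_adj": row["p_adj"],
                    "stars": row["stars"],
                    "n": summary.n,
                }
            )

    linears: dict[str, LinearFitSummary] = {}
    for xcol, ycol in LINEAR_PAIRS:
        fit = linear_fit(table[xcol], table[ycol])
        key = f"{ycol}~{xcol}"
        linears[key] = fit
        report_rows.append(
            {
                "model": f"lm:{key}",
                "term": xcol,
                "estimate": fit.slope,
                "edf": 1.0,
                "F": np.nan,
                "p": fit.p_value,
                "p_adj": fit.p_value,
                "stars": significance_stars(fit.p_value),
                "n": fit.n,
            }
        )
    report = pd.DataFrame(report_rows)
    return {"gams": gams, "linear": linears, "report": report, "table": table}
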