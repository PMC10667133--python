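"""Progression statistics: paired tests, logistic risk models, agreement.

This is the statistical stage of the pipeline, exposed statsmodels-style:
:class:`ProgressionModel` wraps a two-visit cohort table and ``fit()``
returns a :class:`ProgressionResults` carrying per-slab paired tests and
univariate/multivariate logistic odds ratios with Wald 95% CIs, plus a
``summary()`` text table.  Free functions implement each primitive so the
pieces are independently testable and scriptable.

Conventions
-----------
* Paired differences are follow-up minus baseline, so a positive t
  statistic means lesion counts increased over the interval.
* Odds ratios come from maximum-likelihood logistic fits; CIs and p-values
  are Wald by default (the SPSS logistic default), with profile-likelihood
  CIs and Firth-penalized estimation available behind flags for the
  univariate model.
* A predictor with no variation, or one exhibiting complete/quasi
  separation, is reported with status ``inestimable`` (the "NA" convention
  of clinical tables) rather than with a wildly diverged estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps
from scipy.special import expit

from ._util import round_half_up

__all__ = [
    "PairedTestResult",
    "RegressionResult",
    "KappaResult",
    "paired_count_test",
    "logistic_univariate",
    "logistic_multivariate",
    "intergrader_agreement",
    "ProgressionModel",
    "ProgressionResults",
    "build_report",
]

COUNT_COLUMNS = [f"base_{k}" for k in range(1, 6)] + [f"fu_{k}" for k in range(1, 6)]

# |coefficient| above this (OR > ~e^12) is treated as a separation artifact
_SEPARATION_COEF = 12.0
_SEPARATION_SE = 30.0


# ---------------------------------------------------------------------------
# paired visit-to-visit comparison


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t on per-eye counts (difference = follow-up - baseline)."""

    t: float
    p: float
    df: int
    n: int
    mean_baseline: float
    sd_baseline: float
    mean_followup: float
    sd_followup: float
    total_baseline: int
    total_followup: int
    status: str = "ok"  # ok | degenerate


def paired_count_test(baseline, followup) -> PairedTestResult:
    """Paired t test of per-eye lesion counts between two visits.

    Differences are taken as follow-up minus baseline.  If every
    difference is identical the t statistic is undefined: identical visits
    give t = 0, p = 1; a constant nonzero shift is flagged ``degenerate``
    (no p-value can be formed from zero-variance differences).
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and follow-up must be equal-length vectors")
    n = b.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    diff = f - b
    summary = dict(
        n=n,
        mean_baseline=float(b.mean()),
        sd_baseline=float(b.std(ddof=1)),
        mean_followup=float(f.mean()),
        sd_followup=float(f.std(ddof=1)),
        total_baseline=int(round(b.sum())),
        total_followup=int(round(f.sum())),
    )
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedTestResult(t=0.0, p=1.0, df=n - 1, status="ok", **summary)
        return PairedTestResult(
            t=float("nan"), p=float("nan"), df=n - 1, status="degenerate", **summary
        )
    res = sps.ttest_rel(f, b)
    return PairedTestResult(
        t=float(res.statistic), p=float(res.pvalue), df=n - 1, status="ok", **summary
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class RegressionResult:
    """One predictor's odds ratio from a logistic progression model."""

    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    model_type: str  # univariate | multivariate
    coding: str  # continuous | categorical
    status: str = "ok"  # ok | inestimable
    note: str = ""

    @property
    def estimable(self) -> bool:
        return self.status == "ok"


def _inestimable(predictor, model_type, coding, note) -> RegressionResult:
    nan = float("nan")
    return RegressionResult(
        predictor, nan, nan, nan, nan, model_type, coding, status="inestimable", note=note
    )


def _predictor_vector(records: pd.DataFrame, slab: int, kind: str, coding: str):
    """Extract one slab predictor: baseline count, 2-year delta, or presence."""
    if kind == "baseline":
        x = records[f"base_{slab}"].to_numpy(dtype=float)
        label = f"slab {slab}"
    elif kind == "delta":
        x = (records[f"fu_{slab}"] - records[f"base_{slab}"]).to_numpy(dtype=float)
        label = f"delta slab {slab}"
    else:
        raise ValueError(f"unknown predictor kind {kind!r}")
    if coding == "categorical":
        # presence vs absence, absence as the reference level
        x = (x > 0).astype(float)
    elif coding != "continuous":
        raise ValueError(f"unknown coding {coding!r}")
    return x, label


def _loglik(y, X, beta):
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _fit_firth(y, X, max_iter=100, tol=1e-8):
    """Firth-penalized logistic fit (Jeffreys-prior bias reduction)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        info = X.T @ (X * W[:, None])
        inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, inv, X * W[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        step = inv @ score
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    p = expit(X @ beta)
    W = p * (1 - p)
    cov = np.linalg.pinv(X.T @ (X * W[:, None]))
    return beta, np.sqrt(np.diag(cov))


def _fit_ml(y, X):
    """ML logistic fit; returns (params, bse, pvalues) or None on separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return None
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.isfinite(params).all() or not np.isfinite(bse).all():
        return None
    if np.abs(params[1:]).max(initial=0.0) > _SEPARATION_COEF or bse.max() > _SEPARATION_SE:
        return None
    return params, bse, np.asarray(res.pvalues, dtype=float)


def _profile_ci_univariate(y, X, beta_hat, se, level=0.95):
    """Profile-likelihood CI for the slope of an intercept+slope logistic fit."""
    crit = sps.chi2.ppf(level, df=1) / 2.0

    def profile_deficit(b1):
        # maximize log-likelihood over the intercept at fixed slope
        def neg(b0):
            return -_loglik(y, X, np.array([b0, b1]))

        res = optimize.minimize_scalar(neg, bracket=(beta_hat[0] - 2, beta_hat[0] + 2))
        return (-res.fun) - (lmax - crit)

    lmax = _loglik(y, X, beta_hat)
    lo_guess, hi_guess = beta_hat[1] - 10 * se, beta_hat[1] + 10 * se
    try:
        lo = optimize.brentq(profile_deficit, lo_guess, beta_hat[1])
        hi = optimize.brentq(profile_deficit, beta_hat[1], hi_guess)
    except ValueError:
        return None
    return lo, hi


def logistic_univariate(
    records: pd.DataFrame,
    slab: int,
    kind: str = "baseline",
    coding: str = "continuous",
    ci_method: str = "wald",
    penalized: bool = False,
) -> RegressionResult:
    """Single-predictor logistic regression of progression on one slab.

    ``kind`` selects the baseline count or the 2-year change; ``coding``
    the continuous count or presence/absence (absence as reference).
    ``ci_method='profile'`` replaces the Wald CI with a profile-likelihood
    interval; ``penalized=True`` uses Firth bias reduction (usable even
    under separation).
    """
    x, label = _predictor_vector(records, slab, kind, coding)
    y = records["progressed"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        return _inestimable(label, "univariate", coding, "single outcome class")
    if np.ptp(x) == 0:
        return _inestimable(label, "univariate", coding, "predictor has no variation")
    X = sm.add_constant(x)

    if penalized:
        params, bse = _fit_firth(y, X)
        z = params[1] / bse[1]
        p = 2 * sps.norm.sf(abs(z))
        lo, hi = params[1] - 1.959963984540054 * bse[1], params[1] + 1.959963984540054 * bse[1]
        return RegressionResult(
            label, math.exp(params[1]), math.exp(lo), math.exp(hi), float(p),
            "univariate", coding, note="firth",
        )

    fit = _fit_ml(y, X)
    if fit is None:
        return _inestimable(label, "univariate", coding, "complete or quasi separation")
    params, bse, pvalues = fit
    beta1, se1 = params[1], bse[1]
    if ci_method == "profile":
        ci = _profile_ci_univariate(y, X, params, se1)
        if ci is None:
            return _inestimable(label, "univariate", coding, "profile CI failed")
        lo, hi = ci
        note = "profile"
    elif ci_method == "wald":
        lo, hi = beta1 - 1.959963984540054 * se1, beta1 + 1.959963984540054 * se1
        note = ""
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RegressionResult(
        label, math.exp(beta1), math.exp(lo), math.exp(hi), float(pvalues[1]),
        "univariate", coding, note=note,
    )


def logistic_multivariate(
    records: pd.DataFrame,
    slabs: Sequence[int],
    kind: str = "baseline",
    coding: str = "continuous",
) -> list:
    """Joint logistic fit over several slab predictors (adjusted ORs).

    Zero-variance or collinear predictors are reported ``inestimable`` and
    the remaining predictors are fitted jointly; if the joint fit itself
    separates, every requested predictor is flagged.
    """
    y = records["progressed"].to_numpy(dtype=float)
    cols, labels, dropped = [], [], []
    if len(np.unique(y)) < 2:
        out = []
        for s in slabs:
            _, label = _predictor_vector(records, s, kind, coding)
            out.append(_inestimable(label, "multivariate", coding, "single outcome class"))
        return out

    for s in slabs:
        x, label = _predictor_vector(records, s, kind, coding)
        if np.ptp(x) == 0:
            dropped.append((label, "predictor has no variation"))
            continue
        candidate = np.column_stack([np.ones_like(y)] + cols + [x])
        if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
            dropped.append((label, "collinear with other predictors"))
            continue
        cols.append(x)
        labels.append(label)

    results = []
    if cols:
        X = sm.add_constant(np.column_stack(cols))
        fit = _fit_ml(y, X)
        if fit is None:
            for label in labels:
                results.append(
                    _inestimable(label, "multivariate", coding, "complete or quasi separation")
                )
        else:
            params, bse, pvalues = fit
            for j, label in enumerate(labels, start=1):
                lo = params[j] - 1.959963984540054 * bse[j]
                hi = params[j] + 1.959963984540054 * bse[j]
                results.append(
                    RegressionResult(
                        label, math.exp(params[j]), math.exp(lo), math.exp(hi),
                        float(pvalues[j]), "multivariate", coding,
                    )
                )
    for label, why in dropped:
        results.append(_inestimable(label, "multivariate", coding, why))
    order = {lab: i for i, lab in enumerate(
        _predictor_vector(records, s, kind, coding)[1] for s in slabs
    )}
    results.sort(key=lambda r: order.get(r.predictor, 99))
    return results


# ---------------------------------------------------------------------------
# inter-grader agreement


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    n: int
    status: str = "ok"  # ok | undefined


def intergrader_agreement(ratings_a, ratings_b) -> KappaResult:
    """Unweighted Cohen's kappa with a large-sample 95% CI.

    The CI uses the standard large-sample standard error
    sqrt(po(1-po) / (n (1-pe)^2)); the p-value tests kappa = 0 with the
    null-hypothesis standard error of Fleiss, Cohen & Everitt.  If both
    graders used only one category agreement is undefined (pe = 1).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length vectors")
    n = a.size
    if n == 0:
        raise ValueError("empty ratings")
    cats = np.unique(np.concatenate([a, b]))
    if cats.size < 2:
        return KappaResult(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            n, status="undefined",
        )
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    table = np.zeros((cats.size, cats.size), dtype=float)
    np.add.at(table, (ai, bi), 1.0)
    po = np.trace(table) / n
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    pe = float(pa @ pb)
    if pe >= 1.0:
        return KappaResult(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            n, status="undefined",
        )
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(max(po * (1 - po), 0.0) / (n * (1 - pe) ** 2))
    z95 = 1.959963984540054
    lo, hi = max(kappa - z95 * se, -1.0), min(kappa + z95 * se, 1.0)
    se0_num = pe + pe**2 - float(((pa + pb) * pa * pb).sum())
    se0 = math.sqrt(max(se0_num, 0.0)) / ((1 - pe) * math.sqrt(n))
    p = 2 * sps.norm.sf(abs(kappa / se0)) if se0 > 0 else float("nan")
    return KappaResult(kappa, lo, hi, se, p, n)


# ---------------------------------------------------------------------------
# model / results objects and report generation


def _fmt_or(r: RegressionResult) -> tuple:
    if not r.estimable:
        return ("NA", "NA", "NA")
    return (
        f"{round_half_up(r.odds_ratio, 2):.2f}",
        f"{round_half_up(r.ci_low, 2):.2f}-{round_half_up(r.ci_high, 2):.2f}",
        "<0.001" if r.p < 0.001 else f"{round_half_up(r.p, 3):.3f}",
    )


class ProgressionModel:
    """Two-visit cohort model of progression risk from per-slab IHRF counts.

    Parameters
    ----------
    cohort : DataFrame with columns ``base_1..base_5``, ``fu_1..fu_5`` and
        boolean ``progressed`` (one row per eye).
    """

    def __init__(self, cohort: pd.DataFrame):
        missing = [c for c in COUNT_COLUMNS + ["progressed"] if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns: {missing}")
        if (cohort[COUNT_COLUMNS] < 0).any().any():
            raise ValueError("lesion counts must be non-negative")
        self.cohort = cohort.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "ProgressionModel":
        return cls(pd.read_csv(path))

    @property
    def n_eyes(self) -> int:
        return len(self.cohort)

    def fit(self, multivariate_slabs: Optional[Sequence[int]] = None) -> "ProgressionResults":
        """Fit every stage: paired tests, quantitative, delta, qualitative.

        ``multivariate_slabs=None`` selects, per table, the slabs whose
        predictor varies in the data (for cohorts shaped like the reference
        study this is slabs 1-3 at baseline).
        """
        rec = self.cohort
        paired = {}
        for k in range(1, 6):
            paired[k] = paired_count_test(rec[f"base_{k}"], rec[f"fu_{k}"])

        def _auto(kind, coding):
            slabs = []
            for k in range(1, 6):
                x, _ = _predictor_vector(rec, k, kind, coding)
                if np.ptp(x) > 0:
                    slabs.append(k)
            return slabs

        tables = {}
        for name, kind, coding in (
            ("baseline_quantitative", "baseline", "continuous"),
            ("delta_quantitative", "delta", "continuous"),
            ("baseline_qualitative", "baseline", "categorical"),
        ):
            uni = [logistic_univariate(rec, k, kind, coding) for k in range(1, 6)]
            mv_slabs = (
                list(multivariate_slabs) if multivariate_slabs is not None else _auto(kind, coding)
            )
            multi = logistic_multivariate(rec, mv_slabs, kind, coding)
            tables[name] = (uni, multi)

        return ProgressionResults(self, paired, tables)


class ProgressionResults:
    """Fitted progression statistics with summary tables."""

    def __init__(self, model: ProgressionModel, paired: dict, tables: dict):
        self.model = model
        self.paired_tests = paired
        self._tables = tables

    # -- assembled report tables -------------------------------------------

    def table_counts(self) -> pd.DataFrame:
        """Per-slab totals, mean +/- SD per visit, and the paired-test p."""
        rows = []
        for k in range(1, 6):
            r = self.paired_tests[k]
            p = (
                "NA"
                if r.status != "ok"
                else ("<0.001" if r.p < 0.001 else f"{round_half_up(r.p, 3):.3f}")
            )
            rows.append(
                dict(
                    slab=k,
                    baseline_total=r.total_baseline,
                    baseline_mean=round_half_up(r.mean_baseline, 1),
                    baseline_sd=round_half_up(r.sd_baseline, 2),
                    followup_total=r.total_followup,
                    followup_mean=round_half_up(r.mean_followup, 1),
                    followup_sd=round_half_up(r.sd_followup, 2),
                    p_value=p,
                )
            )
        return pd.DataFrame(rows)

    def _or_table(self, name: str) -> pd.DataFrame:
        uni, multi = self._tables[name]
        multi_by_label = {r.predictor: r for r in multi}
        rows = []
        for r in uni:
            m = multi_by_label.get(
                r.predictor,
                _inestimable(r.predictor, "multivariate", r.coding, "not in joint model"),
            )
            u_or, u_ci, u_p = _fmt_or(r)
            m_or, m_ci, m_p = _fmt_or(m)
            rows.append(
                dict(
                    predictor=r.predictor,
                    uni_or=u_or, uni_ci=u_ci, uni_p=u_p,
                    multi_or=m_or, multi_ci=m_ci, multi_p=m_p,
                )
            )
        return pd.DataFrame(rows)

    def table_baseline_quantitative(self) -> pd.DataFrame:
        return self._or_table("baseline_quantitative")

    def table_delta_quantitative(self) -> pd.DataFrame:
        return self._or_table("delta_quantitative")

    def table_baseline_qualitative(self) -> pd.DataFrame:
        return self._or_table("baseline_qualitative")

    def regression(self, name: str, model_type: str = "univariate") -> list:
        """Raw RegressionResult objects for one table and model type."""
        uni, multi = self._tables[name]
        return list(uni if model_type == "univariate" else multi)

    def summary(self) -> str:
        """Human-readable report covering all four analysis tables."""
        n = self.model.n_eyes
        total_b = sum(self.paired_tests[k].total_baseline for k in range(1, 6))
        total_f = sum(self.paired_tests[k].total_followup for k in range(1, 6))
        prog = int(self.model.cohort["progressed"].sum())
        lines = [
            "IHRF progression analysis",
            "=" * 60,
            f"Eyes analyzed: {n}; progressed to late AMD: {prog} "
            f"({round_half_up(100 * prog / n, 1)}%)",
            f"Total IHRF: {total_b} at baseline, {total_f} at follow-up "
            f"(mean per eye {round_half_up(total_b / n, 1)} -> {round_half_up(total_f / n, 1)})",
            "",
            "Per-slab lesion counts (paired t, follow-up - baseline)",
            self.table_counts().to_string(index=False),
            "",
            "Baseline counts (continuous) vs progression",
            self.table_baseline_quantitative().to_string(index=False),
            "",
            "2-year change (continuous) vs progression",
            self.table_delta_quantitative().to_string(index=False),
            "",
            "Baseline presence (categorical) vs progression",
            self.table_baseline_qualitative().to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_slab_counts(self, path=None):
        """Bar chart of per-slab totals at the two visits."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.table_counts()
        fig, ax = plt.subplots(figsize=(6, 4))
        w = 0.38
        ax.bar(t.slab - w / 2, t.baseline_total, w, label="baseline")
        ax.bar(t.slab + w / 2, t.followup_total, w, label="2 years")
        ax.set_xlabel("retinal slab (1 = adjacent to RPE)")
        ax.set_ylabel("total IHRF count")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def build_report(results: ProgressionResults, outdir=None) -> dict:
    """Emit the four analysis tables as CSV plus a text report.

    Returns a dict of DataFrames (+ the report text under ``"report"``);
    if ``outdir`` is given the CSVs and ``report.md`` are written there.
    Missing stages yield an explicit gap note instead of a silent omission.
    """
    from pathlib import Path

    tables = {}
    gaps = []
    builders = {
        "table_counts": results.table_counts,
        "table_baseline_quantitative": results.table_baseline_quantitative,
        "table_delta_quantitative": results.table_delta_quantitative,
        "table_baseline_qualitative": results.table_baseline_qualitative,
    }
    for name, fn in builders.items():
        try:
            tables[name] = fn()
        except Exception as exc:  # partial report with explicit gaps
            gaps.append(f"{name}: {exc}")
    report = results.summary() if not gaps else (
        results.summary() + "\n\nMISSING STAGES:\n" + "\n".join(gaps)
    )
    tables["report"] = report
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.md").write_text(report + "\n")
    return tables
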