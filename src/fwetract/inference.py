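"""Group-comparison statistics and multiplicity control.

Omnibus Kruskal-Wallis, pairwise Mann-Whitney U, Shapiro-Wilk normality
screening, Spearman correlation and dummy-coded regressions (glioblastoma
reference) are delegated to scipy.stats / statsmodels; the family-stratified
Benjamini-Hochberg FDR — the piece that carries the analysis's multiplicity
logic — is implemented here and oracle-tested. All tests are two-sided.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

REFERENCE_GROUP = "glioblastoma"


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    family: str = ""
    groups: tuple[str, ...] = ()
    group_sizes: tuple[int, ...] = ()
    effect_direction: float = 0.0
    q_value: float | None = None
    flag: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RegressionResult:
    outcome: str
    family: str  # "linear" | "logistic"
    coefficients: pd.DataFrame  # term, estimate, std_err, p_value
    covariates: tuple[str, ...] = ()
    flag: str = ""
    model: object = field(default=None, repr=False)


def _clean(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    return arr[np.isfinite(arr)]


def kruskal_wallis(groups: dict[str, np.ndarray] | list[np.ndarray],
                   family: str = "") -> TestResult:
    """Rank-based omnibus test across >= 2 groups (tie-corrected H)."""
    if isinstance(groups, dict):
        names, samples = tuple(groups), [_clean(v) for v in groups.values()]
    else:
        names, samples = tuple(f"g{i}" for i in range(len(groups))), \
            [_clean(v) for v in groups]
    if len(samples) < 2 or any(len(s) < 1 for s in samples):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    if sum(len(s) for s in samples) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal-wallis", 0.0, 1.0, family, names,
                          tuple(len(s) for s in samples),
                          flag="all values identical")
    stat, p = sps.kruskal(*samples)
    return TestResult("kruskal-wallis", float(stat), float(p), family, names,
                      tuple(len(s) for s in samples))


def mann_whitney_pairwise(groups: dict[str, np.ndarray],
                          family: str = "") -> list[TestResult]:
    """Two-sided Mann-Whitney U for every unordered pair of groups.

    Exact p-values for small samples (both n <= 10, no ties), normal
    approximation with continuity and tie correction otherwise.
    """
    names = list(groups)
    cleaned = {k: _clean(v) for k, v in groups.items()}
    results = []
    for a, b in combinations(names, 2):
        xa, xb = cleaned[a], cleaned[b]
        if len(xa) < 1 or len(xb) < 1:
            raise ValueError(f"empty group in pair ({a}, {b})")
        pooled = np.concatenate([xa, xb])
        if np.ptp(pooled) == 0:
            results.append(TestResult("mann-whitney", len(xa) * len(xb) / 2.0,
                                      1.0, family, (a, b), (len(xa), len(xb)),
                                      flag="all values identical"))
            continue
        method = "exact" if max(len(xa), len(xb)) <= 10 else "asymptotic"
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        direction = float(np.sign(np.median(xa) - np.median(xb)))
        results.append(TestResult("mann-whitney", float(res.statistic),
                                  float(res.pvalue), family, (a, b),
                                  (len(xa), len(xb)), direction))
    return results


def bh_fdr(p_values: np.ndarray, family_labels: list[str] | None = None
           ) -> np.ndarray:
    """Benjamini-Hochberg q-values, computed independently within families.

    Within each family of m tests, with p-values sorted ascending,
    q_(i) = min_{j >= i} (p_(j) * m / j), mapped back to input order and
    capped at 1. NaN p-values yield NaN q-values and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    labels = np.asarray(family_labels if family_labels is not None
                        else [""] * len(p), dtype=object)
    if len(labels) != len(p):
        raise ValueError("family_labels length mismatch")
    q = np.full_like(p, np.nan)
    for fam in dict.fromkeys(labels):  # preserves first-seen order
        sel = np.nonzero((labels == fam) & finite)[0]
        if sel.size == 0:
            continue
        m = sel.size
        order = np.argsort(p[sel], kind="stable")
        ranked = p[sel][order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q_fam = np.empty(m)
        q_fam[order] = np.clip(q_sorted, 0.0, 1.0)
        q[sel] = q_fam
    return q


def attach_q_values(results: list[TestResult]) -> list[TestResult]:
    """Fill ``q_value`` on a list of TestResults, stratified by ``family``."""
    p = np.array([r.p_value for r in results])
    fams = [r.family for r in results]
    q = bh_fdr(p, fams)
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality screen (parametric vs nonparametric routing)."""
    arr = _clean(values)
    if not 3 <= len(arr) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        return TestResult("shapiro-wilk", float("nan"), float("nan"),
                          group_sizes=(len(arr),), flag="constant input")
    stat, p = sps.shapiro(arr)
    return TestResult("shapiro-wilk", float(stat), float(p),
                      group_sizes=(len(arr),))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("fewer than 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def group_regression(outcome, pathology, covariates: pd.DataFrame | None = None,
                     family: str = "linear", outcome_name: str = "outcome",
                     reference: str = REFERENCE_GROUP) -> RegressionResult:
    """Dummy-coded group regression with a fixed reference level.

    ``family='linear'`` fits OLS; ``family='logistic'`` fits a logit by
    maximum likelihood. Perfect separation in the logistic model is flagged
    rather than silently accepted; a rank-deficient design raises with the
    collinear column names.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    path = pd.Series(pathology, dtype=str)
    levels = [lv for lv in path.unique() if lv != reference]
    if reference not in set(path):
        raise ValueError(f"reference level '{reference}' absent from data")
    if len(levels) < 1:
        raise ValueError("pathology must have >= 2 levels present")

    X = pd.DataFrame({"const": np.ones(len(y))})
    for lv in sorted(levels):
        X[lv] = (path == lv).astype(float).to_numpy()
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        for col in covariates.columns:
            vals = covariates[col]
            if vals.dtype == object or str(vals.dtype) == "category":
                codes = pd.Categorical(vals).codes.astype(float)
                X[col] = codes
            else:
                X[col] = np.asarray(vals, dtype=float)
        cov_names = tuple(covariates.columns)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-10] if r.shape[0] >= X.shape[1] else list(X.columns)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    flag = ""
    if family == "linear":
        model = sm.OLS(y, X).fit()
    elif family == "logistic":
        from statsmodels.tools.sm_exceptions import PerfectSeparationError
        try:
            with np.errstate(all="ignore"):
                model = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not model.mle_retvals.get("converged", True):
                flag = "did not converge"
            fitted = model.predict(X)
            if np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)):
                flag = "perfect separation"
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            model = None
            flag = f"perfect separation ({exc})"
    else:
        raise ValueError("family must be 'linear' or 'logistic'")

    if model is not None:
        coef = pd.DataFrame({
            "term": X.columns,
            "estimate": np.asarray(model.params),
            "std_err": np.asarray(model.bse),
            "p_value": np.asarray(model.pvalues),
        })
    else:
        coef = pd.DataFrame(columns=["term", "estimate", "std_err", "p_value"])
    return RegressionResult(outcome_name, family, coef, cov_names, flag, model)


def tumor_volume_proportion(segmentation, brain_mask: np.ndarray | None = None,
                            ventricle_mask: np.ndarray | None = None,
                            label_map: dict[str, int] | None = None
                            ) -> dict[str, float]:
    """Compartment volume normalized to brain volume excluding ventricles."""
    from .volumes import COMPARTMENTS, DEFAULT_LABEL_MAP
    label_map = label_map or DEFAULT_LABEL_MAP
    data = segmentation.data
    brain = (np.ones(data.shape, dtype=bool) if brain_mask is None
             else np.asarray(brain_mask, dtype=bool))
    if ventricle_mask is not None:
        brain = brain & ~np.asarray(ventricle_mask, dtype=bool)
    denom = float(brain.sum())
    if denom == 0:
        raise ValueError("empty brain mask")
    out = {}
    for comp in COMPARTMENTS + ("combined",):
        mask = segmentation.compartment_mask(comp, label_map)
        out[comp] = float((mask & brain).sum()) / denom
    return out
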