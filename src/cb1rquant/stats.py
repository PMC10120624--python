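"""Statistical analysis: blocked/covariate ANCOVA, post hocs, ratio tests.

The dependent measures (per-subject × layer sum CB1R intensity; per-subject ×
layer × terminal-class mean CB1R intensity) are analysed with ordinary
least-squares ANCOVA using sum-to-zero contrasts and Type III tests:

* paired variant — fixed effects plus subject pair as a fixed blocking factor
  absorbing matched-design variance;
* unpaired variant — the blocking factor replaced by cohort covariates (sex,
  race, age, postmortem interval, storage time).

A term listed as an interaction whose sub-interactions among the same factors
are not themselves listed absorbs those subspaces into its joint test — the
convention of classic GLM custom models, which reproduces the
F(2, 315)/F(25, 315)-style degree-of-freedom layout of blocked terminal-type
analyses at 10 pairs × 6 layers × 3 classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import patsy
import statsmodels.api as sm

DEFAULT_COVARIATES = ("sex", "race", "age_years", "pmi_hours", "storage_months")

CATEGORICAL_COVARIATES = ("sex", "race")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative ANCOVA specification.

    ``fixed_effects`` are factor names or colon-joined interactions, e.g.
    ``["group", "layer", "group:layer"]``.  ``blocking`` (pair) and
    ``covariates`` are mutually exclusive: the paired variant blocks on pair,
    the unpaired variant adjusts for covariates instead.
    """

    response: str
    fixed_effects: tuple
    blocking: str | None = None
    covariates: tuple = ()
    contrast_coding: str = "sum"

    def __post_init__(self) -> None:
        if self.blocking and self.covariates:
            raise ValueError(
                "blocking factor and covariates are mutually exclusive "
                "(paired vs unpaired model variants)"
            )
        if self.contrast_coding != "sum":
            raise ValueError("only sum-to-zero contrasts are supported")


def sum_intensity_spec(paired: bool = True) -> ModelSpec:
    """Group + layer + group×layer model for the sum CB1R measure."""
    return ModelSpec(
        response="sum_cb1r",
        fixed_effects=("group", "layer", "group:layer"),
        blocking="pair_id" if paired else None,
        covariates=() if paired else DEFAULT_COVARIATES,
    )


def terminal_type_spec(paired: bool = True) -> ModelSpec:
    """Group + layer + class + group×class + group×layer×class model."""
    return ModelSpec(
        response="response",
        fixed_effects=(
            "group",
            "layer",
            "terminal_class",
            "group:terminal_class",
            "group:layer:terminal_class",
        ),
        blocking="pair_id" if paired else None,
        covariates=() if paired else DEFAULT_COVARIATES,
    )


@dataclass
class AnovaResult:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    adjusted_p: float | None = None


def _patsy_factor(name: str) -> str:
    return f"C({name}, Sum)"


def _expand_terms(fixed_effects) -> dict[str, list[str]]:
    """Map each reported term to the patsy interaction terms it spans.

    An interaction term absorbs every sub-interaction (order ≥ 2) of its
    factors that is not separately listed.
    """
    listed = {tuple(t.split(":")) for t in fixed_effects}
    mapping: dict[str, list[str]] = {}
    for term in fixed_effects:
        factors = tuple(term.split(":"))
        if len(factors) == 1:
            mapping[term] = [_patsy_factor(factors[0])]
            continue
        spanned = []
        for r in range(2, len(factors) + 1):
            for sub in itertools.combinations(factors, r):
                if sub == factors or sub not in listed:
                    spanned.append(":".join(_patsy_factor(f) for f in sub))
        # claim sub-interactions not already claimed by a listed shorter term
        claimed = set()
        for other in fixed_effects:
            of = tuple(other.split(":"))
            if other != term and len(of) > 1 and set(of) < set(factors):
                claimed.add(":".join(_patsy_factor(f) for f in of))
        mapping[term] = [t for t in spanned if t not in claimed]
    return mapping


def _covariate_formula(data: pd.DataFrame, covariates) -> list[str]:
    out = []
    for cov in covariates:
        if cov in CATEGORICAL_COVARIATES or data[cov].dtype == object:
            ref = data[cov].mode().iloc[0]
            if data[cov].nunique() < 2:
                warnings.warn(f"covariate {cov!r} is constant; dropped", stacklevel=3)
                continue
            out.append(f"C({cov}, Treatment(reference={ref!r}))")
        else:
            out.append(cov)
    return out


def fit_ancova(data: pd.DataFrame, spec: ModelSpec):
    """Fit the ANCOVA and return per-term Type III F tests.

    Returns ``(results, fit)`` where ``results`` is a list of
    :class:`AnovaResult` (one per fixed effect, in spec order) and ``fit`` the
    underlying statsmodels OLS results (for post hocs).
    """
    data = data.copy()
    for col in ("group", "layer", "terminal_class", "pair_id"):
        if col in data.columns:
            data[col] = data[col].astype(str)
    term_map = _expand_terms(spec.fixed_effects)
    rhs = [t for terms in term_map.values() for t in terms]
    if spec.blocking:
        rhs.append(_patsy_factor(spec.blocking))
    if spec.covariates:
        rhs.extend(_covariate_formula(data, spec.covariates))
    formula = f"{spec.response} ~ " + " + ".join(rhs)
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _find_aliased_term(X, term_map)
        raise ValueError(
            f"rank-deficient design: term {aliased!r} is aliased "
            f"(rank {rank} < {X.shape[1]} columns)"
        )
    fit = sm.OLS(y, X).fit()
    degenerate = fit.ssr <= max(1e-12 * max(fit.centered_tss, 1.0), 1e-300)
    design_info = X.design_info
    results = []
    for term, patsy_terms in term_map.items():
        cols = []
        for pt in patsy_terms:
            cols.extend(range(*design_info.term_name_slices[pt].indices(X.shape[1])))
        df_num = len(cols)
        if degenerate:
            results.append(
                AnovaResult(term, 0.0, df_num, int(fit.df_resid), 1.0)
            )
            continue
        L = np.zeros((df_num, X.shape[1]))
        for i, c in enumerate(cols):
            L[i, c] = 1.0
        w = fit.wald_test(L, use_f=True, scalar=True)
        results.append(
            AnovaResult(
                term=term,
                F=float(w.fvalue),
                df_num=df_num,
                df_den=int(fit.df_resid),
                p=float(w.pvalue),
            )
        )
    return results, fit


def _find_aliased_term(X: pd.DataFrame, term_map) -> str:
    arr = X.to_numpy()
    design_info = X.design_info
    base_rank = np.linalg.matrix_rank(arr)
    for term, patsy_terms in term_map.items():
        cols = []
        for pt in patsy_terms:
            cols.extend(range(*design_info.term_name_slices[pt].indices(X.shape[1])))
        rest = np.delete(arr, cols, axis=1)
        if np.linalg.matrix_rank(rest) == base_rank:
            return term
    return "<unknown>"


def anova_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "F": r.F,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p": r.p,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# post hoc contrasts


def bonferroni_adjust(p: float, k: int) -> float:
    """adjusted p = min(1, p × k)."""
    if k < 1:
        raise ValueError("number of comparisons k must be >= 1")
    return min(1.0, float(p) * k)


def posthoc_bonferroni(
    data: pd.DataFrame,
    response: str = "response",
    between: str = "group",
    within: str = "terminal_class",
    fit=None,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise group contrasts within each class level.

    Cell means are contrasted between the two groups within each level of
    ``within``; the standard error uses the residual variance of the supplied
    fitted model (or of the paired terminal-type model fitted here), and raw p
    values are multiplied by the number of comparisons (capped at 1).
    """
    levels = sorted(data[within].unique())
    groups = sorted(data[between].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required for pairwise contrasts")
    if fit is None:
        spec = terminal_type_spec(paired=True)
        _, fit = fit_ancova(data, spec)
    s2 = fit.mse_resid
    dof = int(fit.df_resid)
    k = len(levels)
    rows = []
    g0, g1 = groups
    for lev in levels:
        a = data[(data[within] == lev) & (data[between] == g1)][response]
        b = data[(data[within] == lev) & (data[between] == g0)][response]
        diff = a.mean() - b.mean()
        se = np.sqrt(s2 * (1.0 / len(a) + 1.0 / len(b)))
        t = diff / se
        p = 2.0 * sps.t.sf(abs(t), dof)
        rows.append(
            {
                within: lev,
                "contrast": f"{g1} - {g0}",
                "difference": diff,
                "t": t,
                "df": dof,
                "p": p,
                "adjusted_p": bonferroni_adjust(p, k),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simple arithmetic and auxiliary tests


def group_percent_difference(mean_sz: float, mean_ctrl: float) -> float:
    """100 × (SZ − Ctrl) / Ctrl."""
    if mean_ctrl <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (mean_sz - mean_ctrl) / mean_ctrl


def pooled_t_test(a, b):
    """Two-tailed pooled-variance (Student) t test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) == 1 or len(b) == 1:
        warnings.warn(
            "a group has n=1: its variance is not estimable; pooled variance "
            "uses the other group only",
            stacklevel=2,
        )
    dof = len(a) + len(b) - 2
    if dof < 1:
        raise ValueError("not enough observations for a pooled t test")
    sp2 = (
        ((len(a) - 1) * np.var(a, ddof=1) if len(a) > 1 else 0.0)
        + ((len(b) - 1) * np.var(b, ddof=1) if len(b) > 1 else 0.0)
    ) / dof
    if sp2 == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return float(t), float(p)


def within_pair_ratio_test(ratios, exposure_flags):
    """Compare within-pair Ctrl/SZ intensity ratios by exposure history.

    Pooled-variance two-tailed t test of the per-pair ratios between pairs
    whose SZ subject has the exposure history and pairs whose SZ subject does
    not.  Returns (t, p).
    """
    ratios = np.asarray(ratios, dtype=float)
    flags = np.asarray(exposure_flags, dtype=bool)
    if ratios.shape != flags.shape:
        raise ValueError("ratios and exposure flags must align")
    exposed, unexposed = ratios[flags], ratios[~flags]
    if len(exposed) == 0 or len(unexposed) == 0:
        raise ValueError("both exposure groups must be non-empty")
    return pooled_t_test(exposed, unexposed)


def fisher_exact_two_sided(table) -> float:
    """Two-sided exact hypergeometric p for a 2×2 table."""
    _, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def demographic_tests(manifest: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons of cohort covariates.

    One row per subject is extracted from the manifest; categorical variables
    (sex, race, exposure histories) get a two-sided Fisher exact test,
    continuous variables (age, PMI, storage time, pH) a pooled two-tailed t
    test.  Variables with an empty category level are dropped with a warning.
    """
    subjects = manifest.drop_duplicates("subject_id")
    groups = sorted(subjects["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g0, g1 = groups
    rows = []
    categorical = [
        c
        for c in (
            "sex", "race", "cannabis_history", "antipsychotic_history",
            "antidepressant_history", "benzodiazepine_history",
            "valproate_history",
        )
        if c in subjects.columns
    ]
    continuous = [
        c
        for c in ("age_years", "pmi_hours", "storage_months", "ph")
        if c in subjects.columns
    ]
    for var in categorical:
        levels = sorted(subjects[var].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"{var!r} has a single level; dropped", stacklevel=2)
            continue
        if len(levels) > 2:
            warnings.warn(f"{var!r} has >2 levels; using top level vs rest", stacklevel=2)
        top = levels[-1]
        tab = []
        for g in (g0, g1):
            sel = subjects[subjects["group"] == g][var].astype(str)
            tab.append([(sel == top).sum(), (sel != top).sum()])
        rows.append(
            {"variable": var, "test": "fisher_exact",
             "statistic": float("nan"), "p": fisher_exact_two_sided(tab)}
        )
    for var in continuous:
        a = subjects[subjects["group"] == g1][var]
        b = subjects[subjects["group"] == g0][var]
        t, p = pooled_t_test(a, b)
        rows.append({"variable": var, "test": "pooled_t", "statistic": t, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pair-ratio arithmetic


@dataclass
class PairRatioTable:
    table: pd.DataFrame
    summary: pd.DataFrame


def build_pair_ratio_table(ihc_ratios_pct, ligand_ratios_pct) -> PairRatioTable:
    """Per-pair magnitude differences (ligand − IHC) and column means/SDs.

    Standard deviations use the n−1 denominator.
    """
    ihc = np.asarray(ihc_ratios_pct, dtype=float)
    ligand = np.asarray(ligand_ratios_pct, dtype=float)
    if ihc.shape != ligand.shape:
        raise ValueError("ratio lists must have equal length")
    table = pd.DataFrame(
        {
            "pair_id": np.arange(1, len(ihc) + 1),
            "ihc_ratio_pct": ihc,
            "ligand_ratio_pct": ligand,
            "magnitude_difference": ligand - ihc,
        }
    )
    summary = pd.DataFrame(
        {
            "column": ["ihc_ratio_pct", "ligand_ratio_pct", "magnitude_difference"],
            "mean": [ihc.mean(), ligand.mean(), (ligand - ihc).mean()],
            "sd": [
                ihc.std(ddof=1),
                ligand.std(ddof=1),
                (ligand - ihc).std(ddof=1),
            ],
        }
    )
    return PairRatioTable(table=table, summary=summary)
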