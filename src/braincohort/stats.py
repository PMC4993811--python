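"""Linked statistical analysis over cohort variables.

The modelling surface follows the Model/Results convention: a
:class:`CohortModel` is built from a tidy per-subject DataFrame (or straight
from the cohort database), its :meth:`~CohortModel.fit` returns a
:class:`CohortFit` carrying coefficient estimates with uncertainties, the
per-term Type-II ANOVA table, residual diagnostics and a ``summary()``; and
outlier exclusion is an explicit, logged refit
(:meth:`CohortFit.refit_excluding`) that never mutates the original result.

Model structure is deliberately small: one numeric outcome, main effects
(numeric or nominal regressors) and pairwise interactions.  Nominal
variables enter through treatment (reference-level) dummy coding with the
first sorted level as reference; interaction columns are elementwise
products of the coded columns.  Rows with any missing value are dropped
listwise and counted — an aggregate never hides how many subjects it lost.

Per-term F statistics use Type-II sums of squares: each term is adjusted for
every other term that does not contain it, with the denominator mean square
taken from the full model.  Type-II is order-invariant for main effects,
which suits exploratory model-juggling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CollinearityError,
    DegenerateDesignError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Specification + design construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome ~ regressors (+ pairwise interactions) on a sample."""

    outcome: str
    regressors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    sample: tuple[str, ...] | None = None  # subject ids; None = all rows
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "regressors", tuple(self.regressors))
        object.__setattr__(self, "interactions",
                           tuple(tuple(p) for p in self.interactions))
        object.__setattr__(self, "exclusions", frozenset(self.exclusions))
        for a, b in self.interactions:
            if a not in self.regressors or b not in self.regressors:
                raise ValidationError(
                    f"interaction {a}:{b} members must appear as main effects")
        if self.sample is not None:
            sample = tuple(str(s) for s in self.sample)
            object.__setattr__(self, "sample", sample)
            if not self.exclusions <= set(sample):
                raise ValidationError("exclusions must be a subset of the sample")


@dataclass
class Design:
    """A realised design matrix plus the bookkeeping around it."""

    X: pd.DataFrame  # columns named; index = subject ids used
    y: pd.Series
    terms: dict[str, list[str]]  # term -> its design column names
    n_missing_excluded: int
    n_outlier_excluded: int
    nominal_levels: dict[str, list[str]]  # observed levels per nominal term


def _is_nominal(series: pd.Series, declared: set[str], name: str) -> bool:
    if name in declared:
        return True
    return not pd.api.types.is_numeric_dtype(series)


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 nominal: set[str] | frozenset[str] = frozenset()) -> Design:
    """Build intercept + treatment-coded design for a model spec.

    ``data`` holds one row per subject (index = subject id).  Columns listed
    in ``nominal`` — or any non-numeric column — are dummy-coded with the
    first sorted level as reference.  Rows with a missing outcome or
    regressor are dropped and counted; excluded subjects are dropped and
    counted separately.
    """
    needed = [spec.outcome, *spec.regressors]
    missing_cols = [c for c in needed if c not in data.columns]
    if missing_cols:
        raise ValidationError(f"variables not in data: {missing_cols}")
    frame = data.loc[[str(i) for i in (spec.sample or data.index)], needed].copy()
    frame.index = frame.index.astype(str)

    n_before = len(frame)
    frame = frame.drop(index=[s for s in spec.exclusions if s in frame.index])
    n_outlier = n_before - len(frame)
    complete = frame.dropna()
    n_missing = len(frame) - len(complete)
    if len(complete) == 0:
        raise DegenerateDesignError("no complete rows left to fit")

    X = pd.DataFrame(index=complete.index)
    X["Intercept"] = 1.0
    terms: dict[str, list[str]] = {"Intercept": ["Intercept"]}
    nominal_levels: dict[str, list[str]] = {}
    nominal = set(nominal)

    for reg in spec.regressors:
        col = complete[reg]
        if _is_nominal(col, nominal, reg):
            levels = sorted(str(v) for v in col.unique())
            nominal_levels[reg] = levels
            if len(levels) < 2:
                raise DegenerateDesignError(
                    f"nominal regressor {reg!r} has a single level "
                    f"({levels}) in the fitted rows")
            cols = []
            for level in levels[1:]:  # first sorted level = reference
                cname = f"{reg}[T.{level}]"
                X[cname] = (col.astype(str) == level).astype(float)
                cols.append(cname)
            terms[reg] = cols
        else:
            X[reg] = col.astype(float)
            terms[reg] = [reg]

    for a, b in spec.interactions:
        cols = []
        for ca, cb in itertools.product(terms[a], terms[b]):
            cname = f"{ca}:{cb}"
            X[cname] = X[ca] * X[cb]
            cols.append(cname)
        terms[f"{a}:{b}"] = cols

    if len(complete) < X.shape[1]:
        raise ValidationError(
            f"under-determined design: {len(complete)} rows for "
            f"{X.shape[1]} columns")
    return Design(X, complete[spec.outcome].astype(float), terms,
                  n_missing, n_outlier, nominal_levels)


def _check_full_rank(X: pd.DataFrame):
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name the aliased columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X.values, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[p] for p in piv[len(diag):]]
        raise CollinearityError(f"design is rank deficient; aliased terms: {aliased}")


# ---------------------------------------------------------------------------
# Model + results
# ---------------------------------------------------------------------------


class CohortModel:
    """OLS model of one numeric outcome on cohort variables.

    Parameters
    ----------
    data : DataFrame indexed by subject id, one column per variable.
    spec : the model specification.
    nominal : variable names to treat as nominal even if numerically coded.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 nominal=frozenset()):
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        self.spec = spec
        self.nominal = frozenset(nominal)

    @classmethod
    def from_db(cls, db, spec: ModelSpec, sample_name: str | None = None
                ) -> "CohortModel":
        """Pull the spec's variables from a cohort database.

        Nominal variables are decoded to their level labels so coefficient
        names read as ``group[T.preterm]`` rather than integer codes.
        """
        names = [spec.outcome, *spec.regressors]
        variables = {n: db.get_variable(n) for n in names}
        if variables[spec.outcome].var_type != "numeric":
            raise ValidationError("outcome must be a numeric variable")
        subjects = None
        if sample_name is not None:
            subjects = db.get_sample(sample_name).subjects
            spec = replace(spec, sample=subjects)
        frame = db.get_values(names, subjects)
        nominal = set()
        for name, var in variables.items():
            if var.var_type == "nominal":
                nominal.add(name)
                labels = var.levels or {}
                frame[name] = frame[name].map(
                    lambda code: labels.get(int(code), str(int(code)))
                    if pd.notna(code) else np.nan)
        return cls(frame, spec, nominal)

    def fit(self) -> "CohortFit":
        design = build_design(self.data, self.spec, self.nominal)
        _check_full_rank(design.X)
        import statsmodels.api as sm

        res = sm.OLS(design.y.values, design.X.values).fit()
        params = pd.Series(res.params, index=design.X.columns)
        return CohortFit(
            model=self,
            design=design,
            params=params,
            bse=pd.Series(res.bse, index=design.X.columns),
            tvalues=pd.Series(res.tvalues, index=design.X.columns),
            pvalues=pd.Series(res.pvalues, index=design.X.columns),
            rsquared=float(res.rsquared),
            fitted=pd.Series(res.fittedvalues, index=design.X.index),
            residuals=pd.Series(res.resid, index=design.X.index),
            df_resid=int(res.df_resid),
            scale=float(res.scale),
        )


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(np.sum(y ** 2))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclass
class CohortFit:
    """Results object: estimates, uncertainties, diagnostics, refits."""

    model: CohortModel
    design: Design
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    fitted: pd.Series  # keyed by subject id
    residuals: pd.Series  # keyed by subject id
    df_resid: int
    scale: float  # residual mean square of the full model
    _anova: pd.DataFrame | None = field(default=None, repr=False)

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_used(self) -> int:
        return len(self.design.y)

    @property
    def n_missing_excluded(self) -> int:
        return self.design.n_missing_excluded

    @property
    def n_outlier_excluded(self) -> int:
        return self.design.n_outlier_excluded

    @property
    def subjects_used(self) -> tuple[str, ...]:
        return tuple(self.design.X.index)

    # -- Type-II ANOVA -----------------------------------------------------

    def anova_table(self) -> pd.DataFrame:
        """Per-term Type-II sums of squares, F and p.

        For each term T: SS(T) = SSE(others not containing T) -
        SSE(others not containing T, plus T); F uses the full model's
        residual mean square.
        """
        if self._anova is not None:
            return self._anova
        X, y = self.design.X, self.design.y.values
        terms = {t: cols for t, cols in self.design.terms.items()
                 if t != "Intercept"}
        # scale of "numerically zero" sums of squares for this response
        tol = 1e-12 * max(1.0, float(y @ y))
        rows = []
        for term, cols in terms.items():
            containing = [t for t in terms
                          if t != term and term in t.split(":")]
            base_terms = [t for t in terms if t != term and t not in containing]
            base_cols = ["Intercept"] + [c for t in base_terms
                                         for c in terms[t]]
            sse_without = _sse(X[base_cols].values, y)
            sse_with = _sse(X[base_cols + cols].values, y)
            ss = max(sse_without - sse_with, 0.0)
            if ss < tol:
                ss = 0.0
            df = len(cols)
            if self.scale < tol:
                # degenerate residual variance: a zero SS is a null effect,
                # a non-zero SS against zero noise is unbounded evidence
                F = 0.0 if ss == 0.0 else np.inf
            else:
                F = (ss / df) / self.scale
            p = float(sps.f.sf(F, df, self.df_resid))
            rows.append((term, ss, df, F, p))
        sse_full = float(self.residuals.values @ self.residuals.values)
        rows.append(("Residual", sse_full, self.df_resid, np.nan, np.nan))
        table = pd.DataFrame(rows, columns=["term", "sum_sq", "df", "F", "p"]
                             ).set_index("term")
        self._anova = table
        return table

    # -- diagnostics -------------------------------------------------------

    def residual_diagnostics(self) -> "ResidualDiagnostics":
        """Residual summary, residual-vs-fitted pairs and Shapiro-Wilk W.

        Pairs are keyed by subject id so any odd point can be traced back to
        its subject.
        """
        if self.n_used < 3:
            raise ValidationError(
                "residual diagnostics need at least 3 fitted subjects")
        r = self.residuals
        if np.allclose(r.values, 0.0):
            W, p = 1.0, 1.0  # perfect fit; normality test is vacuous
        else:
            W, p = sps.shapiro(r.values)
        return ResidualDiagnostics(
            residuals=r.copy(),
            fitted=self.fitted.copy(),
            shapiro_w=float(W),
            shapiro_p=float(p),
            summary={"mean": float(r.mean()), "sd": float(r.std(ddof=1)),
                     "min": float(r.min()), "max": float(r.max())},
        )

    # -- refitting ---------------------------------------------------------

    def refit_excluding(self, subject_ids, db=None) -> "CohortFit":
        """Re-fit the identical spec with extra subjects excluded.

        The original result is untouched; exclusions accumulate.  Excluding
        ids that were not used is an error; when a database is given both
        the original spec and the exclusion are logged.
        """
        ids = frozenset(str(s) for s in subject_ids)
        if not ids <= set(self.subjects_used):
            stray = sorted(ids - set(self.subjects_used))
            raise ValidationError(f"cannot exclude unused subjects: {stray}")
        spec = self.model.spec
        sample = spec.sample or tuple(self.model.data.index.astype(str))
        new_spec = replace(spec, sample=tuple(sample),
                           exclusions=spec.exclusions | ids)
        refit = CohortModel(self.model.data, new_spec, self.model.nominal).fit()
        for reg, levels in self.design.nominal_levels.items():
            kept = refit.design.nominal_levels.get(reg, [])
            lost = sorted(set(levels) - set(kept))
            if lost:
                raise DegenerateDesignError(
                    f"exclusion empties level(s) {lost} of nominal "
                    f"regressor {reg!r}")
        if db is not None:
            db.log_event("stats", {"action": "refit_excluding",
                                   "excluded": sorted(ids),
                                   "outcome": spec.outcome})
        return refit

    # -- presentation ------------------------------------------------------

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "std_err": self.bse,
                             "t": self.tvalues, "p": self.pvalues})

    def summary(self) -> str:
        lines = [
            f"Outcome: {self.model.spec.outcome}",
            f"n used = {self.n_used}  "
            f"(missing excluded = {self.n_missing_excluded}, "
            f"outliers excluded = {self.n_outlier_excluded})",
            f"R-squared = {self.rsquared:.4f}",
            "",
            "Coefficients (treatment coding, reference = first sorted level):",
            self.coefficient_table().to_string(float_format="%.4g"),
            "",
            "Type-II ANOVA:",
            self.anova_table().to_string(float_format="%.4g"),
        ]
        return "\n".join(lines)


@dataclass
class ResidualDiagnostics:
    residuals: pd.Series
    fitted: pd.Series
    shapiro_w: float
    shapiro_p: float
    summary: dict

    def pairs(self) -> pd.DataFrame:
        """Residual-vs-fitted pairs keyed by subject id (plot-ready)."""
        return pd.DataFrame({"fitted": self.fitted, "residual": self.residuals})


# ---------------------------------------------------------------------------
# Module-level convenience surface
# ---------------------------------------------------------------------------


def fit_linear_model(data: pd.DataFrame, spec: ModelSpec,
                     nominal=frozenset()) -> CohortFit:
    """OLS fit with coefficient table, standard errors, t, p and R^2."""
    return CohortModel(data, spec, nominal).fit()


def fit_anova(data: pd.DataFrame, spec: ModelSpec,
              nominal=frozenset()) -> CohortFit:
    """Same OLS core as :func:`fit_linear_model`, with the Type-II ANOVA
    table precomputed.  Fitted values and residuals are identical between
    the two entry points by construction."""
    result = CohortModel(data, spec, nominal).fit()
    result.anova_table()
    return result


def correlation_matrix(data: pd.DataFrame, variables,
                       sample=None, exclusions=frozenset(),
                       bh_adjust: bool = False):
    """Pairwise-complete Pearson correlations with per-pair n and p-values.

    Returns (r, n, p) DataFrames.  A pair with fewer than 3 complete
    subjects is left undefined (NaN r/p, its n still reported).  With
    ``bh_adjust`` the off-diagonal p-values get a Benjamini-Hochberg
    adjustment; raw p-values are the default, in keeping with an exploratory
    workflow where the analyst sees unfiltered links.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValidationError("correlation matrix needs >= 2 variables")
    frame = data.copy()
    frame.index = frame.index.astype(str)
    if sample is not None:
        frame = frame.loc[[str(s) for s in sample]]
    frame = frame.drop(index=[str(s) for s in exclusions
                              if str(s) in frame.index])
    frame = frame[variables].astype(float)

    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    n = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    p = pd.DataFrame(np.nan, index=variables, columns=variables)
    np.fill_diagonal(p.values, 0.0)
    for i in range(k):
        n.iloc[i, i] = int(frame[variables[i]].notna().sum())
    raw_ps = []
    cells = []
    for i, j in itertools.combinations(range(k), 2):
        pair = frame[[variables[i], variables[j]]].dropna()
        n.iloc[i, j] = n.iloc[j, i] = len(pair)
        if len(pair) < 3:
            r.iloc[i, j] = r.iloc[j, i] = np.nan
            continue
        rij, pij = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        r.iloc[i, j] = r.iloc[j, i] = float(rij)
        p.iloc[i, j] = p.iloc[j, i] = float(pij)
        raw_ps.append(float(pij))
        cells.append((i, j))
    if bh_adjust and raw_ps:
        from statsmodels.stats.multitest import multipletests

        _, adj, *_ = multipletests(raw_ps, method="fdr_bh")
        for (i, j), q in zip(cells, adj):
            p.iloc[i, j] = p.iloc[j, i] = float(q)
    return r, n, p
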