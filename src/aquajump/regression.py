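"""GRF prediction-equation development: OLS with backward elimination.

The prediction target is the per-jump landing peak vertical ground
reaction force in land-body-weight units (``grf_v_l_bw``); the candidate
predictors are the peak C7 resultant acceleration (g), PWDH (water depth
as percent of body height), age (years) and body weight (kg).  Starting
from the full ordinary-least-squares model, the highest-p-value term is
removed while its p-value exceeds ``alpha_remove`` (default 0.10); the
intercept is never removed.  The published reference equation

    GRF_V_L_BW = -1.712 + 0.658*C7ACC + 0.016*PWDH + 0.008*age + 0.003*weight

is available as :data:`REFERENCE_EQUATION` for prediction without
refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PredictionModel",
    "REFERENCE_EQUATION",
    "SingularDesignError",
    "BackwardEliminationRegression",
    "SplitResult",
    "split_dd_vd",
    "fit_linear_model",
    "backward_eliminate",
    "predict_grf",
    "compare_groups",
]


class SingularDesignError(ValueError):
    """Rank-deficient design matrix; names the offending columns."""


@dataclass
class PredictionModel:
    """A fitted (or published) linear GRF prediction equation.

    ``coefficients`` maps predictor names to slopes in BW per predictor
    unit; terms eliminated during fitting are simply absent.
    """

    intercept: float
    coefficients: dict[str, float]
    pvalues: dict[str, float] | None = None
    adjusted_r2: float | None = None
    n_obs: int | None = None
    elimination_trail: list[str] = field(default_factory=list)

    def predict(self, data) -> np.ndarray | float:
        """Evaluate the equation on a DataFrame, mapping, or keyword-free dict."""
        if isinstance(data, pd.DataFrame):
            out = np.full(len(data), self.intercept, dtype=float)
            for name, beta in self.coefficients.items():
                out += beta * data[name].to_numpy(dtype=float)
            return out
        out = self.intercept
        for name, beta in self.coefficients.items():
            out = out + beta * np.asarray(data[name], dtype=float)
        return out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionModel":
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "PredictionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: The published prediction equation (BW; C7ACC in g, PWDH in percent,
#: age in years, weight in kg).
REFERENCE_EQUATION = PredictionModel(
    intercept=-1.712,
    coefficients={"c7acc": 0.658, "pwdh": 0.016, "age": 0.008, "weight": 0.003},
)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.copy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _check_design(X: pd.DataFrame) -> None:
    constant = [c for c in X.columns if np.std(X[c].to_numpy()) == 0]
    if constant:
        raise SingularDesignError(f"predictor(s) with zero variance: {constant}")
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # Identify near-dependent columns from the QR diagonal.
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i - 1] for i in range(1, design.shape[1]) if diag[i] < 1e-8 * diag.max()]
        raise SingularDesignError(f"design matrix is rank deficient; collinear column(s): {bad or list(X.columns)}")


def select_removal_candidate(pvals: pd.Series, cols: list[str]) -> str:
    """The predictor backward elimination drops next: the largest p-value.

    On exact p-value ties the later column in the current order loses,
    so the final model does not depend on float-noise ordering of
    equally uninformative terms.
    """
    worst_p = max(pvals[c] for c in cols)
    ties = [c for c in cols if pvals[c] == worst_p]
    return ties[-1]


class BackwardEliminationRegression(RegressorMixin, BaseEstimator):
    """OLS regression with p-value-driven backward elimination.

    Parameters
    ----------
    alpha_remove : float
        Removal threshold: while the largest predictor p-value exceeds
        it, that predictor is dropped and the model refitted.  On exact
        p-value ties the later column (in current order) is removed.
    eliminate : bool
        If False the full model is fitted with no elimination.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
        Slopes in input-column order; eliminated terms are 0.
    retained_ : list of str
        Names of the surviving predictors.
    pvalues_ : dict
        Two-sided t-test p-values of the final model's terms.
    adjusted_r2_ : float
    elimination_trail_ : list of str
        Predictors in removal order.
    model_ : PredictionModel
        Portable form of the fitted equation.
    """

    def __init__(self, alpha_remove: float = 0.10, eliminate: bool = True):
        self.alpha_remove = alpha_remove
        self.eliminate = eliminate

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or len(X) != y.size:
            raise ValueError("y must be 1-D and aligned with X")
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(f"need more observations ({n}) than predictors + 1 ({p + 1})")
        _check_design(X)

        cols = list(X.columns)
        trail: list[str] = []
        while True:
            res = sm.OLS(y, sm.add_constant(X[cols], has_constant="add")).fit()
            # A zero-residual fit yields NaN p-values; such terms are
            # perfectly determined and must never be eliminated.
            pvals = res.pvalues.drop("const").fillna(0.0)
            if not self.eliminate or len(cols) == 0:
                break
            if pvals.max() <= self.alpha_remove:
                break
            victim = select_removal_candidate(pvals, cols)
            cols.remove(victim)
            trail.append(victim)
            if not cols:
                warnings.warn(
                    "all predictors eliminated; returning the intercept-only model",
                    UserWarning,
                    stacklevel=2,
                )
                res = sm.OLS(y, np.ones((n, 1))).fit()
                break

        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.retained_ = cols
        self.intercept_ = float(np.asarray(res.params)[0])
        coef = dict.fromkeys(X.columns, 0.0)
        for c in cols:
            coef[c] = float(res.params[c])
        self.coef_ = np.array([coef[c] for c in X.columns])
        self.pvalues_ = {c: float(res.pvalues[c]) for c in cols}
        self.bse_ = {c: float(res.bse[c]) for c in cols}
        self.adjusted_r2_ = float(res.rsquared_adj) if cols else 0.0
        self.n_obs_ = n
        self.elimination_trail_ = trail
        self.model_ = PredictionModel(
            intercept=self.intercept_,
            coefficients={c: coef[c] for c in cols},
            pvalues=dict(self.pvalues_),
            adjusted_r2=self.adjusted_r2_,
            n_obs=n,
            elimination_trail=list(trail),
        )
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted; call fit first")
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            X = X[list(self.feature_names_in_)]
        return self.intercept_ + X.to_numpy(dtype=float) @ self.coef_


@dataclass
class SplitResult:
    """Development/validation partition of the per-jump records."""

    dd: pd.DataFrame
    vd: pd.DataFrame
    seed: int | None
    ratio: float


def split_dd_vd(
    records: pd.DataFrame,
    ratio: float = 2.0 / 3.0,
    seed: int | None = None,
    stratify_by: str | None = None,
) -> SplitResult:
    """Randomly allocate records to development (DD) and validation (VD) sets.

    A uniform random permutation under ``seed`` sends the first
    ``floor(ratio * n)`` records to DD (applied within groups when
    ``stratify_by`` names a column, e.g. ``"subject_id"`` to keep the
    split balanced across subjects).
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    if len(records) < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(seed)

    def _split_idx(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        perm = rng.permutation(idx)
        n_dd = int(np.floor(ratio * idx.size))
        return perm[:n_dd], perm[n_dd:]

    if stratify_by is None:
        dd_idx, vd_idx = _split_idx(np.arange(len(records)))
    else:
        dd_parts, vd_parts = [], []
        for _, grp in records.groupby(stratify_by, sort=True):
            d, v = _split_idx(grp.index.to_numpy())
            dd_parts.append(d)
            vd_parts.append(v)
        dd_idx = np.concatenate(dd_parts)
        vd_idx = np.concatenate(vd_parts)
    dd = records.iloc[np.sort(dd_idx)].reset_index(drop=True)
    vd = records.iloc[np.sort(vd_idx)].reset_index(drop=True)
    return SplitResult(dd=dd, vd=vd, seed=seed, ratio=ratio)


def fit_linear_model(y, X) -> PredictionModel:
    """Fit the full OLS model (intercept + all predictors), no elimination."""
    est = BackwardEliminationRegression(eliminate=False).fit(X, y)
    return est.model_


def backward_eliminate(y, X, alpha_remove: float = 0.10) -> PredictionModel:
    """Backward-eliminate from the full model; see the estimator class."""
    est = BackwardEliminationRegression(alpha_remove=alpha_remove).fit(X, y)
    return est.model_


def predict_grf(c7acc, pwdh, age, weight, model: PredictionModel | None = None):
    """Predicted GRF in land-body-weight units from the four predictors.

    ``pwdh`` must be on the percent scale (0-100); a value at or below 1
    triggers a unit-sanity warning because a depth *fraction* would
    contribute an implausibly small term.
    """
    model = model or REFERENCE_EQUATION
    if np.any(np.asarray(pwdh, dtype=float) <= 1.0):
        warnings.warn(
            "pwdh <= 1: the equation expects percent of body height (0-100), "
            "not a fraction; check the input scale",
            UserWarning,
            stacklevel=2,
        )
    data = {"c7acc": c7acc, "pwdh": pwdh, "age": age, "weight": weight}
    out = model.predict(data)
    return float(out) if np.isscalar(c7acc) else out


def compare_groups(dd: pd.DataFrame, vd: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Independent two-sample t-tests (pooled variance) per outcome variable."""
    if len(dd) < 2 or len(vd) < 2:
        raise ValueError("each group needs at least two records")
    rows = []
    for var in variables:
        a = dd[var].to_numpy(dtype=float)
        b = vd[var].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "variable": var,
                "mean_dd": a.mean(),
                "mean_vd": b.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
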