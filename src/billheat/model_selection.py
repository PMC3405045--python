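"""AICc multimodel inference over Gaussian random-intercept models.

Each response (surface temperatures, bill heat loss, bill share of total
heat loss, relative humidity) is modelled by a fixed candidate set of
linear mixed models with a per-individual random intercept, a mandatory
square-root-of-activity covariate, and fixed effects drawn from subspecies
(SSP), ambient temperature Ta, its square and cube, and SSP x Ta
interactions, respecting marginality.  Models are fitted by full maximum
likelihood (not REML) because the candidates differ in their fixed
effects; ranking uses the small-sample Akaike criterion

    AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1)

with K counting fixed coefficients plus the two variance parameters.
Akaike weights, evidence ratios, and model-averaged predictions with
unconditional (model-uncertainty-inflated) standard errors follow the
standard Burnham-Anderson recipes.  Prediction standard errors are
fixed-effects-only, conditional on random effects at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelComparison",
    "RESPONSES",
    "build_model_set",
    "design_matrix",
    "fit_model",
    "fit_model_set",
    "aicc",
    "compare_models",
    "evidence_ratio",
    "model_average_predictions",
    "residual_correlogram",
    "pooled_t_bonferroni",
    "aggregate_steps",
]

RESPONSES = ("t_bill", "t_base", "t_body", "t_legs", "q_bill", "percent_q_bill", "rh")

#: Term vocabulary, in canonical column order.
_TERM_ORDER = ("ssp", "ta", "ta2", "ta3", "ssp:ta", "ssp:ta2", "ssp:ta3")

# internal centring of Ta for polynomial conditioning; spans are unchanged
_TA_CENTER = 26.0
_TA_SCALE = 11.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure.

    ``terms`` use the vocabulary ssp, ta, ta2, ta3, ssp:ta, ssp:ta2,
    ssp:ta3; the intercept, the sqrt-activity covariate and the individual
    random intercept are implicit in every model.
    """

    response: str
    terms: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        terms = set(self.terms)
        unknown = terms - set(_TERM_ORDER)
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        for inter in ("ssp:ta", "ssp:ta2", "ssp:ta3"):
            if inter in terms:
                main = inter.split(":")[1]
                if "ssp" not in terms or main not in terms:
                    raise ValueError(f"{inter} requires its main effects")
        for hi, lo in (("ta3", "ta2"), ("ta2", "ta")):
            if hi in terms and lo not in terms:
                raise ValueError(f"{hi} requires {lo}")

    @property
    def k(self) -> int:
        """Parameter count: intercept + terms + sqrt_activity + 2 variances."""
        return 1 + len(self.terms) + 1 + 2


@dataclass(frozen=True)
class ModelFit:
    """A fitted candidate model."""

    spec: ModelSpec
    coefficients: pd.Series
    cov_fixed: pd.DataFrame
    random_intercept_var: float
    residual_var: float
    loglik: float
    n: int

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    def predict(self, newdata: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Fixed-effects predictions and their standard errors on new data."""
        X = design_matrix(newdata, self.spec.terms)
        Xv = X.to_numpy()
        yhat = Xv @ self.coefficients.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xv, self.cov_fixed.to_numpy(), Xv))
        return yhat, se


def build_model_set(response: str) -> list[ModelSpec]:
    """The full candidate set for one response, null through saturated."""
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}; expected one of {RESPONSES}")
    sets: list[tuple[str, tuple[str, ...]]] = [
        ("1", ()),
        ("SSP", ("ssp",)),
        ("Ta", ("ta",)),
        ("SSP + Ta", ("ssp", "ta")),
        ("Ta + Ta^2", ("ta", "ta2")),
        ("SSP + Ta + Ta^2", ("ssp", "ta", "ta2")),
        ("SSP * Ta", ("ssp", "ta", "ssp:ta")),
        ("Ta + Ta^2 + Ta^3", ("ta", "ta2", "ta3")),
        ("SSP + Ta + Ta^2 + Ta^3", ("ssp", "ta", "ta2", "ta3")),
        ("SSP * Ta + SSP * Ta^2", ("ssp", "ta", "ta2", "ssp:ta", "ssp:ta2")),
        (
            "SSP * Ta + SSP * Ta^2 + SSP * Ta^3",
            ("ssp", "ta", "ta2", "ta3", "ssp:ta", "ssp:ta2", "ssp:ta3"),
        ),
    ]
    return [ModelSpec(response, terms, label) for label, terms in sets]


def design_matrix(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Fixed-effects design: intercept, requested terms, sqrt_activity.

    ``data`` needs columns ``subspecies``, ``ta`` and ``activity``.  Ta is
    centred and scaled internally (same span, better conditioning for the
    cubic models); subspecies is an atlantica indicator.
    """
    z = (data["ta"].to_numpy(float) - _TA_CENTER) / _TA_SCALE
    ssp = (data["subspecies"].to_numpy() == "atlantica").astype(float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    built = {
        "ssp": ssp,
        "ta": z,
        "ta2": z**2,
        "ta3": z**3,
        "ssp:ta": ssp * z,
        "ssp:ta2": ssp * z**2,
        "ssp:ta3": ssp * z**3,
    }
    for t in _TERM_ORDER:
        if t in terms:
            cols[t] = built[t]
    cols["sqrt_activity"] = np.sqrt(np.clip(data["activity"].to_numpy(float), 0, None))
    return pd.DataFrame(cols, index=data.index)


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one random-intercept model by full maximum likelihood.

    Rows with missing response values are dropped.  Raises on a singular
    fixed-effects design (naming the collinear columns) and on failure of
    every optimizer.
    """
    cols = ["bird_id", "subspecies", "ta", "activity", spec.response]
    df = data[cols].dropna(subset=[spec.response])
    if df["bird_id"].nunique() < 2:
        raise ValueError("need at least 2 individuals to fit a random intercept")
    X = design_matrix(df, spec.terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"singular design for model '{spec.label}': columns {list(X.columns)} "
            f"have rank {rank}"
        )
    y = df[spec.response].to_numpy(float)
    model = MixedLM(y, X, groups=df["bird_id"].to_numpy())
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                candidate = model.fit(reml=False, method=method, maxiter=500)
            except Exception:
                continue
            if np.isfinite(candidate.llf):
                result = candidate
                break
    if result is None:
        raise RuntimeError(f"mixed-model fit failed to converge for '{spec.label}'")
    p = X.shape[1]
    fe = pd.Series(np.asarray(result.fe_params), index=X.columns)
    cov = pd.DataFrame(
        np.asarray(result.cov_params())[:p, :p], index=X.columns, columns=X.columns
    )
    return ModelFit(
        spec=spec,
        coefficients=fe,
        cov_fixed=cov,
        random_intercept_var=float(np.asarray(result.cov_re).ravel()[0]),
        residual_var=float(result.scale),
        loglik=float(result.llf),
        n=len(df),
    )


def fit_model_set(data: pd.DataFrame, response: str) -> list[ModelFit]:
    """Fit the full candidate set for one response."""
    return [fit_model(data, spec) for spec in build_model_set(response)]


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample Akaike criterion -2logL + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


@dataclass(frozen=True)
class ModelComparison:
    """Ranked AICc table plus the underlying fits (full set, unranked order)."""

    fits: tuple[ModelFit, ...]
    table: pd.DataFrame = field(repr=False)

    def weight(self, label: str) -> float:
        row = self.table.loc[self.table["model"] == label]
        if row.empty:
            raise KeyError(f"model {label!r} not in comparison")
        return float(row["weight"].iloc[0])

    @property
    def top(self) -> ModelFit:
        best = self.table.iloc[0]["model"]
        return next(f for f in self.fits if f.spec.label == best)

    def display_table(self, delta_max: float = 5.0) -> pd.DataFrame:
        """Rows with delta-AICc below ``delta_max`` (display convention only)."""
        return self.table.loc[self.table["delta_aicc"] < delta_max].reset_index(drop=True)


def compare_models(fits: list[ModelFit]) -> ModelComparison:
    """AICc ranking, deltas and Akaike weights over a candidate set."""
    if not fits:
        raise ValueError("no fits to compare")
    rows = pd.DataFrame(
        {
            "model": [f.spec.label for f in fits],
            "K": [f.k for f in fits],
            "aicc": [f.aicc for f in fits],
        }
    )
    rows["delta_aicc"] = rows["aicc"] - rows["aicc"].min()
    rel = np.exp(-rows["delta_aicc"] / 2.0)
    rows["weight"] = rel / rel.sum()
    rows = rows.sort_values("aicc", kind="stable").reset_index(drop=True)
    return ModelComparison(fits=tuple(fits), table=rows)


def evidence_ratio(comparison: ModelComparison, label_a: str, label_b: str) -> float:
    """Relative support weight(a)/weight(b)."""
    wb = comparison.weight(label_b)
    if wb <= 0:
        raise ZeroDivisionError(f"model {label_b!r} has zero weight")
    return comparison.weight(label_a) / wb


def model_average_predictions(
    comparison: ModelComparison, grid: pd.DataFrame
) -> pd.DataFrame:
    """Akaike-weighted predictions with unconditional standard errors.

    For each grid row, the average is sum_i w_i yhat_i and the
    unconditional SE is sum_i w_i sqrt(se_i^2 + (yhat_i - ybar)^2), which
    folds between-model spread into the reported uncertainty.
    """
    weights = {
        row.model: row.weight for row in comparison.table.itertuples(index=False)
    }
    preds, ses, ws = [], [], []
    for f in comparison.fits:
        yhat, se = f.predict(grid)
        preds.append(yhat)
        ses.append(se)
        ws.append(weights[f.spec.label])
    P = np.vstack(preds)
    S = np.vstack(ses)
    w = np.asarray(ws)[:, None]
    ybar = (w * P).sum(axis=0)
    unc_se = (w * np.sqrt(S**2 + (P - ybar) ** 2)).sum(axis=0)
    out = grid.copy()
    out["fit"] = ybar
    out["unconditional_se"] = unc_se
    return out


def residual_correlogram(
    fit: ModelFit, data: pd.DataFrame, lag_max: int = 6
) -> pd.DataFrame:
    """Within-individual residual autocorrelation by lag in step order.

    Residuals are taken against the fixed-effects prediction plus the
    individual's mean residual (absorbing its random intercept), ordered by
    ambient-temperature step within each individual, and paired at lags
    1..lag_max across individuals.  The approximate 95% null bound for each
    lag is +-1.96/sqrt(n_pairs).  Lag 0 is 1 by construction.  With short
    per-individual series the estimator carries the usual ~ -1/(n-1)
    negative bias from demeaning, so treat the bounds as a one-sided guard
    against positive temporal autocorrelation.
    """
    df = data.dropna(subset=[fit.spec.response]).copy()
    yhat, _ = fit.predict(df)
    df["_resid"] = df[fit.spec.response].to_numpy(float) - yhat
    df["_resid"] -= df.groupby("bird_id")["_resid"].transform("mean")
    rows = [{"lag": 0, "autocorrelation": 1.0, "bound": 0.0, "n_pairs": len(df)}]
    for lag in range(1, lag_max + 1):
        x, y = [], []
        for _, g in df.sort_values("ta").groupby("bird_id"):
            r = g["_resid"].to_numpy()
            if len(r) > lag:
                x.append(r[:-lag])
                y.append(r[lag:])
        if not x:
            break
        x = np.concatenate(x)
        y = np.concatenate(y)
        denom = np.sqrt((x**2).sum() * (y**2).sum())
        ac = float((x * y).sum() / denom) if denom > 0 else 0.0
        rows.append(
            {
                "lag": lag,
                "autocorrelation": ac,
                "bound": 1.96 / np.sqrt(len(x)),
                "n_pairs": len(x),
            }
        )
    return pd.DataFrame(rows)


def pooled_t_bonferroni(
    group_a: np.ndarray, group_b: np.ndarray, n_tests: int = 1
) -> float:
    """Equal-variance two-sample t-test P, Bonferroni-multiplied, capped at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    t = stats.ttest_ind(np.asarray(group_a), np.asarray(group_b), equal_var=True)
    return float(min(t.pvalue * n_tests, 1.0))


def aggregate_steps(observations: pd.DataFrame) -> pd.DataFrame:
    """Collapse frame-level rows to per-(bird x ambient step) means.

    This is the default analysis unit: the five frames of a step average
    into one row, keeping identity columns and averaging every numeric
    response/covariate present.
    """
    keys = ["bird_id", "subspecies", "ta"]
    numeric = [
        c
        for c in observations.columns
        if c not in keys + ["frame_index"]
        and pd.api.types.is_numeric_dtype(observations[c])
    ]
    return observations.groupby(keys, as_index=False)[numeric].mean()
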