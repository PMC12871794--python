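"""PGS×E interaction models and their scale (λ) profiles.

The core model, fit by ordinary least squares on a transformed phenotype
Y*:

    Y* = intercept + PGS·beta + E·alpha + (PGS·E)·gamma + C·eta + (C·E)·sigma + eps

The covariate-by-environment block (C·E) guards against confounding of the
interaction term by covariate effects that themselves vary with E.  The
reported p-value is the two-sided Wald test on gamma (a joint F-test when a
categorical E expands to several contrasts).

:func:`profile_lambda` refits the model on Box-Cox transforms of the
phenotype across a λ grid (optionally adding the rank inverse normal
transform), yielding the p-versus-λ profile used to separate
scale-dependent from scale-independent interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .transforms import DEFAULT_LAMBDA_GRID, box_cox, rint

__all__ = [
    "InteractionFit",
    "LambdaProfile",
    "fit_interaction",
    "profile_lambda",
    "classify_scale_dependence",
    "default_threshold",
]

_TINY_P = 5e-324  # smallest subnormal; keeps p-values in (0, 1]


@dataclass
class InteractionFit:
    """Result of one PGS×E model fit."""

    gamma_hat: float | np.ndarray
    gamma_se: float | np.ndarray
    p_interaction: float
    coefficients: pd.DataFrame  # term, estimate, se, t, p
    n_used: int


@dataclass
class LambdaProfile:
    """Interaction p-values across the transformation family."""

    lambdas: np.ndarray
    p_values: np.ndarray
    gamma_hats: np.ndarray
    rint_p: float | None
    threshold: float
    classification: str | None

    def __post_init__(self) -> None:
        if len(self.lambdas) != len(self.p_values):
            raise ValueError("lambdas and p_values must have equal length")

    def p_at(self, lam: float) -> float:
        idx = np.flatnonzero(np.isclose(self.lambdas, lam))
        if idx.size == 0:
            raise KeyError(f"lambda={lam} is not on the profile grid")
        return float(self.p_values[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "transform": [f"lambda={l:g}" for l in self.lambdas],
                "lam": self.lambdas,
                "p_value": self.p_values,
            }
        )
        if self.rint_p is not None:
            rows = pd.concat(
                [rows, pd.DataFrame({"transform": ["rint"], "lam": [np.nan], "p_value": [self.rint_p]})],
                ignore_index=True,
            )
        return rows


def default_threshold(n_lambdas: int, include_rint: bool = True, alpha: float = 0.05) -> float:
    """Bonferroni-corrected significance cutoff for one profile.

    Corrects ``alpha`` for the number of transformations tested (the λ grid
    plus RINT when included); 0.05/26 with the default 25-point grid.
    """
    return alpha / (n_lambdas + int(include_rint))


def _as_column_frame(x, name: str) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x.copy()
    if isinstance(x, pd.Series):
        return x.to_frame(name=x.name or name)
    x = np.asarray(x)
    if x.ndim == 1:
        return pd.DataFrame({name: x})
    return pd.DataFrame(x, columns=[f"{name}{j + 1}" for j in range(x.shape[1])])


def _encode_categoricals(df: pd.DataFrame) -> pd.DataFrame:
    """Expand non-numeric columns to indicator contrasts.

    The reference level is the first level in sorted order and is dropped.
    """
    out = []
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            out.append(s.astype(float))
        else:
            levels = sorted(pd.unique(s.dropna()))
            for level in levels[1:]:
                out.append((s == level).astype(float).rename(f"{col}[{level}]"))
    return pd.concat(out, axis=1)


def fit_interaction(
    y,
    pgs,
    e,
    covariates=None,
    include_cov_by_e: bool = True,
    robust: bool = False,
) -> InteractionFit:
    """OLS fit of the PGS×E interaction model on an already-transformed y.

    Rows with any missing value are dropped (``n_used`` reports the
    remainder).  Categorical covariates and a categorical E are expanded to
    indicator contrasts against the first sorted level.  A rank-deficient
    design is refused with the collinear columns named, as is a
    zero-variance PGS or E.

    With ``robust=True`` heteroskedasticity-consistent (HC0) standard errors
    replace the classical ones.
    """
    parts = [
        pd.DataFrame({"__y": np.asarray(y, dtype=float)}),
        _as_column_frame(pgs, "pgs").set_axis(["pgs"], axis=1),
        _as_column_frame(e, "E").set_axis(["E"], axis=1),
    ]
    if covariates is not None:
        cov = _as_column_frame(covariates, "C")
        if not isinstance(covariates, (pd.DataFrame, pd.Series)):
            cov.columns = [f"C{j + 1}" for j in range(cov.shape[1])]
        cov.columns = [str(c) for c in cov.columns]
        parts.append(cov)
    lengths = {len(p) for p in parts}
    if len(lengths) != 1:
        raise ValueError(f"inputs are not sample-aligned (lengths {sorted(lengths)})")
    data = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    data = data.dropna()
    n_used = len(data)
    if n_used < 5:
        raise ValueError(f"too few complete cases to fit the model (n={n_used})")

    yv = data["__y"].to_numpy()
    if np.var(yv) == 0:
        raise ValueError("phenotype has zero variance")
    pgs_v = data[["pgs"]].astype(float)["pgs"].to_numpy()
    if np.var(pgs_v) == 0:
        raise ValueError("PGS has zero variance")
    e_frame = _encode_categoricals(data[["E"]])
    if e_frame.shape[1] == 0 or np.all(e_frame.var(axis=0) == 0):
        raise ValueError("E has zero variance")
    cov_frame = None
    if covariates is not None:
        cov_frame = _encode_categoricals(data.drop(columns=["__y", "pgs", "E"]))

    blocks: dict[str, np.ndarray] = {"const": np.ones(n_used), "pgs": pgs_v}
    for col in e_frame.columns:
        blocks[str(col)] = e_frame[col].to_numpy()
    inter_names = []
    for col in e_frame.columns:
        name = f"pgs:{col}"
        inter_names.append(name)
        blocks[name] = pgs_v * e_frame[col].to_numpy()
    if cov_frame is not None:
        for col in cov_frame.columns:
            blocks[str(col)] = cov_frame[col].to_numpy()
        if include_cov_by_e:
            for ccol in cov_frame.columns:
                for ecol in e_frame.columns:
                    blocks[f"{ccol}:{ecol}"] = cov_frame[ccol].to_numpy() * e_frame[ecol].to_numpy()

    names = list(blocks)
    X = np.column_stack([blocks[n] for n in names])

    # a collinear design makes the interaction Wald test ill-defined; identify
    # the redundant columns (QR with column pivoting) and refuse to fit
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        keep = set(piv[:r])
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        raise ValueError(f"design is rank deficient; collinear columns: {dropped}")

    model = sm.OLS(yv, X)
    res = model.fit(cov_type="HC0") if robust else model.fit()

    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    inter_idx = [names.index(n) for n in inter_names if n in names]
    if len(inter_idx) == 1:
        j = inter_idx[0]
        gamma_hat = float(res.params[j])
        gamma_se = float(res.bse[j])
        p_inter = float(res.pvalues[j])
    else:
        contrast = np.zeros((len(inter_idx), len(names)))
        for row, j in enumerate(inter_idx):
            contrast[row, j] = 1.0
        p_inter = float(res.f_test(contrast).pvalue)
        gamma_hat = res.params[inter_idx]
        gamma_se = res.bse[inter_idx]
    return InteractionFit(
        gamma_hat=gamma_hat,
        gamma_se=gamma_se,
        p_interaction=max(p_inter, _TINY_P),
        coefficients=coef,
        n_used=n_used,
    )


def profile_lambda(
    y,
    pgs,
    e,
    covariates=None,
    lambdas=None,
    include_rint: bool = True,
    threshold: float | None = None,
    include_cov_by_e: bool = True,
    robust: bool = False,
) -> LambdaProfile:
    """Profile the interaction p-value over Box-Cox transforms of y.

    For each λ on the grid the phenotype is Box-Cox transformed and the
    interaction model refit; with ``include_rint`` the rank inverse normal
    transform is profiled as well.  The significance ``threshold`` defaults
    to the Bonferroni correction over the number of transformations tested.
    The profile is classified as scale-dependent, scale-independent, or not
    significant (RINT excluded from the classification).
    """
    lambdas = DEFAULT_LAMBDA_GRID if lambdas is None else np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if threshold is None:
        threshold = default_threshold(len(lambdas), include_rint)

    y = np.asarray(y, dtype=float)
    p_values = np.empty(len(lambdas))
    gamma_hats = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        try:
            fit = fit_interaction(
                box_cox(y, lam), pgs, e, covariates,
                include_cov_by_e=include_cov_by_e, robust=robust,
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            raise ValueError(f"profile failed at lambda={lam:g}: {err}") from err
        p_values[i] = fit.p_interaction
        g = fit.gamma_hat
        gamma_hats[i] = float(np.atleast_1d(g)[0])

    rint_p = None
    if include_rint:
        fit = fit_interaction(
            rint(y), pgs, e, covariates,
            include_cov_by_e=include_cov_by_e, robust=robust,
        )
        rint_p = fit.p_interaction

    classification = None
    if np.any(np.isclose(lambdas, 1.0)):
        classification = classify_scale_dependence(p_values, lambdas, threshold)
    return LambdaProfile(
        lambdas=lambdas,
        p_values=p_values,
        gamma_hats=gamma_hats,
        rint_p=rint_p,
        threshold=threshold,
        classification=classification,
    )


def classify_scale_dependence(
    p_values,
    lambdas,
    threshold: float,
    default_lambda: float = 1.0,
) -> str:
    """Classify a p-versus-λ profile.

    * ``not_significant`` — no interaction on the default scale (λ=1);
    * ``scale_independent`` — significant on every scale in the grid;
    * ``scale_dependent`` — significant on the default scale but removable
      by some power transformation.

    The default (untransformed) λ must be on the grid.
    """
    p_values = np.asarray(p_values, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    idx = np.flatnonzero(np.isclose(lambdas, default_lambda))
    if idx.size == 0:
        raise ValueError(f"default lambda={default_lambda} is not on the grid")
    if p_values[idx[0]] >= threshold:
        return "not_significant"
    if np.all(p_values < threshold):
        return "scale_independent"
    return "scale_dependent"
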