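"""Multinomial logistic risk models with bootstrap stability selection.

The outcome is the 4-level milk-supply class (reference: the adequate
class). Models lock a fixed confounder set (infant age at measurement,
sex, birth weight, birth mode, parity) into every fit and select among the
ten candidate maternal risk factors by refitting on bootstrap resamples:
factors chosen by more than half the resampled models are retained in the
final model. Composite four-level factors (neither / A only / B only /
both) probe whether co-occurring risks compound.

The multinomial maximum-likelihood fit uses Newton iterations with
step-halving on the exact log-likelihood, a small ridge stabiliser on the
observed information, and Wald covariance / confidence intervals.
Continuous predictors are standardised internally and the coefficients
mapped back, so reported ORs are per original unit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConvergenceError, SeparationWarning
from .measures import CONFOUNDER_COLUMNS, RISK_FACTOR_COLUMNS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design matrices


def build_design(df: pd.DataFrame, predictors: list[str]):
    """Numeric design matrix (with intercept) from mixed-type columns.

    Booleans become 0/1; object/categorical columns expand to first-level-
    dropped dummies; numeric columns pass through. Returns (X, names).
    Rows must already be complete cases on ``predictors``.
    """
    parts = [pd.Series(1.0, index=df.index, name="intercept")]
    for col in predictors:
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
        elif s.dtype.kind == "b" or str(s.dtype) == "boolean":
            parts.append(s.astype(float).rename(col))
        else:
            parts.append(s.astype(float))
    X = pd.concat(parts, axis=1)
    return X.to_numpy(float), list(X.columns)


# ---------------------------------------------------------------------------
# multinomial fit


@dataclass
class MultinomialModel:
    """A fitted multinomial logit with Wald inference.

    ``coef`` has one row per non-reference outcome level; the reference
    level implicitly carries zero coefficients.
    """

    levels: list
    reference: object
    feature_names: list[str]
    coef: np.ndarray            # (K-1) x p
    cov: np.ndarray             # ((K-1)p) x ((K-1)p)
    loglik: float
    n: int
    converged: bool
    grad_norm: float
    ridge: float

    @property
    def n_params(self) -> int:
        return self.coef.size

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)).reshape(self.coef.shape)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def ci(self, level: float = 0.95):
        zq = norm.ppf(0.5 + level / 2.0)
        lo = np.exp(self.coef - zq * self.se)
        hi = np.exp(self.coef + zq * self.se)
        return lo, hi

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * norm.sf(np.abs(z))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.hstack([np.zeros((X.shape[0], 1)), X @ self.coef.T])
        eta -= eta.max(axis=1, keepdims=True)
        expeta = np.exp(eta)
        return expeta / expeta.sum(axis=1, keepdims=True)

    def report(self) -> pd.DataFrame:
        """Long-format OR table (forest-plot ready)."""
        lo, hi = self.ci()
        rows = []
        nonref = [lv for lv in self.levels if lv != self.reference]
        for i, lv in enumerate(nonref):
            for j, name in enumerate(self.feature_names):
                rows.append(
                    {
                        "outcome_level": lv, "predictor": name,
                        "coef": self.coef[i, j], "or": np.exp(self.coef[i, j]),
                        "ci_low": lo[i, j], "ci_high": hi[i, j],
                        "p": self.p_values[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _loglik_grad_hess(X, Y, coef, want_hess=True):
    n, p = X.shape
    Km1 = Y.shape[1]
    eta = np.hstack([np.zeros((n, 1)), X @ coef.T])
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    P = expeta / expeta.sum(axis=1, keepdims=True)   # n x K, col 0 = reference
    Pk = P[:, 1:]
    ll = float(np.log(np.clip(np.where(Y.any(1, keepdims=True),
                                       (P[:, 1:] * Y).sum(1, keepdims=True),
                                       P[:, :1]), 1e-300, None)).sum())
    grad = ((Y - Pk).T @ X).ravel()                  # (K-1)p
    if not want_hess:
        return ll, grad, None
    H = np.empty((Km1 * p, Km1 * p))
    for a in range(Km1):
        for b in range(a, Km1):
            w = Pk[:, a] * ((a == b) - Pk[:, b])
            block = X.T @ (X * w[:, None])
            H[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
            if a != b:
                H[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
    return ll, grad, H


def fit_multinomial(
    X: np.ndarray,
    y,
    feature_names: list[str] | None = None,
    reference_level=None,
    ridge: float = 1e-8,
    max_iter: int = 200,
    tol: float = 1e-6,
    standardize: bool = True,
) -> MultinomialModel:
    """Maximum-likelihood multinomial logit by ridge-stabilised Newton.

    ``X`` must already contain the intercept column first. Convergence is
    max-norm of the score below ``tol`` (on the standardised scale); the
    log-likelihood never decreases thanks to step-halving. Diverging
    coefficients trigger a separation warning; the ridge-stabilised
    estimate is still returned.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, p = X.shape
    levels = sorted(pd.unique(y).tolist())
    if reference_level is None:
        reference_level = levels[0]
    if len(levels) < 2:
        raise ValueError("outcome needs at least 2 levels")
    levels = [reference_level] + [lv for lv in levels if lv != reference_level]
    Km1 = len(levels) - 1
    Y = np.column_stack([(y == lv).astype(float) for lv in levels[1:]])

    # internal standardisation of non-intercept continuous columns,
    # encoded as an affine map X_std = X @ A so estimates map back exactly
    A = np.eye(p)
    if standardize:
        for j in range(1, p):
            col = X[:, j]
            s = col.std()
            if s > 0 and not set(np.unique(col)) <= {0.0, 1.0}:
                A[0, j] = -col.mean() / s
                A[j, j] = 1.0 / s
    Xs = X @ A

    coef = np.zeros((Km1, p))
    ll, grad, H = _loglik_grad_hess(Xs, Y, coef)
    converged = False
    for _ in range(max_iter):
        gnorm = np.abs(grad).max()
        if gnorm < tol:
            converged = True
            break
        Hr = H + ridge * np.eye(H.shape[0])
        step = np.linalg.solve(Hr, grad).reshape(Km1, p)
        # step-halving: never accept a decrease in the log-likelihood
        factor = 1.0
        for _ in range(40):
            new_coef = coef + factor * step
            new_ll, new_grad, new_H = _loglik_grad_hess(Xs, Y, new_coef)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            break
        coef, ll, grad, H = new_coef, new_ll, new_grad, new_H
    gnorm = float(np.abs(grad).max())
    if not converged:
        raise ConvergenceError(
            f"multinomial fit did not converge (|grad|={gnorm:.2e})",
            gradient_norm=gnorm,
        )
    if np.abs(coef).max() > 15:
        warnings.warn(
            "coefficients diverging; quasi-complete separation likely "
            "(ridge-stabilised estimate returned)",
            SeparationWarning, stacklevel=2,
        )
    cov_std = np.linalg.inv(H + ridge * np.eye(H.shape[0]))
    # map back to the original scale: beta_orig = A beta_std (per class)
    G = np.kron(np.eye(Km1), A)
    cov = G @ cov_std @ G.T
    coef_orig = (A @ coef.T).T
    return MultinomialModel(
        levels=levels, reference=reference_level,
        feature_names=feature_names or [f"x{j}" for j in range(p)],
        coef=coef_orig, cov=cov, loglik=ll, n=n,
        converged=converged, grad_norm=gnorm, ridge=ridge,
    )


def fit_multinomial_df(
    df: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    reference_level=None,
    **kwargs,
) -> MultinomialModel:
    """Complete-case multinomial fit straight from a cohort table."""
    cols = [outcome, *predictors]
    sub = df[cols].dropna()
    X, names = build_design(sub, predictors)
    return fit_multinomial(
        X, sub[outcome].to_numpy(), feature_names=names,
        reference_level=reference_level, **kwargs,
    )


# ---------------------------------------------------------------------------
# bootstrap stability selection


def backward_select(
    df: pd.DataFrame,
    outcome: str,
    locked: list[str],
    candidates: list[str],
    reference_level=None,
    criterion: str = "bic",
) -> list[str]:
    """Backward elimination over ``candidates``, with the ``locked``
    confounders present in every model.

    ``criterion='bic'`` (default) drops a factor whenever removal lowers
    BIC; its ln(n)-scaled bar keeps chance associations — in particular the
    winner's-curse factor among many null candidates — from being retained
    by a majority of bootstrap resamples. ``'aic'`` gives the laxer
    classical trade-off."""
    current = list(candidates)

    def _score(cands):
        m = fit_multinomial_df(df, outcome, locked + cands,
                               reference_level=reference_level)
        if criterion == "aic":
            return m.aic
        if criterion == "bic":
            return -2.0 * m.loglik + m.n_params * np.log(m.n)
        raise ValueError(f"unknown criterion {criterion!r}")

    best = _score(current)
    while current:
        options = [(c, _score([x for x in current if x != c])) for c in current]
        drop, without = min(options, key=lambda t: t[1])
        if without < best:
            current.remove(drop)
            best = without
        else:
            break
    return current


@dataclass
class StabilitySelection:
    """Per-factor selection frequencies over bootstrap resamples."""

    B: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    retained: list[str]
    locked: list[str]
    seed: int | None
    final_model: MultinomialModel | None = None
    n_redrawn: int = 0

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": list(self.frequencies),
                "frequency": list(self.frequencies.values()),
                "retained": [f in self.retained for f in self.frequencies],
            }
        )


def bootstrap_stability(
    df: pd.DataFrame,
    outcome: str,
    risk_factors: list[str] | None = None,
    confounders: list[str] | None = None,
    B: int = 500,
    seed: int | None = None,
    reference_level=None,
    retention_threshold: float = 0.5,
    max_retry: int = 100,
    selector_criterion: str = "bic",
) -> StabilitySelection:
    """Bootstrap stability selection of risk factors.

    Draws ``B`` resamples with replacement from the complete-case rows,
    runs backward elimination (BIC by default) over the risk factors
    (confounders locked) on each, and retains factors selected in more than
    ``retention_threshold`` of the resamples. The final model refits the
    original data with the retained factors plus confounders. Resamples
    missing an outcome level are redrawn (logged, bounded).
    """
    risk_factors = list(risk_factors or RISK_FACTOR_COLUMNS)
    confounders = list(confounders or CONFOUNDER_COLUMNS)
    data = df[[outcome, *confounders, *risk_factors]].dropna().reset_index(drop=True)
    n = len(data)
    levels = set(data[outcome])
    rng = np.random.default_rng(seed)
    counts = {f: 0 for f in risk_factors}
    n_redrawn = 0
    for b in range(B):
        for _ in range(max_retry):
            idx = rng.integers(0, n, n)
            boot = data.iloc[idx]
            if set(boot[outcome]) == levels:
                break
            n_redrawn += 1
        else:
            raise ConvergenceError(
                f"resample {b}: could not draw all outcome levels in "
                f"{max_retry} tries"
            )
        try:
            with warnings.catch_warnings():
                # rare factors can separate a small class within a resample;
                # the ridge-stabilised fits are expected here
                warnings.simplefilter("ignore", SeparationWarning)
                kept = backward_select(boot, outcome, confounders, risk_factors,
                                       reference_level=reference_level,
                                       criterion=selector_criterion)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            log.warning("resample %d selector failed (%s); skipped", b, exc)
            continue
        for f in kept:
            counts[f] += 1
    freqs = {f: c / B if B else 0.0 for f, c in counts.items()}
    retained = [f for f in risk_factors if freqs[f] > retention_threshold]
    final = fit_multinomial_df(
        data, outcome, confounders + retained, reference_level=reference_level
    ) if retained or confounders else None
    return StabilitySelection(
        B=B, counts=counts, frequencies=freqs, retained=retained,
        locked=confounders, seed=seed, final_model=final, n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# composite four-level factors

COMPOSITE_LEVELS = ["neither", "a_only", "b_only", "both"]


def make_composite(
    a_flag: pd.Series, b_flag: pd.Series, name: str = "composite"
) -> pd.Series:
    """Four-level composite of two binary risk factors.

    Levels: neither < a_only < b_only < both, with ``neither`` the
    reference. Rows missing either flag are NA (excluded from fits)."""
    a = a_flag.astype("boolean")
    b = b_flag.astype("boolean")
    out = pd.Series(pd.NA, index=a.index, dtype="object", name=name)
    ok = a.notna() & b.notna()
    codes = a[ok].astype(int) + 2 * b[ok].astype(int)
    out[ok] = np.array(["neither", "a_only", "b_only", "both"])[codes]
    return pd.Series(
        pd.Categorical(out, categories=COMPOSITE_LEVELS), index=a.index, name=name
    )


def fit_composite_model(
    df: pd.DataFrame,
    composite: pd.Series,
    retained_predictors: list[str],
    confounders: list[str] | None = None,
    source_flags: tuple[str, str] | None = None,
    outcome: str = "class_label",
    reference_level=None,
) -> tuple[MultinomialModel, dict]:
    """Multinomial fit with a composite factor's three non-reference levels.

    Adjusts for confounders and previously retained predictors, excluding
    the composite's two source flags as separate terms. Empty composite
    levels are dropped from the design and reported as undefined with their
    (zero) counts.
    """
    confounders = list(confounders or CONFOUNDER_COLUMNS)
    source_flags = source_flags or ()
    others = [p for p in retained_predictors
              if p not in source_flags and p != composite.name]
    work = df.copy()
    work[composite.name] = composite.values
    cols = [outcome, composite.name, *confounders, *others]
    sub = work[cols].dropna()
    level_counts = sub[composite.name].value_counts().to_dict()
    empty = [lv for lv in COMPOSITE_LEVELS[1:] if level_counts.get(lv, 0) == 0]
    if empty:
        log.warning("composite levels with no observations: %s", empty)
        sub[composite.name] = sub[composite.name].cat.remove_unused_categories()
    model = fit_multinomial_df(
        sub, outcome, [composite.name, *confounders, *others],
        reference_level=reference_level,
    )
    info = {"level_counts": level_counts, "undefined_levels": empty}
    return model, info
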