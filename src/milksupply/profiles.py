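"""Latent profile analysis of the five milk-supply indicators.

A latent profile model is a finite Gaussian mixture over continuous
indicators — here 24 h milk production, total infant intake, formula
intake, WAZ and delta-WAZ, square-root transformed where skewed and then
z-standardised. The default variance structure is class-varying diagonal
covariances: with a zero-inflated formula indicator (~80% exact zeros) a
variance shared across classes cannot represent both the zero spike and
the formula users' spread, and the fitted classes degrade into formula
strata. Shared diagonal variances remain available via
``equal_variances=True``.

Model selection follows five criteria: decreasing BIC relative to K-1;
classification entropy >= 0.8; a significant parametric bootstrap
likelihood ratio test (BLRT) of K against K-1; average posterior
probability >= 0.5 in every class; and a smallest-class share above 5%.
The selected model is the largest K satisfying all five.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import skew

from .errors import (
    AmbiguousLabellingError,
    DegenerateIndicatorError,
    FitFailureError,
)
from .measures import INDICATOR_COLUMNS

log = logging.getLogger(__name__)

CANONICAL_CLASS_NAMES = {1: "adequate", 2: "oversupply",
                         3: "severe_low_supply", 4: "slow_growth"}
NMS_CLASSES = frozenset({"adequate", "oversupply"})


@dataclass
class IndicatorMatrix:
    """Standardised indicator matrix with its preparation bookkeeping."""

    X: np.ndarray                      # n x d, mean 0 / SD 1 per column
    columns: list[str]
    index: np.ndarray                  # dyad ids of the complete-case rows
    sqrt_applied: np.ndarray           # bool per column
    shift: np.ndarray                  # pre-sqrt shift per column
    center: np.ndarray                 # post-transform mean per column
    scale: np.ndarray                  # post-transform SD per column

    def to_original(self, Z: np.ndarray) -> np.ndarray:
        """Map points on the standardised scale back to measurement units."""
        V = Z * self.scale + self.center
        out = np.where(self.sqrt_applied, np.maximum(V, 0.0) ** 2 - self.shift, V)
        return out


def prepare_indicators(
    records: pd.DataFrame,
    columns: list[str] | None = None,
    skew_threshold: float = 1.0,
) -> IndicatorMatrix:
    """Complete-case rows, square-root transform of skewed columns, z-scores.

    A column is transformed when its absolute sample skewness exceeds
    ``skew_threshold`` (shifted to non-negative support first if needed).
    """
    columns = columns or INDICATOR_COLUMNS
    sub = records[["dyad_id", *columns]].dropna()
    X = sub[columns].to_numpy(float)
    n, d = X.shape
    sqrt_applied = np.zeros(d, dtype=bool)
    shift = np.zeros(d)
    for j in range(d):
        col = X[:, j]
        if col.std() == 0:
            raise DegenerateIndicatorError(f"indicator {columns[j]!r} is constant")
        if abs(skew(col)) > skew_threshold:
            sqrt_applied[j] = True
            shift[j] = max(0.0, -col.min())
            X[:, j] = np.sqrt(col + shift[j])
            if X[:, j].std() == 0:
                raise DegenerateIndicatorError(
                    f"indicator {columns[j]!r} degenerate after transform"
                )
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    X = (X - center) / scale
    return IndicatorMatrix(
        X=X, columns=list(columns), index=sub["dyad_id"].to_numpy(),
        sqrt_applied=sqrt_applied, shift=shift, center=center, scale=scale,
    )


@dataclass
class ProfileModel:
    """A fitted K-class Gaussian profile model."""

    K: int
    weights: np.ndarray        # K
    means: np.ndarray          # K x d
    variances: np.ndarray      # d (shared) or K x d
    equal_variances: bool
    loglik: float
    n: int
    posterior: np.ndarray      # n x K
    n_iter: int = 0

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n_params(self) -> int:
        var_terms = self.d if self.equal_variances else self.K * self.d
        return (self.K - 1) + self.K * self.d + var_terms

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n)

    @property
    def entropy(self) -> float:
        return entropy(self.posterior)

    @property
    def assignments(self) -> np.ndarray:
        return self.posterior.argmax(axis=1)

    @property
    def avg_posterior_per_class(self) -> np.ndarray:
        """Mean posterior probability among members modally assigned to
        each class (NaN for an empty class)."""
        a = self.assignments
        out = np.full(self.K, np.nan)
        for k in range(self.K):
            mask = a == k
            if mask.any():
                out[k] = self.posterior[mask, k].mean()
        return out

    @property
    def smallest_class_share(self) -> float:
        counts = np.bincount(self.assignments, minlength=self.K)
        return counts.min() / self.n


def entropy(P: np.ndarray) -> float:
    """Normalised classification entropy, 1 - sum(-p ln p) / (n ln K).

    1 means perfectly separated classes, 0 uniform posteriors; defined as
    1 for a single-class model.
    """
    P = np.asarray(P, float)
    n, K = P.shape
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(K)))


def _logsumexp_rows(logp):
    # lean replacement for scipy's logsumexp (row-wise over a 2-D array)
    m = logp.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(logp - m).sum(axis=1, keepdims=True)))[:, 0]


def _log_gauss(X, means, variances, equal_variances):
    # returns n x K matrix of component log-densities
    if equal_variances:
        var = variances[None, None, :]           # 1 x 1 x d
    else:
        var = variances[None, :, :]              # 1 x K x d
    diff2 = (X[:, None, :] - means[None, :, :]) ** 2
    return -0.5 * (diff2 / var + np.log(2 * np.pi * var)).sum(axis=2)


def _kmeanspp_centers(X, K, rng):
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            ((X[:, None, :] - np.array(centers)[None]) ** 2).sum(-1), axis=1
        )
        p = d2 / d2.sum() if d2.sum() > 0 else None
        centers.append(X[rng.choice(n, p=p)])
    return np.array(centers)


def _em_once(X, K, rng, equal_variances, tol, max_iter, var_floor,
             init_params=None):
    n, d = X.shape
    if init_params is not None:
        # warm start from (weights, means, variances) of a previous fit
        w0, mu0, var0 = init_params
        logp = _log_gauss(X, mu0, var0, equal_variances) + np.log(w0)
        resp = np.exp(logp - _logsumexp_rows(logp)[:, None])
    else:
        centers = _kmeanspp_centers(X, K, rng)
        assign = ((X[:, None, :] - centers[None]) ** 2).sum(-1).argmin(1)
        resp = np.zeros((n, K))
        resp[np.arange(n), assign] = 1.0
        resp = resp * 0.9 + 0.1 / K  # soften one-hot start

    X2 = X**2
    ll_prev = -np.inf
    for it in range(max_iter):
        # M-step
        Nk = resp.sum(axis=0)
        if Nk.min() < 1.0:
            raise FitFailureError(f"component collapsed (N_k={Nk.min():.3g})")
        weights = Nk / n
        means = (resp.T @ X) / Nk[:, None]
        # E[(x - mu)^2] per component via sufficient statistics
        sq = (resp.T @ X2) - Nk[:, None] * means**2          # K x d
        if equal_variances:
            variances = np.maximum(sq.sum(axis=0) / n, var_floor)
            var = variances[None, :]
        else:
            variances = np.maximum(sq / Nk[:, None], var_floor)
            var = variances
        # E-step: component log-densities via the same expansion
        # (x - mu)^2 = x^2 - 2 x mu + mu^2
        quad = (X2 @ (1.0 / var).T
                - 2.0 * X @ (means / var).T
                + (means**2 / var).sum(axis=1))
        logp = -0.5 * (quad + np.log(2 * np.pi * var).sum(axis=1)) + np.log(weights)
        norm = _logsumexp_rows(logp)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        if ll < ll_prev - 1e-6:
            raise FitFailureError(f"log-likelihood decreased ({ll_prev} -> {ll})")
        if ll - ll_prev < tol:
            ll_prev = ll
            break
        ll_prev = ll
    return ProfileModel(
        K=K, weights=weights, means=means, variances=variances,
        equal_variances=equal_variances, loglik=ll_prev, n=n,
        posterior=resp, n_iter=it + 1,
    )


def fit_gmm(
    X: np.ndarray | IndicatorMatrix,
    K: int,
    n_restarts: int = 20,
    seed=None,
    *,
    equal_variances: bool = False,
    tol: float = 1e-8,
    max_iter: int = 1000,
    var_floor: float = 1e-4,
) -> ProfileModel:
    """Fit a K-class profile model by EM, best of ``n_restarts`` starts."""
    if isinstance(X, IndicatorMatrix):
        X = X.X
    X = np.asarray(X, float)
    n, d = X.shape
    if K < 1 or n <= 5 * K:
        raise FitFailureError(f"need n > 5K (n={n}, K={K})")
    if K == 1:
        means = X.mean(axis=0, keepdims=True)
        var = np.maximum(X.var(axis=0), var_floor)
        logp = _log_gauss(X, means, var, True)
        return ProfileModel(
            K=1, weights=np.array([1.0]), means=means,
            variances=var if equal_variances else var[None, :],
            equal_variances=equal_variances, loglik=float(logp.sum()), n=n,
            posterior=np.ones((n, 1)),
        )
    rng = np.random.default_rng(seed)
    best = None
    failures = []
    for r in range(n_restarts):
        try:
            model = _em_once(X, K, rng, equal_variances, tol, max_iter, var_floor)
        except FitFailureError as exc:
            failures.append(str(exc))
            continue
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise FitFailureError(
            f"all {n_restarts} restarts failed for K={K}", diagnostics=failures
        )
    return best


def sample_from_model(model: ProfileModel, n: int, rng: np.random.Generator):
    """Parametric draw of n points from a fitted profile model."""
    z = rng.choice(model.K, size=n, p=model.weights)
    if model.equal_variances:
        sd = np.sqrt(model.variances)[None, :]
    else:
        sd = np.sqrt(model.variances)[z]
    return model.means[z] + rng.normal(size=(n, model.d)) * sd


def blrt(
    X: np.ndarray | IndicatorMatrix,
    K: int,
    n_boot: int = 99,
    seed=None,
    *,
    n_restarts: int = 10,
    n_restarts_boot: int = 2,
    min_success: float = 0.8,
    equal_variances: bool = False,
    models: tuple[ProfileModel, ProfileModel] | None = None,
    early_stop_alpha: float | None = None,
    warm_start: bool = True,
) -> float:
    """Parametric bootstrap likelihood ratio test of K classes vs K-1.

    Simulates ``n_boot`` datasets from the fitted (K-1)-class model, refits
    both models on each, and returns p = (1 + #{boot LRT >= observed}) /
    (successes + 1). Failed refits are dropped; fewer than
    ``min_success * n_boot`` successes raises. Note the +1 convention makes
    1/(n_boot+1) the smallest attainable p, so testing at level alpha needs
    n_boot >= 1/alpha.
    """
    if isinstance(X, IndicatorMatrix):
        X = X.X
    if K < 2:
        raise ValueError("BLRT needs K >= 2")
    rng = np.random.default_rng(seed)
    if models is None:
        m0 = fit_gmm(X, K - 1, n_restarts, rng.integers(2**31),
                     equal_variances=equal_variances)
        m1 = fit_gmm(X, K, n_restarts, rng.integers(2**31),
                     equal_variances=equal_variances)
    else:
        m0, m1 = models
    lrt_obs = 2.0 * (m1.loglik - m0.loglik)
    n = X.shape[0]
    exceed = 0
    success = 0

    def _boot_fit(Xb, model, n_random):
        """Refit a model on a bootstrap dataset.

        With ``warm_start`` the EM starts from the observed fit's parameters
        (for the null model: its own generating parameters) plus a few
        random restarts — fast, and slightly conservative because the
        observed alternative fit received more optimisation effort. Without
        it, boot fits use pure random restarts; matching ``n_restarts_boot``
        to the observed fits' restarts gives the symmetric, calibrated
        protocol."""
        best = None
        if warm_start:
            try:
                best = _em_once(Xb, model.K, rng, equal_variances, 1e-6, 300,
                                1e-4,
                                init_params=(model.weights, model.means,
                                             model.variances))
            except FitFailureError:
                pass
        for _ in range(n_random):
            try:
                cand = _em_once(Xb, model.K, rng, equal_variances, 1e-6, 300,
                                1e-4)
            except FitFailureError:
                continue
            if best is None or cand.loglik > best.loglik:
                best = cand
        if best is None:
            raise FitFailureError(f"bootstrap refit failed for K={model.K}")
        return best

    n_random_null = 0 if warm_start else n_restarts_boot
    stop_count = (
        None if early_stop_alpha is None
        else int(np.ceil(early_stop_alpha * (n_boot + 1)))
    )
    for b in range(n_boot):
        Xb = sample_from_model(m0, n, rng)
        try:
            b0 = _boot_fit(Xb, m0, n_random_null)
            b1 = _boot_fit(Xb, m1, n_restarts_boot)
        except FitFailureError as exc:
            log.debug("BLRT bootstrap %d failed: %s", b, exc)
            continue
        success += 1
        if 2.0 * (b1.loglik - b0.loglik) >= lrt_obs:
            exceed += 1
        if stop_count is not None and exceed >= stop_count:
            # p can no longer fall below alpha; stop early and report the
            # (conservative) p over the bootstraps completed so far
            break
    if stop_count is None and success < min_success * n_boot:
        raise FitFailureError(
            f"only {success}/{n_boot} bootstrap refits succeeded"
        )
    return (1 + exceed) / (success + 1)


@dataclass
class SelectionCriteria:
    """Thresholds of the five model-fit criteria."""

    entropy_min: float = 0.8
    posterior_min: float = 0.5
    min_class_share: float = 0.05
    blrt_alpha: float = 0.05


@dataclass
class ModelSelectionReport:
    rows: list[dict]
    models: dict[int, ProfileModel]
    selected_k: int | None
    criteria: SelectionCriteria

    @property
    def selected(self) -> ProfileModel | None:
        return self.models.get(self.selected_k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def select_model(
    X: np.ndarray | IndicatorMatrix,
    K_range=range(1, 6),
    seed=None,
    *,
    criteria: SelectionCriteria | None = None,
    n_restarts: int = 20,
    n_boot: int = 99,
    n_restarts_boot: int = 2,
    equal_variances: bool = False,
) -> ModelSelectionReport:
    """Fit all K in ``K_range`` and apply the five selection criteria.

    A candidate K passes when entropy, average posteriors and smallest-class
    share clear their thresholds AND its BIC improves on K-1 AND its BLRT
    against K-1 is significant (the BIC/BLRT conditions are vacuous at the
    smallest K). The selected model is the largest passing K; ``None`` when
    nothing passes.
    """
    if isinstance(X, IndicatorMatrix):
        X = X.X
    criteria = criteria or SelectionCriteria()
    rng = np.random.default_rng(seed)
    Ks = sorted(K_range)
    models: dict[int, ProfileModel] = {}
    rows = []
    for K in Ks:
        models[K] = fit_gmm(X, K, n_restarts, rng.integers(2**31),
                            equal_variances=equal_variances)
    for K in Ks:
        m = models[K]
        avg_post = m.avg_posterior_per_class
        row = {
            "K": K,
            "loglik": m.loglik,
            "bic": m.bic,
            "entropy": m.entropy,
            "min_avg_posterior": float(np.nanmin(avg_post)),
            "smallest_class_share": m.smallest_class_share,
            "blrt_p": np.nan,
        }
        prev = models.get(K - 1)
        if prev is not None:
            row["bic_improves"] = m.bic < prev.bic
            row["blrt_p"] = blrt(
                X, K, n_boot, rng.integers(2**31),
                n_restarts_boot=n_restarts_boot,
                equal_variances=equal_variances, models=(prev, m),
                early_stop_alpha=criteria.blrt_alpha,
            )
            row["blrt_significant"] = row["blrt_p"] < criteria.blrt_alpha
        else:
            row["bic_improves"] = True
            row["blrt_significant"] = True
        row["entropy_ok"] = row["entropy"] >= criteria.entropy_min
        row["posterior_ok"] = row["min_avg_posterior"] >= criteria.posterior_min
        row["share_ok"] = row["smallest_class_share"] > criteria.min_class_share
        row["passed"] = all(
            row[f] for f in
            ["bic_improves", "blrt_significant", "entropy_ok", "posterior_ok", "share_ok"]
        )
        rows.append(row)
    passing = [r["K"] for r in rows if r["passed"]]
    selected = max(passing) if passing else None
    return ModelSelectionReport(rows=rows, models=models,
                                selected_k=selected, criteria=criteria)


def canonical_class_order(model: ProfileModel, im: IndicatorMatrix) -> list[int]:
    """Map raw component indices to canonical clinical labels.

    For a four-class model: the highest-MP class with intake below MP is
    the oversupply class; of the rest, the lowest-MP (and highest-formula)
    class is severe low supply; of the remaining two, the lower-WAZ class
    is slow growth and the other adequate. Returned list gives raw indices
    in canonical label order 1..K. Other K fall back to MP-descending order.
    """
    means_orig = im.to_original(model.means)
    cols = {c: j for j, c in enumerate(im.columns)}
    mp = means_orig[:, cols["mp_24h"]]
    total = means_orig[:, cols["total_intake_24h"]]
    formula = means_orig[:, cols["formula_intake_24h"]]
    wazc = means_orig[:, cols["waz_current"]]
    if model.K != 4:
        return list(np.argsort(-mp))
    oversupply = int(np.argmax(mp))
    if total[oversupply] >= mp[oversupply]:
        raise AmbiguousLabellingError(
            "highest-MP class does not show intake below production; "
            f"class means:\n{means_orig}"
        )
    rest = [k for k in range(4) if k != oversupply]
    severe = min(rest, key=lambda k: mp[k])
    if formula[severe] < max(formula[k] for k in rest):
        raise AmbiguousLabellingError(
            "lowest-MP class is not the highest-formula class; "
            f"class means:\n{means_orig}"
        )
    rest2 = [k for k in rest if k != severe]
    slow = min(rest2, key=lambda k: wazc[k])
    adequate = [k for k in rest2 if k != slow][0]
    return [adequate, oversupply, severe, slow]


def assign_and_group(model: ProfileModel, im: IndicatorMatrix) -> pd.DataFrame:
    """Modal class assignment with canonical labels and NMS/LMS grouping.

    Posterior ties resolve to the lower canonical label (and are logged).
    The NMS group merges the adequate and oversupply classes; every other
    class is LMS. For K != 4 classes are labelled by descending MP and the
    group column is left empty.
    """
    order = canonical_class_order(model, im)
    P = model.posterior[:, order]          # columns now in canonical order
    assign = P.argmax(axis=1)
    n_ties = int((np.abs(P - P.max(axis=1, keepdims=True)) < 1e-12).sum(axis=1).max())
    if n_ties > 1:
        log.info("posterior ties resolved toward the lower canonical class")
    if model.K == 4:
        names = [CANONICAL_CLASS_NAMES[k + 1] for k in range(4)]
        groups = ["NMS" if nm in NMS_CLASSES else "LMS" for nm in names]
    else:
        names = [f"class_{k + 1}" for k in range(model.K)]
        groups = [None] * model.K
    return pd.DataFrame(
        {
            "dyad_id": im.index,
            "class_label": assign + 1,
            "class_name": [names[a] for a in assign],
            "posterior_max": P.max(axis=1),
            "group": [groups[a] for a in assign],
        }
    )
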