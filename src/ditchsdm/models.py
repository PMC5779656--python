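"""Distribution models: binomial-logit GLM and presence-background Maxent.

Two complementary models of species occurrence on the ditch network:

* :func:`fit_glm` -- logistic regression (binomial GLM, logit link) on
  presence/absence data, fitted by iteratively reweighted least squares with
  Wald inference. Because every covariate is rescaled to [0, 1] beforehand,
  the absolute coefficient values double as relative variable importance.

* :func:`fit_maxent` -- a maximum-entropy (Gibbs) distribution over the
  background cells, constrained toward the presence-sample feature means and
  L1-regularized per feature. Fitting is sequential coordinate descent over
  features with a line search, stopping when the regularized training gain
  changes by less than the convergence threshold (default 1e-5) or at the
  iteration cap (default 5000). Per-variable percent contributions accumulate
  the gain improvements credited to each variable's features, normalized to
  sum to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "GlmFit",
    "MaxentConfig",
    "MaxentFit",
    "SeparationError",
    "fit_glm",
    "fit_maxent",
    "predict",
    "variable_importance",
    "importance_flags",
]


class SeparationError(RuntimeError):
    """Raised when the likelihood diverges because a covariate separates the classes."""


@dataclass
class GlmFit:
    """A fitted binomial-logit GLM."""

    coefficients: pd.Series  # includes "(Intercept)"
    std_errors: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    deviance_trace: list[float]
    converged: bool

    @property
    def deviance(self) -> float:
        return self.deviance_trace[-1]

    def significant(self, alpha: float = 0.05) -> pd.Series:
        """Coefficients with p < alpha (intercept excluded), as shown in tables."""
        keep = (self.p_values < alpha) & (self.p_values.index != "(Intercept)")
        return self.coefficients[keep]

    def table_row(self, names: list[str], alpha: float = 0.05, digits: int = 1) -> dict:
        """One report row: rounded coefficients, blank where p >= alpha."""
        sig = self.significant(alpha)
        return {n: (round(float(sig[n]), digits) if n in sig.index else "") for n in names}


def fit_glm(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    separation_bound: float = 15.0,
) -> GlmFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` holds the rescaled covariates (no intercept column; one is added).
    Deviance decreases monotonically (step-halving enforces it). Raises
    :class:`SeparationError`, naming the worst variable, if any coefficient
    exceeds ``separation_bound`` in absolute value -- on [0, 1] covariates
    that indicates (quasi-)complete separation.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one presence and one absence")
    names = names or [f"x{i}" for i in range(X.shape[1])]
    Xd = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient")
    labels = ["(Intercept)"] + list(names)

    beta = np.zeros(Xd.shape[1])
    eta = Xd @ beta
    mu = special.expit(eta)

    def deviance_of(mu_: np.ndarray) -> float:
        eps = 1e-12
        return float(
            -2.0 * np.sum(y * np.log(mu_ + eps) + (1 - y) * np.log(1 - mu_ + eps))
        )

    trace = [deviance_of(mu)]
    converged = False
    for _ in range(max_iter):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = Xd * w[:, None]
        try:
            beta_new = np.linalg.solve(Xd.T @ WX, Xd.T @ (w * z))
        except np.linalg.LinAlgError:
            raise SeparationError("IRLS normal equations singular (separation or collinearity)")
        # step halving keeps the deviance monotone
        step = beta_new - beta
        for _half in range(30):
            cand = beta + step
            mu_c = special.expit(Xd @ cand)
            dev_c = deviance_of(mu_c)
            if dev_c <= trace[-1] + 1e-12:
                break
            step *= 0.5
        beta = beta + step
        eta = Xd @ beta
        mu = special.expit(eta)
        dev = deviance_of(mu)
        if np.max(np.abs(beta)) > separation_bound:
            worst = labels[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"coefficient for {worst} exceeds {separation_bound} on rescaled data: "
                "(quasi-)complete separation"
            )
        done = abs(trace[-1] - dev) < tol * (abs(dev) + 1.0)
        trace.append(dev)
        if done:
            converged = True
            break

    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]))
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    return GlmFit(
        coefficients=pd.Series(beta, index=labels),
        std_errors=pd.Series(se, index=labels),
        z_values=pd.Series(zval, index=labels),
        p_values=pd.Series(pval, index=labels),
        deviance_trace=trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Maxent
# ---------------------------------------------------------------------------


@dataclass
class MaxentConfig:
    """Feature classes, regularization and stopping rule of the Maxent fit."""

    convergence_tol: float = 1e-5
    max_iterations: int = 5000
    use_linear: bool = True
    use_quadratic: bool = True
    use_hinge: bool = True  # auto-disabled below hinge_min_presences
    hinge_min_presences: int = 15
    hinge_knots: int = 8
    beta_multiplier: float = 1.0

    # default L1 multipliers by presence-sample size, per feature class:
    # linear/quadratic interpolate (10, 1.0) (30, 0.2) (100, 0.05); hinge 0.5
    def reg_multiplier(self, kind: str, n_presence: int) -> float:
        if kind == "hinge":
            return 0.5 * self.beta_multiplier
        xs, ys = [10.0, 30.0, 100.0], [1.0, 0.2, 0.05]
        return float(np.interp(n_presence, xs, ys)) * self.beta_multiplier


@dataclass
class Feature:
    variable: str
    kind: str  # linear | quadratic | hinge_fwd | hinge_rev
    knot: float | None = None

    @property
    def label(self) -> str:
        if self.knot is None:
            return f"{self.kind}({self.variable})"
        return f"{self.kind}({self.variable};{self.knot:.3f})"

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            return x
        if self.kind == "quadratic":
            return x**2
        if self.kind == "hinge_fwd":
            return np.clip((x - self.knot) / max(1.0 - self.knot, 1e-9), 0.0, 1.0)
        if self.kind == "hinge_rev":
            return np.clip((self.knot - x) / max(self.knot, 1e-9), 0.0, 1.0)
        raise ValueError(f"unknown feature kind {self.kind}")


@dataclass
class MaxentFit:
    """A fitted maximum-entropy presence-background model."""

    features: list[Feature]
    lambdas: np.ndarray  # one weight per feature
    log_z: float  # log partition over background
    entropy: float  # Shannon entropy of the fitted background distribution
    contributions: pd.Series  # percent per variable, sums to 100
    gain_trace: list[float]  # regularized training gain per accepted update
    converged: bool
    variables: list[str] = field(default_factory=list)

    @property
    def gain(self) -> float:
        return self.gain_trace[-1] if self.gain_trace else 0.0

    def raw_scores(self, X: pd.DataFrame) -> np.ndarray:
        F = np.column_stack([f.evaluate(X[f.variable].to_numpy(dtype=float)) for f in self.features])
        return F @ self.lambdas

    def logistic(self, X: pd.DataFrame) -> np.ndarray:
        """Logistic-output transform: bounded (0, 1) suitability score."""
        return special.expit(self.raw_scores(X) - self.log_z + self.entropy)


def _build_features(
    X: pd.DataFrame, variables: list[str], n_presence: int, config: MaxentConfig
) -> list[Feature]:
    feats: list[Feature] = []
    for v in variables:
        if config.use_linear:
            feats.append(Feature(v, "linear"))
        if config.use_quadratic:
            feats.append(Feature(v, "quadratic"))
        if config.use_hinge and n_presence >= config.hinge_min_presences:
            qs = np.quantile(
                X[v].to_numpy(dtype=float), np.linspace(0.05, 0.95, config.hinge_knots)
            )
            for k in np.unique(np.round(qs, 6)):
                if 0.0 < k < 1.0:
                    feats.append(Feature(v, "hinge_fwd", float(k)))
                    feats.append(Feature(v, "hinge_rev", float(k)))
    return feats


def fit_maxent(
    presence_cells: list,
    background: pd.DataFrame,
    cells: list,
    config: MaxentConfig | None = None,
    variables: list[str] | None = None,
) -> MaxentFit:
    """Fit the maximum-entropy distribution over background cells.

    ``background`` holds the rescaled covariates of all surveyed ditch cells
    (one row per cell, in the order of ``cells``); ``presence_cells`` selects
    the presence rows. The fit maximizes the L1-penalized mean log-density of
    the presences under the Gibbs distribution q(x) = exp(lambda . f(x)) / Z.
    """
    config = config or MaxentConfig()
    variables = variables or [c for c in background.columns if c not in ("row", "col")]
    values = background[variables].to_numpy(dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("covariates take fewer than 2 distinct values overall")
    cell_index = {c: i for i, c in enumerate(cells)}
    try:
        pres_idx = np.array([cell_index[c] for c in presence_cells], dtype=int)
    except KeyError as err:
        raise KeyError(f"presence cell {err.args[0]} not in background") from None
    m = len(pres_idx)
    if m < 1:
        raise ValueError("no presence cells")

    feats = _build_features(background, variables, m, config)
    F = np.column_stack(
        [f.evaluate(background[f.variable].to_numpy(dtype=float)) for f in feats]
    )
    n_bg = F.shape[0]
    Fp_mean = F[pres_idx].mean(axis=0)
    # per-feature L1 penalty: multiplier * sd of the feature over presences / sqrt(m)
    sd_pres = F[pres_idx].std(axis=0, ddof=1) if m > 1 else np.full(F.shape[1], 0.0)
    sd_pres = np.maximum(sd_pres, 1e-4)
    reg = np.array(
        [config.reg_multiplier("hinge" if f.kind.startswith("hinge") else "lq", m) for f in feats]
    ) * sd_pres / np.sqrt(m)

    lam = np.zeros(F.shape[1])
    eta = np.zeros(n_bg)  # F @ lam

    def log_z(e: np.ndarray) -> float:
        return float(special.logsumexp(e))

    def objective(e: np.ndarray, l: np.ndarray) -> float:
        """Regularized training gain relative to the uniform distribution."""
        return float(Fp_mean @ l - log_z(e) + np.log(n_bg) - np.sum(reg * np.abs(l)))

    gain = objective(eta, lam)
    gain_trace = [gain]
    credit: dict[str, float] = {v: 0.0 for v in variables}
    converged = False
    n_feat = F.shape[1]
    rel_change = np.inf
    it = 0
    while it < config.max_iterations:
        cycle_start = gain
        for j in range(n_feat):
            it += 1
            q = np.exp(eta - log_z(eta))
            fj = F[:, j]
            g = Fp_mean[j] - float(q @ fj)  # gradient of unpenalized gain
            h = float(q @ fj**2) - float(q @ fj) ** 2  # curvature
            if h <= 1e-12:
                continue
            # soft-thresholded Newton step on the L1-penalized 1-d problem
            raw = lam[j] + g / h
            target = np.sign(raw) * max(abs(raw) - reg[j] / h, 0.0)
            step = target - lam[j]
            if step == 0.0:
                continue
            for _half in range(25):
                cand = lam.copy()
                cand[j] = lam[j] + step
                eta_c = eta + step * fj
                new_gain = objective(eta_c, cand)
                if new_gain >= gain - 1e-12:
                    break
                step *= 0.5
            else:
                continue
            if new_gain > gain:
                credit[feats[j].variable] += new_gain - gain
                lam, eta, gain = cand, eta_c, new_gain
                gain_trace.append(gain)
            if it >= config.max_iterations:
                break
        rel_change = gain - cycle_start
        if rel_change < config.convergence_tol:
            converged = True
            break

    total_credit = sum(credit.values())
    if total_credit > 1e-12:
        contrib = pd.Series({v: 100.0 * credit[v] / total_credit for v in variables})
    else:  # no informative feature: spread evenly
        contrib = pd.Series({v: 100.0 / len(variables) for v in variables})

    lz = log_z(eta)
    q = np.exp(eta - lz)
    entropy = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
    return MaxentFit(
        features=feats,
        lambdas=lam,
        log_z=lz,
        entropy=entropy,
        contributions=contrib,
        gain_trace=gain_trace,
        converged=converged,
        variables=list(variables),
    )


def predict(fit: GlmFit | MaxentFit, X: pd.DataFrame) -> np.ndarray:
    """Per-cell score in [0, 1] for either model on rescaled covariates.

    GLM: inverse-logit probability. Maxent: logistic-output transform of the
    raw Gibbs density. Warns if covariates leave [-0.1, 1.1] (extrapolation
    beyond the training rescale bounds).
    """
    names = (
        [n for n in fit.coefficients.index if n != "(Intercept)"]
        if isinstance(fit, GlmFit)
        else fit.variables
    )
    vals = X[names].to_numpy(dtype=float)
    if np.any((vals < -0.1) | (vals > 1.1)):
        warnings.warn("covariates outside [-0.1, 1.1]: extrapolating beyond training range",
                      stacklevel=2)
    if isinstance(fit, GlmFit):
        eta = fit.coefficients["(Intercept)"] + vals @ fit.coefficients[names].to_numpy()
        return special.expit(eta)
    return fit.logistic(X)


def variable_importance(fit: GlmFit | MaxentFit, alpha: float = 0.05) -> pd.Series:
    """Per-variable importance: |significant coefficient| (GLM) or percent
    contribution (Maxent)."""
    if isinstance(fit, GlmFit):
        sig = fit.significant(alpha)
        if sig.empty:
            warnings.warn("no significant GLM terms; importance is empty", stacklevel=2)
        return sig.abs()
    return fit.contributions.copy()


def importance_flags(values: pd.Series, pooled: np.ndarray | None = None) -> pd.Series:
    """Flag variables whose importance is strictly above the median.

    ``pooled`` supplies the value set the median is taken over (for example
    all species' coefficients together); by default the series itself.
    """
    ref = np.asarray(pooled, dtype=float) if pooled is not None else values.to_numpy(dtype=float)
    med = float(np.median(np.abs(ref)))
    return values.abs() > med
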