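"""Penalized-spline distributed lag models.

The model regresses a behavioral t-score on 144 monthly exposures plus
covariates,

    y_i = alpha + sum_j beta_j x_ij + c_i' gamma + eps_i,

with the lag coefficients constrained to a smooth function of the month of
life, beta_j = f(j), f represented in a spline basis with a roughness
penalty.  Writing B for the L x K basis matrix over lags and theta for the
spline coefficients, the exposure block of the design is Z = X B and the fit
minimizes

    ||y - alpha - Z theta - C gamma||^2 + lambda theta' S theta,

where S penalizes curvature of f.  The smoothing parameter is selected by
restricted maximum likelihood (default) or GCV; model complexity is
summarized by the effective degrees of freedom (edf) of the spline block,
the trace of the corresponding block of the influence matrix.  Following the
study design this reproduces, the default basis places a knot at every lag;
if the selected edf exceeds 20 the model is refit with at most 20 equally
spaced knots.

Two basis dialects are provided: "cr", a natural cubic regression spline
parameterized by its values at the knots with the exact integrated squared
second derivative as penalty, and "ps", cubic B-splines with a second-order
difference penalty (P-splines).  Both have a two-dimensional penalty null
space (affine functions of lag, for "ps" via the difference operator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, stats

logger = logging.getLogger("leadlag.dlm")

#: smoothing-parameter search bracket (on lambda) and tolerance on log-lambda
LAMBDA_BRACKET = (1e-8, 1e12)
LAMBDA_TOL = 1e-6
#: edf cap triggering the equally-spaced-knot refit
EDF_CAP_DEFAULT = 20
#: reference level absorbed into the intercept for maternal education
EDUCATION_REFERENCE = "high school or less"


# ---------------------------------------------------------------------------
# Lag basis
# ---------------------------------------------------------------------------

@dataclass
class LagBasis:
    """Spline basis over lags 1..L with a roughness penalty.

    ``basis_matrix`` is L x K (row = lag, column = basis function) and
    ``penalty_matrix`` is the K x K symmetric PSD curvature penalty whose
    null space contains straight lines in lag.
    """

    basis_matrix: np.ndarray
    penalty_matrix: np.ndarray
    knots: np.ndarray
    kind: str       # "every-lag" | "equally-spaced"
    dialect: str    # "cr" | "ps"

    @property
    def n_lags(self) -> int:
        return self.basis_matrix.shape[0]

    @property
    def n_coef(self) -> int:
        return self.basis_matrix.shape[1]


def _natural_spline_matrices(knots: np.ndarray):
    """Green & Silverman band matrices for a natural cubic spline.

    Returns (F, S): F maps values-at-knots theta to second derivatives at all
    knots (natural boundary: zero at the ends) and S = D' B^{-1} D is the
    integrated squared second derivative in the theta coordinates.
    """
    K = len(knots)
    h = np.diff(knots)
    D = np.zeros((K - 2, K))
    B = np.zeros((K - 2, K - 2))
    for i in range(K - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < K - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = linalg.solve(B, D, assume_a="pos")
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0
    F = np.zeros((K, K))
    F[1:-1] = Binv_D
    return F, S


def _cr_eval(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Evaluation matrix of a natural cubic spline given values at knots.

    Row t gives f(x_t) as a linear combination of theta; linear extrapolation
    outside the knot range (natural boundary conditions).
    """
    K = len(knots)
    h = np.diff(knots)
    M = np.zeros((len(x), K))
    idx = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, K - 2)
    for t, (xt, i) in enumerate(zip(x, idx)):
        hi = h[i]
        lo, up = knots[i], knots[i + 1]
        if xt < knots[0]:      # linear extrapolation, slope from end segment
            am, ap = 1.0 - (xt - lo) / hi, (xt - lo) / hi
            cm = cp = 0.0
            # second-derivative terms at the boundary knot vanish (natural);
            # derivative continuation handled by the linear part plus the
            # boundary slope correction below
            M[t, i] += am
            M[t, i + 1] += ap
            # slope at x0: (th1-th0)/h0 - h0/6*(2*g0+g1); g0=0
            M[t] += (xt - knots[0]) * 0.0  # linear part already exact for g=0
            M[t] -= (xt - knots[0]) * (hi / 6.0) * F[i + 1]
            continue
        if xt > knots[-1]:
            am, ap = 1.0 - (xt - lo) / hi, (xt - lo) / hi
            M[t, i] += am
            M[t, i + 1] += ap
            M[t] += (xt - knots[-1]) * (hi / 6.0) * F[i]
            continue
        am = (up - xt) / hi
        ap = (xt - lo) / hi
        cm = ((up - xt) ** 3 / hi - hi * (up - xt)) / 6.0
        cp = ((xt - lo) ** 3 / hi - hi * (xt - lo)) / 6.0
        M[t, i] += am
        M[t, i + 1] += ap
        M[t] += cm * F[i] + cp * F[i + 1]
    return M


def build_lag_basis(n_lags: int, kind: str = "every-lag",
                    max_knots: int | None = None,
                    dialect: str = "cr") -> LagBasis:
    """Construct the spline basis and curvature penalty over lags 1..n_lags.

    kind "every-lag" places a knot at every lag (K = n_lags; for the "cr"
    dialect the basis matrix is then the identity, since the basis is
    parameterized by the spline's values at the knots).  kind
    "equally-spaced" uses ``max_knots`` knots evenly spanning [1, n_lags].
    """
    if n_lags < 4:
        raise ValueError("need at least 4 lags for a cubic spline basis")
    lags = np.arange(1, n_lags + 1, dtype=float)
    if kind == "every-lag":
        knots = lags.copy()
    elif kind == "equally-spaced":
        if max_knots is None or not 4 <= max_knots <= n_lags:
            raise ValueError("equally-spaced basis needs 4 <= max_knots <= n_lags")
        knots = np.linspace(1, n_lags, max_knots)
    else:
        raise ValueError(f"unknown basis kind {kind!r}")

    if dialect == "cr":
        F, S = _natural_spline_matrices(knots)
        if kind == "every-lag":
            M = np.eye(n_lags)
        else:
            M = _cr_eval(lags, knots, F)
    elif dialect == "ps":
        K = len(knots)
        # cubic B-splines on uniform unclamped knots (P-splines): the
        # second-order difference penalty then annihilates affine functions
        h = (n_lags - 1) / (K - 3)
        t = 1.0 + h * np.arange(-3, K + 1)
        M = interpolate.BSpline.design_matrix(lags, t, 3).toarray()
        D2 = np.diff(np.eye(K), n=2, axis=0)
        S = D2.T @ D2
    else:
        raise ValueError(f"unknown basis dialect {dialect!r}")
    return LagBasis(basis_matrix=M, penalty_matrix=S, knots=knots,
                    kind=kind, dialect=dialect)


# ---------------------------------------------------------------------------
# Model specification and fit containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What to fit: outcome, covariates, basis and smoothing choices."""

    outcome_name: str = "outcome"
    covariate_names: tuple = ()
    n_lags: int = 144
    basis_kind: str = "every-lag"
    dialect: str = "cr"
    max_knots: int = EDF_CAP_DEFAULT
    smoothing: str = "reml"      # "reml" | "gcv"
    adjusted: bool = True
    lam: float | None = None     # fixed smoothing parameter; None = select
    ci_level: float = 0.95
    edf_cap: float = EDF_CAP_DEFAULT

    def __post_init__(self) -> None:
        if self.n_lags < 2:
            raise ValueError("n_lags must be >= 2")
        if self.smoothing not in ("reml", "gcv"):
            raise ValueError("smoothing must be 'reml' or 'gcv'")


@dataclass
class DLMFit:
    """Fitted penalized DLM: coefficients, covariance, lambda and edf."""

    intercept: float
    theta: np.ndarray            # spline coefficients
    gamma: dict                  # covariate name -> coefficient
    lam: float
    edf: float                   # spline-block effective degrees of freedom
    edf_total: float
    coef_covariance: np.ndarray  # joint (intercept, theta, gamma) covariance
    residual_sd: float
    n_used: int
    exclusions: dict             # reason -> list of subject ids/indices
    basis: LagBasis
    spec: ModelSpec
    refit: bool = False
    smoothing_criterion: float = float("nan")

    @property
    def theta_covariance(self) -> np.ndarray:
        K = len(self.theta)
        return self.coef_covariance[1:1 + K, 1:1 + K]


@dataclass
class LagEffectCurve:
    """Per-lag effect of +1 ng/m3 with pointwise confidence limits."""

    lag: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        if np.any(self.ci_low > self.ci_high):
            raise ValueError("ci_low exceeds ci_high")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lag, "beta": self.beta, "se": self.se,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, level: float = 0.95) -> "LagEffectCurve":
        df = pd.read_csv(path)
        return cls(df["lag"].to_numpy(), df["beta"].to_numpy(),
                   df["se"].to_numpy(), df["ci_low"].to_numpy(),
                   df["ci_high"].to_numpy(), level=level)


# ---------------------------------------------------------------------------
# Covariate design
# ---------------------------------------------------------------------------

def build_covariate_design(covariates: pd.DataFrame | None,
                           names: tuple = ()) -> tuple[np.ndarray, list]:
    """Numeric design from a covariate table.

    Numeric columns enter on their natural scale.  Categorical/object columns
    become indicator contrasts; for maternal education the reference level is
    "high school or less", otherwise the first category in sorted order.
    """
    if covariates is None or (names is not None and len(names) == 0):
        return np.empty((0, 0)), []
    cols = list(names) if names else list(covariates.columns)
    blocks, labels = [], []
    for c in cols:
        s = covariates[c]
        if pd.api.types.is_numeric_dtype(s):
            blocks.append(s.to_numpy(dtype=float)[:, None])
            labels.append(c)
        else:
            levels = sorted(s.dropna().unique())
            ref = EDUCATION_REFERENCE if EDUCATION_REFERENCE in levels else levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                blocks.append((s == lev).to_numpy(dtype=float)[:, None])
                labels.append(f"{c}[{lev}]")
            # NaN rows: mark missing across the dummies so complete-case
            # filtering catches them
            if s.isna().any():
                for b in blocks[-(len(levels) - 1):]:
                    b[s.isna().to_numpy(), 0] = np.nan
    C = np.hstack(blocks) if blocks else np.empty((len(covariates), 0))
    return C, labels


def _check_covariate_rank(C: np.ndarray, labels: list) -> None:
    if C.shape[1] == 0:
        return
    X = np.column_stack([np.ones(C.shape[0]), C])
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = X[:, :1]
        for j in range(C.shape[1]):
            cand = np.column_stack([cur, C[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(labels[j])
            else:
                cur = cand
        raise ValueError(f"covariate design is rank deficient; collinear: {bad}")


# ---------------------------------------------------------------------------
# Penalized fit
# ---------------------------------------------------------------------------

def _as_exposure_array(x):
    values = getattr(x, "values", x)
    subjects = getattr(x, "subjects", None)
    values = np.asarray(values, dtype=float)
    if subjects is None:
        subjects = [str(i) for i in range(values.shape[0])]
    return values, list(subjects)


def fit_penalized_dlm(x, outcome, covariates=None,
                      spec: ModelSpec | None = None,
                      basis: LagBasis | None = None) -> DLMFit:
    """Fit the penalized-spline DLM on complete cases.

    Subjects with any missing exposure month, covariate value or outcome are
    dropped and recorded in the fit's exclusion ledger.  lambda is selected
    by the criterion in ``spec.smoothing`` over the bracket [1e-8, 1e12]
    (Brent on log lambda) unless ``spec.lam`` fixes it.
    """
    spec = spec or ModelSpec()
    X, subjects = _as_exposure_array(x)
    n, L = X.shape
    if L != spec.n_lags:
        raise ValueError(f"exposure matrix has {L} lags, spec expects {spec.n_lags}")
    y = np.asarray(pd.Series(outcome), dtype=float)
    if len(y) != n:
        raise ValueError("outcome length does not match exposure matrix")

    if spec.adjusted and covariates is not None:
        C, cov_labels = build_covariate_design(covariates, spec.covariate_names)
    else:
        C, cov_labels = np.empty((n, 0)), []

    # complete cases, with reasons
    miss_x = np.isnan(X).any(axis=1)
    miss_y = np.isnan(y)
    miss_c = np.isnan(C).any(axis=1) if C.size else np.zeros(n, bool)
    exclusions = {}
    for mask, reason in ((miss_c, "missing covariate"),
                         (miss_x, "missing monthly exposure"),
                         (miss_y, "missing outcome")):
        ids = [subjects[i] for i in np.flatnonzero(mask)]
        if ids:
            exclusions[reason] = ids
    keep = ~(miss_x | miss_y | miss_c)
    X, y = X[keep], y[keep]
    C = C[keep] if C.size else np.empty((keep.sum(), 0))
    n_used = int(keep.sum())
    if n_used <= C.shape[1] + 2:
        raise ValueError(f"only {n_used} complete cases for {C.shape[1]} covariates")
    _check_covariate_rank(C, cov_labels)

    if basis is None:
        basis = build_lag_basis(spec.n_lags, spec.basis_kind,
                                spec.max_knots, spec.dialect)
    B, S = basis.basis_matrix, basis.penalty_matrix
    K = basis.n_coef
    Z = X @ B
    Xd = np.column_stack([np.ones(n_used), Z, C])
    p = Xd.shape[1]
    P = np.zeros((p, p))
    P[1:1 + K, 1:1 + K] = S
    s_eigs = np.linalg.eigvalsh(S)
    rank_S = int(np.sum(s_eigs > s_eigs[-1] * 1e-10))
    Mp = p - rank_S  # unpenalized coefficient dimension

    XtX = Xd.T @ Xd
    Xty = Xd.T @ y

    def solve(lam: float):
        H = XtX + lam * P
        try:
            cf = linalg.cho_factor(H, lower=True)
        except linalg.LinAlgError as err:
            raise ValueError(f"normal equations singular at lambda={lam:g}: {err}")
        b = linalg.cho_solve(cf, Xty)
        resid = y - Xd @ b
        rss = float(resid @ resid)
        pen = float(lam * (b @ (P @ b)))
        Hinv = linalg.cho_solve(cf, np.eye(p))
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        influence_diag = np.einsum("ij,ji->i", Hinv, XtX)
        edf_total = float(influence_diag.sum())
        edf_spline = float(influence_diag[1:1 + K].sum())
        return b, rss, pen, Hinv, logdet, edf_total, edf_spline

    def criterion(loglam: float) -> float:
        lam = float(np.exp(loglam))
        try:
            _, rss, pen, _, logdet, edf_total, _ = solve(lam)
        except ValueError:
            return 1e300  # singular normal equations: steer the search away
        if edf_total >= n_used:
            return 1e300
        if spec.smoothing == "reml":
            # profiled restricted likelihood (constants dropped)
            return ((n_used - Mp) * np.log(rss + pen) + logdet
                    - rank_S * loglam)
        return float(n_used * rss / (n_used - edf_total) ** 2)

    if spec.lam is not None:
        lam_hat = float(spec.lam)
        crit_val = float("nan")
    else:
        lo, hi = np.log(LAMBDA_BRACKET[0]), np.log(LAMBDA_BRACKET[1])
        res = optimize.minimize_scalar(criterion, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": LAMBDA_TOL})
        if not res.success:
            raise RuntimeError(
                f"lambda search failed on log-bracket [{lo:.3f}, {hi:.3f}]: "
                f"{res.message}"
            )
        lam_hat = float(np.exp(res.x))
        crit_val = float(res.fun)

    b, rss, pen, Hinv, _, edf_total, edf_spline = solve(lam_hat)
    if n_used - edf_total <= 0:
        raise ValueError("residual degrees of freedom non-positive")
    sigma2 = rss / (n_used - edf_total)
    Vb = sigma2 * Hinv
    Vb = (Vb + Vb.T) / 2.0

    gamma = dict(zip(cov_labels, b[1 + K:]))
    return DLMFit(intercept=float(b[0]), theta=b[1:1 + K], gamma=gamma,
                  lam=lam_hat, edf=edf_spline, edf_total=edf_total,
                  coef_covariance=Vb, residual_sd=float(np.sqrt(sigma2)),
                  n_used=n_used, exclusions=exclusions, basis=basis,
                  spec=spec, smoothing_criterion=crit_val)


def effective_df(fit: DLMFit) -> float:
    """Spline-block effective degrees of freedom of a fit."""
    return fit.edf


def lag_effects(fit: DLMFit, basis: LagBasis | None = None,
                level: float = 0.95) -> LagEffectCurve:
    """Per-lag effects beta_j = B_j . theta with pointwise CIs.

    Standard errors propagate the posterior covariance of theta through the
    basis rows; intervals are normal-based at the requested level.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    basis = basis or fit.basis
    B = basis.basis_matrix
    if B.shape[1] != len(fit.theta):
        raise ValueError("basis and fit are dimensionally inconsistent")
    beta = B @ fit.theta
    V = fit.theta_covariance
    var = np.einsum("ij,jk,ik->i", B, V, B)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return LagEffectCurve(lag=np.arange(1, B.shape[0] + 1), beta=beta, se=se,
                          ci_low=beta - z * se, ci_high=beta + z * se,
                          level=level)


def fit_with_refit_rule(x, outcome, covariates=None,
                        spec: ModelSpec | None = None) -> DLMFit:
    """Fit with a knot at every lag; refit with <= ``edf_cap`` equally
    spaced knots if the selected edf exceeds the cap.

    The returned fit carries ``refit=True`` when the fallback basis was used.
    """
    spec = spec or ModelSpec()
    first = fit_penalized_dlm(x, outcome, covariates,
                              spec=_replace(spec, basis_kind="every-lag"))
    if first.edf <= spec.edf_cap:
        return first
    logger.info("edf %.2f exceeds cap %.1f; refitting with %d equally spaced knots",
                first.edf, spec.edf_cap, int(spec.edf_cap))
    second = fit_penalized_dlm(
        x, outcome, covariates,
        spec=_replace(spec, basis_kind="equally-spaced",
                      max_knots=int(spec.edf_cap)))
    second.refit = True
    return second


def _replace(spec: ModelSpec, **kw) -> ModelSpec:
    from dataclasses import replace
    return replace(spec, **kw)
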