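"""Additive-model fitting by penalized least squares.

The model is ``y = X beta + eps`` where the design matrix concatenates an
intercept, optional section constants and one block per smooth term.  The
fitting objective is

    || W^(1/2) (y - X beta) ||^2  +  sum_j  lambda_j  beta' S_j beta,

with one smoothing parameter per penalty matrix.  Smoothing parameters are
chosen by restricted maximum likelihood (REML) unless fixed by the caller.
Residual autocorrelation in waveform data is handled by an AR(1) whitening
transform, and heavy-tailed artifact noise by a median (quantile) loss.

Confidence intervals are pointwise Bayesian credible intervals from the
posterior covariance of the coefficients given the smoothing parameters,
the standard large-sample calibration for penalized regression smooths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh

from .basis import SmoothBasis
from .exceptions import (
    HemogamWarning,
    IdentifiabilityError,
    MissingCovariateError,
    TooFewObservationsError,
)

__all__ = [
    "GAMDesign",
    "GAMFit",
    "fit_penalized",
    "select_lambda_reml",
    "fit_ar1",
    "fit_quantile",
    "predict_terms",
    "posterior_draws",
    "pinball_loss",
]

_RANK_TOL = 1e-9


@dataclass
class Term:
    label: str
    kind: str  # "intercept" | "section" | "smooth"
    basis: SmoothBasis | None = None
    covariates: tuple = ()
    lam: object = "auto"  # "auto", a float, or a list (one per penalty)
    by: str | None = None  # column name whose given level gates the term
    by_level: object = None
    # filled by GAMDesign.build
    section_column: str | None = None
    reference: object = None
    levels: tuple = ()


class GAMDesign:
    """Ordered list of model terms (intercept, section constants, smooths)."""

    def __init__(self):
        self.terms: list[Term] = []

    def add_intercept(self) -> "GAMDesign":
        if any(t.kind == "intercept" for t in self.terms):
            raise ValueError("design already has an intercept")
        self.terms.append(Term(label="intercept", kind="intercept"))
        return self

    def add_section_constants(self, column: str, reference) -> "GAMDesign":
        """Per-section constant shifts; zero for the reference section."""
        self.terms.append(
            Term(
                label=f"section({column})",
                kind="section",
                section_column=column,
                reference=reference,
            )
        )
        return self

    def add_smooth(
        self,
        label: str,
        basis: SmoothBasis,
        covariates,
        lam="auto",
        by: str | None = None,
        by_level=None,
    ) -> "GAMDesign":
        cov = (covariates,) if isinstance(covariates, str) else tuple(covariates)
        self.terms.append(
            Term(label=label, kind="smooth", basis=basis, covariates=cov,
                 lam=lam, by=by, by_level=by_level)
        )
        return self

    # -- matrix assembly ----------------------------------------------------

    def _term_block(self, term: Term, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        if term.kind == "intercept":
            return np.ones((n, 1))
        if term.kind == "section":
            col = term.section_column
            if col not in data:
                raise MissingCovariateError(f"missing section column {col!r}")
            vals = data[col].to_numpy()
            if not term.levels:
                lev = [v for v in pd.unique(vals) if v != term.reference]
                term.levels = tuple(lev)
            return np.column_stack(
                [(vals == lv).astype(float) for lv in term.levels]
            ) if term.levels else np.zeros((n, 0))
        for c in term.covariates:
            if c not in data:
                raise MissingCovariateError(
                    f"term {term.label!r} needs covariate {c!r}"
                )
        x = data[list(term.covariates)].to_numpy(dtype=float)
        X = term.basis.design(x if x.shape[1] > 1 else x[:, 0])
        if term.by is not None:
            if term.by not in data:
                raise MissingCovariateError(f"missing 'by' column {term.by!r}")
            mask = (data[term.by].to_numpy() == term.by_level).astype(float)
            X = X * mask[:, None]
        return X

    def build(self, data: pd.DataFrame):
        """Return (X, penalty list, term slices).

        Penalties are (slice, S, policy, term_label) tuples, one per
        smoothing parameter, in design order.
        """
        blocks, slices, pens = [], {}, []
        start = 0
        for term in self.terms:
            B = self._term_block(term, data)
            stop = start + B.shape[1]
            sl = slice(start, stop)
            slices[term.label] = sl
            blocks.append(B)
            if term.kind == "smooth":
                lams = term.lam
                if not isinstance(lams, (list, tuple)):
                    lams = [lams] * len(term.basis.penalties)
                if len(lams) != len(term.basis.penalties):
                    raise ValueError(
                        f"term {term.label!r}: {len(term.basis.penalties)} "
                        f"penalties but {len(lams)} smoothing policies"
                    )
                for S, pol in zip(term.basis.penalties, lams):
                    pens.append((sl, S, pol, term.label))
            start = stop
        X = np.hstack(blocks)
        return X, pens, slices


@dataclass
class GAMFit:
    """A fitted additive model."""

    design: GAMDesign
    coefficients: np.ndarray
    posterior_covariance: np.ndarray
    lambdas: np.ndarray
    rho: float
    fitted_values: np.ndarray
    residuals: np.ndarray
    edf: dict
    sigma2: float
    loss_kind: str
    term_slices: dict
    penalty_labels: list
    n_obs: int
    reml_converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def edf_total(self) -> float:
        return float(sum(self.edf.values()))

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


# ---------------------------------------------------------------------------
# Core penalized solve + REML
# ---------------------------------------------------------------------------


def _penalty_groups(pens):
    """Group penalties sharing a coefficient block; precompute ranks."""
    groups = {}
    for j, (sl, S, _pol, label) in enumerate(pens):
        groups.setdefault((sl.start, sl.stop), []).append((j, S))
    out = []
    for (a, b), items in groups.items():
        Ssum = sum(S for _, S in items)
        ev = np.linalg.eigvalsh(Ssum)
        rank = int(np.sum(ev > _RANK_TOL * max(ev.max(), 1.0)))
        out.append({"slice": slice(a, b), "items": items, "rank": rank})
    return out


def _logdet_splus(groups, lam):
    """log generalized determinant of the total penalty at weights lam."""
    total = 0.0
    for g in groups:
        Sl = sum(lam[j] * S for j, S in g["items"])
        ev = np.linalg.eigvalsh(Sl)
        ev = np.sort(ev)[::-1][: g["rank"]]
        ev = np.maximum(ev, 1e-300)
        total += float(np.sum(np.log(ev)))
    return total


def _build_A(XtX, pens, lam):
    A = XtX.copy()
    for lam_j, (sl, S, _pol, _lab) in zip(lam, pens):
        A[sl, sl] += lam_j * S
    return A


def _reml_score(lam, XtX, Xty, yty, pens, groups, n, Mp):
    A = _build_A(XtX, pens, lam)
    try:
        c, low = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    beta = cho_solve((c, low), Xty)
    rss = max(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta), 1e-12)
    pen = 0.0
    for lam_j, (sl, S, _pol, _lab) in zip(lam, pens):
        b = beta[sl]
        pen += lam_j * (b @ S @ b)
    rss_p = rss + max(pen, 0.0)
    sigma2 = rss_p / (n - Mp)
    logdetA = 2.0 * float(np.sum(np.log(np.diag(c))))
    score = (
        0.5 * (n - Mp) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + 0.5 * logdetA
        - 0.5 * _logdet_splus(groups, lam)
    )
    return score


def _optimize_reml(XtX, Xty, yty, pens, n):
    """Maximize the restricted likelihood over the free log-lambdas."""
    groups = _penalty_groups(pens)
    p = XtX.shape[0]
    Mp = p - sum(g["rank"] for g in groups)
    free = [j for j, (_sl, _S, pol, _lab) in enumerate(pens) if pol == "auto"]
    lam = np.array(
        [1.0 if pol == "auto" else float(pol) for (_sl, _S, pol, _lab) in pens]
    )
    converged = True
    if free:
        # scale-matched starting point per penalty
        x0 = []
        for j in free:
            sl, S = pens[j][0], pens[j][1]
            trX = np.trace(XtX[sl, sl])
            trS = np.trace(S)
            x0.append(np.log(max(trX, 1e-8) / max(trS, 1e-8)))
        x0 = np.asarray(x0)

        def score_of(logl):
            lam_full = lam.copy()
            lam_full[free] = np.exp(np.clip(logl, -25.0, 25.0))
            return _reml_score(lam_full, XtX, Xty, yty, pens, groups, n, Mp)

        if len(free) <= 4:
            res = optimize.minimize(
                score_of, x0, method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-7,
                         "maxfev": 400 * max(len(free), 1)},
            )
            best = res.x
            converged = bool(res.success)
        else:
            # coordinate sweeps with 1-D bounded searches; robust in high dim
            best = x0.copy()
            prev = score_of(best)
            for _sweep in range(4):
                for i in range(len(free)):
                    def f1(v, i=i):
                        trial = best.copy()
                        trial[i] = v
                        return score_of(trial)

                    r = optimize.minimize_scalar(
                        f1, bounds=(best[i] - 10.0, best[i] + 10.0),
                        method="bounded", options={"xatol": 0.05},
                    )
                    if r.fun < prev:
                        best[i] = r.x
                        prev = r.fun
        if not converged:
            warnings.warn(
                "REML optimization did not fully converge; using best "
                "smoothing parameters found",
                HemogamWarning,
                stacklevel=2,
            )
        lam[free] = np.exp(np.clip(best, -25.0, 25.0))
    return lam, converged


def _check_identifiability(X, pens, slices, design):
    """Verify the unpenalized span has full rank; name confounded terms."""
    cols, owners = [], []
    pen_by_slice = {}
    for sl, S, _pol, _lab in pens:
        key = (sl.start, sl.stop)
        pen_by_slice[key] = pen_by_slice.get(key, 0) + S
    for term in design.terms:
        sl = slices[term.label]
        if sl.stop == sl.start:
            continue
        if term.kind != "smooth":
            cols.append(X[:, sl])
            owners.extend([term.label] * (sl.stop - sl.start))
        else:
            Ssum = pen_by_slice[(sl.start, sl.stop)]
            ev, V = eigh(Ssum)
            null = V[:, ev < _RANK_TOL * max(ev.max(), 1.0)]
            if null.shape[1]:
                cols.append(X[:, sl] @ null)
                owners.extend([term.label] * null.shape[1])
    if not cols:
        return
    N = np.hstack(cols)
    s = np.linalg.svd(N, compute_uv=False)
    if s[-1] < _RANK_TOL * max(s[0], 1.0) * max(N.shape):
        # identify terms whose removal restores full rank
        bad = []
        for label in dict.fromkeys(owners):
            keep = [i for i, o in enumerate(owners) if o != label]
            sub = N[:, keep]
            ss = np.linalg.svd(sub, compute_uv=False)
            if len(ss) == 0 or ss[-1] > _RANK_TOL * max(ss[0], 1.0) * max(sub.shape):
                bad.append(label)
        raise IdentifiabilityError(
            "confounded unpenalized model terms: " + ", ".join(bad or owners)
        )


def _finalize(design, X, y, pens, slices, lam, converged, w=None,
              rho=0.0, loss_kind="gaussian", X_orig=None, y_orig=None):
    """Solve at fixed lambdas and package a GAMFit.

    X, y are the (possibly whitened / weighted) working data; X_orig/y_orig
    the original scale used for fitted values and residuals.
    """
    n, p = X.shape
    XtX = X.T @ X
    A = _build_A(XtX, pens, lam)
    c, low = cho_factor(A, lower=True)
    beta = cho_solve((c, low), X.T @ y)
    Ainv = cho_solve((c, low), np.eye(p))
    F = Ainv @ XtX
    edf = {}
    dF = np.diag(F)
    for label, sl in slices.items():
        if sl.stop > sl.start:
            edf[label] = float(np.sum(dF[sl]))
    edf_total = float(np.trace(F))
    rss_w = float(np.sum((y - X @ beta) ** 2))
    dof = max(n - edf_total, 1.0)
    sigma2 = rss_w / dof
    V = Ainv * sigma2
    V = (V + V.T) / 2.0
    Xo = X if X_orig is None else X_orig
    yo = y if y_orig is None else y_orig
    fitted = Xo @ beta
    return GAMFit(
        design=design,
        coefficients=beta,
        posterior_covariance=V,
        lambdas=np.asarray(lam, dtype=float),
        rho=float(rho),
        fitted_values=fitted,
        residuals=yo - fitted,
        edf=edf,
        sigma2=float(sigma2),
        loss_kind=loss_kind,
        term_slices=slices,
        penalty_labels=[lab for (_sl, _S, _pol, lab) in pens],
        n_obs=n,
        reml_converged=converged,
    )


def _prepare(design, data, y):
    y = np.asarray(y, dtype=float)
    X, pens, slices = design.build(data)
    n, p = X.shape
    if n != len(y):
        raise ValueError("covariate table and response length differ")
    groups = _penalty_groups(pens) if pens else []
    null_dim = p - sum(g["rank"] for g in groups)
    if n <= null_dim:
        raise TooFewObservationsError(
            f"{n} observations cannot identify {null_dim} unpenalized directions"
        )
    if n < p:
        warnings.warn(
            f"fewer observations ({n}) than coefficients ({p}); penalties "
            "regularize but the fit is weakly determined",
            HemogamWarning,
            stacklevel=3,
        )
    _check_identifiability(X, pens, slices, design)
    return X, pens, slices, y


def fit_penalized(design: GAMDesign, data: pd.DataFrame, y, lambdas="auto",
                  weights=None) -> GAMFit:
    """Fit by penalized least squares.

    ``lambdas='auto'`` honours each term's per-penalty policy (REML for
    'auto' entries); an explicit array fixes every smoothing parameter in
    design order.
    """
    X, pens, slices, y = _prepare(design, data, y)
    Xw, yw = X, y
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * sw[:, None], y * sw
    if isinstance(lambdas, str) and lambdas == "auto":
        lam, conv = _optimize_reml(Xw.T @ Xw, Xw.T @ yw, yw @ yw, pens, len(yw))
    else:
        lam = np.asarray(lambdas, dtype=float)
        if len(lam) != len(pens):
            raise ValueError(f"need {len(pens)} lambdas, got {len(lam)}")
        conv = True
    return _finalize(design, Xw, yw, pens, slices, lam, conv,
                     X_orig=X, y_orig=y)


def select_lambda_reml(design: GAMDesign, data: pd.DataFrame, y) -> np.ndarray:
    """Return the REML-selected smoothing parameters (one per penalty)."""
    X, pens, slices, y = _prepare(design, data, y)
    lam, _conv = _optimize_reml(X.T @ X, X.T @ y, y @ y, pens, len(y))
    return lam


# ---------------------------------------------------------------------------
# AR(1) residuals
# ---------------------------------------------------------------------------


def _whiten(M, rho, starts):
    """AR(1) whitening of rows ordered in time; recursion restarts at
    each index in ``starts`` (section boundaries)."""
    out = M - rho * np.roll(M, 1, axis=0)
    scale = np.sqrt(1.0 - rho * rho)
    out[starts] = M[starts] * scale
    return out


def _section_starts(data, section_col, n):
    if section_col is None or section_col not in getattr(data, "columns", ()):
        return np.array([0])
    vals = data[section_col].to_numpy()
    starts = np.r_[0, np.nonzero(vals[1:] != vals[:-1])[0] + 1]
    return starts


def fit_ar1(design: GAMDesign, data: pd.DataFrame, y, rho="auto",
            section_column: str | None = None) -> GAMFit:
    """Fit with an AR(1) model for the residuals.

    Observations must be ordered by time (approximately uniform spacing
    within each section).  ``rho='auto'`` uses a two-pass scheme: fit with
    rho=0, estimate rho from the lag-1 autocorrelation of the residuals
    (within sections), whiten and refit.  The whitening transform scales
    the first row of each section by sqrt(1-rho^2) and replaces subsequent
    rows r_t by r_t - rho*r_{t-1}; the posterior covariance comes from the
    whitened problem, which is what widens the confidence intervals that
    an independence fit would understate.
    """
    X, pens, slices, y = _prepare(design, data, y)
    starts = _section_starts(data, section_column, len(y))
    if rho == "auto":
        lam0, _ = _optimize_reml(X.T @ X, X.T @ y, y @ y, pens, len(y))
        A = _build_A(X.T @ X, pens, lam0)
        beta0 = np.linalg.solve(A, X.T @ y)
        r = y - X @ beta0
        valid = np.ones(len(r), dtype=bool)
        valid[starts] = False  # don't pair across section boundaries
        num = float(np.sum(r[valid] * np.roll(r, 1)[valid]))
        den = float(r @ r)
        rho_hat = num / den if den > 0 else 0.0
        rho_hat = float(np.clip(rho_hat, 0.0, 0.99))
    else:
        rho_hat = float(rho)
        if not (0.0 <= rho_hat < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {rho_hat}")
    Xw = _whiten(X, rho_hat, starts)
    yw = _whiten(y[:, None], rho_hat, starts)[:, 0]
    lam, conv = _optimize_reml(Xw.T @ Xw, Xw.T @ yw, yw @ yw, pens, len(yw))
    return _finalize(design, Xw, yw, pens, slices, lam, conv, rho=rho_hat,
                     X_orig=X, y_orig=y)


# ---------------------------------------------------------------------------
# Quantile (median) loss
# ---------------------------------------------------------------------------


def pinball_loss(u, tau: float = 0.5):
    """Quantile check loss: u * (tau - 1[u < 0]); |u|/2 at the median."""
    u = np.asarray(u, dtype=float)
    return u * (tau - (u < 0.0))


def fit_quantile(design: GAMDesign, data: pd.DataFrame, y, tau: float = 0.5,
                 max_iter: int = 100, tol: float = 1e-8) -> GAMFit:
    """Fit the tau-quantile (default: median) of the signal.

    Minimizes the penalized pinball loss by iteratively reweighted least
    squares on a smoothed check function, with the smoothing bandwidth tied
    to a robust (MAD) residual scale; makes no distributional assumption on
    the residuals, so transient large artifacts have bounded influence on
    the fit.  Smoothing parameters are re-selected by REML on the working
    weighted problem as the weights stabilize (and so are, in effect,
    chosen on the final weighted problem).
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    X, pens, slices, y = _prepare(design, data, y)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ beta
    mad = np.median(np.abs(r - np.median(r))) * 1.4826
    h = max(0.05 * mad, 1e-6 * (np.std(y) + 1e-12), 1e-12)
    lam = None
    w = np.ones(len(y))
    converged = False
    for it in range(max_iter):
        r = y - X @ beta
        w = np.where(r >= 0, tau, 1.0 - tau) / np.maximum(np.abs(r), h)
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = y * sw
        if it % 10 == 0 or lam is None:
            lam, _ = _optimize_reml(Xw.T @ Xw, Xw.T @ yw, yw @ yw, pens,
                                    len(yw))
        A = _build_A(Xw.T @ Xw, pens, lam)
        new = np.linalg.solve(A, Xw.T @ yw)
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    if not converged:
        warnings.warn(
            "quantile IRLS did not converge; returning last iterate",
            HemogamWarning,
            stacklevel=2,
        )
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    lam_f, conv = _optimize_reml(Xw.T @ Xw, Xw.T @ yw, yw @ yw, pens, len(yw))
    fit = _finalize(design, Xw, yw, pens, slices, lam_f, conv and converged,
                    loss_kind=f"quantile({tau})", X_orig=X, y_orig=y)
    return fit


# ---------------------------------------------------------------------------
# Prediction and posterior simulation
# ---------------------------------------------------------------------------


def predict_terms(fit: GAMFit, newdata: pd.DataFrame):
    """Per-term contributions, overall prediction and 95% intervals.

    Returns a dict with key 'prediction' (DataFrame: fit, se, lo, hi) and
    one key per term (same columns).  The per-term interval uses the
    posterior covariance block of that term's coefficients; the overall
    interval uses the full covariance.
    """
    design = fit.design
    beta = fit.coefficients
    V = fit.posterior_covariance
    out = {}
    blocks = []
    for term in design.terms:
        sl = fit.term_slices[term.label]
        B = design._term_block(term, newdata)
        blocks.append(B)
        contrib = B @ beta[sl]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V[sl, sl], B), 0.0))
        out[term.label] = pd.DataFrame(
            {"fit": contrib, "se": se,
             "lo": contrib - 1.96 * se, "hi": contrib + 1.96 * se}
        )
    Xn = np.hstack(blocks)
    pred = Xn @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xn, V, Xn), 0.0))
    out["prediction"] = pd.DataFrame(
        {"fit": pred, "se": se, "lo": pred - 1.96 * se, "hi": pred + 1.96 * se}
    )
    return out


def posterior_draws(fit: GAMFit, n_draws: int, seed) -> np.ndarray:
    """Draws from the Gaussian posterior of the coefficients.

    Uses an eigendecomposition of the posterior covariance; negative
    eigenvalues from roundoff are clipped to zero (with a warning when the
    clipping is more than roundoff-sized).
    """
    rng = np.random.default_rng(seed)
    V = fit.posterior_covariance
    ev, U = eigh((V + V.T) / 2.0)
    if ev.min() < -1e-8 * max(ev.max(), 1.0):
        warnings.warn(
            "posterior covariance had negative eigenvalues; clipped to zero",
            HemogamWarning,
            stacklevel=2,
        )
    ev = np.clip(ev, 0.0, None)
    Z = rng.standard_normal((n_draws, len(ev)))
    return fit.coefficients + (Z * np.sqrt(ev)) @ U.T
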