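"""The hemodynamic decomposition models and the PPV statistic.

Three model families, all additive with an intercept and centered smooths:

* Pulse pressure:  PP = alpha + f(resp_position) + f(time) + eps, with a
  cyclic cubic smooth over the respiratory cycle and a natural cubic trend.
  Because the smooths are centered, alpha is the mean PP, and the pulse
  pressure variation follows from the respiratory smooth f:

      PPV = 100 * (max f - min f) / alpha   (percent),

  which coincides with the classic (PPmax - PPmin) / mean(PP) definition
  when beats sample the cycle densely.  The PPV confidence interval is
  computed by posterior simulation of the model coefficients.

* CVP:  CVP = alpha + f(cardiac_position) + f(resp_position) [+ f(cardiac,
  resp)] + f(time) + eps, per-sample on the 125 Hz waveform, fitted with an
  AR(1) residual model.  The cardiac smooth is non-cyclic over seconds
  since the latest P wave (cardiac cycles vary in length, so a fractional
  cyclic coordinate would wrongly assume the waveform stretches with cycle
  length); the respiratory smooth is cyclic; the optional tensor term
  captures how the cardiac pattern changes with respiratory phase (e.g.
  the depth of the x' descent).

* Section comparison:  a joint fit of two labelled recording sections
  (e.g. before/after a fluid bolus) with a section constant beta_s (zero
  for the reference section) and separate per-section smooths; the
  respiratory smooth uses an adaptive penalty so it can track the sharp
  inspiration-expiration transition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import basis as bs
from .exceptions import (
    HemogamWarning,
    TooFewObservationsError,
    WrongModelError,
)
from .gam import (
    GAMDesign,
    GAMFit,
    fit_ar1,
    fit_penalized,
    fit_quantile,
    posterior_draws,
    predict_terms,
)

__all__ = [
    "PPVResult",
    "SectionComparison",
    "fit_pp_model",
    "compute_ppv",
    "fit_cvp_additive",
    "fit_cvp_interaction",
    "compare_sections",
    "summary_dict",
    "term_grid_frame",
]


# Default basis dimensions.  The cardiac smooth needs enough resolution for
# five landmarks per cycle; the respiratory and trend effects are smooth.
K_PP_RESP = 10
K_PP_TIME = 10
K_CVP_CARDIAC = 30
K_CVP_RESP = 14
K_TENSOR = (10, 8)
K_TIME = 10
K_ADAPTIVE_RESP = 20
N_ADAPTIVE_SUB = 5


def _cyclic_unit_basis(values, k):
    """Centered cyclic basis on the unit interval (period [0, 1])."""
    knots = bs.KnotVector(np.linspace(0.0, 1.0, k), "uniform")
    return bs.apply_centering(bs.cyclic_cubic_basis(knots), values)


def _natural_basis(values, k, centered=True):
    knots = bs.make_knots(values, k, rule="quantile")
    b = bs.cubic_basis(knots, natural=True)
    return bs.apply_centering(b, values) if centered else b


# ---------------------------------------------------------------------------
# Pulse pressure model and PPV
# ---------------------------------------------------------------------------


def fit_pp_model(beats: pd.DataFrame, k_resp: int = K_PP_RESP,
                 k_time: int = K_PP_TIME, loss: str = "gaussian") -> GAMFit:
    """Fit PP = alpha + f(resp_position) + f(time) + eps.

    ``beats`` needs columns pulse_pressure, resp_position, time_s.  The
    respiratory smooth is a centered cyclic cubic spline on [0, 1); the
    trend a centered natural cubic spline of time.  Smoothing parameters
    by REML; ``loss='median'`` switches to the robust quantile fit.
    """
    if len(beats) < 8:
        raise TooFewObservationsError(
            f"need at least 8 beats, got {len(beats)}")
    pos = beats["resp_position"].to_numpy(dtype=float)
    t = beats["time_s"].to_numpy(dtype=float)
    design = (
        GAMDesign()
        .add_intercept()
        .add_smooth("respiration", _cyclic_unit_basis(pos, k_resp),
                    "resp_position")
        .add_smooth("trend", _natural_basis(t, k_time), "time_s")
    )
    y = beats["pulse_pressure"].to_numpy(dtype=float)
    if loss == "median":
        fit = fit_quantile(design, beats, y, tau=0.5)
    else:
        fit = fit_penalized(design, beats, y)
    fit.meta["model"] = "pp"
    fit.meta["n_beats"] = int(len(beats))
    return fit


@dataclass
class PPVResult:
    """Pulse pressure variation with its 95% credible interval (percent)."""

    ppv: float
    ci_low: float
    ci_high: float
    alpha: float  # mean PP, mmHg
    smooth_range: float  # max - min of the respiratory smooth, mmHg
    n_beats: int
    n_draws: int
    seed: int

    def to_dict(self):
        return asdict(self)


def compute_ppv(fit: GAMFit, n_draws: int = 50_000, seed: int = 0,
                grid_size: int = 512) -> PPVResult:
    """PPV and CI from a fitted pulse-pressure model.

    The respiratory smooth is evaluated on a dense grid over one cycle;
    PPV = 100 * (max - min) / alpha.  The interval is the 2.5/97.5
    percentile of the same statistic recomputed over joint posterior draws
    of (alpha, respiratory-smooth coefficients).
    """
    if fit.meta.get("model") != "pp":
        raise WrongModelError("compute_ppv requires a fit from fit_pp_model")
    sl_a = fit.term_slices["intercept"]
    sl_r = fit.term_slices["respiration"]
    term = next(t for t in fit.design.terms if t.label == "respiration")
    grid = np.linspace(0.0, 1.0, grid_size, endpoint=False)
    G = term.basis.design(grid)
    beta = fit.coefficients
    alpha = float(beta[sl_a][0])
    f = G @ beta[sl_r]
    rng_f = float(f.max() - f.min())
    ppv = 100.0 * rng_f / alpha
    draws = posterior_draws(fit, n_draws, seed)
    ppv_draws = np.empty(n_draws)
    chunk = 8192
    for i in range(0, n_draws, chunk):
        d = draws[i:i + chunk]
        fa = d[:, sl_a][:, 0]
        fd = d[:, sl_r] @ G.T
        ppv_draws[i:i + chunk] = 100.0 * (fd.max(axis=1) - fd.min(axis=1)) / fa
    lo, hi = np.percentile(ppv_draws, [2.5, 97.5])
    return PPVResult(
        ppv=ppv, ci_low=float(min(lo, ppv)), ci_high=float(max(hi, ppv)),
        alpha=alpha, smooth_range=rng_f,
        n_beats=fit.meta.get("n_beats", fit.n_obs),
        n_draws=n_draws, seed=seed,
    )


# ---------------------------------------------------------------------------
# CVP models
# ---------------------------------------------------------------------------


def _check_cvp(samples: pd.DataFrame):
    if len(samples) < 8:
        raise TooFewObservationsError("too few CVP samples")
    for col in ("cvp", "cardiac_position", "resp_position", "time_s"):
        if col not in samples.columns:
            raise ValueError(f"CVP sample table lacks column {col!r}")


def _cvp_design(samples: pd.DataFrame, k_cardiac: int, k_resp: int,
                k_time: int, tensor: tuple | None,
                adaptive: int = 1) -> GAMDesign:
    card = samples["cardiac_position"].to_numpy(dtype=float)
    pos = samples["resp_position"].to_numpy(dtype=float)
    t = samples["time_s"].to_numpy(dtype=float)
    resp_raw = bs.cyclic_cubic_basis(
        bs.KnotVector(np.linspace(0.0, 1.0, k_resp), "uniform"))
    if adaptive > 1:
        resp_raw = bs.adaptive_penalty(resp_raw, adaptive)
    design = (
        GAMDesign()
        .add_intercept()
        .add_smooth("cardiac", _natural_basis(card, k_cardiac),
                    "cardiac_position")
        .add_smooth("respiration", bs.apply_centering(resp_raw, pos),
                    "resp_position")
    )
    if tensor is not None:
        kx, ky = tensor
        mx = _natural_basis(card, kx)
        my = _cyclic_unit_basis(pos, ky)
        tb = bs.apply_centering(
            bs.tensor_smooth(mx, my),
            samples[["cardiac_position", "resp_position"]].to_numpy(),
        )
        design.add_smooth("interaction", tb,
                          ("cardiac_position", "resp_position"))
    design.add_smooth("trend", _natural_basis(t, k_time), "time_s")
    return design


def fit_cvp_additive(samples: pd.DataFrame, k_cardiac: int = K_CVP_CARDIAC,
                     k_resp: int = K_CVP_RESP, k_time: int = K_TIME,
                     ar1="auto", loss: str = "gaussian") -> GAMFit:
    """CVP = alpha + f(cardiac) + f(respiration) + f(time) + eps, AR(1)
    residuals.  Assumes every heartbeat produces the same CVP pattern,
    merely raised and lowered by ventilation."""
    _check_cvp(samples)
    design = _cvp_design(samples, k_cardiac, k_resp, k_time, tensor=None)
    y = samples["cvp"].to_numpy(dtype=float)
    fit = _fit_cvp(design, samples, y, ar1, loss)
    fit.meta["model"] = "cvp_additive"
    return fit


def fit_cvp_interaction(samples: pd.DataFrame,
                        k_cardiac: int = K_CVP_CARDIAC,
                        k_resp: int = K_CVP_RESP,
                        k_tensor: tuple = K_TENSOR, k_time: int = K_TIME,
                        ar1="auto", loss: str = "gaussian") -> GAMFit:
    """CVP model with the cardiac-by-respiratory tensor interaction.

    The tensor smooth is the product of a (centered) non-cyclic cardiac
    margin and a cyclic respiratory margin, with one smoothing parameter
    per direction; centering the margins excludes the marginal main
    effects, so the term holds only genuine interaction structure.
    """
    _check_cvp(samples)
    design = _cvp_design(samples, k_cardiac, k_resp, k_time, tensor=k_tensor)
    y = samples["cvp"].to_numpy(dtype=float)
    fit = _fit_cvp(design, samples, y, ar1, loss)
    fit.meta["model"] = "cvp_interaction"
    return fit


def _fit_cvp(design, samples, y, ar1, loss):
    if loss == "median":
        if ar1 not in (None, "off", 0, 0.0):
            warnings.warn(
                "median loss currently ignores the AR(1) residual model",
                HemogamWarning, stacklevel=3,
            )
        return fit_quantile(design, samples, y, tau=0.5)
    if ar1 in (None, "off"):
        return fit_penalized(design, samples, y)
    return fit_ar1(design, samples, y, rho=ar1, section_column="section")


# ---------------------------------------------------------------------------
# Section comparison (fluid bolus)
# ---------------------------------------------------------------------------


@dataclass
class SectionComparison:
    """Joint two-section CVP fit with a section shift and per-section smooths."""

    fit: GAMFit
    beta_s: float  # constant shift of the non-reference section, mmHg
    beta_s_se: float
    reference: str
    other: str
    smooth_ranges: dict  # {section: {"cardiac": mmHg, "respiration": mmHg}}
    cycle_curves: pd.DataFrame  # predicted cardiac-cycle curves per
    # section at end-inspiration / end-expiration


def compare_sections(pre: pd.DataFrame, post: pd.DataFrame,
                     k_cardiac: int = K_CVP_CARDIAC,
                     k_resp: int = K_ADAPTIVE_RESP,
                     n_adaptive: int = N_ADAPTIVE_SUB,
                     k_tensor: tuple = K_TENSOR, k_time: int = K_TIME,
                     ar1="auto", end_insp: float = 0.3,
                     end_exp: float = 0.95) -> SectionComparison:
    """Fit CVP = alpha + beta_s + f_s(cardiac) + f_s(resp) +
    f_s(cardiac, resp) + f_s(time) + eps over two labelled sections.

    ``pre`` is the reference section (beta = 0).  Separate smooths are
    fitted per section; the respiratory smooth carries an adaptive penalty
    (``n_adaptive`` sub-penalties).  A single AR(1) rho is shared across
    sections, with the whitening recursion restarting at the boundary.
    Also returns predicted cardiac-cycle curves per section at
    end-inspiration and end-expiration respiratory positions.
    """
    for df in (pre, post):
        _check_cvp(df)
    ref = str(pre["section"].iloc[0])
    oth = str(post["section"].iloc[0])
    if ref == oth:
        raise ValueError("sections must carry distinct labels")
    lo1, hi1 = pre["time_s"].min(), pre["time_s"].max()
    lo2, hi2 = post["time_s"].min(), post["time_s"].max()
    if max(lo1, lo2) <= min(hi1, hi2):
        raise ValueError("section time ranges overlap")
    data = pd.concat([pre, post], ignore_index=True).sort_values(
        "time_s", ignore_index=True)

    design = GAMDesign().add_intercept().add_section_constants(
        "section", reference=ref)
    for lab in (ref, oth):
        sel = data["section"] == lab
        card = data.loc[sel, "cardiac_position"].to_numpy(dtype=float)
        pos = data.loc[sel, "resp_position"].to_numpy(dtype=float)
        t = data.loc[sel, "time_s"].to_numpy(dtype=float)
        resp_raw = bs.adaptive_penalty(
            bs.cyclic_cubic_basis(
                bs.KnotVector(np.linspace(0.0, 1.0, k_resp), "uniform")),
            n_adaptive,
        )
        mx = _natural_basis(card, k_tensor[0])
        my = _cyclic_unit_basis(pos, k_tensor[1])
        tb = bs.apply_centering(
            bs.tensor_smooth(mx, my), np.column_stack([card, pos]))
        design.add_smooth(f"cardiac[{lab}]", _natural_basis(card, k_cardiac),
                          "cardiac_position", by="section", by_level=lab)
        design.add_smooth(f"respiration[{lab}]",
                          bs.apply_centering(resp_raw, pos),
                          "resp_position", by="section", by_level=lab)
        design.add_smooth(f"interaction[{lab}]", tb,
                          ("cardiac_position", "resp_position"),
                          by="section", by_level=lab)
        design.add_smooth(f"trend[{lab}]", _natural_basis(t, k_time),
                          "time_s", by="section", by_level=lab)

    y = data["cvp"].to_numpy(dtype=float)
    if ar1 in (None, "off"):
        fit = fit_penalized(design, data, y)
    else:
        fit = fit_ar1(design, data, y, rho=ar1, section_column="section")
    fit.meta["model"] = "compare_sections"
    fit.meta["sections"] = (ref, oth)

    sl_b = fit.term_slices[f"section(section)"]
    beta_s = float(fit.coefficients[sl_b][0])
    beta_se = float(np.sqrt(fit.posterior_covariance[sl_b, sl_b][0, 0]))

    # per-section smooth ranges and predicted cardiac-cycle curves
    grid = np.linspace(0.0, 1.0, 256, endpoint=False)
    ranges = {}
    curves = []
    for lab in (ref, oth):
        sel = data["section"] == lab
        card_max = float(data.loc[sel, "cardiac_position"].quantile(0.99))
        t_mid = float(data.loc[sel, "time_s"].median())
        cgrid = np.linspace(0.0, card_max, 200)
        r = {}
        for stem, xs, col in (("cardiac", cgrid, "cardiac_position"),
                              ("respiration", grid, "resp_position")):
            term = next(t_ for t_ in design.terms
                        if t_.label == f"{stem}[{lab}]")
            sl = fit.term_slices[term.label]
            # evaluate without the section gate (the smooth itself)
            f = term.basis.design(xs) @ fit.coefficients[sl]
            r[stem] = float(f.max() - f.min())
        ranges[lab] = r
        for tag, posv in (("end_inspiration", end_insp),
                          ("end_expiration", end_exp)):
            nd = pd.DataFrame(
                {"cardiac_position": cgrid,
                 "resp_position": np.full_like(cgrid, posv),
                 "time_s": np.full_like(cgrid, t_mid),
                 "section": lab}
            )
            pt = predict_terms(fit, nd)
            pred = pt["prediction"]
            curves.append(pd.DataFrame(
                {"section": lab, "phase": tag, "cardiac_position": cgrid,
                 "cvp": pred["fit"].to_numpy(),
                 "se": pred["se"].to_numpy()}))
    cycle_curves = pd.concat(curves, ignore_index=True)
    return SectionComparison(
        fit=fit, beta_s=beta_s, beta_s_se=beta_se, reference=ref, other=oth,
        smooth_ranges=ranges, cycle_curves=cycle_curves,
    )


# ---------------------------------------------------------------------------
# Tidy exports
# ---------------------------------------------------------------------------


def _lambda_map(labels, values) -> dict:
    counts = {}
    out = {}
    for lab, v in zip(labels, values):
        k = counts.get(lab, 0)
        counts[lab] = k + 1
        out[lab if counts[lab] == 1 and labels.count(lab) == 1
            else f"{lab}[{k}]"] = float(v)
    return out


def summary_dict(fit: GAMFit, ppv: PPVResult | None = None) -> dict:
    """JSON-ready summary: alpha, lambdas, rho, edf per term, sigma, PPV."""
    sl_a = fit.term_slices.get("intercept")
    out = {
        "model": fit.meta.get("model", "gam"),
        "alpha": float(fit.coefficients[sl_a][0]) if sl_a else None,
        # one entry per smoothing parameter; multi-penalty terms (tensor,
        # adaptive) get an index suffix
        "lambdas": _lambda_map(fit.penalty_labels, fit.lambdas),
        "lambda_values": [float(v) for v in fit.lambdas],
        "rho": fit.rho,
        "edf": {k: float(v) for k, v in fit.edf.items()},
        "sigma2": fit.sigma2,
        "loss": fit.loss_kind,
        "n_obs": fit.n_obs,
        "residual_sd": float(np.std(fit.residuals)),
    }
    if "sections" in fit.meta:
        out["sections"] = list(fit.meta["sections"])
    if ppv is not None:
        out["ppv"] = ppv.to_dict()
    return out


def term_grid_frame(fit: GAMFit, newdata: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-term contributions on a covariate grid.

    One row per (term, grid point) with the contribution and its standard
    error — the tidy form used to plot each smooth separately or render the
    interaction surface as a contour plot.
    """
    preds = predict_terms(fit, newdata)
    rows = []
    for label, frame in preds.items():
        if label == "prediction":
            continue
        block = newdata.copy()
        block["term"] = label
        block["contribution"] = frame["fit"].to_numpy()
        block["se"] = frame["se"].to_numpy()
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def write_summary(path, summary: dict):
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
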