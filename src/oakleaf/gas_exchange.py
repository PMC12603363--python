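"""FvCB photosynthesis model, A-Ci curve fitting, and mesophyll conductance.

Implements the biochemical (Farquhar-von Caemmerer-Berry) model of C3
photosynthesis with net assimilation taken as the hard minimum of the
Rubisco-limited, RuBP-regeneration-limited and TPU-limited rates, plus the
two companion estimators used alongside gas exchange:

* the Laisk intersection method, recovering day respiration Rd and the
  intercellular CO2 photocompensation point Ci* from the common crossing
  point of low-Ci linear A-Ci responses, and
* the variable-J chlorophyll-fluorescence method, recovering mesophyll
  conductance gm from An, Ci and the fluorescence-derived electron
  transport rate Jflu.

All constants default to their 30 degC values used throughout; no
temperature response is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GAMMA_STAR_30C",
    "KM_30C",
    "ALPHA_DECIDUOUS",
    "ALPHA_EVERGREEN",
    "BETA_C3",
    "CA_SETPOINTS_BASE",
    "CA_SETPOINTS_EXTRA",
    "HABITS",
    "FvcbParams",
    "AciCurve",
    "FvcbFit",
    "LaiskResult",
    "FluorescenceConfig",
    "GasExchangeError",
    "FitError",
    "fvcb_rates",
    "fit_aci",
    "detect_tpu_limitation",
    "amax_and_normalize",
    "laisk_rd_cistar",
    "jflu",
    "variable_j_gm",
    "fluorescence_gm_profile",
    "extract_at_ca",
]

#: Chloroplast CO2 photocompensation point at 30 degC (umol mol-1).
GAMMA_STAR_30C = 54.9
#: Combined Michaelis-Menten constant for CO2 and O2 at 30 degC (umol mol-1).
KM_30C = 1093.6
#: Leaf absorbance defaults measured per leaf habit (dimensionless).
ALPHA_DECIDUOUS = 0.863
ALPHA_EVERGREEN = 0.844
#: Fraction of absorbed quanta reaching photosystem II for C3 plants.
BETA_C3 = 0.5

#: Chamber CO2 setpoints of the base measurement protocol (umol mol-1).
CA_SETPOINTS_BASE = (50.0, 100.0, 150.0, 250.0, 400.0, 600.0, 800.0, 1200.0, 1600.0)
#: Additional setpoints of the extended protocol.
CA_SETPOINTS_EXTRA = (200.0, 1000.0, 1400.0, 1800.0)

HABITS = ("deciduous", "evergreen")


class GasExchangeError(ValueError):
    """Invalid input to a gas-exchange computation."""


class FitError(RuntimeError):
    """A-Ci curve fit failed to converge or is degenerate."""


@dataclass(frozen=True)
class FvcbParams:
    """Biochemical parameter set for one leaf.

    ``rd`` is stored as a positive respiration magnitude. ``gm`` of ``None``
    means mesophyll conductance is treated as unbounded (Cc = Ci). ``tpu``
    of ``None`` means the TPU-limited rate is not part of the model.
    """

    vcmax: float
    jmax: float
    rd: float = 0.0
    tpu: float | None = None
    gamma_star: float = GAMMA_STAR_30C
    km: float = KM_30C
    gm: float | None = None

    def __post_init__(self) -> None:
        if not self.vcmax > 0:
            raise GasExchangeError(f"vcmax must be positive, got {self.vcmax}")
        if not self.jmax > 0:
            raise GasExchangeError(f"jmax must be positive, got {self.jmax}")
        if self.tpu is not None and not self.tpu > 0:
            raise GasExchangeError(f"tpu must be positive when present, got {self.tpu}")
        if self.rd < 0:
            raise GasExchangeError(f"rd must be >= 0 (respiration magnitude), got {self.rd}")
        if not self.gamma_star > 0:
            raise GasExchangeError("gamma_star must be positive")
        if not self.km > 0:
            raise GasExchangeError("km must be positive")
        if self.gm is not None and not self.gm > 0:
            raise GasExchangeError("gm must be positive or None (unbounded)")


@dataclass
class AciCurve:
    """One leaf's CO2 response: arrays of equal length, one row per setpoint."""

    ca_setpoint: np.ndarray
    an: np.ndarray
    ci: np.ndarray
    gs: np.ndarray
    ppfd: np.ndarray
    leaf_temp: np.ndarray
    phi_psii: np.ndarray | None = None
    species: str = ""
    tree_id: str = ""
    habit: str = "deciduous"
    year: int = 0

    def __post_init__(self) -> None:
        arrays = ["ca_setpoint", "an", "ci", "gs", "ppfd", "leaf_temp"]
        if self.phi_psii is not None:
            arrays.append("phi_psii")
        for name in arrays:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.ca_setpoint.size
        if n < 1:
            raise GasExchangeError("curve must contain at least one point")
        for name in arrays:
            if getattr(self, name).shape != (n,):
                raise GasExchangeError(f"column {name!r} length differs from ca_setpoint")
        if np.any(self.ci < 0):
            raise GasExchangeError("ci must be non-negative")
        if np.any(self.ca_setpoint <= 0):
            raise GasExchangeError("ca_setpoint must be positive")
        if self.habit not in HABITS:
            raise GasExchangeError(f"habit must be one of {HABITS}, got {self.habit!r}")

    def __len__(self) -> int:
        return int(self.ca_setpoint.size)

    def sorted_by_ci(self) -> "AciCurve":
        order = np.argsort(self.ci)
        kwargs = {
            k: getattr(self, k)[order]
            for k in ("ca_setpoint", "an", "ci", "gs", "ppfd", "leaf_temp")
        }
        if self.phi_psii is not None:
            kwargs["phi_psii"] = self.phi_psii[order]
        return AciCurve(species=self.species, tree_id=self.tree_id,
                        habit=self.habit, year=self.year, **kwargs)


@dataclass
class FvcbFit:
    """Fitted FvCB model for one A-Ci curve."""

    params: FvcbParams
    limitation_state: list[str]
    a_c: np.ndarray
    a_j: np.ndarray
    a_p: np.ndarray          # NaN where TPU not in the model
    a_n: np.ndarray
    amax: float
    tpu_evident: bool
    rmse: float
    unidentifiable: tuple[str, ...] = ()
    n_points: int = 0


@dataclass
class LaiskResult:
    """Common intersection of low-Ci linear A-Ci responses."""

    ci_star: float
    rd: float                 # positive respiration magnitude
    intercept_an: float       # signed An at the intersection (= -rd)
    se_ci_star: float
    se_rd: float
    n_lines: int
    slopes: np.ndarray = field(default_factory=lambda: np.array([]))
    intercepts: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass(frozen=True)
class FluorescenceConfig:
    """Leaf absorbance alpha and PSII partitioning beta for Jflu."""

    alpha: float
    beta: float = BETA_C3

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise GasExchangeError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 < self.beta <= 1:
            raise GasExchangeError(f"beta must be in (0, 1], got {self.beta}")

    @classmethod
    def for_habit(cls, habit: str, beta: float = BETA_C3) -> "FluorescenceConfig":
        if habit == "deciduous":
            return cls(alpha=ALPHA_DECIDUOUS, beta=beta)
        if habit == "evergreen":
            return cls(alpha=ALPHA_EVERGREEN, beta=beta)
        raise GasExchangeError(f"unknown habit {habit!r}")


# ---------------------------------------------------------------------------
# Forward model


def fvcb_rates(params: FvcbParams, cc) -> dict:
    """Limitation-specific assimilation rates at chloroplast CO2 ``cc``.

    Returns ``a_c`` (Rubisco), ``a_j`` (RuBP regeneration), ``a_p`` (TPU;
    NaN when ``params.tpu`` is None) and their pointwise minimum ``a_n``,
    all net of day respiration. Units umol m-2 s-1.
    """
    cc = np.asarray(cc, dtype=float)
    if np.any(cc < 0):
        raise GasExchangeError("cc must be non-negative")
    gs_, km, rd = params.gamma_star, params.km, params.rd
    a_c = params.vcmax * (cc - gs_) / (cc + km) - rd
    a_j = params.jmax * (cc - gs_) / (4.0 * cc + 8.0 * gs_) - rd
    if params.tpu is not None:
        a_p = np.full_like(a_c, 3.0 * params.tpu - rd)
        a_n = np.minimum(np.minimum(a_c, a_j), a_p)
    else:
        a_p = np.full_like(a_c, np.nan)
        a_n = np.minimum(a_c, a_j)
    return {"a_c": a_c, "a_j": a_j, "a_p": a_p, "a_n": a_n}


def _cc_from_ci(ci: np.ndarray, an: np.ndarray, gm: float | None) -> np.ndarray:
    """Chloroplast CO2 from intercellular CO2 and the CO2 drawdown An/gm."""
    if gm is None:
        return ci.copy()
    return ci - an / gm


# ---------------------------------------------------------------------------
# Fitting


def _unpack(theta, with_jmax: bool, with_tpu: bool, fixed_rd: float | None):
    """Parameter vector layout: vcmax [, jmax] [, tpu] [, rd]."""
    theta = list(theta)
    vcmax = theta.pop(0)
    jmax = theta.pop(0) if with_jmax else None
    tpu = theta.pop(0) if with_tpu else None
    rd = fixed_rd if fixed_rd is not None else theta.pop(0)
    return vcmax, jmax, tpu, rd


def _model_an(theta: np.ndarray, cc: np.ndarray, gamma_star: float, km: float,
              with_jmax: bool, with_tpu: bool, fixed_rd: float | None) -> np.ndarray:
    vcmax, jmax, tpu, rd = _unpack(theta, with_jmax, with_tpu, fixed_rd)
    a = vcmax * (cc - gamma_star) / (cc + km)
    if jmax is not None:
        a = np.minimum(a, jmax * (cc - gamma_star) / (4.0 * cc + 8.0 * gamma_star))
    if tpu is not None:
        a = np.minimum(a, 3.0 * tpu)
    return a - rd


def _nls(an: np.ndarray, cc: np.ndarray, gamma_star: float, km: float,
         with_tpu: bool, fixed_rd: float | None, with_jmax: bool = True):
    """Trust-region NLS with deterministic multistart over scaled initials."""
    rd0 = 1.0 if fixed_rd is None else fixed_rd
    low = cc < max(300.0, np.median(cc))
    # initial slope region -> vcmax; highest points -> jmax lower bound
    with np.errstate(divide="ignore", invalid="ignore"):
        v0 = np.nanmedian((an[low] + rd0) * (cc[low] + km) / (cc[low] - gamma_star))
    if not np.isfinite(v0) or v0 <= 0:
        v0 = 50.0
    top = np.argsort(cc)[-3:]
    j0 = np.nanmax((an[top] + rd0) * (4.0 * cc[top] + 8.0 * gamma_star)
                   / np.maximum(cc[top] - gamma_star, 1.0))
    if not np.isfinite(j0) or j0 <= 0:
        j0 = 1.8 * v0
    t0 = (np.max(an) + rd0) / 3.0

    best = None
    for scale in (1.0, 0.7, 1.4):
        x0, lb, ub = [v0 * scale], [1e-3], [1e3]
        if with_jmax:
            x0.append(j0 * scale)
            lb.append(1e-3)
            ub.append(1e3)
        if with_tpu:
            x0.append(max(t0 * scale, 0.1))
            lb.append(1e-3)
            ub.append(1e2)
        if fixed_rd is None:
            x0.append(rd0)
            lb.append(0.0)
            ub.append(10.0)
        x0 = np.clip(x0, lb, ub)
        res = least_squares(
            lambda th: _model_an(th, cc, gamma_star, km, with_jmax, with_tpu,
                                 fixed_rd) - an,
            x0, bounds=(lb, ub), method="trf",
            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=5000,
        )
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-18:
            break
    return best


def _assemble_fit(theta, an, cc, gamma_star, km, with_tpu, fixed_rd,
                  with_jmax: bool = True) -> FvcbFit:
    vcmax, jmax, tpu, rd = _unpack(theta, with_jmax, with_tpu, fixed_rd)
    tpu_val = float(tpu) if tpu is not None else None
    # an unidentified jmax is reported as effectively unbounded (never the
    # binding limitation anywhere on the observed curve)
    jmax_val = float(jmax) if jmax is not None else 1e3
    params = FvcbParams(vcmax=float(vcmax), jmax=jmax_val, rd=float(rd),
                        tpu=tpu_val, gamma_star=gamma_star, km=km)
    rates = fvcb_rates(params, cc)
    stacked = [rates["a_c"], rates["a_j"]]
    names = ["Rubisco", "RuBP"]
    if tpu_val is not None:
        stacked.append(rates["a_p"])
        names.append("TPU")
    which = np.argmin(np.stack(stacked), axis=0)
    state = [names[i] for i in which]
    resid = rates["a_n"] - an
    return FvcbFit(
        params=params, limitation_state=state,
        a_c=rates["a_c"], a_j=rates["a_j"], a_p=rates["a_p"], a_n=rates["a_n"],
        amax=float(np.max(an)), tpu_evident=tpu_val is not None,
        rmse=float(np.sqrt(np.mean(resid ** 2))), n_points=an.size,
    )


def fit_aci(
    curve: AciCurve,
    gm: float | None,
    gamma_star: float = GAMMA_STAR_30C,
    km: float = KM_30C,
    detect_tpu: bool = True,
    fixed_rd: float | None = None,
    tpu_slope_threshold: float = 0.005,
    tpu_top_k: int = 2,
    min_points: int = 5,
    high_ci: float = 600.0,
) -> FvcbFit:
    """Fit the FvCB minimum-of-limitations model to an observed A-Ci curve.

    Chloroplast CO2 is taken as Cc = Ci - An/gm using the observed An (the
    standard correction; ``gm=None`` means Cc = Ci). The model is first fit
    without the TPU term; if ``detect_tpu`` and :func:`detect_tpu_limitation`
    confirms a distinct high-Ci plateau, the model is refit with TPU and
    ``tpu_evident`` is set. Parameters whose limitation never binds are
    listed in ``unidentifiable`` (jmax when no point is RuBP-limited, e.g.
    on a low-Ci-only curve).
    """
    curve = curve.sorted_by_ci()
    n = len(curve)
    if n < min_points:
        raise GasExchangeError(f"need at least {min_points} points, got {n}")
    if int(np.sum(curve.ci < 300.0)) < 2:
        raise GasExchangeError("need at least 2 points with Ci < 300 to anchor vcmax")
    an, ci = curve.an, curve.ci
    cc = _cc_from_ci(ci, an, gm)
    if np.any(cc <= 0):
        raise GasExchangeError("non-positive Cc after mesophyll drawdown; check gm")

    # without high-Ci coverage the RuBP-limited branch never binds; fit the
    # Rubisco-only model so the optimizer cannot trade vcmax against jmax
    rubisco_only = int(np.sum(ci > high_ci)) < 2
    res = _nls(an, cc, gamma_star, km, with_tpu=False, fixed_rd=fixed_rd,
               with_jmax=not rubisco_only)
    # status 0 = iteration budget: keep the best point found; only a
    # genuinely degenerate solve (non-finite cost/params) is a failure
    if res is None or res.status < 0 or not np.all(np.isfinite(res.x)):
        raise FitError(f"base fit did not converge: {getattr(res, 'message', 'no result')}")
    fit = _assemble_fit(res.x, an, cc, gamma_star, km, False, fixed_rd,
                        with_jmax=not rubisco_only)

    tpu_evident = False
    if detect_tpu and n > tpu_top_k and not rubisco_only:
        tpu_evident = detect_tpu_limitation(
            curve, fit, k=tpu_top_k, slope_threshold=tpu_slope_threshold,
            gm=gm, fixed_rd=fixed_rd)
    if tpu_evident:
        res_t = _nls(an, cc, gamma_star, km, with_tpu=True, fixed_rd=fixed_rd)
        if res_t is not None and res_t.status >= 0 and np.all(np.isfinite(res_t.x)):
            fit_t = _assemble_fit(res_t.x, an, cc, gamma_star, km, True, fixed_rd)
            if fit_t.rmse <= fit.rmse + 1e-12:
                fit = fit_t
        fit.tpu_evident = fit.params.tpu is not None

    unident = []
    if rubisco_only or "RuBP" not in fit.limitation_state:
        unident.append("jmax")
    if "Rubisco" not in fit.limitation_state:
        unident.append("vcmax")
    fit.unidentifiable = tuple(unident)
    return fit


def detect_tpu_limitation(
    curve: AciCurve,
    fit: FvcbFit,
    k: int = 2,
    slope_threshold: float = 0.005,
    min_binding: int = 2,
    gm: float | None = None,
    fixed_rd: float | None = None,
) -> bool:
    """True iff the high-Ci tail shows a distinct TPU plateau.

    Requires (a) the line through the ``k`` highest-Ci points to have slope
    <= ``slope_threshold`` (umol m-2 s-1 per umol mol-1), (b) those points
    not to exceed the TPU-free fitted RuBP-limited rate by more than the fit
    rmse, and (c) a candidate refit with the TPU term to place the TPU rate
    strictly below both other limitations at >= ``min_binding`` setpoints --
    i.e. a plateau genuinely distinct from the RuBP-limited curve, not just
    its natural high-Ci flattening.
    """
    curve = curve.sorted_by_ci()
    n = len(curve)
    if n < k + 1:
        raise GasExchangeError(f"need more than {k} points for plateau detection")
    ci, an = curve.ci, curve.an
    top = slice(n - k, n)
    slope = np.polyfit(ci[top], an[top], 1)[0]
    if slope > slope_threshold:
        return False
    cc = _cc_from_ci(ci, an, gm)
    excess = an[top] - fit.a_j[top]
    if np.any(excess > fit.rmse + 1e-9):
        return False
    res = _nls(an, cc, fit.params.gamma_star, fit.params.km,
               with_tpu=True, fixed_rd=fixed_rd)
    if res is None or res.status < 0 or not np.all(np.isfinite(res.x)):
        return False
    cand = _assemble_fit(res.x, an, cc, fit.params.gamma_star, fit.params.km,
                         True, fixed_rd)
    n_binding = int(np.sum(cand.a_p < np.minimum(cand.a_c, cand.a_j)))
    no_worse = cand.rmse <= fit.rmse + max(cand.rmse, 1e-9)
    return bool(n_binding >= min_binding and no_worse)


def amax_and_normalize(
    curve: AciCurve,
    fit: FvcbFit | None = None,
    l_leaf: float | None = None,
    lma: float | None = None,
) -> dict:
    """Maximum observed An and its thickness/mass normalizations.

    ``amax`` is the highest observed An on the curve (umol m-2 s-1);
    ``amax_per_thickness`` divides by leaf thickness in um and
    ``amax_per_mass`` by LMA in mg cm-2. The fit's ``tpu_evident`` flag is
    carried through so reports can distinguish saturated curves.
    """
    if len(curve) < 1:
        raise GasExchangeError("empty curve")
    amax = float(np.max(curve.an))
    out = {"amax": amax, "tpu_evident": bool(fit.tpu_evident) if fit else False}
    if l_leaf is not None:
        if not l_leaf > 0:
            raise GasExchangeError(f"l_leaf must be positive, got {l_leaf}")
        out["amax_per_thickness"] = amax / l_leaf
    if lma is not None:
        if not lma > 0:
            raise GasExchangeError(f"lma must be positive, got {lma}")
        out["amax_per_mass"] = amax / lma
    return out


# ---------------------------------------------------------------------------
# Laisk intersection


def _intersect_lines(slopes: np.ndarray, intercepts: np.ndarray) -> tuple[float, float]:
    """Least-squares common point of y = m_i x + b_i over all lines."""
    if np.ptp(slopes) < 1e-12:
        raise GasExchangeError("lines are parallel or identical; no unique intersection")
    A = np.column_stack([slopes, -np.ones_like(slopes)])
    sol, *_ = np.linalg.lstsq(A, -intercepts, rcond=None)
    x, y = sol
    return float(x), float(y)


def laisk_rd_cistar(
    curves: Sequence[AciCurve],
    ci_cutoff: float = 150.0,
    mode: str = "per_curve",
) -> LaiskResult:
    """Day respiration Rd and Ci* from the common low-Ci intersection.

    Fits one straight line per curve to the points with Ci <= ``ci_cutoff``
    and finds the least-squares common intersection (x*, y*) over all
    lines; Ci* = x* and Rd = -y* (reported as a positive magnitude, with
    the signed An intercept also returned). Standard errors come from a
    leave-one-curve-out jackknife (NaN with fewer than three lines).

    ``mode='grouped'`` first averages line coefficients within species and
    intersects the species-mean lines, mirroring analyses run on averaged
    curves; ``'per_curve'`` uses every replicate line.
    """
    if mode not in ("per_curve", "grouped"):
        raise GasExchangeError(f"unknown mode {mode!r}")
    slopes, intercepts, labels = [], [], []
    for c in curves:
        m = c.ci <= ci_cutoff
        if int(m.sum()) < 2:
            warnings.warn(
                f"curve {c.species}/{c.tree_id} has <2 points at Ci<={ci_cutoff}; excluded",
                stacklevel=2)
            continue
        b1, b0 = np.polyfit(c.ci[m], c.an[m], 1)
        slopes.append(b1)
        intercepts.append(b0)
        labels.append(c.species or c.tree_id)
    slopes = np.asarray(slopes)
    intercepts = np.asarray(intercepts)
    if mode == "grouped":
        uniq = sorted(set(labels))
        slopes = np.array([slopes[[l == u for l in labels]].mean() for u in uniq])
        intercepts = np.array([intercepts[[l == u for l in labels]].mean() for u in uniq])
    n = slopes.size
    if n < 2:
        raise GasExchangeError("need at least 2 usable low-Ci lines")
    x, y = _intersect_lines(slopes, intercepts)

    if n >= 3:
        jack = np.array([
            _intersect_lines(np.delete(slopes, i), np.delete(intercepts, i))
            for i in range(n)
        ])
        mean = jack.mean(axis=0)
        se = np.sqrt((n - 1) / n * np.sum((jack - mean) ** 2, axis=0))
        se_x, se_y = float(se[0]), float(se[1])
    else:
        se_x = se_y = float("nan")
    return LaiskResult(ci_star=x, rd=-y, intercept_an=y,
                       se_ci_star=se_x, se_rd=se_y, n_lines=int(n),
                       slopes=slopes, intercepts=intercepts)


# ---------------------------------------------------------------------------
# Variable-J mesophyll conductance


def jflu(phi_psii, ppfd, config: FluorescenceConfig):
    """Fluorescence-based electron transport rate: PhiPSII x PPFD x alpha x beta."""
    phi_psii = np.asarray(phi_psii, dtype=float)
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any((phi_psii < 0) | (phi_psii > 1)):
        raise GasExchangeError("phi_psii must lie in [0, 1]")
    if np.any(ppfd < 0):
        raise GasExchangeError("ppfd must be non-negative")
    out = phi_psii * ppfd * config.alpha * config.beta
    return float(out) if out.ndim == 0 else out


def variable_j_gm(an, ci, jflu_val, rd, gamma_star: float = GAMMA_STAR_30C):
    """Mesophyll conductance from the variable-J method.

    gm = An / ( Ci - Gamma* (Jflu + 8(An+Rd)) / (Jflu - 4(An+Rd)) ),
    with Rd a positive respiration magnitude. Requires Jflu > 4(An+Rd);
    negative or non-finite results are raised as invalid estimates rather
    than returned.
    """
    an = float(an)
    ci = float(ci)
    jf = float(jflu_val)
    rd = float(rd)
    if ci <= 0:
        raise GasExchangeError("ci must be positive")
    x = an + rd
    denom = jf - 4.0 * x
    if denom <= 0:
        raise GasExchangeError(
            f"jflu must exceed 4*(an+rd) (= {4 * x:.4g}); got jflu = {jf:.4g}")
    bracket = ci - gamma_star * (jf + 8.0 * x) / denom
    if an == 0.0 and rd == 0.0:
        return 0.0
    if bracket <= 0:
        raise GasExchangeError(
            "invalid gm estimate: Ci does not exceed the photocompensation term")
    gm = an / bracket
    if not np.isfinite(gm) or gm < 0:
        raise GasExchangeError(f"invalid gm estimate: {gm}")
    return float(gm)


def fluorescence_gm_profile(
    curve: AciCurve,
    rd: float,
    config: FluorescenceConfig,
    gamma_star: float = GAMMA_STAR_30C,
    gm_max: float = 2.0,
) -> np.ndarray:
    """Per-point variable-J gm along a curve (NaN where invalid).

    Eq.-wise gm is extremely sensitive to measurement noise in An (the
    photocompensation bracket is a small difference of large terms), so
    single-point estimates scatter widely; the median over the valid
    points of a curve is the robust per-leaf summary. Estimates above
    ``gm_max`` (mol m-2 s-1) are treated as invalid, the standard sanity
    filter for this method.
    """
    if curve.phi_psii is None:
        return np.full(len(curve), np.nan)
    out = np.full(len(curve), np.nan)
    for i in range(len(curve)):
        phi = curve.phi_psii[i]
        if not np.isfinite(phi):
            continue
        try:
            g = variable_j_gm(curve.an[i], curve.ci[i],
                              jflu(phi, curve.ppfd[i], config), rd, gamma_star)
        except GasExchangeError:
            continue
        if 0 < g <= gm_max:
            out[i] = g
    return out


def extract_at_ca(curve: AciCurve, target_ca: float = 400.0, rel_tol: float = 0.05) -> dict:
    """Record (an, gs, ci) at the setpoint nearest ``target_ca`` within ``rel_tol``."""
    if len(curve) < 1:
        raise GasExchangeError("empty curve")
    i = int(np.argmin(np.abs(curve.ca_setpoint - target_ca)))
    if abs(curve.ca_setpoint[i] - target_ca) > rel_tol * target_ca:
        raise GasExchangeError(
            f"no setpoint within {rel_tol:.0%} of {target_ca}; nearest is "
            f"{curve.ca_setpoint[i]}")
    out = {"an": float(curve.an[i]), "gs": float(curve.gs[i]), "ci": float(curve.ci[i]),
           "ca_setpoint": float(curve.ca_setpoint[i])}
    if curve.phi_psii is not None:
        out["phi_psii"] = float(curve.phi_psii[i])
        out["ppfd"] = float(curve.ppfd[i])
    return out
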