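"""Maximum-likelihood multi-session spatial capture-recapture (SCR).

Model
-----
Activity centers follow an inhomogeneous Poisson point process over the
discrete state space: pixel *s* in session *g* holds an expected
``mu_g(s) = exp(x_d(s,g)' beta_d)`` individuals (log link).  Detection of an
individual with center *s* at trap *j* on occasion *k* is Bernoulli with

    p_jk(s, sex) = p0_jk(sex) * exp(-d(s,j)^2 / (2 sigma^2)),

a half-normal distance decline; ``p0`` is modelled on the logit scale
(occasion, sex, session and trap covariates) and ``sigma`` on the log scale
(session, sex and their interaction).  Sex is a two-component mixture with
probability ``psi`` (logit scale) of being female.  The observed-individual
likelihood marginalises each individual's center over the pixels and adds
the Poisson correction for the expected number of detected individuals:

    logL_g = sum_i log[ psi_{m_i} sum_s mu_g(s) P(y_i | s, m_i) ]
             - sum_s sum_sex psi_sex mu_g(s) pbar(s, sex)

with ``pbar = 1 - prod_jk (1 - p_jk)``.  Additive constants independent of
the parameters are dropped.  Sessions contribute independently.

Covariate structure is given as small formula strings
(``~session+habitat``, ``~occ+sex+session+dist_agr+habitat``,
``~session*sex``) with treatment contrasts; reference levels follow the
field convention here: agricultural fields for pixel habitat, coniferous
forest for trap habitat, female for sex, first session and first occasion
otherwise.  ``a*b`` codes the crossed cells against the joint reference
cell.  Distance covariates are centered at their mean so intercepts refer
to an average location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .encounters import EncounterArray
from .landscape import StateSpace, TrapArray

__all__ = [
    "ModelSpec",
    "FitResult",
    "DensitySurface",
    "detection_prob",
    "SCRLikelihood",
    "neg_log_likelihood",
    "linear_predictors",
    "fit",
    "predict_density",
    "backtransform",
    "backtransform_check",
]


# ---------------------------------------------------------------------------
# Formula mini-language

def parse_formula(formula: str) -> list[str]:
    """Split ``~a+b*c`` into its terms; the intercept is always implied."""
    f = formula.strip()
    if f.startswith("~"):
        f = f[1:]
    terms = [t.strip() for t in f.split("+") if t.strip() and t.strip() != "1"]
    return terms


@dataclass
class Variable:
    kind: str  # 'factor' | 'numeric'
    levels: tuple[str, ...] = ()  # factors: global levels, ref first
    center: float = 0.0  # numerics: value subtracted before coding


def _columns_for_term(term: str, variables: dict[str, Variable]) -> list[tuple[str, tuple]]:
    """Column descriptors for one term.

    Factor -> one column per non-reference level ``('var[lvl]', ('factor',
    var, lvl))``; numeric -> ``('var', ('numeric', var))``; ``a*b`` (both
    factors) -> one column per non-reference cell of the crossed factor.
    """
    if "*" in term:
        a, b = [s.strip() for s in term.split("*")]
        va, vb = variables[a], variables[b]
        if va.kind != "factor" or vb.kind != "factor":
            raise ValueError(f"'{term}': cell interaction needs two factors")
        cols = []
        for la in va.levels:
            for lb in vb.levels:
                if la == va.levels[0] and lb == vb.levels[0]:
                    continue
                cols.append((f"{a}*{b}[{la},{lb}]", ("cell", a, la, b, lb)))
        return cols
    if term not in variables:
        raise ValueError(f"unknown model variable {term!r}")
    v = variables[term]
    if v.kind == "factor":
        return [(f"{term}[{lvl}]", ("factor", term, lvl)) for lvl in v.levels[1:]]
    return [(term, ("numeric", term))]


def build_design(formula: str, variables: dict[str, Variable],
                 data: dict[str, np.ndarray], n_rows: int) -> tuple[np.ndarray, list[str]]:
    """Design matrix for ``formula`` over rows described by ``data``.

    ``data[name]`` holds per-row factor levels (str) or numeric values.
    """
    names = ["(Intercept)"]
    cols = [np.ones(n_rows)]
    for term in parse_formula(formula):
        for name, desc in _columns_for_term(term, variables):
            if desc[0] == "factor":
                _, var, lvl = desc
                col = (np.asarray(data[var]) == lvl).astype(float)
            elif desc[0] == "cell":
                _, a, la, b, lb = desc
                col = ((np.asarray(data[a]) == la) & (np.asarray(data[b]) == lb)).astype(float)
            else:
                _, var = desc
                col = np.asarray(data[var], dtype=float) - variables[var].center
            names.append(name)
            cols.append(col)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Specification and results

@dataclass
class ModelSpec:
    """Symbolic covariate structure for (D, p0, sigma, psi).

    ``density`` is a log-linear model for per-pixel expected counts;
    ``detection`` a logit model for baseline detection; ``sigma`` a
    log-linear model for the half-normal scale (m); the sex ratio ``psi`` is
    a single logit-scale intercept.
    """

    density: str = "~1"
    detection: str = "~1"
    sigma: str = "~1"
    label: str | None = None

    def describe(self) -> str:
        if self.label:
            return self.label
        return (f"D({self.density.lstrip('~')}) "
                f"p({self.detection.lstrip('~')}) sig({self.sigma.lstrip('~')})")


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: np.ndarray
    se: np.ndarray
    names: list[str]
    neg_loglik: float
    converged: bool
    n_individuals: int
    message: str = ""
    likelihood: "SCRLikelihood | None" = field(default=None, repr=False)
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return self.estimates.size

    @property
    def aic(self) -> float:
        return 2.0 * self.neg_loglik + 2.0 * self.K

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.estimates / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        q = stats.norm.ppf(0.5 + level / 2)
        est, se = self.coef(name), self.se_of(name)
        return est - q * se, est + q * se

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names,
            "estimate": self.estimates,
            "se": self.se,
            "z": self.z,
            "p": self.p_values,
        })


@dataclass
class DensitySurface:
    """Predicted density per pixel, per habitat class and in total."""

    per_pixel: pd.DataFrame  # session, x, y, habitat, mu (per pixel), density_km2
    per_class: pd.DataFrame  # session, habitat, density_km2, lcl, ucl
    totals: pd.DataFrame     # session, expected_N, density_km2, lcl, ucl
    pixel_area_km2: float


# ---------------------------------------------------------------------------
# Elementary pieces

def detection_prob(p0, sigma, d):
    """Half-normal detection: ``p0 * exp(-d^2 / (2 sigma^2))``."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    return p0 * np.exp(-(d ** 2) / (2.0 * np.asarray(sigma, dtype=float) ** 2))


# ---------------------------------------------------------------------------
# Likelihood machinery

SEXES = ("F", "M")


class SCRLikelihood:
    """Negative log-likelihood of a multi-session sex-structured SCR model.

    Builds all design matrices once; ``__call__`` evaluates the likelihood
    for a parameter vector laid out as
    ``[density block | detection block | sigma block | psi]``.
    """

    def __init__(self, spec: ModelSpec, encounters: EncounterArray,
                 space: StateSpace, traps: TrapArray):
        if not encounters.sessions:
            raise ValueError("no sessions with detections")
        self.spec = spec
        self.encounters = encounters
        self.space = space
        self.traps = traps
        self.sessions = list(encounters.sessions)
        self.n_pixels = space.n_pixels
        self.n_traps = traps.n_traps

        d2 = ((space.x[:, None] - traps.x[None, :]) ** 2
              + (space.y[:, None] - traps.y[None, :]) ** 2)
        self._d2 = d2  # (n_pixels, n_traps)

        max_occ = max(enc.n_occasions for enc in encounters.sessions.values())
        occ_levels = tuple(str(k) for k in range(1, max_occ + 1))

        # global factor metadata; fixed reference levels
        self.variables_d: dict[str, Variable] = {
            "session": Variable("factor", tuple(self.sessions)),
        }
        if space.habitat is not None:
            levels = ["agricultural"] + sorted(
                set(np.asarray(space.habitat).tolist()) - {"agricultural"})
            self.variables_d["habitat"] = Variable("factor", tuple(levels))
        for name, vals in (("dist_water", space.dist_water),
                           ("dist_artificial", space.dist_artificial)):
            if vals is not None:
                self.variables_d[name] = Variable("numeric", center=float(np.mean(vals)))

        self.variables_p: dict[str, Variable] = {
            "session": Variable("factor", tuple(self.sessions)),
            "occ": Variable("factor", occ_levels),
            "sex": Variable("factor", SEXES),
        }
        if traps.habitat is not None:
            levels = ["coniferous"] + sorted(
                set(np.asarray(traps.habitat).tolist()) - {"coniferous"})
            self.variables_p["habitat"] = Variable("factor", tuple(levels))
        for name, vals in (("dist_agr", traps.dist_agricultural),
                           ("dist_artificial", traps.dist_artificial),
                           ("dist_water", traps.dist_water)):
            if vals is not None:
                self.variables_p[name] = Variable("numeric", center=float(np.mean(vals)))

        self.variables_s: dict[str, Variable] = {
            "session": Variable("factor", tuple(self.sessions)),
            "sex": Variable("factor", SEXES),
        }

        # density designs: one (n_pixels, P_d) matrix per session
        self._Xd: dict[str, np.ndarray] = {}
        for g in self.sessions:
            data = {"session": np.repeat(g, self.n_pixels)}
            if space.habitat is not None:
                data["habitat"] = np.asarray(space.habitat)
            if space.dist_water is not None:
                data["dist_water"] = space.dist_water
            if space.dist_artificial is not None:
                data["dist_artificial"] = space.dist_artificial
            X, names = build_design(spec.density, self.variables_d, data, self.n_pixels)
            self._Xd[g] = X
        self.names_d = [f"D.{n}" for n in names]

        # detection designs: (n_traps * K_g, P_p) per (session, sex); row
        # order is trap-major: row j*K + k  <-> trap j, occasion k
        self._Xp: dict[tuple[str, str], np.ndarray] = {}
        for g in self.sessions:
            K = encounters[g].n_occasions
            n = self.n_traps * K
            base = {
                "session": np.repeat(g, n),
                "occ": np.tile([str(k + 1) for k in range(K)], self.n_traps),
            }
            if traps.habitat is not None:
                base["habitat"] = np.repeat(np.asarray(traps.habitat), K)
            for name, vals in (("dist_agr", traps.dist_agricultural),
                               ("dist_artificial", traps.dist_artificial),
                               ("dist_water", traps.dist_water)):
                if vals is not None:
                    base[name] = np.repeat(np.asarray(vals, dtype=float), K)
            for sex in SEXES:
                data = dict(base, sex=np.repeat(sex, n))
                X, names = build_design(spec.detection, self.variables_p, data, n)
                self._Xp[(g, sex)] = X
        self.names_p = [f"p0.{n}" for n in names]

        # sigma design: one row per (session, sex)
        rows = [(g, sex) for g in self.sessions for sex in SEXES]
        data = {"session": np.array([r[0] for r in rows]),
                "sex": np.array([r[1] for r in rows])}
        Xs, names = build_design(spec.sigma, self.variables_s, data, len(rows))
        self._Xs = {row: Xs[i] for i, row in enumerate(rows)}
        self.names_s = [f"sigma.{n}" for n in names]

        self.names = self.names_d + self.names_p + self.names_s + ["psi.(Intercept)"]
        self._nd = len(self.names_d)
        self._np = len(self.names_p)
        self._ns = len(self.names_s)
        self.n_params = self._nd + self._np + self._ns + 1

        # per-session observed data, grouped by sex label: a (n_i, J*K)
        # 0/1 matrix of detected trap-occasion cells per individual, plus a
        # (n_i, J) per-trap total for the occasion-constant fast path
        self._obs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self.n_individuals = 0
        for g in self.sessions:
            enc = self.encounters[g]
            by_sex: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            sex_labels = np.where(np.isin(enc.sex, SEXES), enc.sex, "unknown")
            for label in ("F", "M", "unknown"):
                idx = np.nonzero(sex_labels == label)[0]
                if idx.size == 0:
                    continue
                yflat = enc.y[idx].reshape(idx.size, -1).astype(float)
                ytrap = enc.y[idx].sum(axis=2).astype(float)
                by_sex[label] = (yflat, ytrap)
            self._obs[g] = by_sex
            self.n_individuals += len(enc.individuals)

    # -- parameter unpacking ------------------------------------------------
    def split(self, params: np.ndarray):
        params = np.asarray(params, dtype=float)
        if params.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {params.size}")
        bd = params[:self._nd]
        bp = params[self._nd:self._nd + self._np]
        bs = params[self._nd + self._np:self._nd + self._np + self._ns]
        psi = params[-1]
        return bd, bp, bs, psi

    def linear_predictors(self, params: np.ndarray, session: str, sex: str):
        """(per-pixel log mu, per-trap-occasion logit p0 as (J, K), log sigma)."""
        bd, bp, bs, _ = self.split(params)
        K = self.encounters[session].n_occasions
        log_mu = self._Xd[session] @ bd
        logit_p0 = (self._Xp[(session, sex)] @ bp).reshape(self.n_traps, K)
        log_sigma = float(self._Xs[(session, sex)] @ bs)
        return log_mu, logit_p0, log_sigma

    #: floor for log detection odds; exp(-800) underflows to 0, so the floor
    #: only replaces -inf (p == 0 after underflow) by a finite stand-in
    _LOG_ODDS_FLOOR = -800.0

    def __call__(self, params: np.ndarray) -> float:
        bd, bp, bs, psi_l = self.split(params)
        psi = {"F": float(expit(psi_l)), "M": float(1.0 - expit(psi_l))}
        total = 0.0
        for g in self.sessions:
            K = self.encounters[g].n_occasions
            log_mu = self._Xd[g] @ bd  # (S,)
            mu = np.exp(log_mu)
            # per-individual marginal log-likelihoods per sex hypothesis:
            # ll[sex] is (n_i,) for each sex-label group
            ll_group: dict[str, dict[str, np.ndarray]] = {}
            gd_cache: dict[float, np.ndarray] = {}
            for sex in SEXES:
                logit_p0 = (self._Xp[(g, sex)] @ bp).reshape(self.n_traps, K)
                sigma = np.exp(float(self._Xs[(g, sex)] @ bs))
                if sigma not in gd_cache:
                    gd_cache[sigma] = np.exp(-self._d2 / (2.0 * sigma * sigma))
                gd = gd_cache[sigma]  # (S, J)
                p0 = expit(logit_p0)  # (J, K)
                if K > 1 and np.ptp(logit_p0, axis=1).max() == 0.0:
                    # occasion-constant p0: collapse the occasion axis
                    p = p0[None, :, 0] * gd  # (S, J)
                    with np.errstate(divide="ignore"):
                        lodds = np.maximum(np.log(p) - np.log1p(-p),
                                           self._LOG_ODDS_FLOOR)
                    L0 = K * np.log1p(-p).sum(axis=1)
                    flat = None
                else:
                    p = p0[None, :, :] * gd[:, :, None]  # (S, J, K)
                    with np.errstate(divide="ignore"):
                        l1mp = np.log1p(-p)
                        lodds = np.maximum(np.log(p) - l1mp,
                                           self._LOG_ODDS_FLOOR)
                    L0 = l1mp.sum(axis=(1, 2))
                    flat = lodds.reshape(self.n_pixels, -1)
                # Poisson correction for this sex
                total -= psi[sex] * float(mu @ (-np.expm1(L0)))
                base = log_mu + L0  # (S,)
                for label, (yflat, ytrap) in self._obs[g].items():
                    if label != sex and label != "unknown":
                        continue
                    A = (lodds @ ytrap.T) if flat is None else (flat @ yflat.T)
                    ll = logsumexp(base[:, None] + A, axis=0)  # (n_i,)
                    ll_group.setdefault(label, {})[sex] = ll
            for label, by_sex in ll_group.items():
                if label in SEXES:
                    total += float(np.sum(np.log(psi[label]) + by_sex[label]))
                else:  # unknown sex: mixture over both
                    stacked = np.stack([np.log(psi[s]) + by_sex[s] for s in SEXES])
                    total += float(np.sum(logsumexp(stacked, axis=0)))
        if not np.isfinite(total):
            return 1e300
        return -total

    def default_start(self) -> np.ndarray:
        """Zeros, except log-sigma initialised at half the maximum
        inter-trap distance and the density intercept at roughly one
        individual per pixel-cluster (log of observed n over pixels)."""
        start = np.zeros(self.n_params)
        dx = self.traps.x[:, None] - self.traps.x[None, :]
        dy = self.traps.y[:, None] - self.traps.y[None, :]
        max_d = float(np.sqrt(dx ** 2 + dy ** 2).max())
        start[self._nd + self._np] = np.log(max(max_d / 2.0, 1.0))
        start[0] = np.log(max(self.n_individuals, 1) / self.n_pixels)
        start[self._nd] = -1.0  # logit p0 below 0.5
        return start


def neg_log_likelihood(params, spec: ModelSpec, encounters: EncounterArray,
                       space: StateSpace, traps: TrapArray) -> float:
    """Convenience wrapper building the likelihood object on the fly."""
    return SCRLikelihood(spec, encounters, space, traps)(params)


def linear_predictors(params, spec: ModelSpec, encounters: EncounterArray,
                      space: StateSpace, traps: TrapArray,
                      session: str, sex: str):
    return SCRLikelihood(spec, encounters, space, traps).linear_predictors(
        params, session, sex)


# ---------------------------------------------------------------------------
# Fitting

def fit(spec: ModelSpec, encounters: EncounterArray, space: StateSpace,
        traps: TrapArray, start: np.ndarray | None = None,
        gtol: float = 1e-8) -> FitResult:
    """Minimise the negative log-likelihood by quasi-Newton iteration.

    Standard errors come from the inverse of a numerical Hessian at the
    optimum (Wald inference); non-convergence is flagged on the result, not
    raised.
    """
    nll = SCRLikelihood(spec, encounters, space, traps)
    x0 = nll.default_start() if start is None else np.asarray(start, dtype=float)
    res = optimize.minimize(
        nll, x0, method="BFGS",
        options={"gtol": gtol, "maxiter": 500},
    )
    from statsmodels.tools.numdiff import approx_hess

    se = np.full(res.x.size, np.nan)
    cov = None
    try:
        H = approx_hess(res.x, nll)
        cov = np.linalg.pinv(H)
        diag = np.diag(cov)
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except Exception:  # Hessian failure leaves NaN SEs, fit still usable
        pass
    converged = bool(res.success or np.linalg.norm(res.jac, np.inf) < 1e-3)
    return FitResult(
        spec=spec, estimates=res.x, se=se, names=list(nll.names),
        neg_loglik=float(res.fun), converged=converged,
        n_individuals=nll.n_individuals, message=str(res.message),
        likelihood=nll, cov=cov,
    )


# ---------------------------------------------------------------------------
# Prediction

def predict_density(result: FitResult, space: StateSpace | None = None,
                    level: float = 0.95) -> DensitySurface:
    """Density surface, per-habitat-class densities and per-session totals.

    Class predictions back-transform the class-specific linear predictor
    (numeric covariates at their centering value); confidence intervals use
    the delta method on the log scale and are then exponentiated.
    """
    nll = result.likelihood
    if nll is None:
        raise ValueError("fit carries no likelihood context")
    space = nll.space if space is None else space
    area = space.pixel_area_km2
    bd = result.estimates[:nll._nd]
    cov_d = None
    if result.cov is not None:
        cov_d = result.cov[:nll._nd, :nll._nd]
    q = stats.norm.ppf(0.5 + level / 2)

    pp_rows, cls_rows, tot_rows = [], [], []
    for g in nll.sessions:
        X = nll._Xd[g]
        log_mu = X @ bd
        mu = np.exp(log_mu)
        df = pd.DataFrame({
            "session": g, "x": space.x, "y": space.y,
            "mu": mu, "density_km2": mu / area,
        })
        if space.habitat is not None:
            df["habitat"] = np.asarray(space.habitat)
        pp_rows.append(df)

        # totals with delta-method CI on log(sum mu)
        total_mu = float(mu.sum())
        lcl = ucl = np.nan
        if cov_d is not None:
            grad = (mu @ X) / total_mu
            var = float(grad @ cov_d @ grad)
            if var >= 0:
                half = q * np.sqrt(var)
                lcl = total_mu * np.exp(-half) / space.total_area_km2
                ucl = total_mu * np.exp(half) / space.total_area_km2
        tot_rows.append({
            "session": g, "expected_N": total_mu,
            "density_km2": total_mu / space.total_area_km2,
            "lcl": lcl, "ucl": ucl,
        })

        if space.habitat is not None and "habitat" in nll.variables_d:
            for lvl in nll.variables_d["habitat"].levels:
                data = {"session": np.array([g]), "habitat": np.array([lvl])}
                for nm in ("dist_water", "dist_artificial"):
                    if nm in nll.variables_d:
                        data[nm] = np.array([nll.variables_d[nm].center])
                x_row, _ = build_design(result.spec.density, nll.variables_d, data, 1)
                eta = float(x_row[0] @ bd)
                dens = np.exp(eta) / area
                lcl_c = ucl_c = np.nan
                if cov_d is not None:
                    var = float(x_row[0] @ cov_d @ x_row[0])
                    if var >= 0:
                        half = q * np.sqrt(var)
                        lcl_c, ucl_c = dens * np.exp(-half), dens * np.exp(half)
                cls_rows.append({"session": g, "habitat": lvl,
                                 "density_km2": dens, "lcl": lcl_c, "ucl": ucl_c})
        else:
            cls_rows.append({"session": g, "habitat": "(all)",
                             "density_km2": total_mu / space.total_area_km2,
                             "lcl": tot_rows[-1]["lcl"], "ucl": tot_rows[-1]["ucl"]})

    return DensitySurface(
        per_pixel=pd.concat(pp_rows, ignore_index=True),
        per_class=pd.DataFrame(cls_rows),
        totals=pd.DataFrame(tot_rows),
        pixel_area_km2=area,
    )


# ---------------------------------------------------------------------------
# Back-transformation helpers

def backtransform(estimate: float, contrast: float | None = None,
                  link: str = "logit", pixel_area_km2: float | None = None) -> float:
    """Data-scale value of a link-scale intercept (plus optional contrast).

    ``link='logit'`` inverts to a probability; ``link='exp'`` exponentiates;
    for densities pass ``pixel_area_km2`` to convert individuals/pixel to
    individuals/km².
    """
    eta = float(estimate) + (float(contrast) if contrast is not None else 0.0)
    if link == "logit":
        val = float(expit(eta))
    elif link == "exp":
        val = float(np.exp(eta))
    else:
        raise ValueError(f"unknown link {link!r}")
    if pixel_area_km2 is not None:
        val /= pixel_area_km2
    return val


def _round_half_away(x: float, digits: int) -> float:
    """Round half away from zero at ``digits`` decimals (display rule)."""
    factor = 10.0 ** digits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def backtransform_check(rows: list[dict]) -> pd.DataFrame:
    """Recompute data-scale values from link-scale coefficients and compare
    with independently reported values at their printed precision.

    Each row needs ``estimate``, ``link`` and ``printed``; optional
    ``contrast`` (added to the intercept) and ``pixel_area_km2``.  A row
    whose recomputed value differs at the printed precision is flagged
    (``agrees=False``), never overwritten — reported tables are typically
    back-transformed from unrounded coefficients, so last-digit divergence
    from rounded inputs is expected.
    """
    out = []
    for row in rows:
        val = backtransform(row["estimate"], row.get("contrast"),
                            row.get("link", "logit"), row.get("pixel_area_km2"))
        printed = float(row["printed"])
        digits = len(str(row["printed"]).split(".")[1]) if "." in str(row["printed"]) else 0
        rounded = _round_half_away(val, digits)
        out.append({
            "parameter": row.get("parameter", ""),
            "computed": val,
            "computed_rounded": rounded,
            "printed": printed,
            "agrees": bool(abs(rounded - printed) < 10.0 ** (-digits) / 2),
        })
    return pd.DataFrame(out)
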