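"""AIC tables, Akaike weights and two-step model selection.

The selection strategy mirrors a common SCR workflow: first choose the best
*homogeneous* model (density, detection and sigma varying only by session,
occasion and sex), then add habitat covariates to that top model and rank
the resulting *heterogeneous* candidates.  This keeps the candidate set
manageable when the covariate menu is large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encounters import EncounterArray
from .landscape import StateSpace, TrapArray
from .scr_model import FitResult, ModelSpec, fit

__all__ = [
    "aic",
    "akaike_weights",
    "ModelTable",
    "model_table",
    "default_homogeneous_menu",
    "heterogeneous_menu",
    "two_step_selection",
]


def aic(neg_loglik: float, k: int) -> float:
    """Akaike information criterion: ``2 * negLogL + 2K``."""
    if k < 1:
        raise ValueError("a model has at least one parameter")
    return 2.0 * float(neg_loglik) + 2.0 * int(k)


def akaike_weights(aics) -> tuple[np.ndarray, np.ndarray]:
    """Akaike weights ``exp(-dAIC/2)`` normalised to 1, plus the cumulative
    weights after sorting ascending by AIC.  Invariant to adding a constant
    to every AIC."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    order = np.argsort(a, kind="stable")
    cum = np.empty_like(w)
    cum[order] = np.cumsum(w[order])
    return w, cum


@dataclass
class ModelTable:
    """AIC ranking of a set of fitted models (best first)."""

    table: pd.DataFrame
    fits: list[FitResult]

    @property
    def top(self) -> FitResult:
        return self.fits[0]

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def model_table(fits: list[FitResult]) -> ModelTable:
    """Rank converged fits by AIC; ties break by fewer parameters, then
    label, so the ordering is reproducible."""
    if not fits:
        raise ValueError("no fits to tabulate")
    rows = [
        {"model": f.spec.describe(), "logL": f.neg_loglik, "K": f.K, "AIC": f.aic}
        for f in fits
    ]
    df = pd.DataFrame(rows)
    order = sorted(range(len(fits)),
                   key=lambda i: (df.loc[i, "AIC"], df.loc[i, "K"], df.loc[i, "model"]))
    df = df.iloc[order].reset_index(drop=True)
    w, _ = akaike_weights(df["AIC"].to_numpy())
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    df["weight"] = w
    df["cum_weight"] = np.cumsum(w)
    return ModelTable(table=df, fits=[fits[i] for i in order])


def default_homogeneous_menu() -> list[ModelSpec]:
    """Candidate grid over session/occasion/sex structure.

    The full crossing of {1, session} x {1, occ, sex, session,
    combinations} x {1, sex, session, session*sex} is large; this default
    keeps the axes that matter for a two-season sex-structured survey and
    is user-editable.
    """
    density_terms = ["~1", "~session"]
    detection_terms = ["~1", "~session", "~sex", "~occ",
                       "~occ+sex", "~occ+session", "~sex+session",
                       "~occ+sex+session"]
    sigma_terms = ["~1", "~sex", "~session", "~session*sex"]
    return [
        ModelSpec(density=d, detection=p, sigma=s)
        for d in density_terms for p in detection_terms for s in sigma_terms
    ]


def heterogeneous_menu(base: ModelSpec,
                       density_covariates: list[str] = ("habitat",),
                       detection_covariates: list[str] = (
                           "habitat", "dist_agr", "dist_water", "dist_artificial"),
                       ) -> list[ModelSpec]:
    """Heterogeneous variants of the top homogeneous model.

    Adds the habitat-class term to density and each detection covariate
    (singly and, for habitat+distance, jointly) to the detection model.
    """
    def extend(formula: str, extra: str) -> str:
        body = formula.lstrip("~")
        return f"~{body}+{extra}" if body and body != "1" else f"~{extra}"

    specs: list[ModelSpec] = []
    density_opts = [base.density] + [extend(base.density, c) for c in density_covariates]
    detection_opts = [base.detection] + [extend(base.detection, c)
                                         for c in detection_covariates]
    # habitat on both D and p plus the distance terms pairwise with habitat-D
    for d in density_opts:
        for p in detection_opts:
            if d == base.density and p == base.detection:
                continue
            specs.append(ModelSpec(density=d, detection=p, sigma=base.sigma))
    # joint habitat + distance-to-field detection structure
    if "habitat" in detection_covariates and "dist_agr" in detection_covariates:
        for d in density_opts:
            specs.append(ModelSpec(
                density=d,
                detection=extend(extend(base.detection, "dist_agr"), "habitat"),
                sigma=base.sigma))
    # drop duplicates, keep first occurrence
    seen, uniq = set(), []
    for s in specs:
        key = (s.density, s.detection, s.sigma)
        if key not in seen:
            seen.add(key)
            uniq.append(s)
    return uniq


def _fit_all(specs: list[ModelSpec], encounters: EncounterArray,
             space: StateSpace, traps: TrapArray) -> list[FitResult]:
    fits = []
    for spec in specs:
        res = fit(spec, encounters, space, traps)
        if not res.converged:
            warnings.warn(f"model {spec.describe()} did not converge; excluded")
            continue
        fits.append(res)
    return fits


def two_step_selection(encounters: EncounterArray, space: StateSpace,
                       traps: TrapArray,
                       homogeneous: list[ModelSpec] | None = None,
                       heterogeneous: list[ModelSpec] | None = None,
                       ) -> tuple[FitResult, ModelTable, ModelTable]:
    """Two-step AIC selection.

    Step 1 ranks the homogeneous candidates; step 2 ranks habitat-covariate
    extensions of the step-1 winner (the winner itself is included as the
    null).  Returns (top homogeneous fit, homogeneous table, heterogeneous
    table)."""
    homogeneous = default_homogeneous_menu() if homogeneous is None else homogeneous
    if not homogeneous:
        raise ValueError("homogeneous candidate list is empty")
    hom_fits = _fit_all(homogeneous, encounters, space, traps)
    if not hom_fits:
        raise RuntimeError("no homogeneous candidate converged")
    hom_table = model_table(hom_fits)
    top = hom_table.top
    if heterogeneous is None:
        heterogeneous = heterogeneous_menu(top.spec)
    het_fits = [top] + _fit_all(heterogeneous, encounters, space, traps)
    het_table = model_table(het_fits)
    return top, hom_table, het_table
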