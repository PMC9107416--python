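"""Regression of rating differences on ROI delta-zfALFF.

The behavioral stage asks whether post-minus-pre changes in hunger or
satiety ratings (VAS units) relate to the activity changes in the ROIs
that drove classification, and whether that relation differs by
treatment arm.  Candidate predictors are each ROI's delta-zfALFF, the
treatment indicator (0 = sham, 1 = treatment) and each ROI x treatment
interaction; a bidirectional stepwise search over these candidates
minimises an information criterion under the marginality constraint
that an interaction may only enter alongside both of its main effects.

A post-hoc hemispheric asymmetry index (right ROI minus left ROI;
positive = right-dominant) supports per-group simple regressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelFit",
    "fit_linear_model",
    "build_candidates",
    "stepwise_select",
    "asymmetry_index",
    "per_group_regression",
]


@dataclass(frozen=True)
class ModelFit:
    """An ordinary-least-squares fit summary.

    ``terms`` excludes the intercept; per-term p-values are t-based.
    ``df_resid`` = n - len(terms) - 1 (the intercept is always present).
    """

    response: str
    terms: tuple[str, ...]
    coefficients: Mapping[str, float]
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_value: float
    term_p_values: Mapping[str, float]
    aic: float
    bic: float
    nobs: int

    def predict(self, values: Mapping[str, float]) -> float:
        """Evaluate b0 + sum(b_i * x_i) at the given predictor values."""
        return self.intercept + sum(
            self.coefficients[t] * values[t] for t in self.terms
        )

    def to_dict(self) -> dict:
        return {
            "response": self.response, "terms": list(self.terms),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "adj_r_squared": self.adj_r_squared,
            "f_statistic": self.f_statistic,
            "df": [self.df_model, self.df_resid], "p_value": self.p_value,
            "term_p_values": dict(self.term_p_values),
        }


def fit_linear_model(y: Sequence[float], design: pd.DataFrame,
                     response: str = "y") -> ModelFit:
    """OLS of ``y`` on the columns of ``design`` (intercept added).

    Raises a collinearity error naming aliased columns when the design
    is rank-deficient.
    """
    y = np.asarray(y, dtype=float)
    if design.shape[0] != y.shape[0]:
        raise ValueError("y and design have different lengths")
    if y.shape[0] <= design.shape[1] + 1:
        raise ValueError(
            f"need n > n_terms + 1 ({y.shape[0]} rows, {design.shape[1]} terms)")
    Xm = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xm]))
    if rank < design.shape[1] + 1:
        # name the columns involved in the rank deficiency
        aliased = []
        kept = [np.ones(len(y))]
        for c in design.columns:
            trial = np.column_stack(kept + [design[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                kept.append(design[c].to_numpy(dtype=float))
            else:
                aliased.append(c)
        raise ValueError(f"design is rank-deficient; aliased terms: {aliased}")
    X = sm.add_constant(design.astype(float), has_constant="add")
    res = sm.OLS(y, X).fit()
    terms = tuple(design.columns)
    return ModelFit(
        response=response, terms=terms,
        coefficients={t: float(res.params[t]) for t in terms},
        intercept=float(res.params["const"]),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_statistic=float(res.fvalue) if terms else float("nan"),
        df_model=int(res.df_model), df_resid=int(res.df_resid),
        p_value=float(res.f_pvalue) if terms else float("nan"),
        term_p_values={t: float(res.pvalues[t]) for t in terms},
        aic=float(res.aic), bic=float(res.bic), nobs=int(res.nobs),
    )


def _intercept_only(y: np.ndarray, response: str) -> ModelFit:
    n = len(y)
    return ModelFit(
        response=response, terms=(), coefficients={},
        intercept=float(np.mean(y)), r_squared=0.0, adj_r_squared=0.0,
        f_statistic=float("nan"), df_model=0, df_resid=n - 1,
        p_value=float("nan"), term_p_values={},
        aic=float(sm.OLS(y, np.ones((n, 1))).fit().aic),
        bic=float(sm.OLS(y, np.ones((n, 1))).fit().bic), nobs=n,
    )


INTERACTION_SEP = ":"


def build_candidates(features: pd.DataFrame, treatment: Sequence[int],
                     rois: Sequence[str] | None = None) -> pd.DataFrame:
    """Design-candidate table: each ROI, ``treatment``, and each
    ``roi:treatment`` interaction column."""
    rois = list(rois) if rois is not None else [
        c for c in features.columns if c != "group"]
    t = np.asarray(treatment, dtype=float)
    out = pd.DataFrame(index=features.index)
    for r in rois:
        out[r] = features[r].to_numpy(dtype=float)
    out["treatment"] = t
    for r in rois:
        out[f"{r}{INTERACTION_SEP}treatment"] = out[r] * t
    return out


def _parents(term: str) -> tuple[str, ...]:
    if INTERACTION_SEP in term:
        a, b = term.split(INTERACTION_SEP, 1)
        return (a, b)
    return ()


def _children(term: str, candidates: Sequence[str]) -> list[str]:
    return [c for c in candidates if term in _parents(c)]


def stepwise_select(
    y: Sequence[float],
    candidates: pd.DataFrame,
    criterion: str = "aic",
    response: str = "y",
    max_steps: int = 100,
) -> tuple[ModelFit, list[dict]]:
    """Bidirectional stepwise OLS over candidate columns.

    Each step tries every hierarchy-respecting addition or single-term
    removal and keeps the move that most lowers the chosen information
    criterion ('aic' or 'bic'); the search stops when no move improves.
    An interaction ``a:treatment`` enters together with whichever of its
    main effects are still missing (a composite move, so a strong
    interaction is reachable even when its parents are weak alone), and
    a main effect cannot leave while one of its interactions remains.

    Returns the selected fit (intercept-only if nothing improves on the
    empty model) and a step log.
    """
    if criterion not in {"aic", "bic"}:
        raise ValueError("criterion must be 'aic' or 'bic'")
    if candidates.shape[1] == 0:
        raise ValueError("no candidate terms")
    y = np.asarray(y, dtype=float)
    cols = list(candidates.columns)

    def score(fit: ModelFit) -> float:
        return getattr(fit, criterion)

    def fit_terms(terms: list[str]) -> ModelFit:
        if not terms:
            return _intercept_only(y, response)
        return fit_linear_model(y, candidates[terms], response=response)

    current: list[str] = []
    current_fit = fit_terms(current)
    log: list[dict] = []
    for _ in range(max_steps):
        # moves: (score, action, terms added/removed)
        moves: list[tuple[float, str, tuple[str, ...]]] = []
        for c in cols:
            if c in current:
                continue
            # an interaction enters together with any missing main effects
            # (a composite move), so a strong interaction is reachable even
            # when its parents are weak on their own
            added = [p for p in _parents(c) if p not in current] + [c]
            if len(y) <= len(current) + len(added) + 1:
                continue  # keep the fit well-posed
            try:
                moves.append((score(fit_terms(current + added)), "add",
                              tuple(added)))
            except ValueError:
                continue  # collinear candidate
        for c in current:
            if _children(c, current):
                continue  # hierarchy: interactions leave first
            reduced = [t for t in current if t != c]
            moves.append((score(fit_terms(reduced)), "remove", (c,)))
        if not moves:
            break
        best_score, action, terms = min(moves, key=lambda m: (m[0], m[1], m[2]))
        if best_score >= score(current_fit) - 1e-10:
            break
        if action == "add":
            current = current + list(terms)
        else:
            current = [t for t in current if t not in terms]
        current_fit = fit_terms(current)
        log.append({"action": action, "moved": list(terms),
                    criterion: best_score, "terms": list(current)})
    return current_fit, log


def asymmetry_index(right_roi, left_roi):
    """Hemispheric asymmetry: right minus left (positive = right-dominant)."""
    return np.asarray(right_roi, dtype=float) - np.asarray(left_roi, dtype=float)


def per_group_regression(
    y: Sequence[float],
    x: Sequence[float],
    groups: Sequence,
    predictor: str = "x",
    response: str = "y",
) -> dict[str, ModelFit]:
    """Independent simple regressions of y on x within each group."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    fits: dict[str, ModelFit] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() < 4:
            raise ValueError(f"group {g!r} has fewer than 4 subjects")
        design = pd.DataFrame({predictor: x[sel]})
        fits[str(g)] = fit_linear_model(y[sel], design, response=response)
    return fits
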