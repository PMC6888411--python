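"""DIC-guided forward selection of interior spline knots.

Selection starts from a single knot at the centred year 0 (the centre year
itself) and greedily adds the candidate knot whose inclusion most lowers
the fit criterion, stopping once the best available drop falls below a
materiality threshold (default 2, the conventional DIC difference worth
acting on).  The fit function is injectable: the production path fits the
Bayesian model by MCMC and returns its DIC, while cheap surrogates (e.g. a
penalised GLM deviance) exercise the same selection logic quickly.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .data import PanelCounts
from .models import ModelSpec

__all__ = ["forward_knot_selection", "mcmc_dic_fit_fn"]

FitFn = Callable[[PanelCounts, ModelSpec, tuple[float, ...]], float]


class KnotSelectionError(RuntimeError):
    def __init__(self, knots: tuple[float, ...], cause: Exception):
        super().__init__(f"model fit failed at knot set {knots}: {cause}")
        self.knots = knots
        self.cause = cause


def forward_knot_selection(
    data: PanelCounts,
    model_spec: ModelSpec,
    candidate_knots: Sequence[float],
    fit_fn: FitFn,
    dic_drop_threshold: float = 2.0,
    initial_knots: tuple[float, ...] = (0.0,),
) -> tuple[tuple[float, ...], list[tuple[tuple[float, ...], float]]]:
    """Greedy forward knot selection.

    Returns the chosen knot set and the trace of every evaluated
    ``(knot set, criterion)`` pair, in evaluation order, so the search can
    be reported alongside the result.
    """
    chosen = tuple(sorted(initial_knots))

    def fit(knots: tuple[float, ...]) -> float:
        try:
            return float(fit_fn(data, model_spec, knots))
        except Exception as err:
            raise KnotSelectionError(knots, err) from err

    trace: list[tuple[tuple[float, ...], float]] = []
    current = fit(chosen)
    trace.append((chosen, current))
    remaining = [k for k in candidate_knots if k not in chosen]
    while remaining and np.isfinite(dic_drop_threshold):
        scores = []
        for cand in remaining:
            ks = tuple(sorted(chosen + (cand,)))
            dic = fit(ks)
            trace.append((ks, dic))
            scores.append((dic, cand, ks))
        best_dic, best_cand, best_ks = min(scores)
        if current - best_dic < dic_drop_threshold:
            break
        chosen, current = best_ks, best_dic
        remaining = [k for k in remaining if k != best_cand]
    return chosen, trace


def mcmc_dic_fit_fn(basis_waves, center_year, prior_config=None, mcmc_config=None) -> FitFn:
    """Production fit function: fit by MCMC and return the DIC."""
    from .basis import build_basis
    from .inference import MCMCConfig, run_mcmc

    config = mcmc_config

    def fit(data: PanelCounts, spec: ModelSpec, knots: tuple[float, ...]) -> float:
        basis = build_basis(basis_waves, knots, center_year)
        fit_ = run_mcmc(spec, data, basis, prior_config, config or MCMCConfig.desk_scale())
        return fit_.dic[2]

    return fit
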