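"""Two-step parameter optimisation and best-filter selection.

For every (architecture, scenario) pair the canceller is run over a coarse
parameter grid (filter length L crossed with step size mu or forgetting
factor lam); the figure of merit is the RMSE between the cleaned output
e(n) and the pure Alvarez-wave signal (atoms only, no noise).  The coarse
argmin seeds a fine grid of +-1 coarse step at ``refine`` times the
resolution, one pass.  The best architectures are then selected by the
majority criterion: lowest RMSE in the majority of the scenarios, ties at
three significant digits reported jointly; when a winner's optimal
parameter differs across scenarios the value from the second (triangular,
worst-case) scenario is kept.

Grid-point evaluations that go numerically unstable are recorded as +inf
(never dropped, so surfaces stay rectangular) and excluded from the argmin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .adafilt import FILTER_PARAM, FilterInstabilityError, FilterSpec, rmse, run_filter
from .synthgen import ScenarioSignals

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterGrid",
    "RMSESurface",
    "OptimizationResult",
    "FilterRanking",
    "DEFAULT_GRIDS",
    "coarse_search",
    "fine_tune",
    "optimize_filter",
    "select_filters",
    "round_sig",
]

#: Global floor on searched filter lengths (the shared lower bound of every
#: default grid; a single-tap canceller is outside the searched space).
L_FLOOR = 2


@dataclass
class ParameterGrid:
    """Rectangular (L x parameter) search grid, ranges as (min, max, step)."""

    L_range: tuple
    mu_range: tuple | None = None
    lam_range: tuple | None = None

    def __post_init__(self):
        if self.mu_range is not None and self.lam_range is not None:
            raise ValueError("a grid carries at most one of mu_range / lam_range")
        for rng in (self.L_range, self.mu_range, self.lam_range):
            if rng is None:
                continue
            lo, hi, step = rng
            if not step > 0:
                raise ValueError(f"grid step must be > 0, got {rng}")
            if lo > hi:
                raise ValueError(f"grid min must be <= max, got {rng}")

    @property
    def param_kind(self) -> str | None:
        if self.mu_range is not None:
            return "mu"
        if self.lam_range is not None:
            return "lam"
        return None

    def L_values(self) -> np.ndarray:
        lo, hi, step = self.L_range
        return np.arange(int(lo), int(hi) + 1, int(step), dtype=int)

    def param_values(self) -> np.ndarray:
        rng = self.mu_range if self.mu_range is not None else self.lam_range
        if rng is None:
            return np.array([np.nan])
        lo, hi, step = rng
        vals = np.round(np.arange(lo, hi + 0.5 * step, step), 10)
        return vals[vals <= hi + 1e-9]


#: Coarse ranges that bracket an RMSE minimum for each architecture
#: (FTF's forgetting factor is constrained to [1 - 0.5/L, 1] and is searched
#: as a fraction of that admissible interval; the Wiener filter has only L).
DEFAULT_GRIDS = {
    "LMS": ParameterGrid((2, 20, 2), mu_range=(0.0, 10.0, 0.5)),
    "NLMS": ParameterGrid((2, 20, 2), mu_range=(0.5, 2.0, 0.5)),
    "FDAF": ParameterGrid((2, 20, 2), mu_range=(0.2, 1.0, 0.2)),
    "BLMS": ParameterGrid((2, 20, 2), mu_range=(0.0, 10.0, 0.5)),
    "FXLMS": ParameterGrid((2, 20, 2), mu_range=(0.0, 10.0, 0.5)),
    "SELMS": ParameterGrid((2, 20, 2), mu_range=(0.0, 10.0, 0.5)),
    "SDLMS": ParameterGrid((2, 20, 2), mu_range=(0.0, 3.0, 0.5)),
    "SSLMS": ParameterGrid((2, 20, 2), mu_range=(0.0, 5.0, 0.5)),
    "LSL": ParameterGrid((5, 100, 5), lam_range=(0.10, 1.00, 0.10)),
    "RLS": ParameterGrid((2, 20, 2), lam_range=(0.95, 1.00, 0.01)),
    "HRLS": ParameterGrid((2, 20, 2), lam_range=(0.40, 1.00, 0.10)),
    "SWRLS": ParameterGrid((2, 20, 2), lam_range=(0.95, 1.00, 0.01)),
    "HSWRLS": ParameterGrid((2, 20, 2), lam_range=(0.20, 1.00, 0.10)),
    "QRD-RLS": ParameterGrid((2, 20, 2), lam_range=(0.10, 1.00, 0.10)),
    "FTF": ParameterGrid((2, 20, 2), lam_range=(0.0, 1.0, 0.1)),  # fraction of [1-0.5/L, 1]
    "Wiener": ParameterGrid((2, 20, 2)),
}


@dataclass
class RMSESurface:
    """RMSE over a rectangular (L x parameter) grid, +inf where unstable."""

    filter_name: str
    scenario_id: int | str
    axis1: np.ndarray  # L values
    axis2: np.ndarray  # mu or lam values (or fraction for FTF; [nan] for Wiener)
    rmse: np.ndarray  # shape (len(axis1), len(axis2))
    param_kind: str | None
    L_step: int = 2
    param_step: float | None = None
    n_unstable: int = 0

    @property
    def argmin(self) -> tuple:
        """(L*, p*) attaining the matrix minimum among finite entries."""
        if not np.any(np.isfinite(self.rmse)):
            raise FilterInstabilityError(
                f"every grid point of {self.filter_name} was unstable"
            )
        i, j = np.unravel_index(np.nanargmin(np.where(np.isfinite(self.rmse), self.rmse, np.nan)), self.rmse.shape)
        p = self.axis2[j] if self.param_kind is not None else None
        return int(self.axis1[i]), p

    @property
    def rmse_min(self) -> float:
        return float(np.min(self.rmse[np.isfinite(self.rmse)]))


@dataclass
class OptimizationResult:
    """Fine-tuned optimum for one (architecture, scenario) pair."""

    filter_name: str
    scenario_id: int | str
    L_opt: int
    mu_opt: float | None
    lam_opt: float | None
    rmse_opt: float
    n_evals: int = 0
    seed: int | None = None

    def spec(self, **kwargs) -> FilterSpec:
        return FilterSpec(
            self.filter_name, L=self.L_opt, mu=self.mu_opt, lam=self.lam_opt, **kwargs
        )


@dataclass
class FilterRanking:
    """Majority-criterion ranking with worst-case-scenario parameter rule."""

    ranks: list  # list of lists of filter names; ranks[0] are the winners
    per_scenario_best: dict  # scenario_id -> list of names tied at the scenario minimum
    selected_params: dict  # name -> {"L":..., "mu":..., "lam":...}
    scenario_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# evaluation


def _ftf_lam(L: int, frac: float) -> float:
    lo = 1.0 - 0.5 / L
    return lo + frac * (1.0 - lo)


def _make_evaluator(filter_name: str, signals: ScenarioSignals, spec_kwargs: dict):
    """RMSE(clean, e) at one (L, p) grid point; +inf when unstable."""
    kind = FILTER_PARAM[filter_name]

    def evaluate(L: int, p: float | None) -> float:
        kw = dict(spec_kwargs)
        if kind == "mu":
            kw["mu"] = p
        elif kind == "lam":
            kw["lam"] = _ftf_lam(L, p) if filter_name == "FTF" else p
        spec = FilterSpec(filter_name, L=int(L), **kw)
        try:
            run = run_filter(spec, signals.noisy, signals.interference)
        except FilterInstabilityError as exc:
            logger.info("unstable grid point: %s", exc)
            return math.inf
        return rmse(signals.clean, run.e)

    return evaluate


def coarse_search(
    filter_name: str,
    grid: ParameterGrid | None,
    signals: ScenarioSignals,
    *,
    evaluate=None,
    **spec_kwargs,
) -> RMSESurface:
    """Evaluate the canceller at every coarse grid point.

    ``evaluate(L, p)`` may be injected (e.g. for surface-shape tests);
    by default each point runs the filter on ``signals`` and scores
    RMSE(clean, e).
    """
    if grid is None:
        grid = DEFAULT_GRIDS[filter_name]
    kind = grid.param_kind
    if kind != FILTER_PARAM[filter_name] and filter_name != "Wiener":
        raise ValueError(
            f"grid parameter {kind!r} does not match {filter_name} "
            f"(expects {FILTER_PARAM[filter_name]!r})"
        )
    if evaluate is None:
        evaluate = _make_evaluator(filter_name, signals, spec_kwargs)
    Ls = grid.L_values()
    ps = grid.param_values()
    mat = np.empty((Ls.size, ps.size))
    n_unstable = 0
    for i, L in enumerate(Ls):
        for j, p in enumerate(ps):
            val = evaluate(int(L), None if kind is None else float(p))
            if not np.isfinite(val):
                val = math.inf
                n_unstable += 1
            mat[i, j] = val
    prng = grid.mu_range if grid.mu_range is not None else grid.lam_range
    sc_id = signals.scenario.scenario_id if signals is not None and signals.scenario else None
    return RMSESurface(
        filter_name=filter_name,
        scenario_id=sc_id,
        axis1=Ls,
        axis2=ps,
        rmse=mat,
        param_kind=FILTER_PARAM[filter_name] if kind is not None else None,
        L_step=int(grid.L_range[2]),
        param_step=None if prng is None else float(prng[2]),
        n_unstable=n_unstable,
    )


def _param_domain(filter_name: str) -> tuple:
    if FILTER_PARAM[filter_name] == "mu":
        return (0.0, math.inf)
    if filter_name == "FTF":
        return (0.0, 1.0)  # fraction of the admissible interval
    return (1e-6, 1.0)


def fine_tune(
    filter_name: str,
    surface: RMSESurface,
    signals: ScenarioSignals,
    refine: int = 10,
    *,
    evaluate=None,
    **spec_kwargs,
) -> OptimizationResult:
    """Re-grid +-1 coarse step around the coarse argmin at step/refine
    resolution (one pass) and return the refined minimiser.

    Integer L candidates are deduplicated and floored at L >= 2; mu is kept
    non-negative and lam inside (0, 1]; for FTF the search runs over the
    fraction of the admissible [1 - 0.5/L, 1] interval, so the constraint
    holds for every candidate.  The coarse argmin is part of the candidate
    set, hence the refined RMSE never exceeds the coarse one.
    """
    if refine < 2:
        raise ValueError("refine must be >= 2")
    if evaluate is None:
        evaluate = _make_evaluator(filter_name, signals, spec_kwargs)
    L_star, p_star = surface.argmin
    L_cands = sorted(
        {
            int(L)
            for L in range(L_star - surface.L_step, L_star + surface.L_step + 1)
            if L >= L_FLOOR
        }
    )
    kind = surface.param_kind
    if kind is None:
        p_cands = [None]
    else:
        step = surface.param_step
        lo_dom, hi_dom = _param_domain(filter_name)
        fine_step = step / refine
        raw = np.round(
            p_star + fine_step * np.arange(-refine, refine + 1), 12
        )
        p_cands = sorted({float(p) for p in raw if lo_dom <= p <= hi_dom})
        if float(p_star) not in p_cands and lo_dom <= p_star <= hi_dom:
            p_cands.append(float(p_star))
    best = (math.inf, None, None)
    n_evals = 0
    for L in L_cands:
        for p in p_cands:
            val = evaluate(int(L), p)
            n_evals += 1
            if val < best[0]:
                best = (val, L, p)
    if not np.isfinite(best[0]):
        raise FilterInstabilityError(
            f"every fine-tune point of {filter_name} was unstable"
        )
    val, L_opt, p_opt = best
    mu_opt = lam_opt = None
    if kind == "mu":
        mu_opt = p_opt
    elif kind == "lam":
        lam_opt = _ftf_lam(L_opt, p_opt) if filter_name == "FTF" else p_opt
    return OptimizationResult(
        filter_name=filter_name,
        scenario_id=surface.scenario_id,
        L_opt=int(L_opt),
        mu_opt=mu_opt,
        lam_opt=None if lam_opt is None else float(np.round(lam_opt, 10)),
        rmse_opt=float(val),
        n_evals=n_evals,
    )


def optimize_filter(
    filter_name: str,
    signals: ScenarioSignals,
    grid: ParameterGrid | None = None,
    refine: int = 10,
    **spec_kwargs,
) -> tuple[RMSESurface, OptimizationResult]:
    """Coarse search followed by fine-tuning for one architecture."""
    surface = coarse_search(filter_name, grid, signals, **spec_kwargs)
    result = fine_tune(filter_name, surface, signals, refine=refine, **spec_kwargs)
    result.n_evals += surface.rmse.size
    if signals.scenario is not None:
        result.seed = signals.scenario.seed
    return surface, result


# ---------------------------------------------------------------------------
# selection


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant digits (inf/nan pass through)."""
    if not math.isfinite(x) or x == 0.0:
        return x
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1))


def select_filters(results, n_top: int = 2, tie_sig: int = 3) -> FilterRanking:
    """Rank architectures by the lowest-RMSE majority criterion.

    ``results`` is an iterable of :class:`OptimizationResult` covering every
    (filter, scenario) cell.  Rank r is the set of remaining filters that
    attain the scenario minimum (ties within ``tie_sig`` significant digits)
    in a majority of scenarios; if no majority emerges the filters with the
    most scenario wins are reported jointly.  For each winner, a parameter
    that differs across scenarios resolves to the second scenario's value.
    """
    table: dict = {}
    for r in results:
        table[(r.filter_name, r.scenario_id)] = r
    names = sorted({k[0] for k in table})
    scenarios = sorted({k[1] for k in table}, key=str)
    for nm in names:
        for sc in scenarios:
            if (nm, sc) not in table:
                raise ValueError(f"missing optimization result for ({nm}, {sc})")
    remaining = list(names)
    ranks = []
    per_scenario_best = {
        sc: _scenario_minimizers(table, names, sc, tie_sig) for sc in scenarios
    }
    while remaining and len(ranks) < n_top:
        wins = {nm: 0 for nm in remaining}
        for sc in scenarios:
            for nm in _scenario_minimizers(table, remaining, sc, tie_sig):
                wins[nm] += 1
        majority = [nm for nm in remaining if wins[nm] > len(scenarios) / 2]
        if not majority:
            top = max(wins.values())
            majority = [nm for nm in remaining if wins[nm] == top]
        ranks.append(sorted(majority))
        remaining = [nm for nm in remaining if nm not in majority]
    # the worst-case parameter rule applies to every architecture, whether
    # or not it made the reported ranks
    selected_params = {nm: _select_params(table, nm, scenarios) for nm in names}
    return FilterRanking(
        ranks=ranks,
        per_scenario_best=per_scenario_best,
        selected_params=selected_params,
        scenario_ids=scenarios,
    )


def _scenario_minimizers(table, names, sc, tie_sig):
    vals = {nm: round_sig(table[(nm, sc)].rmse_opt, tie_sig) for nm in names}
    best = min(vals.values())
    return sorted(nm for nm, v in vals.items() if v == best)


def _select_params(table, nm, scenarios):
    out = {}
    for attr in ("L_opt", "mu_opt", "lam_opt"):
        vals = [getattr(table[(nm, sc)], attr) for sc in scenarios]
        if any(v is None for v in vals):
            out[attr.replace("_opt", "")] = None
            continue
        if all(np.isclose(v, vals[0]) for v in vals):
            out[attr.replace("_opt", "")] = vals[0]
        else:
            # worst-case rule: take the second scenario's value
            idx = 1 if len(vals) > 1 else 0
            out[attr.replace("_opt", "")] = vals[idx]
    return out
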