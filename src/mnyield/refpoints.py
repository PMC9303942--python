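"""Yield curves and maximum-nutrient-yield reference points.

Builds equilibrium catch and nutrient yield curves over a community-wide
exploitation gradient in which every species is fished at its single-species
F_MSY times a shared effort multiplier *E*.  From the curves it identifies
the multispecies maximum sustainable yield (mMSY, maximum total catch), the
multispecies maximum nutrient yield (mMNY, maximum yield of each nutrient,
where nutrient yield is catch times concentration summed over species), the
community fishing levels F_mMSY and F_mMNY at which they occur, stock
collapses (equilibrium biomass below 10% of unfished), and the resulting
classification of each nutrient as overfished (F_mMNY < F_mMSY), underfished
(F_mMNY > F_mMSY) or neutral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .sizespectrum import (
    CommunityState,
    FishingPolicy,
    SizeSpectrumModel,
)

__all__ = [
    "NUTRIENTS",
    "NUTRIENT_UNIT_FACTOR",
    "NutrientProfile",
    "SpeciesRefPoints",
    "YieldCurve",
    "CurveSummary",
    "nutrient_yield",
    "profiles_to_matrix",
    "estimate_species_fmsy",
    "estimate_all_fmsy",
    "sweep_effort",
    "summarise_curve",
    "rescale_curves",
]

logger = logging.getLogger(__name__)

#: The seven nutrients tracked throughout: four minerals, two vitamins and
#: long-chain omega-3 fatty acids, on a per-100 g edible tissue basis
#: (calcium/iron/zinc mg, selenium/vitamins ug, omega-3 g).
NUTRIENTS = (
    "calcium",
    "iron",
    "zinc",
    "selenium",
    "vitamin_a",
    "vitamin_d",
    "omega3",
)

#: (amount per 100 g) x (tonnes of catch) -> amount of nutrient:
#: 1 tonne = 1e6 g = 1e4 x 100 g portions.
NUTRIENT_UNIT_FACTOR = 1.0e4


@dataclass
class NutrientProfile:
    """Concentrations of the seven nutrients for one species (per 100 g)."""

    species: str
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        keys = set(self.concentrations)
        if keys != set(NUTRIENTS):
            missing = set(NUTRIENTS) - keys
            extra = keys - set(NUTRIENTS)
            raise ValueError(
                f"profile for {self.species!r} must carry exactly the seven "
                f"nutrient keys (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for nut, c in self.concentrations.items():
            if c < 0:
                raise ValueError(
                    f"negative {nut} concentration for {self.species!r}"
                )


@dataclass(frozen=True)
class SpeciesRefPoints:
    """Single-species reference points within the multispecies model."""

    species: str
    F_MSY: float
    yield_at_FMSY: float
    B0: float

    def __post_init__(self) -> None:
        if self.F_MSY <= 0:
            raise ValueError("F_MSY must be positive")
        if self.B0 <= 0:
            raise ValueError("unfished biomass B0 must be positive")


def profiles_to_matrix(
    profiles: Sequence[NutrientProfile],
    species_names: Sequence[str],
    nutrients: Sequence[str] = NUTRIENTS,
) -> np.ndarray:
    """Concentration matrix (species x nutrients) aligned to ``species_names``."""
    by_name = {p.species: p for p in profiles}
    missing = [s for s in species_names if s not in by_name]
    if missing:
        raise KeyError(f"no nutrient profile for species: {missing}")
    return np.array(
        [[by_name[s].concentrations[n] for n in nutrients] for s in species_names]
    )


def nutrient_yield(
    catch_by_species: Mapping[str, float] | pd.Series,
    profiles: Sequence[NutrientProfile],
) -> dict[str, float]:
    """Per-nutrient yield: ``Y_n = sum_i C_i * c_in * 1e4`` (nutrient units/yr)."""
    if isinstance(catch_by_species, pd.Series):
        catch_by_species = catch_by_species.to_dict()
    names = list(catch_by_species)
    conc = profiles_to_matrix(profiles, names)
    catches = np.array([catch_by_species[s] for s in names])
    yields = NUTRIENT_UNIT_FACTOR * catches @ conc
    return dict(zip(NUTRIENTS, yields))


# ---------------------------------------------------------------------------
# Single-species F_MSY within the multispecies model
# ---------------------------------------------------------------------------

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _focal_yield(
    model: SizeSpectrumModel,
    species_F: np.ndarray,
    focal: int,
    F: float,
    warm: dict,
    equil_kwargs: dict,
) -> float:
    Fvec = species_F.copy()
    Fvec[focal] = F
    policy = model.policy_for_species_F(Fvec)
    state, _ = model.project_to_equilibrium(
        policy, state=warm.get("state"), **equil_kwargs
    )
    warm["state"] = state
    return float(model.species_yield(state, policy)[focal])


def estimate_species_fmsy(
    model: SizeSpectrumModel,
    species: str,
    background_F: Mapping[str, float] | Sequence[float],
    F_scan: Sequence[float] | None = None,
    rel_tol: float = 0.005,
    B0: float | None = None,
    warm_state: CommunityState | None = None,
    **equil_kwargs,
) -> SpeciesRefPoints:
    """F at maximum equilibrium yield for one species, others held fixed.

    Scans a coarse F grid, then refines the bracket around the best point by
    golden-section search.  Raises if the species has no fishable selectivity.
    ``warm_state`` seeds the first equilibrium run (each subsequent run is
    warm-started from the previous one).
    """
    focal = model.species_index(species)
    sel_ok = any(
        sel.species == species and sel.Q > 0 for sel in model.gears
    )
    if not sel_ok:
        raise ValueError(f"no fishable selectivity for species {species!r}")
    if isinstance(background_F, Mapping):
        species_F = np.array(
            [background_F.get(s, 0.0) for s in model.species_names]
        )
    else:
        species_F = np.asarray(background_F, dtype=float).copy()

    warm: dict = {} if warm_state is None else {"state": warm_state.copy()}
    if F_scan is None:
        # adaptive ascending scan: geometric steps upward, stopping once the
        # yield has clearly passed its peak (high-F evaluations sit in the
        # collapse region and are by far the most expensive)
        F_list, y_list = [], []
        f = 0.02
        while f <= 2.5 * 1.0001:
            F_list.append(f)
            y_list.append(
                _focal_yield(model, species_F, focal, f, warm, equil_kwargs)
            )
            if len(y_list) >= 3 and y_list[-1] < 0.8 * max(y_list):
                break
            f *= 1.9
        F_scan = np.array(F_list)
        yields = np.array(y_list)
    else:
        F_scan = np.asarray(F_scan, dtype=float)
        yields = np.array(
            [
                _focal_yield(model, species_F, focal, f, warm, equil_kwargs)
                for f in F_scan
            ]
        )
    k = int(np.argmax(yields))
    lo = F_scan[max(k - 1, 0)]
    hi = F_scan[min(k + 1, F_scan.size - 1)]
    if lo == hi:  # degenerate scan
        lo, hi = 0.5 * F_scan[k], 1.5 * F_scan[k]

    # golden-section search on [lo, hi]
    a, b = float(lo), float(hi)
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = _focal_yield(model, species_F, focal, c, warm, equil_kwargs)
    fd = _focal_yield(model, species_F, focal, d, warm, equil_kwargs)
    while (b - a) > rel_tol * max(b, 1e-6):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = _focal_yield(model, species_F, focal, c, warm, equil_kwargs)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = _focal_yield(model, species_F, focal, d, warm, equil_kwargs)
    F_best = c if fc >= fd else d
    y_best = max(fc, fd)

    if B0 is None:
        state0, _ = model.project_to_equilibrium(None, **equil_kwargs)
        B0 = float(model.biomass(state0)[focal])
    return SpeciesRefPoints(
        species=species, F_MSY=float(F_best), yield_at_FMSY=float(y_best), B0=B0
    )


def estimate_all_fmsy(
    model: SizeSpectrumModel,
    initial_F: float = 0.5,
    max_rounds: int = 10,
    round_tol: float = 0.01,
    damping: float = 0.5,
    F_scan: Sequence[float] | None = None,
    rel_tol: float = 0.005,
    **equil_kwargs,
) -> dict[str, SpeciesRefPoints]:
    """Iterate the one-species-at-a-time F_MSY search to a fixed point.

    Each round re-estimates every species' F_MSY with the others held at the
    current estimates, moving each estimate a fraction ``damping`` of the way
    to its new value (damping suppresses the predator--prey feedback cycles a
    plain fixed-point sweep can fall into); rounds stop when no estimate
    moves by more than ``round_tol`` (relative), or after ``max_rounds``.
    """
    names = model.species_names
    state0, _ = model.project_to_equilibrium(None, **equil_kwargs)
    B0 = model.biomass(state0)
    current = np.full(len(names), float(initial_F))
    results: dict[str, SpeciesRefPoints] = {}
    for rnd in range(max_rounds):
        previous = current.copy()
        for i, name in enumerate(names):
            rp = estimate_species_fmsy(
                model,
                name,
                current,
                F_scan=F_scan,
                rel_tol=rel_tol,
                B0=float(B0[i]),
                warm_state=state0,
                **equil_kwargs,
            )
            current[i] = damping * rp.F_MSY + (1.0 - damping) * current[i]
            results[name] = SpeciesRefPoints(
                species=name,
                F_MSY=float(current[i]),
                yield_at_FMSY=rp.yield_at_FMSY,
                B0=float(B0[i]),
            )
        shift = float(np.max(np.abs(current - previous) / previous))
        logger.info("F_MSY round %d: max relative shift %.3g", rnd + 1, shift)
        if shift < round_tol:
            break
    return results


# ---------------------------------------------------------------------------
# Yield curves over the exploitation gradient
# ---------------------------------------------------------------------------

@dataclass
class YieldCurve:
    """Equilibrium outputs along an effort-multiplier gradient."""

    efforts: np.ndarray
    exploitation_rate: np.ndarray
    catch_by_species: pd.DataFrame  # index: effort, columns: species
    nutrient_yield: pd.DataFrame  # index: effort, columns: nutrients
    biomass_by_species: pd.DataFrame  # index: effort, columns: species
    community_biomass: np.ndarray
    fishable_biomass: np.ndarray
    mean_max_size: np.ndarray
    n_collapsed: np.ndarray
    collapsed_species: list[frozenset[str]]
    B0_by_species: pd.Series
    F_MSY: pd.Series  # the per-species F_MSY scaled by the effort axis
    truncated: bool = False

    @property
    def total_catch(self) -> np.ndarray:
        return self.catch_by_species.to_numpy().sum(axis=1)

    def with_profiles(
        self, profiles: Sequence["NutrientProfile"]
    ) -> "YieldCurve":
        """The same sweep with nutrient yields recomputed for new profiles.

        Catches and biomasses are equilibrium properties of the fishing
        policy alone, so swapping concentration profiles only rescales the
        nutrient yield columns.
        """
        conc = profiles_to_matrix(
            profiles, list(self.catch_by_species.columns)
        )
        nut = pd.DataFrame(
            NUTRIENT_UNIT_FACTOR * self.catch_by_species.to_numpy() @ conc,
            index=self.catch_by_species.index,
            columns=list(NUTRIENTS),
        )
        return replace(self, nutrient_yield=nut)


def sweep_effort(
    model: SizeSpectrumModel,
    refpoints: Mapping[str, SpeciesRefPoints],
    effort_grid: Sequence[float],
    profiles: Sequence[NutrientProfile],
    collapse_frac: float = 0.10,
    stop_biomass_frac: float = 0.10,
    stop_collapsed_frac: float = 0.50,
    mean_size_weighting: str = "biomass",
    **equil_kwargs,
) -> YieldCurve:
    """Build a yield curve by fishing every species at ``F_MSY_i * E``.

    The sweep starts unfished (E = 0), warm-starts each equilibrium from the
    previous one, flags a species as collapsed when its biomass falls below
    ``collapse_frac`` of unfished, and truncates after the first effort level
    at which community biomass drops below ``stop_biomass_frac`` of unfished
    or more than ``stop_collapsed_frac`` of species are collapsed.
    """
    effort_grid = np.asarray(effort_grid, dtype=float)
    if effort_grid[0] != 0.0:
        raise ValueError("effort grid must start at 0 (unfished)")
    if np.any(np.diff(effort_grid) <= 0):
        raise ValueError("effort grid must be strictly increasing")

    names = model.species_names
    fmsy = np.array([refpoints[s].F_MSY for s in names])
    conc = profiles_to_matrix(profiles, names)

    rows: list[dict] = []
    state: CommunityState | None = None
    B0 = None
    truncated = False
    for E in effort_grid:
        policy = model.policy_for_species_F(fmsy * E)
        state, report = model.project_to_equilibrium(
            policy, state=state, **equil_kwargs
        )
        if not report.converged:
            logger.warning(
                "sweep at E=%.3g did not converge (max rel change %.3g)",
                E, report.max_rel_change,
            )
        B = model.biomass(state)
        if B0 is None:
            B0 = B.copy()
        catches = model.species_yield(state, policy)
        collapsed = frozenset(
            n for n, b, b0 in zip(names, B, B0) if b < collapse_frac * b0
        )
        total_catch = float(catches.sum())
        total_biomass = float(B.sum())
        rows.append(
            {
                "effort": E,
                "catch": catches,
                "biomass": B,
                "fishable": model.fishable_biomass(state),
                "mean_size": model.mean_max_size(
                    state, mean_size_weighting,
                    catches if mean_size_weighting == "catch" else None,
                ),
                "collapsed": collapsed,
                "exploitation": (
                    total_catch / total_biomass if total_biomass > 0 else np.nan
                ),
            }
        )
        frac_collapsed = len(collapsed) / len(names)
        if (
            total_biomass < stop_biomass_frac * float(B0.sum())
            or frac_collapsed > stop_collapsed_frac
        ):
            truncated = True
            logger.info(
                "sweep stopped at E=%.3g (biomass fraction %.3g, "
                "collapsed fraction %.2f)",
                E, total_biomass / float(B0.sum()), frac_collapsed,
            )
            break

    efforts = np.array([r["effort"] for r in rows])
    catch_df = pd.DataFrame(
        [r["catch"] for r in rows], index=efforts, columns=names
    )
    nut_df = pd.DataFrame(
        NUTRIENT_UNIT_FACTOR * np.vstack([r["catch"] for r in rows]) @ conc,
        index=efforts,
        columns=list(NUTRIENTS),
    )
    biom_df = pd.DataFrame(
        [r["biomass"] for r in rows], index=efforts, columns=names
    )
    return YieldCurve(
        efforts=efforts,
        exploitation_rate=np.array([r["exploitation"] for r in rows]),
        catch_by_species=catch_df,
        nutrient_yield=nut_df,
        biomass_by_species=biom_df,
        community_biomass=np.array([r["biomass"].sum() for r in rows]),
        fishable_biomass=np.array([r["fishable"] for r in rows]),
        mean_max_size=np.array([r["mean_size"] for r in rows]),
        n_collapsed=np.array([len(r["collapsed"]) for r in rows]),
        collapsed_species=[r["collapsed"] for r in rows],
        B0_by_species=pd.Series(B0, index=names),
        F_MSY=pd.Series(fmsy, index=names),
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Curve summaries
# ---------------------------------------------------------------------------

def _refined_argmax(x: np.ndarray, y: np.ndarray) -> tuple[int, float, float]:
    """Grid argmax with local 3-point quadratic refinement.

    Returns ``(grid index, refined x, refined max)``; the refined location is
    clamped to the neighbouring grid interval.
    """
    k = int(np.argmax(y))
    if k == 0 or k == y.size - 1:
        return k, float(x[k]), float(y[k])
    x3 = x[k - 1 : k + 2]
    y3 = y[k - 1 : k + 2]
    a, b, c = np.polyfit(x3, y3, 2)
    if a >= 0:  # not locally concave: keep the grid point
        return k, float(x[k]), float(y[k])
    xv = float(np.clip(-b / (2.0 * a), x3[0], x3[-1]))
    yv = float(a * xv**2 + b * xv + c)
    return k, xv, max(yv, float(y[k]))


def _interp(x: np.ndarray, y: np.ndarray, x0: float) -> float:
    return float(np.interp(x0, x, y))


@dataclass
class CurveSummary:
    """mMSY/mMNY reference points extracted from a yield curve."""

    mMSY: float
    F_mMSY: float
    F_mMSY_idx: int
    exploitation_at_mMSY: float
    mMNY: dict[str, float]
    F_mMNY: dict[str, float]
    F_mMNY_idx: dict[str, int]
    exploitation_at_mMNY: dict[str, float]
    ratio: dict[str, float]  # F_mMNY / F_mMSY on the effort axis
    classification: dict[str, str]
    yield_at_mMSY_fraction: dict[str, float]
    tolerance: float


def summarise_curve(curve: YieldCurve, tolerance: float = 0.05) -> CurveSummary:
    """Locate mMSY and per-nutrient mMNY and classify over/underfishing.

    The argmax of each series is found on the effort grid and refined by a
    local quadratic; a nutrient is neutral when ``|F_mMNY/F_mMSY - 1|`` is
    within ``tolerance``, otherwise overfished (below) or underfished (above).
    """
    if curve.efforts.size < 3:
        raise ValueError("curve must have at least 3 effort levels")
    total = curve.total_catch
    if not np.any(total > 0):
        raise ValueError("total catch is zero everywhere; cannot locate mMSY")
    x = curve.efforts
    k_tot, F_tot, mmsy = _refined_argmax(x, total)

    mmny: dict[str, float] = {}
    f_mmny: dict[str, float] = {}
    idx: dict[str, int] = {}
    expl: dict[str, float] = {}
    ratio: dict[str, float] = {}
    klass: dict[str, str] = {}
    frac: dict[str, float] = {}
    for nut in curve.nutrient_yield.columns:
        y = curve.nutrient_yield[nut].to_numpy()
        if not np.any(y > 0):
            mmny[nut] = 0.0
            f_mmny[nut] = math.nan
            idx[nut] = -1
            expl[nut] = math.nan
            ratio[nut] = math.nan
            klass[nut] = "neutral"
            frac[nut] = math.nan
            continue
        k, Fn, yn = _refined_argmax(x, y)
        mmny[nut] = yn
        f_mmny[nut] = Fn
        idx[nut] = k
        expl[nut] = _interp(x, curve.exploitation_rate, Fn)
        r = Fn / F_tot
        ratio[nut] = r
        if math.isinf(tolerance) or abs(r - 1.0) <= tolerance:
            klass[nut] = "neutral"
        elif r < 1.0:
            klass[nut] = "overfished"
        else:
            klass[nut] = "underfished"
        # proportional series give the same refined argmax up to rounding
        if np.isclose(Fn, F_tot, rtol=1e-9, atol=1e-12):
            frac[nut] = 1.0
        else:
            frac[nut] = _interp(x, y, F_tot) / yn

    return CurveSummary(
        mMSY=mmsy,
        F_mMSY=F_tot,
        F_mMSY_idx=k_tot,
        exploitation_at_mMSY=_interp(x, curve.exploitation_rate, F_tot),
        mMNY=mmny,
        F_mMNY=f_mmny,
        F_mMNY_idx=idx,
        exploitation_at_mMNY=expl,
        ratio=ratio,
        classification=klass,
        yield_at_mMSY_fraction=frac,
        tolerance=tolerance,
    )


def rescale_curves(curve: YieldCurve) -> pd.DataFrame:
    """Every series as a proportion of its maximum (for reporting/plots).

    Series with a non-positive maximum are reported as all-missing.
    """
    out = pd.DataFrame(index=curve.efforts)
    out.index.name = "effort"

    def scaled(values: np.ndarray) -> np.ndarray:
        m = np.nanmax(values) if values.size else 0.0
        if not np.isfinite(m) or m <= 0:
            return np.full(values.shape, np.nan)
        return values / m

    out["total_catch"] = scaled(curve.total_catch)
    out["community_biomass"] = scaled(curve.community_biomass)
    out["fishable_biomass"] = scaled(curve.fishable_biomass)
    out["mean_max_size"] = scaled(curve.mean_max_size)
    for nut in curve.nutrient_yield.columns:
        out[f"yield_{nut}"] = scaled(curve.nutrient_yield[nut].to_numpy())
    return out
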