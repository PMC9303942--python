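"""Dynamic trait-based multispecies size-spectrum simulator.

The community is described by abundance densities :math:`N_i(w)` (numbers per
gram body mass) for each species *i* on a logarithmic body-mass grid, plus a
background resource spectrum that feeds the smallest individuals.  Individuals
encounter prey through a lognormal predator--prey mass-ratio kernel, split
assimilated energy between somatic growth and reproduction according to an
allometric energy budget, and die from size-based predation, a constant
allometric background rate, and size-selective fishing

.. math::

    F_{g,i}(w) = S_{g,i}(w)\\,Q_{g,i}\\,E_g

summed over gears *g*.  The population dynamics follow the
McKendrick--von Foerster transport equation

.. math::

    \\partial_t N + \\partial_w (g N) = -\\mu N

with a recruitment boundary flux capped by a Beverton--Holt
stock--recruitment relationship, and the resource follows semi-chemostat
dynamics.  Time stepping uses an implicit upwind sweep for the growth
transport combined with exact exponential decay for total mortality, which is
unconditionally stable and reproduces constant-mortality decay exactly.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import expit

try:  # compiled stepping kernel; pure-numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "GRAMS_PER_TONNE",
    "SizeGrid",
    "SpeciesParams",
    "ResourceParams",
    "GearSelectivity",
    "FishingPolicy",
    "CommunityState",
    "ConvergenceReport",
    "build_grid",
    "feeding_kernel",
    "trawl_selectivity",
    "fishing_mortality",
    "SizeSpectrumModel",
]

logger = logging.getLogger(__name__)

GRAMS_PER_TONNE = 1.0e6


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeGrid:
    """Logarithmic body-mass grid for the fish community and resource.

    Attributes
    ----------
    w : ndarray
        Fish body masses (g), strictly increasing, log-spaced.
    dw : ndarray
        Bin widths (g), consistent with the log spacing.
    w_full : ndarray
        Extended grid including resource sizes below ``w[0]``.
    dw_full : ndarray
        Bin widths on the extended grid.
    fish_offset : int
        Index of ``w[0]`` within ``w_full``.
    """

    w: np.ndarray
    dw: np.ndarray
    w_full: np.ndarray
    dw_full: np.ndarray
    fish_offset: int

    @property
    def n_bins(self) -> int:
        return self.w.size

    @property
    def log_step(self) -> float:
        return float(np.log(self.w[1] / self.w[0]))


def build_grid(
    w_min_global: float,
    w_max_global: float,
    n_bins: int,
    resource_decades: float = 3.0,
) -> SizeGrid:
    """Build a log-spaced body-mass grid with a resource extension.

    The fish grid spans ``[w_min_global, w_max_global]`` with ``n_bins``
    nodes at uniform logarithmic spacing; the resource grid extends the same
    spacing ``resource_decades`` decades below the smallest fish size.
    """
    if w_min_global <= 0 or w_max_global <= 0:
        raise ValueError("body masses must be positive")
    if w_min_global >= w_max_global:
        raise ValueError("w_min_global must be strictly below w_max_global")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")

    w = np.geomspace(w_min_global, w_max_global, n_bins)
    step = math.log(w_max_global / w_min_global) / (n_bins - 1)
    n_res = int(math.ceil(resource_decades * math.log(10.0) / step))
    w_full = w[0] * np.exp(step * np.arange(-n_res, n_bins))
    # bin widths follow the log spacing so that dw[k] = w[k+1] - w[k],
    # extrapolated for the last bin
    dw_full = w_full * math.expm1(step)
    dw = dw_full[n_res:]
    return SizeGrid(w=w, dw=dw, w_full=w_full, dw_full=dw_full, fish_offset=n_res)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SpeciesParams:
    """Life-history, feeding, mortality and recruitment traits of one species.

    Masses in grams, rates per year.  ``interaction`` is this species' row of
    the interaction matrix: availability :math:`\\theta_{ij} \\in [0, 1]` of
    each prey species *j* to this predator.
    """

    name: str
    w_min: float
    w_inf: float
    w_mat: float
    L_inf: float
    h: float
    n: float
    gamma: float
    q: float
    beta: float
    sigma: float
    alpha: float
    ks: float
    p: float
    mu_b0: float
    erepro: float
    R_max: float
    interaction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 < self.w_min < self.w_mat < self.w_inf):
            raise ValueError(
                f"species {self.name!r}: need 0 < w_min < w_mat < w_inf, got "
                f"w_min={self.w_min}, w_mat={self.w_mat}, w_inf={self.w_inf}"
            )
        if self.beta <= 1:
            raise ValueError(f"species {self.name!r}: beta must exceed 1")
        if self.sigma <= 0:
            raise ValueError(f"species {self.name!r}: sigma must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError(f"species {self.name!r}: alpha must be in (0, 1]")
        if self.R_max <= 0:
            raise ValueError(f"species {self.name!r}: R_max must be positive")
        if self.interaction is not None:
            self.interaction = np.asarray(self.interaction, dtype=float)


@dataclass(frozen=True)
class ResourceParams:
    """Semi-chemostat background resource spectrum.

    Carrying capacity is ``kappa * w**(-lam)`` up to ``w_res_max``;
    regeneration rate is ``r0 * w**(n-1)`` with the community intake
    exponent ``n``.
    """

    kappa: float
    lam: float
    r0: float
    w_res_max: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")


@dataclass(frozen=True)
class GearSelectivity:
    """Sigmoid trawl selectivity of one gear for one species."""

    gear: str
    species: str
    w50: float
    slope: float
    Q: float = 1.0

    def __post_init__(self) -> None:
        if self.w50 <= 0:
            raise ValueError("w50 must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.Q < 0:
            raise ValueError("catchability Q must be non-negative")

    def at(self, w: np.ndarray) -> np.ndarray:
        return trawl_selectivity(w, self.w50, self.slope)


@dataclass(frozen=True)
class FishingPolicy:
    """Relative fishing effort per gear, together with the gear selectivities."""

    efforts: Mapping[str, float]
    selectivities: tuple[GearSelectivity, ...]

    def __post_init__(self) -> None:
        for gear, effort in self.efforts.items():
            if effort < 0:
                raise ValueError(f"negative effort for gear {gear!r}")
        object.__setattr__(self, "selectivities", tuple(self.selectivities))

    @staticmethod
    def unfished(selectivities: Sequence[GearSelectivity]) -> "FishingPolicy":
        return FishingPolicy(
            efforts={s.gear: 0.0 for s in selectivities},
            selectivities=tuple(selectivities),
        )


@dataclass
class CommunityState:
    """Abundance densities of the fish community and resource."""

    N: np.ndarray  # (n_species, n_bins), numbers per g
    N_res: np.ndarray  # (n_full,), numbers per g
    t: float = 0.0

    def copy(self) -> "CommunityState":
        return CommunityState(N=self.N.copy(), N_res=self.N_res.copy(), t=self.t)


@dataclass(frozen=True)
class ConvergenceReport:
    converged: bool
    t_final: float
    n_steps: int
    max_rel_change: float


# ---------------------------------------------------------------------------
# Elementary rates
# ---------------------------------------------------------------------------

def trawl_selectivity(w, w50: float, slope: float):
    """Sigmoid trawl selectivity in log body mass, 0.5 at ``w50``."""
    w = np.asarray(w, dtype=float)
    return expit(slope * (np.log(w) - math.log(w50)))


def feeding_kernel(pred_mass, prey_mass, beta: float, sigma: float):
    """Lognormal predator--prey size-preference kernel.

    ``phi = exp(-(ln(w_pred / (beta * w_prey)))**2 / (2 sigma**2))``, maximal
    (= 1) when the predator is ``beta`` times heavier than its prey.
    """
    pred = np.asarray(pred_mass, dtype=float)
    prey = np.asarray(prey_mass, dtype=float)
    if np.any(pred <= 0) or np.any(prey <= 0):
        raise ValueError("body masses must be positive")
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.log(pred / (beta * prey))
    return np.exp(-(x**2) / (2.0 * sigma**2))


def fishing_mortality(
    policy: FishingPolicy, species: str, w: np.ndarray
) -> np.ndarray:
    """Fishing mortality at size: ``F_i(w) = sum_g S_gi(w) Q_gi E_g``."""
    known = {s.species for s in policy.selectivities}
    if species not in known:
        raise KeyError(f"species {species!r} not present in policy selectivities")
    w = np.asarray(w, dtype=float)
    F = np.zeros_like(w)
    for sel in policy.selectivities:
        if sel.species != species:
            continue
        effort = policy.efforts.get(sel.gear, 0.0)
        if effort < 0:
            raise ValueError(f"negative effort for gear {sel.gear!r}")
        F += sel.at(w) * sel.Q * effort
    return F


@njit(cache=True)
def _advance_compiled(
    N, N_res, F, dt, n_steps, theta, theta_T, kernel, search, intake_max,
    metab, psi, alpha, mu_b, R_max, erepro, w_min_arr, w_min_idx, dw, bw,
    res_rate, res_cc, off,
):  # pragma: no cover - exercised via the model API
    n_s, nw = N.shape
    nf = N_res.size
    for _ in range(n_steps):
        prey = np.dot(theta, N)
        E = np.empty((n_s, nw))
        weighted = np.empty(nf)
        M = np.empty((n_s, nf))
        for i in range(n_s):
            for b in range(nf):
                weighted[b] = N_res[b] * bw[b]
            for b in range(nw):
                weighted[off + b] += prey[i, b] * bw[off + b]
            E[i] = np.dot(kernel[i], weighted) * search[i]
        f = E / (E + intake_max)
        e_net = alpha.reshape(n_s, 1) * f * intake_max - metab
        for i in range(n_s):
            for a in range(nw):
                if e_net[i, a] < 0.0:
                    e_net[i, a] = 0.0
        g = e_net * (1.0 - psi)
        repro = e_net * psi
        pred_rate = (1.0 - f) * search * N * dw.reshape(1, nw)
        for i in range(n_s):
            M[i] = np.dot(pred_rate[i], kernel[i])
        mu_res = M.sum(axis=0)
        mu = np.dot(theta_T, M[:, off:].copy()) + mu_b.reshape(n_s, 1) + F
        E_repro = ((repro * N) * dw.reshape(1, nw)).sum(axis=1)
        R_di = erepro * E_repro / (2.0 * w_min_arr)
        R = R_max * R_di / (R_max + R_di)
        N_new = np.zeros_like(N)
        for i in range(n_s):
            k0 = w_min_idx[i]
            prev = (N[i, k0] + dt * R[i] / dw[k0]) / (1.0 + dt * g[i, k0] / dw[k0])
            N_new[i, k0] = prev
            for k in range(k0 + 1, nw):
                prev = (N[i, k] + dt * g[i, k - 1] / dw[k] * prev) / (
                    1.0 + dt * g[i, k] / dw[k]
                )
                N_new[i, k] = prev
        N_new *= np.exp(-mu * dt)
        N_res = (N_res + dt * res_rate * res_cc) / (
            1.0 + dt * (res_rate + mu_res)
        )
        N = N_new
    ok = np.all(np.isfinite(N)) and np.all(np.isfinite(N_res))
    return N, N_res, ok


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class SizeSpectrumModel:
    """Multispecies size-spectrum community with size-selective fishing.

    Parameters
    ----------
    species : sequence of SpeciesParams
    resource : ResourceParams
    gears : sequence of GearSelectivity
        All gears that can operate on this community; fishing policies refer
        to these by gear name.
    n_bins : int
        Number of fish size bins (log-spaced from the smallest ``w_min`` to
        the largest ``w_inf``).
    dt : float
        Default time step (yr).
    interaction : ndarray, optional
        Square interaction matrix ``theta[i, j]`` (predator i, prey j);
        overrides the per-species rows; defaults to all ones.
    """

    def __init__(
        self,
        species: Sequence[SpeciesParams],
        resource: ResourceParams,
        gears: Sequence[GearSelectivity] = (),
        n_bins: int = 100,
        dt: float = 0.1,
        resource_decades: float = 3.0,
        interaction: np.ndarray | None = None,
        grid: SizeGrid | None = None,
    ) -> None:
        if not species:
            raise ValueError("at least one species is required")
        self.species = list(species)
        self.resource = resource
        self.gears = tuple(gears)
        self.dt = float(dt)

        if grid is None:
            w_lo = min(sp.w_min for sp in self.species)
            w_hi = max(sp.w_inf for sp in self.species)
            grid = build_grid(w_lo, w_hi, n_bins, resource_decades)
        self.grid = grid

        n_s, nw, nf = len(self.species), grid.n_bins, grid.w_full.size
        w, w_full = grid.w, grid.w_full

        if interaction is not None:
            theta = np.asarray(interaction, dtype=float)
        elif all(sp.interaction is not None for sp in self.species):
            theta = np.vstack([sp.interaction for sp in self.species])
        else:
            theta = np.ones((n_s, n_s))
        if theta.shape != (n_s, n_s):
            raise ValueError(
                f"interaction matrix must be {n_s}x{n_s}, got {theta.shape}"
            )
        self.theta = np.ascontiguousarray(theta)
        self._theta_T = np.ascontiguousarray(theta.T)

        # per-species precomputed arrays
        self.intake_max = np.empty((n_s, nw))  # h w^n
        self.metab = np.empty((n_s, nw))  # ks w^p
        self.search = np.empty((n_s, nw))  # gamma w^q
        self.psi = np.empty((n_s, nw))  # maturity allocation
        self.kernel = np.empty((n_s, nw, nf))  # phi(w_pred / w_prey)
        self.mu_b = np.empty(n_s)
        self.w_min_idx = np.empty(n_s, dtype=int)
        for i, sp in enumerate(self.species):
            self.intake_max[i] = sp.h * w**sp.n
            self.metab[i] = sp.ks * w**sp.p
            self.search[i] = sp.gamma * w**sp.q
            sigmoid = 1.0 / (1.0 + (w / sp.w_mat) ** (-10.0))
            psi = sigmoid * (w / sp.w_inf) ** (1.0 - sp.n)
            psi[w >= sp.w_inf] = 1.0
            self.psi[i] = np.minimum(psi, 1.0)
            self.kernel[i] = feeding_kernel(
                w[:, None], w_full[None, :], sp.beta, sp.sigma
            )
            self.mu_b[i] = sp.mu_b0 * sp.w_inf ** (sp.n - 1.0)
            self.w_min_idx[i] = int(np.searchsorted(w, sp.w_min))

        self.alpha = np.array([sp.alpha for sp in self.species])
        self.R_max = np.array([sp.R_max for sp in self.species])
        self.erepro = np.array([sp.erepro for sp in self.species])
        self.w_min_arr = np.array([sp.w_min for sp in self.species])
        self.w_inf_arr = np.array([sp.w_inf for sp in self.species])
        self.L_inf_arr = np.array([sp.L_inf for sp in self.species])

        # resource carrying capacity and regeneration on the full grid
        n_mean = float(np.mean([sp.n for sp in self.species]))
        cc = resource.kappa * w_full ** (-resource.lam)
        cc[w_full > resource.w_res_max] = 0.0
        self.res_cc = cc
        self.res_rate = resource.r0 * w_full ** (n_mean - 1.0)

        # prey biomass weights: w * dw on the full grid
        self._bw = w_full * grid.dw_full

    # -- basic accessors ----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    # -- policies -----------------------------------------------------------

    def unfished_policy(self) -> FishingPolicy:
        return FishingPolicy.unfished(self.gears)

    def policy_for_species_F(
        self, F: Mapping[str, float] | Sequence[float]
    ) -> FishingPolicy:
        """Build a policy imposing a fully-selected mortality ``F_i`` per species.

        Requires a one-to-one mapping between species and gears (each species
        caught by exactly one dedicated gear with ``Q > 0``); the gear effort
        is then ``F_i / Q``.
        """
        if not isinstance(F, Mapping):
            F = dict(zip(self.species_names, F))
        by_species: dict[str, GearSelectivity] = {}
        for sel in self.gears:
            if sel.species in by_species:
                raise ValueError(
                    f"species {sel.species!r} is targeted by multiple gears; "
                    "per-species fishing mortality needs a dedicated gear"
                )
            by_species[sel.species] = sel
        gear_targets: dict[str, set[str]] = {}
        for sel in self.gears:
            gear_targets.setdefault(sel.gear, set()).add(sel.species)
        efforts = {sel.gear: 0.0 for sel in self.gears}
        for name, f_val in F.items():
            if f_val < 0:
                raise ValueError(f"negative fishing mortality for {name!r}")
            sel = by_species.get(name)
            if sel is None:
                raise KeyError(f"no gear targets species {name!r}")
            if len(gear_targets[sel.gear]) > 1:
                raise ValueError(
                    f"gear {sel.gear!r} targets multiple species; cannot set "
                    "per-species fishing mortality independently"
                )
            if sel.Q <= 0 and f_val > 0:
                raise ValueError(f"no fishable selectivity for species {name!r}")
            efforts[sel.gear] = f_val / sel.Q if sel.Q > 0 else 0.0
        return FishingPolicy(efforts=efforts, selectivities=self.gears)

    def fishing_mortality_matrix(self, policy: FishingPolicy) -> np.ndarray:
        """Per-species fishing mortality at size, shape (n_species, n_bins)."""
        F = np.zeros((self.n_species, self.grid.n_bins))
        name_to_idx = {n: i for i, n in enumerate(self.species_names)}
        for sel in policy.selectivities:
            i = name_to_idx.get(sel.species)
            if i is None:
                raise KeyError(
                    f"policy selects unknown species {sel.species!r}"
                )
            effort = policy.efforts.get(sel.gear, 0.0)
            if effort < 0:
                raise ValueError(f"negative effort for gear {sel.gear!r}")
            if effort == 0.0 or sel.Q == 0.0:
                continue
            F[i] += sel.at(self.grid.w) * sel.Q * effort
        return F

    # -- rates --------------------------------------------------------------

    def encounter(self, state: CommunityState) -> np.ndarray:
        """Encountered prey biomass flux per predator species (g/yr)."""
        N, N_res = state.N, state.N_res
        if N.shape != (self.n_species, self.grid.n_bins):
            raise ValueError("state dimensions do not match the model grid")
        off = self.grid.fish_offset
        prey = np.broadcast_to(N_res, (self.n_species, N_res.size)).copy()
        prey[:, off:] += self.theta @ N
        weighted = prey * self._bw
        enc = np.matmul(self.kernel, weighted[:, :, None])[:, :, 0]
        return self.search * enc

    def feeding_level(self, state: CommunityState) -> np.ndarray:
        """Realised intake as a fraction of maximum intake, in [0, 1]."""
        E = self.encounter(state)
        return E / (E + self.intake_max)

    def growth_and_repro(
        self, feeding: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Somatic growth g(w) and reproduction energy flux (both g/yr)."""
        e_net = np.maximum(
            self.alpha[:, None] * feeding * self.intake_max - self.metab, 0.0
        )
        return e_net * (1.0 - self.psi), e_net * self.psi

    def growth_rate(self, feeding: np.ndarray) -> np.ndarray:
        return self.growth_and_repro(feeding)[0]

    def _predation_fields(
        self, state: CommunityState, feeding: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predation mortality on fish (n_s, nw) and on the resource (nf,)."""
        pred_rate = (
            (1.0 - feeding) * self.search * state.N * self.grid.dw
        )  # (n_s, nw)
        M = np.matmul(pred_rate[:, None, :], self.kernel)[:, 0, :]  # (n_s, nf)
        mu_res = M.sum(axis=0)
        mu_fish = self.theta.T @ M[:, self.grid.fish_offset :]
        return mu_fish, mu_res

    def total_mortality(
        self, state: CommunityState, policy: FishingPolicy | None = None
    ) -> np.ndarray:
        """Predation + background + fishing mortality, per species at size."""
        feeding = self.feeding_level(state)
        mu_fish, _ = self._predation_fields(state, feeding)
        mu = mu_fish + self.mu_b[:, None]
        if policy is not None:
            mu = mu + self.fishing_mortality_matrix(policy)
        return mu

    def recruitment(
        self, state: CommunityState, repro_energy: np.ndarray | None = None
    ) -> np.ndarray:
        """Beverton--Holt-capped recruitment flux (numbers/yr per species)."""
        if repro_energy is None:
            _, repro_energy = self.growth_and_repro(self.feeding_level(state))
        E_repro = np.sum(repro_energy * state.N * self.grid.dw, axis=1)
        R_di = self.erepro * E_repro / (2.0 * self.w_min_arr)
        return self.R_max * R_di / (self.R_max + R_di)

    # -- stepping -----------------------------------------------------------

    def step(
        self,
        state: CommunityState,
        policy: FishingPolicy | np.ndarray | None = None,
        dt: float | None = None,
    ) -> CommunityState:
        """Advance the community one time step.

        ``policy`` may be a :class:`FishingPolicy` or a precomputed fishing
        mortality matrix; ``None`` means unfished.
        """
        dt = self.dt if dt is None else float(dt)
        if dt <= 0:
            raise ValueError("dt must be positive")
        F = self._as_F_matrix(policy)
        N_new, Nres_new = self._advance(state.N, state.N_res, F, dt)
        return CommunityState(N=N_new, N_res=Nres_new, t=state.t + dt)

    def _as_F_matrix(
        self, policy: FishingPolicy | np.ndarray | None
    ) -> np.ndarray:
        if policy is None:
            return np.zeros((self.n_species, self.grid.n_bins))
        if isinstance(policy, FishingPolicy):
            return self.fishing_mortality_matrix(policy)
        F = np.asarray(policy, dtype=float)
        if F.shape != (self.n_species, self.grid.n_bins):
            raise ValueError("fishing mortality matrix has wrong shape")
        return F

    def _advance(
        self,
        N: np.ndarray,
        N_res: np.ndarray,
        F: np.ndarray,
        dt: float,
        n_steps: int = 1,
    ) -> tuple[np.ndarray, np.ndarray]:
        if _HAVE_NUMBA:
            N_new, N_res_new, ok = _advance_compiled(
                np.ascontiguousarray(N),
                np.ascontiguousarray(N_res),
                np.ascontiguousarray(F),
                float(dt),
                int(n_steps),
                self.theta,
                self._theta_T,
                self.kernel,
                self.search,
                self.intake_max,
                self.metab,
                self.psi,
                self.alpha,
                self.mu_b,
                self.R_max,
                self.erepro,
                self.w_min_arr,
                self.w_min_idx,
                self.grid.dw,
                self._bw,
                self.res_rate,
                self.res_cc,
                self.grid.fish_offset,
            )
            if not ok:
                raise RuntimeError(
                    "size-spectrum step produced non-finite densities "
                    "(numerical blow-up)"
                )
            return N_new, N_res_new
        for _ in range(n_steps):
            N, N_res = self._advance_numpy(N, N_res, F, dt)
        return N, N_res

    def _advance_numpy(
        self, N: np.ndarray, N_res: np.ndarray, F: np.ndarray, dt: float
    ) -> tuple[np.ndarray, np.ndarray]:
        state = CommunityState(N=N, N_res=N_res)
        feeding = self.feeding_level(state)
        g, repro = self.growth_and_repro(feeding)
        mu_fish, mu_res = self._predation_fields(state, feeding)
        mu = mu_fish + self.mu_b[:, None] + F
        R = self.recruitment(state, repro)

        dw = self.grid.dw
        nw = self.grid.n_bins
        N_new = np.zeros_like(N)
        ab = np.zeros((2, nw))
        for i in range(self.n_species):
            k0 = self.w_min_idx[i]
            m = nw - k0
            gi = g[i, k0:]
            ab[0, :m] = 1.0 + dt * gi / dw[k0:]
            ab[1, : m - 1] = -dt * gi[:-1] / dw[k0 + 1 :]
            rhs = N[i, k0:].copy()
            rhs[0] += dt * R[i] / dw[k0]
            N_new[i, k0:] = solve_banded(
                (1, 0), ab[:, :m], rhs, overwrite_ab=True, overwrite_b=True
            )
        # exact exponential decay for mortality (operator splitting)
        N_new *= np.exp(-mu * dt)
        N_res_new = (N_res + dt * self.res_rate * self.res_cc) / (
            1.0 + dt * (self.res_rate + mu_res)
        )
        if not (np.all(np.isfinite(N_new)) and np.all(np.isfinite(N_res_new))):
            raise RuntimeError(
                "size-spectrum step produced non-finite densities "
                "(numerical blow-up)"
            )
        np.maximum(N_new, 0.0, out=N_new)
        return N_new, N_res_new

    # -- initialisation and equilibrium -------------------------------------

    def initial_state(self, depletion: float = 0.01) -> CommunityState:
        """Power-law initial condition scaled off the resource spectrum."""
        w = self.grid.w
        N = np.zeros((self.n_species, w.size))
        for i, sp in enumerate(self.species):
            mask = (w >= sp.w_min) & (w <= sp.w_inf)
            N[i, mask] = (
                depletion
                * self.resource.kappa
                * w[mask] ** (-self.resource.lam)
                / self.n_species
            )
        return CommunityState(N=N, N_res=self.res_cc.copy(), t=0.0)

    def project_to_equilibrium(
        self,
        policy: FishingPolicy | np.ndarray | None = None,
        state: CommunityState | None = None,
        tol: float = 1e-5,
        t_max: float = 600.0,
        window: float = 10.0,
        check_every: float = 1.0,
        dt: float | None = None,
    ) -> tuple[CommunityState, ConvergenceReport]:
        """Run the dynamics until the community biomass stabilises.

        Convergence requires the relative change of every species' biomass,
        per year averaged over a trailing ``window`` (yr), to fall below
        ``tol``.  Returns the final state and a convergence report.
        """
        if tol <= 0:
            raise ValueError("tol must be positive")
        dt = self.dt if dt is None else float(dt)
        state = self.initial_state() if state is None else state.copy()
        F = self._as_F_matrix(policy)

        steps_per_check = max(1, int(round(check_every / dt)))
        n_window = max(1, int(round(window / (steps_per_check * dt))))
        history: deque[np.ndarray] = deque(maxlen=n_window + 1)

        bw = self.grid.w * self.grid.dw
        B = state.N @ bw
        history.append(B)
        floor = max(B.sum(), self.res_cc @ self._bw) * 1e-12

        t, n_steps = 0.0, 0
        max_rel = np.inf
        converged = False
        while t < t_max - 1e-9:
            chunk = min(
                steps_per_check, max(1, int(round((t_max - t) / dt)))
            )
            state.N, state.N_res = self._advance(
                state.N, state.N_res, F, dt, n_steps=chunk
            )
            state.t += chunk * dt
            t += chunk * dt
            n_steps += chunk
            B = state.N @ bw
            history.append(B)
            if len(history) == n_window + 1:
                span = len(history) - 1
                rel = np.abs(B - history[0]) / np.maximum(B, floor)
                # species whose biomass is negligible at community scale are
                # exempt: a stock decaying towards zero never stabilises in
                # relative terms but contributes nothing to any output
                B_tot = max(B.sum(), history[0].sum())
                if self.n_species > 1 and B_tot > 0:
                    rel[np.maximum(B, history[0]) < 1e-6 * B_tot] = 0.0
                max_rel = float(rel.max() / (span * steps_per_check * dt))
                if max_rel < tol:
                    converged = True
                    break
        report = ConvergenceReport(
            converged=converged, t_final=state.t, n_steps=n_steps,
            max_rel_change=max_rel,
        )
        logger.debug(
            "projection: converged=%s t=%.1f steps=%d max_rel_change=%.3g",
            report.converged, report.t_final, report.n_steps,
            report.max_rel_change,
        )
        return state, report

    # -- outputs ------------------------------------------------------------

    def biomass(self, state: CommunityState) -> np.ndarray:
        """Per-species biomass (tonnes)."""
        return (state.N @ (self.grid.w * self.grid.dw)) / GRAMS_PER_TONNE

    def species_yield(
        self, state: CommunityState, policy: FishingPolicy | np.ndarray | None
    ) -> np.ndarray:
        """Per-species catch rate ``C_i = int F_i(w) N_i(w) w dw`` (tonnes/yr)."""
        F = self._as_F_matrix(policy)
        bw = self.grid.w * self.grid.dw
        return ((F * state.N) @ bw) / GRAMS_PER_TONNE

    def fishable_biomass(
        self, state: CommunityState, selectivities: Sequence[GearSelectivity] | None = None
    ) -> float:
        """Biomass weighted by the best available selectivity at size (tonnes)."""
        sels = self.gears if selectivities is None else tuple(selectivities)
        w = self.grid.w
        total = 0.0
        bw = w * self.grid.dw
        for i, name in enumerate(self.species_names):
            S = [sel.at(w) for sel in sels if sel.species == name]
            if not S:
                continue
            S_max = np.maximum.reduce(S)
            total += float((S_max * state.N[i]) @ bw)
        return total / GRAMS_PER_TONNE

    def mean_max_size(
        self,
        state: CommunityState,
        weighting: str = "biomass",
        catches: np.ndarray | None = None,
    ) -> float:
        """Weighted mean of species' asymptotic length L_inf (cm)."""
        if weighting == "biomass":
            weights = self.biomass(state)
        elif weighting == "catch":
            if catches is None:
                raise ValueError("catch weighting requires catches")
            weights = np.asarray(catches, dtype=float)
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        total = weights.sum()
        if total <= 0:
            return float("nan")
        return float((weights * self.L_inf_arr).sum() / total)

    def biomass_indicators(
        self,
        state: CommunityState,
        policy: FishingPolicy | None = None,
        weighting: str = "biomass",
    ) -> dict:
        """Community biomass, fishable biomass, mean maximum size, per-species biomass."""
        per_species = self.biomass(state)
        sels = policy.selectivities if policy is not None else self.gears
        catches = (
            self.species_yield(state, policy) if weighting == "catch" else None
        )
        return {
            "community_biomass": float(per_species.sum()),
            "fishable_biomass": self.fishable_biomass(state, sels),
            "mean_max_size": self.mean_max_size(state, weighting, catches),
            "species_biomass": dict(zip(self.species_names, per_species)),
        }
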