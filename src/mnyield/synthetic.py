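"""Synthetic communities, nutrient profiles and catch tables.

Generates every input the pipeline consumes: a generic interacting fish
community with log-spaced asymptotic sizes, per-species trawl gears and
lognormal nutrient concentration profiles; regional catch tables with skewed
catch shares, rank-incomplete taxonomy and length-correlated vulnerability
scores; and small communities with a nutrient deliberately loaded onto a
resilient or vulnerable species for directional checks.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .refpoints import NUTRIENTS, NutrientProfile
from .sizespectrum import (
    GearSelectivity,
    ResourceParams,
    SizeSpectrumModel,
    SpeciesParams,
)

__all__ = [
    "CommunitySpec",
    "CatchTableSpec",
    "CommunityBundle",
    "NutrientLoadingFixture",
    "make_generic_community",
    "make_catch_table",
    "make_nutrient_loading_fixture",
]

# Standard trait-based community allometry.  Exponents and coefficients are
# the conventional choices for this model class: intake exponent n = 3/4,
# search exponent q = 0.8, resource exponent lambda = 2 + q - n.
_N = 0.75
_P = 0.75
_Q = 0.8
_LAMBDA = 2.0 + _Q - _N
_BETA = 100.0
_SIGMA = 1.3
_ALPHA = 0.6
_H = 30.0  # maximum intake coefficient, g^(1-n)/yr
_F0 = 0.6  # expected feeding level on an unperturbed resource spectrum
_FC = 0.2  # critical feeding level fixing the metabolic coefficient
_KS = _FC * _ALPHA * _H  # valid because p = n
_MU_B0 = 0.6
_EREPRO = 0.1
_KAPPA = 1.0e11
_R0 = 4.0
_W_RES_MAX = 100.0
_W_EGG = 1.0e-3
_RMAX_COEF = 10.0  # R_max = coef * kappa * w_inf^(-1.5)

# Median concentration per 100 g edible tissue and lognormal log-sd, loosely
# on the scale of the seven nutrients' customary units.
_NUTRIENT_MEDIANS = {
    "calcium": 40.0,  # mg
    "iron": 1.0,  # mg
    "zinc": 0.8,  # mg
    "selenium": 30.0,  # ug
    "vitamin_a": 20.0,  # ug
    "vitamin_d": 5.0,  # ug
    "omega3": 0.4,  # g
}
_NUTRIENT_LOG_SD = 0.6
_SIZE_LOADING = -0.7  # correlation of log concentration with log w_inf


def default_resource() -> ResourceParams:
    """The standard background resource spectrum used by all generators."""
    return ResourceParams(
        kappa=_KAPPA, lam=_LAMBDA, r0=_R0, w_res_max=_W_RES_MAX
    )


@dataclass(frozen=True)
class CommunitySpec:
    """Specification of a generic interacting community.

    ``recruitment_level`` is the unfished ratio of realised recruitment to
    its Beverton--Holt ceiling ``R_max``; reproduction efficiencies are
    calibrated so every species sits at this level, which controls how
    strongly stocks respond to fishing (closer to 1 = more resilient).
    """

    n_species: int = 15
    w_inf_range: tuple[float, float] = (10.0, 1.0e5)
    nutrient_model: str = "independent"  # or "size-correlated"
    seed: int = 0
    gears_per_species: int = 1
    recruitment_level: float = 0.9

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be at least 1")
        lo, hi = self.w_inf_range
        if not (0 < lo < hi):
            raise ValueError("w_inf_range must be positive and increasing")
        if self.nutrient_model not in ("independent", "size-correlated"):
            raise ValueError(f"unknown nutrient model {self.nutrient_model!r}")
        if not 0 < self.recruitment_level < 1:
            raise ValueError("recruitment_level must be in (0, 1)")


@dataclass
class CommunityBundle:
    """A complete simulator input set."""

    species: list[SpeciesParams]
    gears: list[GearSelectivity]
    profiles: list[NutrientProfile]
    resource: ResourceParams

    def model(self, **kwargs) -> SizeSpectrumModel:
        return SizeSpectrumModel(
            self.species, self.resource, self.gears, **kwargs
        )


def _length_from_mass(w_inf: float) -> float:
    """Asymptotic length (cm) from the standard length-weight relation w = 0.01 L^3."""
    return (w_inf / 0.01) ** (1.0 / 3.0)


def _gamma_for_f0(kappa: float) -> float:
    """Search-volume coefficient giving feeding level f0 on the resource spectrum."""
    lam = _LAMBDA
    denom = (
        (1.0 - _F0)
        * math.sqrt(2.0 * math.pi)
        * kappa
        * _SIGMA
        * _BETA ** (lam - 2.0)
        * math.exp((lam - 2.0) ** 2 * _SIGMA**2 / 2.0)
    )
    return _F0 * _H / denom


def make_generic_community(spec: CommunitySpec) -> CommunityBundle:
    """Generate a generic interacting community with varying nutrient content.

    Asymptotic masses are log-spaced across ``w_inf_range``; maturation is at
    a quarter of the asymptotic mass; maximum recruitment scales as
    ``w_inf**-1.5``.  Each species gets a dedicated trawl gear selecting at
    5% of its asymptotic mass with catchability 1.  Nutrient concentrations
    are lognormal per nutrient and, in ``size-correlated`` mode, loaded
    negatively on log asymptotic mass (smaller species are richer).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    if n == 1:
        w_inf = np.array([math.sqrt(spec.w_inf_range[0] * spec.w_inf_range[1])])
    else:
        w_inf = np.geomspace(*spec.w_inf_range, n)
    gamma = _gamma_for_f0(_KAPPA)

    species: list[SpeciesParams] = []
    gears: list[GearSelectivity] = []
    for i, wi in enumerate(w_inf):
        name = f"sp{i + 1:02d}"
        species.append(
            SpeciesParams(
                name=name,
                w_min=_W_EGG,
                w_inf=float(wi),
                w_mat=0.25 * float(wi),
                L_inf=_length_from_mass(float(wi)),
                h=_H,
                n=_N,
                gamma=gamma,
                q=_Q,
                beta=_BETA,
                sigma=_SIGMA,
                alpha=_ALPHA,
                ks=_KS,
                p=_P,
                mu_b0=_MU_B0,
                erepro=_EREPRO,
                R_max=_RMAX_COEF * _KAPPA * float(wi) ** -1.5,
                interaction=np.ones(n),
            )
        )
        gears.append(
            GearSelectivity(
                gear=f"trawl_{name}",
                species=name,
                w50=0.05 * float(wi),
                slope=3.0,
                Q=1.0,
            )
        )

    z_size = -(np.log(w_inf) - np.log(w_inf).mean())
    sd = z_size.std()
    z_size = z_size / sd if sd > 0 else np.zeros(n)
    profiles: list[NutrientProfile] = []
    log_conc = {}
    for nutrient in NUTRIENTS:
        eps = rng.standard_normal(n)
        if spec.nutrient_model == "size-correlated":
            rho = -_SIZE_LOADING  # positive loading on z_size = -log w_inf
            z = rho * z_size + math.sqrt(1.0 - rho**2) * eps
        else:
            z = eps
        log_conc[nutrient] = (
            math.log(_NUTRIENT_MEDIANS[nutrient]) + _NUTRIENT_LOG_SD * z
        )
    for i, sp in enumerate(species):
        profiles.append(
            NutrientProfile(
                species=sp.name,
                concentrations={
                    nut: float(np.exp(log_conc[nut][i])) for nut in NUTRIENTS
                },
            )
        )

    resource = default_resource()
    bundle = CommunityBundle(
        species=species, gears=gears, profiles=profiles, resource=resource
    )
    _calibrate_recruitment(bundle, spec.recruitment_level)
    return bundle


def _calibrate_recruitment(
    bundle: CommunityBundle,
    level: float | np.ndarray,
    passes: int = 2,
    n_bins: int = 80,
) -> None:
    """Set reproduction efficiencies so unfished R/R_max equals ``level``.

    The unfished ratio of density-independent egg production to maximum
    recruitment, ``rho = R_di / R_max``, fixes how hard a stock can be fished
    before recruitment declines; the target ``level = rho / (1 + rho)`` may
    be a scalar or per-species array.  Each pass runs the community to its
    unfished equilibrium and rescales ``erepro`` towards the target
    (in place).
    """
    level = np.asarray(level, dtype=float)
    rho_target = level / (1.0 - level)
    for _ in range(passes):
        model = bundle.model(n_bins=n_bins)
        state, _ = model.project_to_equilibrium()
        _, repro = model.growth_and_repro(model.feeding_level(state))
        E_repro = np.sum(repro * state.N * model.grid.dw, axis=1)
        R_di = model.erepro * E_repro / (2.0 * model.w_min_arr)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = rho_target * model.R_max / R_di
        for sp, s in zip(bundle.species, scale):
            if np.isfinite(s) and s > 0:
                sp.erepro = float(np.clip(sp.erepro * s, 1e-8, 1.0))


# ---------------------------------------------------------------------------
# Catch tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatchTableSpec:
    """Specification of a synthetic regional catch table."""

    n_regions: int = 30
    taxa_per_region: tuple[int, int] = (8, 25)
    share_skew: float = 1.5  # lognormal sigma of catch shares
    rank_missing_rate: float = 0.3  # fraction demoted to genus/family rank
    vuln_length_corr: float = 0.6
    seed: int = 0
    n_pool: int = 60  # size of the global species pool

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_pool < 1:
            raise ValueError("counts must be at least 1")
        if not 0 <= self.rank_missing_rate <= 1:
            raise ValueError("rank_missing_rate must be in [0, 1]")
        if not -1 <= self.vuln_length_corr <= 1:
            raise ValueError("vuln_length_corr must be in [-1, 1]")


def make_catch_table(
    spec: CatchTableSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a regional catch table and the matching species-profile table.

    Returns ``(catch, profiles)``.  ``catch`` has columns ``region, taxon,
    rank, catch_tonnes, vulnerability``; ``profiles`` is keyed by species with
    ``genus`` and ``family`` lineage columns plus one column per nutrient.
    Catch shares are lognormal with sigma ``share_skew``; a
    ``rank_missing_rate`` fraction of records is demoted to genus or family
    rank (losing its species-level profile); vulnerability (1-100) follows a
    Gaussian copula with the stated correlation to asymptotic length.
    """
    rng = np.random.default_rng(spec.seed)
    n_pool = spec.n_pool
    n_fam = max(2, n_pool // 8)
    n_gen = max(n_fam, n_pool // 3)

    genus_of_species = rng.integers(0, n_gen, size=n_pool)
    family_of_genus = rng.integers(0, n_fam, size=n_gen)
    sp_names = [f"Genus{genus_of_species[i]:02d} species{i:03d}" for i in range(n_pool)]
    genus_names = [f"Genus{g:02d}" for g in range(n_gen)]
    family_names = [f"Family{f:02d}" for f in range(n_fam)]

    log_len = rng.normal(math.log(30.0), 0.8, size=n_pool)  # lengths ~ cm
    z_len = (log_len - log_len.mean()) / log_len.std()
    rho = spec.vuln_length_corr
    z_v = rho * z_len + math.sqrt(1.0 - rho**2) * rng.standard_normal(n_pool)
    vulnerability = 1.0 + 99.0 * norm.cdf(z_v)

    conc = {
        nut: np.exp(
            math.log(_NUTRIENT_MEDIANS[nut])
            + _NUTRIENT_LOG_SD * rng.standard_normal(n_pool)
        )
        for nut in NUTRIENTS
    }
    profiles = pd.DataFrame(
        {
            "species": sp_names,
            "genus": [genus_names[g] for g in genus_of_species],
            "family": [family_names[family_of_genus[g]] for g in genus_of_species],
            **conc,
        }
    )

    lo, hi = spec.taxa_per_region
    records = []
    for r in range(spec.n_regions):
        region = f"region{r + 1:03d}"
        k = int(rng.integers(lo, hi + 1))
        k = min(k, n_pool)
        idx = rng.choice(n_pool, size=k, replace=False)
        shares = np.exp(spec.share_skew * rng.standard_normal(k))
        shares /= shares.sum()
        total = float(np.exp(rng.normal(math.log(1.0e5), 0.5)))
        demote = rng.random(k) < spec.rank_missing_rate
        to_family = rng.random(k) < 0.5
        for j, i_sp in enumerate(idx):
            if demote[j]:
                g = genus_of_species[i_sp]
                if to_family[j]:
                    rank = "family"
                    taxon = family_names[family_of_genus[g]]
                else:
                    rank = "genus"
                    taxon = genus_names[g]
                # higher-rank records carry the group-mean vulnerability
                if rank == "genus":
                    members = genus_of_species == g
                else:
                    members = np.array(
                        [family_of_genus[gg] == family_of_genus[g] for gg in genus_of_species]
                    )
                vuln = float(vulnerability[members].mean())
            else:
                rank = "species"
                taxon = sp_names[i_sp]
                vuln = float(vulnerability[i_sp])
            records.append(
                {
                    "region": region,
                    "taxon": taxon,
                    "rank": rank,
                    "catch_tonnes": float(total * shares[j]),
                    "vulnerability": vuln,
                }
            )
    catch = pd.DataFrame.from_records(records)
    return catch, profiles


# ---------------------------------------------------------------------------
# Directional loading fixtures
# ---------------------------------------------------------------------------

@dataclass
class NutrientLoadingFixture:
    """A small community with one nutrient concentrated on one species."""

    bundle: CommunityBundle
    nutrient: str
    target_species: str
    target_class: str  # "resilient" or "vulnerable"


# The loading fixture community: a resilient forage species coexisting with
# two mid-size bystanders and two large piscivores whose juveniles and adults
# prey on the forage.  Fishing down the piscivores releases the forage from
# predation, so its catch keeps rising beyond the community-wide optimum —
# the mechanism that makes a nutrient carried by a resilient species
# underfished at maximum total catch, and one carried by a vulnerable
# piscivore overfished.
_LOADING_W_INF = (100.0, 250.0, 450.0, 2000.0, 9000.0)
_LOADING_RMAX_BOOST = (1.0, 1.0, 1.0, 5.0, 5.0)
_LOADING_RECRUIT_LEVEL = (0.95, 0.5, 0.5, 0.35, 0.35)
_LOADING_R0 = 50.0  # near-chemostat resource: interactions act via predation


def make_nutrient_loading_fixture(
    target_class: str,
    seed: int = 0,
    nutrient: str = "selenium",
) -> NutrientLoadingFixture:
    """Build a community whose ``nutrient`` sits on an extreme-F_MSY species.

    ``target_class="resilient"`` concentrates the nutrient on the smallest,
    most resilient species (a lightly density-dependent forage fish with the
    highest single-species F_MSY); ``"vulnerable"`` concentrates it on the
    largest piscivore, the most vulnerable stock.  The community structure is
    fixed by design (sizes, relative recruitment ceilings and recruitment
    levels above); only the nutrient profiles depend on ``seed``.
    """
    if target_class not in ("resilient", "vulnerable"):
        raise ValueError(f"unknown target class {target_class!r}")
    bundle = make_generic_community(CommunitySpec(n_species=5, seed=seed))
    for sp, gear, wi, boost in zip(
        bundle.species, bundle.gears, _LOADING_W_INF, _LOADING_RMAX_BOOST
    ):
        sp.w_inf = wi
        sp.w_mat = 0.25 * wi
        sp.L_inf = _length_from_mass(wi)
        sp.R_max = boost * _RMAX_COEF * _KAPPA * wi**-1.0
    bundle.gears = [
        GearSelectivity(
            gear=f"trawl_{sp.name}", species=sp.name,
            w50=0.05 * sp.w_inf, slope=3.0, Q=1.0,
        )
        for sp in bundle.species
    ]
    bundle.resource = ResourceParams(
        kappa=bundle.resource.kappa, lam=bundle.resource.lam,
        r0=_LOADING_R0, w_res_max=bundle.resource.w_res_max,
    )
    _calibrate_recruitment(bundle, np.array(_LOADING_RECRUIT_LEVEL))

    idx = 0 if target_class == "resilient" else len(bundle.species) - 1
    target = bundle.species[idx].name
    loaded_high = 50.0 * _NUTRIENT_MEDIANS[nutrient]
    loaded_low = 0.02 * _NUTRIENT_MEDIANS[nutrient]
    for prof in bundle.profiles:
        prof.concentrations[nutrient] = (
            loaded_high if prof.species == target else loaded_low
        )
    return NutrientLoadingFixture(
        bundle=bundle,
        nutrient=nutrient,
        target_species=target,
        target_class=target_class,
    )
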