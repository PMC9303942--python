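"""Evenness--vulnerability analysis of catch composition.

Implements the catch-data framework for predicting nutrient over- and
underfishing without a full ecosystem model: for each region the evenness of
each nutrient's catch among taxa (Pielou's J, Shannon diversity over log
richness) and the mean fishing vulnerability of the taxa supplying it,
weighted by their nutrient catch.  A nutrient supplied by taxa less
vulnerable than those supplying total catch is classed resilient (potential
nutrient underfishing: its maximum sits above the fishing level that
maximises total catch); more vulnerable is classed vulnerable (potential
nutrient overfishing).

Two vulnerability currencies are supported: simulated single-species F_MSY
(model mode, where higher F_MSY means *less* vulnerable) and the intrinsic
vulnerability index on a 1-100 scale used with catch tables (where higher
means *more* vulnerable).  Taxa recorded at genus or family rank inherit the
mean nutrient profile of their group's species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .refpoints import NUTRIENTS, NUTRIENT_UNIT_FACTOR

__all__ = [
    "SIX_NUTRIENTS",
    "FrameworkResult",
    "pielou_evenness",
    "weighted_vulnerability",
    "nutrient_weights",
    "resolve_profiles",
    "classify_nutrient_model",
    "classify_nutrient_index",
    "regional_summary",
    "global_deviation_summary",
    "simulated_catch_framework",
    "framework_results_to_frame",
]

logger = logging.getLogger(__name__)

#: Nutrients used in catch-table mode (vitamin D concentrations are not
#: available for most marine fish in global catch databases).
SIX_NUTRIENTS = tuple(n for n in NUTRIENTS if n != "vitamin_d")

VALID_RANKS = ("species", "genus", "family")


def pielou_evenness(weights) -> float:
    """Pielou's evenness J of a composition: Shannon diversity / ln(richness).

    Richness counts taxa with positive weight only; a single-taxon
    composition is defined as maximally uneven (J = 0).
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or np.any(w < 0):
        raise ValueError("weights must be a non-empty, non-negative vector")
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("at least one weight must be positive")
    if w.size == 1:
        return 0.0
    p = w / w.sum()
    shannon = float(-xlogy(p, p).sum())  # xlogy: p ln p with 0 ln 0 = 0
    return shannon / math.log(w.size)


def weighted_vulnerability(weights, vuln) -> float:
    """Mean vulnerability of taxa, weighted by their catch or nutrient catch.

    ``vuln`` may be single-species F_MSY (1/yr, model mode) or an intrinsic
    vulnerability index (1-100, catch-table mode); the result is on the same
    scale.  Raises if a positively-weighted taxon lacks a vulnerability
    score.
    """
    if isinstance(weights, pd.Series) and isinstance(vuln, pd.Series):
        vuln = vuln.reindex(weights.index)
        labels = weights.index
        w = weights.to_numpy(dtype=float)
        v = vuln.to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        v = np.asarray(vuln, dtype=float)
        labels = pd.RangeIndex(w.size)
    if w.shape != v.shape:
        raise ValueError("weights and vulnerabilities are not aligned")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    bad = (w > 0) & ~np.isfinite(v)
    if np.any(bad):
        raise ValueError(
            "missing vulnerability for positively-weighted taxa: "
            f"{list(labels[bad])}"
        )
    return float(np.where(w > 0, w * v, 0.0).sum() / total)


def resolve_profiles(
    records: pd.DataFrame,
    species_profiles: pd.DataFrame,
    nutrients=SIX_NUTRIENTS,
) -> tuple[pd.DataFrame, int]:
    """Attach nutrient concentrations to catch records, by taxonomic fallback.

    Species-rank records get their own profile; genus- and family-rank
    records get the unweighted mean concentration of the species in that
    group.  Records whose taxon cannot be resolved are dropped, with the
    count returned (and logged).

    ``records`` needs columns ``region, taxon, rank, catch_tonnes,
    vulnerability``; ``species_profiles`` needs ``species, genus, family``
    plus one column per nutrient.
    """
    required = {"region", "taxon", "rank", "catch_tonnes", "vulnerability"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"catch records lack columns: {sorted(missing)}")
    bad_rank = set(records["rank"]) - set(VALID_RANKS)
    if bad_rank:
        raise ValueError(f"unknown taxonomic ranks: {sorted(bad_rank)}")

    nutrients = list(nutrients)
    by_species = species_profiles.set_index("species")[nutrients]
    by_genus = species_profiles.groupby("genus")[nutrients].mean()
    by_family = species_profiles.groupby("family")[nutrients].mean()
    lookup = {"species": by_species, "genus": by_genus, "family": by_family}

    parts = []
    n_excluded = 0
    for rank, table in lookup.items():
        sub = records[records["rank"] == rank]
        if sub.empty:
            continue
        joined = sub.join(table, on="taxon", how="left")
        unresolved = joined[nutrients[0]].isna()
        n_excluded += int(unresolved.sum())
        parts.append(joined[~unresolved])
    resolved = (
        pd.concat(parts).sort_index()
        if parts
        else records.iloc[0:0].assign(**{n: [] for n in nutrients})
    )
    if n_excluded:
        logger.info(
            "resolve_profiles: excluded %d records with no resolvable profile",
            n_excluded,
        )
    return resolved, n_excluded


def nutrient_weights(resolved: pd.DataFrame, nutrient: str) -> pd.Series:
    """Per-taxon nutrient-yield weights: catch x concentration x 1e4.

    Records of the same taxon are merged (catches summed) before weighting.
    """
    if nutrient not in resolved.columns:
        raise KeyError(f"records not resolved for nutrient {nutrient!r}")
    w = resolved["catch_tonnes"] * resolved[nutrient] * NUTRIENT_UNIT_FACTOR
    return w.groupby(resolved["taxon"]).sum()


def classify_nutrient_model(weighted_fmsy: float, reference_fmsy: float) -> str:
    """Class from F_MSY-weighted vulnerability: higher F_MSY = more resilient.

    ``resilient`` (nutrient underfishing) when the nutrient-catch-weighted
    mean F_MSY exceeds the reference (total-catch) value, ``vulnerable``
    (nutrient overfishing) when below, ``neutral`` on a tie.
    """
    if weighted_fmsy <= 0 or reference_fmsy <= 0:
        raise ValueError("F_MSY values must be positive")
    if weighted_fmsy > reference_fmsy:
        return "resilient"
    if weighted_fmsy < reference_fmsy:
        return "vulnerable"
    return "neutral"


def classify_nutrient_index(weighted_vuln: float, reference_vuln: float) -> str:
    """Class on the intrinsic-vulnerability scale (higher = more vulnerable)."""
    if weighted_vuln < reference_vuln:
        return "resilient"
    if weighted_vuln > reference_vuln:
        return "vulnerable"
    return "neutral"


@dataclass
class FrameworkResult:
    """Per-region evenness and vulnerability of nutrient and total catches."""

    region: str
    evenness: dict[str, float]  # per nutrient
    vulnerability: dict[str, float]  # per nutrient (index scale)
    evenness_total: float
    vulnerability_total: float
    delta_vulnerability: dict[str, float]  # V_n - V_tot
    classification: dict[str, str]
    mean_evenness: float
    mean_vulnerability: float
    sem2_evenness: float
    sem2_vulnerability: float


def regional_summary(
    records: pd.DataFrame,
    species_profiles: pd.DataFrame,
    nutrients=SIX_NUTRIENTS,
) -> list[FrameworkResult]:
    """Evenness--vulnerability summary of every region in a catch table.

    For each region and nutrient: Pielou evenness of the nutrient catch,
    nutrient-catch-weighted mean intrinsic vulnerability, its deviation from
    the total-catch value, and the resulting class.  The region mean and
    2 SEM are taken across the nutrients (sample SEM, n = len(nutrients)).
    Regions with no resolvable or all-zero catch are skipped and logged.
    """
    nutrients = list(nutrients)
    resolved, _ = resolve_profiles(records, species_profiles, nutrients)
    results: list[FrameworkResult] = []
    for region, sub in resolved.groupby("region", sort=True):
        catch = sub.groupby("taxon")["catch_tonnes"].sum()
        if catch.sum() <= 0:
            logger.info("region %s skipped: zero total catch", region)
            continue
        vuln = sub.groupby("taxon")["vulnerability"].first()
        J_tot = pielou_evenness(catch.to_numpy())
        V_tot = weighted_vulnerability(catch, vuln)
        J: dict[str, float] = {}
        V: dict[str, float] = {}
        dV: dict[str, float] = {}
        klass: dict[str, str] = {}
        for nut in nutrients:
            w = nutrient_weights(sub, nut)
            if w.sum() <= 0:
                logger.info(
                    "region %s nutrient %s skipped: zero nutrient catch",
                    region, nut,
                )
                J[nut] = math.nan
                V[nut] = math.nan
                dV[nut] = math.nan
                klass[nut] = "neutral"
                continue
            J[nut] = pielou_evenness(w.to_numpy())
            V[nut] = weighted_vulnerability(w, vuln)
            dV[nut] = V[nut] - V_tot
            klass[nut] = classify_nutrient_index(V[nut], V_tot)
        j_vals = np.array([J[n] for n in nutrients])
        v_vals = np.array([V[n] for n in nutrients])
        n_eff = len(nutrients)
        results.append(
            FrameworkResult(
                region=str(region),
                evenness=J,
                vulnerability=V,
                evenness_total=J_tot,
                vulnerability_total=V_tot,
                delta_vulnerability=dV,
                classification=klass,
                mean_evenness=float(np.nanmean(j_vals)),
                mean_vulnerability=float(np.nanmean(v_vals)),
                sem2_evenness=2.0 * float(np.nanstd(j_vals, ddof=1))
                / math.sqrt(n_eff),
                sem2_vulnerability=2.0 * float(np.nanstd(v_vals, ddof=1))
                / math.sqrt(n_eff),
            )
        )
    return results


def global_deviation_summary(
    results: list[FrameworkResult], nutrients=SIX_NUTRIENTS
) -> pd.DataFrame:
    """Fractions of regions where each nutrient catch is less or more
    vulnerable than total catch (negative / positive deviation), with ties
    counted separately."""
    if not results:
        raise ValueError("no regional results")
    rows = []
    for nut in nutrients:
        dv = np.array(
            [r.delta_vulnerability.get(nut, math.nan) for r in results]
        )
        dv = dv[np.isfinite(dv)]
        n = dv.size
        rows.append(
            {
                "nutrient": nut,
                "n_regions": n,
                "frac_negative": float((dv < 0).sum() / n) if n else math.nan,
                "frac_positive": float((dv > 0).sum() / n) if n else math.nan,
                "frac_zero": float((dv == 0).sum() / n) if n else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("nutrient")


def simulated_catch_framework(curve, summary, refpoints, profiles) -> pd.DataFrame:
    """Model-mode framework: evenness and F_MSY-weighted vulnerability of
    simulated catches at each nutrient's maximum, against total catch at the
    total-catch maximum.

    The vulnerability currency is each species' simulated F_MSY, so higher
    values mean *less* vulnerable; a nutrient whose catch-weighted mean F_MSY
    exceeds the total-catch value is classed resilient (expected
    F_mMNY > F_mMSY), and conversely vulnerable.
    """
    from .refpoints import NUTRIENT_UNIT_FACTOR, profiles_to_matrix

    names = list(curve.catch_by_species.columns)
    fmsy = pd.Series({s: refpoints[s].F_MSY for s in names})
    conc = profiles_to_matrix(profiles, names)
    catch_at_mmsy = curve.catch_by_species.iloc[summary.F_mMSY_idx]
    J_tot = pielou_evenness(catch_at_mmsy.to_numpy())
    V_tot = weighted_vulnerability(catch_at_mmsy, fmsy)
    rows = []
    for j, nut in enumerate(curve.nutrient_yield.columns):
        idx = summary.F_mMNY_idx[nut]
        if idx < 0:
            continue
        w = (
            curve.catch_by_species.iloc[idx]
            * conc[:, j]
            * NUTRIENT_UNIT_FACTOR
        )
        if w.sum() <= 0:
            continue
        V_n = weighted_vulnerability(w, fmsy)
        rows.append(
            {
                "nutrient": nut,
                "evenness": pielou_evenness(w.to_numpy()),
                "weighted_fmsy": V_n,
                "evenness_total": J_tot,
                "weighted_fmsy_total": V_tot,
                "classification": classify_nutrient_model(V_n, V_tot),
            }
        )
    return pd.DataFrame(rows).set_index("nutrient")


def framework_results_to_frame(results: list[FrameworkResult]) -> pd.DataFrame:
    """Tidy one-row-per-region-and-nutrient view of framework results."""
    rows = []
    for r in results:
        for nut in r.evenness:
            rows.append(
                {
                    "region": r.region,
                    "nutrient": nut,
                    "evenness": r.evenness[nut],
                    "vulnerability": r.vulnerability[nut],
                    "evenness_total": r.evenness_total,
                    "vulnerability_total": r.vulnerability_total,
                    "delta_vulnerability": r.delta_vulnerability[nut],
                    "classification": r.classification[nut],
                    "mean_evenness": r.mean_evenness,
                    "mean_vulnerability": r.mean_vulnerability,
                    "sem2_evenness": r.sem2_evenness,
                    "sem2_vulnerability": r.sem2_vulnerability,
                }
            )
    return pd.DataFrame(rows)
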