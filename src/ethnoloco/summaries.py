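"""Society-level summary statistics: modality presence, versatility,
set overlap, ecological and functional breakdowns, gender engagement.

Conventions
-----------
* Statistics derived from the full-sample presence/absence codes carry
  both a raw proportion and a phylogenetically corrected one (corrected
  via :mod:`ethnoloco.correction` when a weight table or distance matrix
  is supplied).
* Ecological, functional-domain and gender breakdowns are reported raw
  only; each output table carries a ``corrected`` tag so the policy is
  explicit per statistic rather than global.
* Special-activity shares are corrected with isolation weights re-derived
  on the exact denominator subsample (societies with documented
  subsistence functionality in that modality).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ethnoloco.coding import SocietyCodes
from ethnoloco.correction import (
    DEFAULT_N_RESAMPLES,
    DEFAULT_SEED,
    corrected_distribution,
    corrected_proportion,
)
from ethnoloco.ethnodata import (
    APPLICABLE_MODALITIES,
    NON_BIPEDAL,
    Biome6,
    FunctionalDomain,
    GenderCode,
    Modality,
    Proficiency,
    SocietyRecord,
    SpecialActivity,
    biome_simplify,
)
from ethnoloco.phyloweight import isolation_weights

__all__ = [
    "biome_simplify",
    "modality_presence_counts",
    "higher_proficiency_shares",
    "versatility_histogram",
    "venn_proportions",
    "ecology_breakdown",
    "functional_domain_proportions",
    "special_activity_stats",
    "gender_proportions",
    "coastal_split",
    "summarize_all",
]

SPECIAL_PAIRS = [
    (Modality.running, SpecialActivity.persistence_hunting),
    (Modality.climbing, SpecialActivity.honey_climbing),
    (Modality.diving, SpecialActivity.underwater_hunting),
]


def _presence_map(codes: Sequence[SocietyCodes], modality: Modality) -> dict[str, int]:
    return {sc.society_id: int(sc[modality].present) for sc in codes}


def modality_presence_counts(
    codes: Sequence[SocietyCodes],
    weights: pd.DataFrame | None = None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Count of societies engaging in each modality, with raw and (when
    full-sample isolation weights are given) corrected proportions."""
    n = len(codes)
    rows = []
    for m in Modality:
        trait = _presence_map(codes, m)
        k = sum(trait.values())
        row = {
            "modality": m.value,
            "n_present": k,
            "n_total": n,
            "raw_prop": k / n if n else math.nan,
            "corrected": weights is not None,
        }
        if weights is not None:
            est = corrected_proportion(
                trait, weights, n_resamples, seed, label=f"presence[{m.value}]"
            )
            row["corrected_prop"] = est.corrected_value
            row["mc_se"] = est.mc_se
        rows.append(row)
    return pd.DataFrame(rows)


def higher_proficiency_shares(
    codes: Sequence[SocietyCodes],
    dist: pd.DataFrame | None = None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Share of 'higher'-proficiency societies among those engaging in
    each modality; weights re-derived on each engaging subsample."""
    rows = []
    for m in Modality:
        engaged = [sc for sc in codes if sc[m].present]
        k = sum(sc[m].proficiency is Proficiency.higher for sc in engaged)
        row = {
            "modality": m.value,
            "n_higher": k,
            "n_present": len(engaged),
            "raw_prop": k / len(engaged) if engaged else math.nan,
            "corrected": dist is not None,
        }
        if dist is not None and len(engaged) >= 2:
            sub = [sc.society_id for sc in engaged]
            w = isolation_weights(dist, sub)
            trait = {
                sc.society_id: int(sc[m].proficiency is Proficiency.higher)
                for sc in engaged
            }
            est = corrected_proportion(
                trait, w, n_resamples, seed, label=f"higher[{m.value}]"
            )
            row["corrected_prop"] = est.corrected_value
            row["mc_se"] = est.mc_se
        rows.append(row)
    return pd.DataFrame(rows)


def versatility_histogram(
    codes: Sequence[SocietyCodes],
    weights: pd.DataFrame | None = None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Distribution of societies by number of non-bipedal modalities
    (climbing, swimming, diving) engaged in, plus the any-non-bipedal
    indicator and the count engaging all three locomotor domains
    (terrestrial + arboreal + aquatic)."""
    n = len(codes)
    k_map = {sc.society_id: sc.n_non_bipedal for sc in codes}
    any_nb = {s: int(k > 0) for s, k in k_map.items()}
    all_domains = {
        sc.society_id: int(
            sc[Modality.running].present
            and sc[Modality.climbing].present
            and (sc[Modality.swimming].present or sc[Modality.diving].present)
        )
        for sc in codes
    }
    dist_est = (
        corrected_distribution(k_map, weights, n_resamples, seed, label="versatility")
        if weights is not None
        else None
    )
    rows = []
    for k in range(4):
        count = sum(v == k for v in k_map.values())
        row = {
            "stratum": str(k),
            "count": count,
            "n_total": n,
            "raw_prop": count / n if n else math.nan,
            "corrected": weights is not None,
        }
        if dist_est is not None:
            est = dist_est.get(k)
            row["corrected_prop"] = est.corrected_value if est else 0.0
            row["mc_se"] = est.mc_se if est else 0.0
        rows.append(row)
    for label, trait in (("any_non_bipedal", any_nb), ("all_three_domains", all_domains)):
        count = sum(trait.values())
        row = {
            "stratum": label,
            "count": count,
            "n_total": n,
            "raw_prop": count / n if n else math.nan,
            "corrected": weights is not None,
        }
        if weights is not None:
            est = corrected_proportion(trait, weights, n_resamples, seed, label=label)
            row["corrected_prop"] = est.corrected_value
            row["mc_se"] = est.mc_se
        rows.append(row)
    return pd.DataFrame(rows)


_REGION_ORDER = ["none", "C", "S", "D", "CS", "CD", "SD", "CSD"]


def _region(sc: SocietyCodes) -> str:
    tag = ""
    if sc[Modality.climbing].present:
        tag += "C"
    if sc[Modality.swimming].present:
        tag += "S"
    if sc[Modality.diving].present:
        tag += "D"
    return tag or "none"


def venn_proportions(
    codes: Sequence[SocietyCodes],
    weights: pd.DataFrame | None = None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Seven-region set overlap of climbing/swimming/diving engagement
    (plus the none region).  The region masses partition the sample, so
    the seven non-empty regions sum to the any-non-bipedal mass."""
    n = len(codes)
    region_map = {sc.society_id: _region(sc) for sc in codes}
    dist_est = (
        corrected_distribution(region_map, weights, n_resamples, seed, label="venn")
        if weights is not None
        else None
    )
    rows = []
    for region in _REGION_ORDER:
        count = sum(v == region for v in region_map.values())
        row = {
            "region": region,
            "count": count,
            "raw_prop": count / n if n else math.nan,
            "corrected": weights is not None,
        }
        if dist_est is not None:
            est = dist_est.get(region)
            row["corrected_prop"] = est.corrected_value if est else 0.0
            row["mc_se"] = est.mc_se if est else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def ecology_breakdown(
    codes: Sequence[SocietyCodes], societies: Sequence[SocietyRecord]
) -> dict[str, pd.DataFrame]:
    """Raw (uncorrected) ecological breakdowns.

    Returns ``by_biome`` (per biome x modality: societies present, split
    by proficiency level) and ``temperature`` (per modality: minimum mean
    annual temperature at which it is present, and engagement among
    societies below 0 degrees C).
    """
    soc_by_id = {s.society_id: s for s in societies}
    rows = []
    for biome in Biome6:
        in_biome = [
            sc for sc in codes if soc_by_id[sc.society_id].biome6 is biome
        ]
        for m in Modality:
            present = [sc for sc in in_biome if sc[m].present]
            rows.append(
                {
                    "biome6": biome.value,
                    "modality": m.value,
                    "n_societies": len(in_biome),
                    "n_present": len(present),
                    "n_basic": sum(
                        sc[m].proficiency is Proficiency.basic for sc in present
                    ),
                    "n_higher": sum(
                        sc[m].proficiency is Proficiency.higher for sc in present
                    ),
                    "corrected": False,
                }
            )
    by_biome = pd.DataFrame(rows)

    temp_rows = []
    cold = [sc for sc in codes if soc_by_id[sc.society_id].mean_annual_temp_C < 0.0]
    for m in Modality:
        temps = [
            soc_by_id[sc.society_id].mean_annual_temp_C
            for sc in codes
            if sc[m].present
        ]
        temp_rows.append(
            {
                "modality": m.value,
                "n_present": len(temps),
                "min_temp_C": min(temps) if temps else math.nan,
                "max_temp_C": max(temps) if temps else math.nan,
                "n_below_0C_present": sum(sc[m].present for sc in cold),
                "n_below_0C_total": len(cold),
                "corrected": False,
            }
        )
    return {"by_biome": by_biome, "temperature": pd.DataFrame(temp_rows)}


def functional_domain_proportions(
    codes: Sequence[SocietyCodes],
) -> tuple[pd.DataFrame, list[str]]:
    """Per modality x functional domain: share of engaging societies with
    that domain documented, raw only.

    Masked (not applicable) cells — observation outside climbing, travel
    outside running/swimming — are reported with ``applicable=False`` and
    a NaN proportion, never as zero.  A domain observed in a masked cell
    is a data error and is returned as a diagnostic line.
    """
    rows = []
    diagnostics: list[str] = []
    for m in Modality:
        engaged = [sc for sc in codes if sc[m].present]
        for dom in FunctionalDomain:
            allowed = APPLICABLE_MODALITIES.get(dom)
            applicable = allowed is None or m in allowed
            k = sum(dom in sc[m].functional_domains for sc in engaged)
            if not applicable and k:
                offenders = [
                    sc.society_id for sc in engaged if dom in sc[m].functional_domains
                ]
                diagnostics.append(
                    f"domain {dom.value} recorded for {m.value} "
                    f"(not applicable) in: {', '.join(offenders)}"
                )
            rows.append(
                {
                    "modality": m.value,
                    "domain": dom.value,
                    "applicable": applicable,
                    "numerator": k if applicable else 0,
                    "denominator": len(engaged),
                    "raw_prop": (
                        k / len(engaged) if applicable and engaged else math.nan
                    ),
                    "corrected": False,
                }
            )
    return pd.DataFrame(rows), diagnostics


def special_activity_stats(
    codes: Sequence[SocietyCodes],
    dist: pd.DataFrame | None = None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Persistence hunting, honey climbing and underwater hunting as a
    share of the societies with documented subsistence functionality in
    the corresponding modality; isolation weights are re-derived on that
    denominator subsample."""
    rows = []
    for m, activity in SPECIAL_PAIRS:
        denom = [
            sc
            for sc in codes
            if sc[m].present and FunctionalDomain.subsistence in sc[m].functional_domains
        ]
        k = sum(activity in sc[m].special_activities for sc in denom)
        row = {
            "modality": m.value,
            "activity": activity.value,
            "numerator": k,
            "denominator": len(denom),
            "raw_prop": k / len(denom) if denom else math.nan,
            "corrected": dist is not None,
        }
        if dist is not None and len(denom) >= 2:
            w = isolation_weights(dist, [sc.society_id for sc in denom])
            trait = {
                sc.society_id: int(activity in sc[m].special_activities)
                for sc in denom
            }
            est = corrected_proportion(
                trait, w, n_resamples, seed, label=f"{activity.value}"
            )
            row["corrected_prop"] = est.corrected_value
            row["mc_se"] = est.mc_se
        rows.append(row)
    return pd.DataFrame(rows)


def gender_proportions(codes: Sequence[SocietyCodes]) -> pd.DataFrame:
    """Distribution of gender-engagement codes per modality among the
    societies with sufficient information (gender != insufficient_info),
    raw only."""
    rows = []
    categories = [g for g in GenderCode if g is not GenderCode.insufficient_info]
    for m in Modality:
        coded = [
            sc
            for sc in codes
            if sc[m].present and sc[m].gender is not GenderCode.insufficient_info
        ]
        denom = len(coded)
        for g in categories:
            k = sum(sc[m].gender is g for sc in coded)
            rows.append(
                {
                    "modality": m.value,
                    "gender": g.value,
                    "count": k,
                    "denominator": denom,
                    "raw_prop": k / denom if denom else math.nan,
                    "corrected": False,
                }
            )
    return pd.DataFrame(rows)


def coastal_split(
    codes: Sequence[SocietyCodes],
    societies: Sequence[SocietyRecord],
    threshold_km: float = 50.0,
) -> pd.DataFrame:
    """Inland (strictly more than ``threshold_km`` from the coast) versus
    coastal counts among societies engaging in each aquatic modality."""
    soc_by_id = {s.society_id: s for s in societies}
    rows = []
    for m in (Modality.swimming, Modality.diving):
        present = [sc for sc in codes if sc[m].present]
        inland = sum(
            soc_by_id[sc.society_id].coast_distance_km > threshold_km for sc in present
        )
        rows.append(
            {
                "modality": m.value,
                "n_inland": inland,
                "n_coastal": len(present) - inland,
                "n_present": len(present),
                "threshold_km": threshold_km,
                "corrected": False,
            }
        )
    return pd.DataFrame(rows)


def summarize_all(
    codes: Sequence[SocietyCodes],
    societies: Sequence[SocietyRecord],
    dist: pd.DataFrame | None = None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = DEFAULT_SEED,
    coast_threshold_km: float = 50.0,
) -> dict:
    """Run every summary statistic and return a JSON-serializable bundle.

    When a patristic distance matrix is supplied, full-sample isolation
    weights drive the corrected statistics, and subsample statistics
    (higher proficiency, special activities) re-derive their own weights.
    """
    weights = None
    if dist is not None and len(codes) >= 2:
        weights = isolation_weights(dist, [sc.society_id for sc in codes])
    domains_table, domain_diags = functional_domain_proportions(codes)
    out = {
        "n_societies": len(codes),
        "modality_presence": modality_presence_counts(
            codes, weights, n_resamples, seed
        ),
        "higher_proficiency": higher_proficiency_shares(codes, dist, n_resamples, seed),
        "versatility": versatility_histogram(codes, weights, n_resamples, seed),
        "venn": venn_proportions(codes, weights, n_resamples, seed),
        "ecology": ecology_breakdown(codes, societies),
        "functional_domains": domains_table,
        "functional_domain_diagnostics": domain_diags,
        "special_activities": special_activity_stats(codes, dist, n_resamples, seed),
        "gender": gender_proportions(codes),
        "coastal": coastal_split(codes, societies, coast_threshold_km),
        "n_resamples": n_resamples,
        "seed": seed,
    }
    return out


def summaries_to_json(bundle: Mapping) -> dict:
    """Convert the summarize_all bundle to plain JSON types."""
    def convert(v):
        if isinstance(v, pd.DataFrame):
            return v.replace({np.nan: None}).to_dict(orient="records")
        if isinstance(v, dict):
            return {k: convert(x) for k, x in v.items()}
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    return {k: convert(v) for k, v in bundle.items()}
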