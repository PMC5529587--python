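"""Analysis tables: one row per offspring, responses and predictors.

Responses: survival at day 1 (hatching), day 6 and day 12, and body mass /
tarsus length at days 6 and 12.  Predictors: clutch size, clutch order,
sex, microsatellite heterozygosity, number of functional MHC alleles, the
presence/absence of the common functional alleles, and (survival only) the
three parental MHC similarity measures.

Risk-set bookkeeping mirrors the study design: the day-1 analysis covers
every embryo; the day-6 analysis covers hatched chicks excluding
non-natural deaths (chicks killed by neighbouring adults cannot inform
natural survival); the day-12 analysis covers chicks alive on day 6.
Growth responses cover chicks alive (and measured) on the respective day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASE_PREDICTORS = ["clutch_size", "clutch_order", "sex",
                   "heterozygosity", "n_fa"]
SIMILARITY_PREDICTORS = ["proportion_shared", "allele_distance", "fa_distance"]

SURVIVAL_RESPONSES = ("survival_day1", "survival_day6", "survival_day12")
GROWTH_RESPONSES = ("mass_day6", "mass_day12", "tarsus_day6", "tarsus_day12")


@dataclass
class SurvivalBookkeeping:
    n_total: int
    n_unhatched: int
    n_hatched: int
    n_dead_before_day6: int
    n_excluded_nonnatural: int
    n_day6_rows: int
    n_alive_day6: int
    n_dead_before_day12: int
    n_alive_day12: int

    def as_dict(self) -> dict:
        return vars(self).copy()


REQUIRED_COLUMNS = [
    "individual", "mother", "father", "aviary", "clutch_id",
    "clutch_order", "clutch_size", "sex",
    "survived_day1", "survived_day6", "survived_day12", "nonnatural_death",
    "mass_day6", "mass_day12", "tarsus_day6", "tarsus_day12",
]


def validate_phenotypes(pheno: pd.DataFrame) -> list[str]:
    """Return a list of schema problems (empty when clean)."""
    issues = [f"missing column: {c}" for c in REQUIRED_COLUMNS
              if c not in pheno.columns]
    if not issues:
        for col in ("survived_day1", "survived_day6", "survived_day12"):
            vals = set(pheno[col].dropna().unique())
            if not vals <= {0, 1}:
                issues.append(f"{col} has values outside {{0,1}}: {sorted(vals)[:5]}")
        # survival must be monotone: alive at day 12 implies alive at day 6
        s = pheno[["survived_day1", "survived_day6", "survived_day12"]].fillna(0)
        if ((s["survived_day12"] > s["survived_day6"])
                | (s["survived_day6"] > s["survived_day1"])).any():
            issues.append("survival columns violate day12 <= day6 <= day1")
    return issues


def survival_bookkeeping(pheno: pd.DataFrame) -> SurvivalBookkeeping:
    """Risk-set counts for the three survival analyses."""
    n_total = len(pheno)
    hatched = pheno[pheno["survived_day1"] == 1]
    dead6 = hatched[hatched["survived_day6"] == 0]
    nonnat = dead6[dead6["nonnatural_death"] == 1]
    alive6 = hatched[hatched["survived_day6"] == 1]
    dead12 = alive6[alive6["survived_day12"] == 0]
    return SurvivalBookkeeping(
        n_total=n_total,
        n_unhatched=n_total - len(hatched),
        n_hatched=len(hatched),
        n_dead_before_day6=len(dead6),
        n_excluded_nonnatural=len(nonnat),
        n_day6_rows=len(hatched) - len(nonnat),
        n_alive_day6=len(alive6),
        n_dead_before_day12=len(dead12),
        n_alive_day12=len(alive6) - len(dead12),
    )


def _merge_predictors(pheno: pd.DataFrame,
                      fa_presence: pd.DataFrame,
                      heterozygosity: pd.Series,
                      pair_similarity: pd.DataFrame | None,
                      common_fas: list[str]) -> pd.DataFrame:
    tab = pheno.copy()
    tab["sex"] = tab["sex"].map({"M": 1, "F": 0, 1: 1, 0: 0}).astype(float)
    tab = tab.merge(heterozygosity.rename("heterozygosity"),
                    left_on="individual", right_index=True, how="left")
    fa = fa_presence.copy()
    fa["n_fa"] = fa.sum(axis=1)
    keep = [c for c in common_fas if c in fa.columns] + ["n_fa"]
    tab = tab.merge(fa[keep], left_on="individual", right_index=True, how="left")
    if pair_similarity is not None:
        sim = pair_similarity.set_index("pair")
        key = tab["mother"].astype(str) + "|" + tab["father"].astype(str)
        for col in ("proportion_shared", "allele_distance", "fa_distance"):
            tab[col] = key.map(sim[col])
    return tab


def build_analysis_table(pheno: pd.DataFrame,
                         fa_presence: pd.DataFrame,
                         heterozygosity: pd.Series,
                         common_fas: list[str],
                         pair_similarity: pd.DataFrame | None = None,
                         response: str = "survival_day6") -> tuple[pd.DataFrame, list[str]]:
    """Build the per-response analysis table and its predictor list.

    Returns (table, predictors); rows are restricted to the response's
    risk set, and rows with missing predictors are dropped (logged via the
    returned table's attrs["n_dropped_incomplete"]).
    """
    issues = validate_phenotypes(pheno)
    if issues:
        raise ValueError("invalid phenotype table: " + "; ".join(issues))
    tab = _merge_predictors(pheno, fa_presence, heterozygosity,
                            pair_similarity, common_fas)

    if response == "survival_day1":
        sub = tab.copy()
        sub["survival_day1"] = sub["survived_day1"].astype(float)
    elif response == "survival_day6":
        sub = tab[tab["survived_day1"] == 1].copy()
        sub = sub[~((sub["survived_day6"] == 0) & (sub["nonnatural_death"] == 1))]
        sub["survival_day6"] = sub["survived_day6"].astype(float)
    elif response == "survival_day12":
        sub = tab[tab["survived_day6"] == 1].copy()
        sub["survival_day12"] = sub["survived_day12"].astype(float)
    elif response in ("mass_day6", "tarsus_day6"):
        sub = tab[tab["survived_day6"] == 1].copy()
    elif response in ("mass_day12", "tarsus_day12"):
        sub = tab[tab["survived_day12"] == 1].copy()
    else:
        raise ValueError(f"unknown response {response!r}")

    predictors = BASE_PREDICTORS + [c for c in common_fas if c in sub.columns]
    if response in SURVIVAL_RESPONSES and pair_similarity is not None:
        predictors = predictors + SIMILARITY_PREDICTORS

    n_before = len(sub)
    sub = sub.dropna(subset=[response] + predictors)
    out_cols = ["individual", "mother", "father", "aviary", "clutch_id",
                response] + predictors
    out = sub[out_cols].reset_index(drop=True)
    out.attrs["n_dropped_incomplete"] = n_before - len(sub)
    out.attrs["response"] = response
    return out, predictors


def check_clutch_order_day_correlation(pheno: pd.DataFrame,
                                       day_col: str = "hatch_day") -> float | None:
    """Pearson correlation between hatch day-of-season and clutch order.

    The two are strongly collinear in a synchronized breeding season, which
    is why only clutch order enters the models; the correlation is computed
    and logged when a day column is present.
    """
    if day_col not in pheno.columns:
        return None
    sub = pheno[[day_col, "clutch_order"]].dropna()
    if len(sub) < 3 or sub[day_col].nunique() < 2:
        return None
    return float(np.corrcoef(sub[day_col], sub["clutch_order"])[0, 1])
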