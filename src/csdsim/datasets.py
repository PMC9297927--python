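"""Published summary counts from the *Leptopilina* CSD and thelytoky experiments.

These are the printed observation tables the analyses operate on: pooled
all-male brood counts per species and group, dead-wasp dissection totals,
ploidy-screen sample sizes, and the antibiotic dose-response table of
thelytokous *L. clavipes* broods. Where an analysis needs per-brood rows
rather than pooled totals, :func:`brood_records_from_counts` expands a
pooled count into a minimal synthetic per-brood table with the same
aggregate composition.
"""

from __future__ import annotations

import pandas as pd

from .broods import BROOD_COLUMNS

__all__ = [
    "ALL_MALE_BROOD_COUNTS",
    "DEAD_WASP_DISSECTIONS",
    "PLOIDY_SCREENS",
    "CONTROL_TITERS",
    "dose_response_observed",
    "brood_records_from_counts",
    "dead_wasp_records",
]

#: (all-male broods, offspring-bearing broods) pooled over generations.
ALL_MALE_BROOD_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "heterotoma": {"inbred": (350, 781), "control": (343, 559)},
    "clavipes": {"inbred": (762, 1054), "control": (704, 783)},
}

#: L. clavipes pupal dissections in B-S 4 to 6:
#: (female dead wasps, dead wasps sexed) among (broods dissected, broods with
#: non-emerged pupae).
DEAD_WASP_DISSECTIONS = {
    "females": 520,
    "total": 605,
    "broods_dissected": 43,
    "broods_total": 110,
}

#: Males screened for ploidy by flow cytometry (all haploid).
PLOIDY_SCREENS = {
    "heterotoma": {"B-S 3": 80},
    "clavipes": {"B-S 5+6": 109},
}

#: Mean relative Wolbachia titer (+- SE) of untreated thelytokous females.
CONTROL_TITERS = {"water": (6.10, 0.32), "ethanol": (6.44, 0.38)}

_DOSE_RESPONSE_ROWS = [
    # group, dose mg tetracycline / g yeast, n parasitizing mothers,
    # n progeny, n male, n males tested (0 diploid in every row),
    # emerged flies, non-emerged flies
    ("control", 0.0, 1, 12, 0, 0, 8, 1),
    ("control", 0.0, 4, 10, 0, 0, 90, 3),
    ("treatment_1", 0.004, 3, 42, 0, 0, 56, 5),
    ("treatment_1", 0.008, 5, 33, 0, 0, 108, 1),
    ("treatment_1", 0.016, 2, 2, 0, 0, 36, 0),
    ("treatment_1", 0.031, 5, 12, 0, 0, 116, 3),
    ("treatment_1", 0.063, 1, 2, 0, 0, 21, 0),
    ("treatment_1", 0.125, 6, 38, 0, 0, 89, 6),
    ("treatment_1", 0.25, 7, 153, 99, 39, 107, 9),
    ("treatment_1", 0.5, 6, 36, 36, 17, 83, 4),
    ("treatment_1", 1.0, 8, 62, 62, 25, 108, 3),
    ("treatment_2", 0.067, 3, 19, 10, 9, 52, 3),
    ("treatment_2", 0.089, 5, 37, 1, 1, 75, 1),
    ("treatment_2", 0.119, 2, 5, 4, 4, 22, 1),
    ("treatment_2", 0.158, 5, 14, 6, 3, 90, 4),
    ("treatment_2", 0.211, 5, 59, 51, 12, 87, 2),
    ("treatment_2", 0.281, 8, 67, 65, 30, 131, 2),
    ("treatment_2", 0.375, 4, 32, 32, 16, 95, 2),
]


def dose_response_observed() -> pd.DataFrame:
    """Progeny of antibiotic-treated thelytokous *L. clavipes* females.

    One row per treatment dose (mg tetracycline per g yeast). No diploid
    male was found in any row; 65% of offspring at the 0.25 mg/g dose were
    male, rising to 100% at 0.5 mg/g and above.
    """
    rows = []
    for group, dose, mothers, prog, male, tested, flies, unem in _DOSE_RESPONSE_ROWS:
        rows.append(
            {
                "group": group,
                "dose": dose,
                "n_mothers": mothers,
                "n_offspring": prog,
                "n_female": prog - male,
                "n_male": male,
                "n_males_tested": tested,
                "n_diploid_males_found": 0,
                "n_flies_emerged": flies,
                "n_flies_unemerged": unem,
            }
        )
    return pd.DataFrame(rows)


def brood_records_from_counts(
    n_all_male: int,
    n_total: int,
    group: str = "inbred",
    generation: str = "pooled",
    males_per_all_male_brood: int = 10,
    females_per_mixed_brood: int = 7,
    males_per_mixed_brood: int = 3,
) -> pd.DataFrame:
    """Synthetic per-brood table reproducing a pooled all-male brood count.

    The published data report only the pooled counts (``n_all_male`` of
    ``n_total`` offspring-bearing broods); this expands them into one row
    per brood with fixed per-brood compositions so the per-brood statistics
    can run on them.
    """
    if not 0 <= n_all_male <= n_total:
        raise ValueError("need 0 <= n_all_male <= n_total")
    rows = []
    for j in range(n_total):
        all_male = j < n_all_male
        rows.append(
            {
                "mother_id": f"{group}-{generation}-{j}",
                "group": group,
                "generation": generation,
                "n_female_adults": 0 if all_male else females_per_mixed_brood,
                "n_male_adults": males_per_all_male_brood
                if all_male
                else males_per_mixed_brood,
                "n_flies_emerged": 0,
                "n_fly_pupae_unemerged": 0,
                "n_hosts": 0,
                "n_dead_wasps_female": 0,
                "n_dead_wasps_male": 0,
            }
        )
    return pd.DataFrame(rows, columns=BROOD_COLUMNS)


def dead_wasp_records() -> pd.DataFrame:
    """Synthetic per-brood expansion of the pooled dissection totals.

    520 female and 85 male dead wasps among the 43 dissected broods, spread
    as evenly as integer counts allow.
    """
    n_broods = DEAD_WASP_DISSECTIONS["broods_dissected"]
    fem_total = DEAD_WASP_DISSECTIONS["females"]
    male_total = DEAD_WASP_DISSECTIONS["total"] - fem_total
    rows = []
    for j in range(n_broods):
        fem = fem_total // n_broods + (1 if j < fem_total % n_broods else 0)
        male = male_total // n_broods + (1 if j < male_total % n_broods else 0)
        rows.append(
            {
                "mother_id": f"dissected-{j}",
                "group": "inbred",
                "generation": "B-S 4-6",
                "n_female_adults": 1,
                "n_male_adults": 1,
                "n_flies_emerged": 0,
                "n_fly_pupae_unemerged": fem + male,
                "n_hosts": 0,
                "n_dead_wasps_female": fem,
                "n_dead_wasps_male": male,
            }
        )
    return pd.DataFrame(rows, columns=BROOD_COLUMNS)
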