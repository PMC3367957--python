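"""Reference tables from a published multiple-choice predation experiment.

A study of prey selectivity by predatory aquatic insects in small fishless
pools offered seven prey species simultaneously to 13 predator stages (nine
species of diving beetles, water bugs and odonate larvae) and reported, in its
main text, the predator and prey rosters, pairwise Pianka diet overlaps of the
predators, pairwise overlaps of the predator assemblages attacking each prey,
stage-contrast t statistics for ontogenetic diet shifts, and aggregate counts
from a review of 59 published selectivity experiments.  Those printed tables
are bundled here as :class:`pandas.DataFrame` objects so that the clustering,
ordination and meta-analytic machinery in this package can be exercised on
real published values.  The underlying per-replicate prey counts were
distributed only as supplementary spreadsheets and are *not* included; use
:mod:`preysel.simulate` to generate trial-level data of the same shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PREDATOR_IDS = [
    "Hydaticus_A", "Acilius_L2", "Acilius_L3", "Acilius_A", "Dytiscus_L3",
    "Dytiscus_A", "Ilyocoris_A", "Notonecta_A", "Coenagrion_F0",
    "Libellula_F2", "Libellula_F0", "Sympetrum_F0", "Anax_F0",
]

PREY_IDS = ["Asellus", "Chironomus", "Cloeon", "Culex", "Daphnia", "Lymnaea", "Rana"]


def predators() -> pd.DataFrame:
    """Predator roster: species, stage, replicate count, body length, microhabitat."""
    rows = [
        # id, species, stage, microhabitat, n_replicates, body mm mean, sd
        ("Hydaticus_A", "Hydaticus seminiger", "adult", "bottom", 8, 14.8, 0.29),
        ("Acilius_L2", "Acilius canaliculatus", "L2", "water_column", 7, 12.9, 0.54),
        ("Acilius_L3", "Acilius canaliculatus", "L3", "water_column", 8, 21.7, 1.90),
        ("Acilius_A", "Acilius canaliculatus", "adult", "bottom", 8, 15.4, 0.70),
        ("Dytiscus_L3", "Dytiscus marginalis", "L3", "bottom", 5, 47.8, 2.95),
        ("Dytiscus_A", "Dytiscus marginalis", "adult", "bottom", 9, 32.9, 0.81),
        ("Ilyocoris_A", "Ilyocoris cimicoides", "adult", "bottom", 8, 14.1, 0.54),
        ("Notonecta_A", "Notonecta glauca", "adult", "water_column", 8, 15.1, 0.42),
        ("Coenagrion_F0", "Coenagrion puella", "F-0", "water_column", 9, 12.5, 0.90),
        ("Libellula_F2", "Libellula depressa", "F-2", "bottom", 7, 15.3, 0.63),
        ("Libellula_F0", "Libellula depressa", "F-0", "bottom", 6, 21.9, 1.18),
        ("Sympetrum_F0", "Sympetrum sanguineum", "F-0", "bottom", 8, 15.7, 0.80),
        ("Anax_F0", "Anax imperator", "F-0", "bottom", 9, 48.1, 2.54),
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "species", "stage", "microhabitat", "n_replicates",
                 "body_length_mean", "body_length_sd"],
    )


def prey() -> pd.DataFrame:
    """Prey roster: taxon, microhabitat, number offered per trial, control mortality.

    ``control_mortality_pct`` is the percent of offered individuals dying in
    predator-free control trials (four controls with the full prey mixture).
    """
    rows = [
        # id, taxon_order, microhabitat, n_offered, body mm mean, sd, control %
        ("Asellus", "Isopoda", "bottom", 10, 7.63, 1.03, 0.0),
        ("Chironomus", "Diptera", "bottom", 10, 9.38, 0.64, 11.7),
        ("Cloeon", "Ephemeroptera", "bottom", 10, 6.51, 0.73, 3.3),
        ("Culex", "Diptera", "water_column", 10, 9.16, 0.34, 3.3),
        ("Daphnia", "Cladocera", "water_column", 30, 2.34, 0.22, 6.1),
        ("Lymnaea", "Pulmonata", "water_column", 6, 13.19, 1.87, 0.0),
        ("Rana", "Anura", "bottom", 6, 6.33, 0.30, 0.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "taxon_order", "microhabitat", "n_offered_default",
                 "body_length_mean", "body_length_sd", "control_mortality_pct"],
    )


# Lower triangles of the two published overlap matrices (Pianka index,
# rounded to 2 decimals as printed).

_DIET_OVERLAP_LT = [
    [0.09],
    [0.30, 0.89],
    [0.94, 0.41, 0.55],
    [0.59, 0.21, 0.35, 0.64],
    [0.78, 0.21, 0.35, 0.80, 0.92],
    [0.78, 0.26, 0.39, 0.79, 0.82, 0.95],
    [0.21, 0.97, 0.87, 0.52, 0.28, 0.30, 0.34],
    [0.14, 0.88, 0.66, 0.41, 0.17, 0.22, 0.27, 0.80],
    [0.89, 0.50, 0.57, 0.98, 0.58, 0.76, 0.78, 0.57, 0.57],
    [0.76, 0.69, 0.78, 0.93, 0.61, 0.72, 0.73, 0.79, 0.58, 0.91],
    [0.72, 0.74, 0.77, 0.91, 0.59, 0.71, 0.73, 0.82, 0.67, 0.92, 0.99],
    [0.56, 0.72, 0.81, 0.76, 0.80, 0.78, 0.74, 0.78, 0.57, 0.74, 0.90, 0.89],
]

_PRED_OVERLAP_LT = [
    [0.56],
    [0.59, 0.75],
    [0.41, 0.39, 0.78],
    [0.79, 0.51, 0.73, 0.64],
    [0.44, 0.22, 0.27, 0.13, 0.36],
    [0.83, 0.47, 0.44, 0.17, 0.67, 0.43],
]


def _from_lower_triangle(lt: list[list[float]], labels: list[str]) -> pd.DataFrame:
    n = len(labels)
    m = np.eye(n)
    for i in range(1, n):
        for j in range(i):
            m[i, j] = m[j, i] = lt[i - 1][j]
    return pd.DataFrame(m, index=labels, columns=labels)


def diet_overlap_published() -> pd.DataFrame:
    """Published pairwise Pianka diet overlaps of the 13 predator stages."""
    return _from_lower_triangle(_DIET_OVERLAP_LT, PREDATOR_IDS)


#: row/column order of the printed predator-overlap table (not roster order)
_PRED_OVERLAP_ORDER = [
    "Asellus", "Cloeon", "Culex", "Daphnia", "Chironomus", "Lymnaea", "Rana",
]


def predation_pressure_overlap_published() -> pd.DataFrame:
    """Published pairwise overlaps of predator assemblages between the 7 prey."""
    return _from_lower_triangle(_PRED_OVERLAP_LT, _PRED_OVERLAP_ORDER)


def ontogenetic_shift_tests_published() -> pd.DataFrame:
    """Published stage-contrast t statistics (positive = later stage prefers more).

    NaN marks prey consumed by neither stage of the contrast.
    """
    idx = PREY_IDS
    cols = {
        "Acilius_A_vs_L3": [-0.93, 7.72, -11.15, -3.28, 1.18, np.nan, 2.66],
        "Acilius_A_vs_L2": [-0.99, 10.42, -2.42, -3.43, -1.75, np.nan, 2.66],
        "Acilius_L3_vs_L2": [-0.20, 4.00, 3.50, -1.47, -2.05, np.nan, np.nan],
        "Dytiscus_A_vs_L3": [-0.46, 2.58, -2.41, 0.03, 1.90, 1.93, -2.61],
        "Libellula_F0_vs_F2": [1.17, -0.96, 2.01, 1.58, -4.40, np.nan, 1.14],
    }
    return pd.DataFrame(cols, index=idx)


def literature_preference_counts() -> pd.DataFrame:
    """Per-taxon counts from the published review of selectivity experiments.

    ``n_offered`` = experiments offering the taxon alongside prey from another
    order; ``n_preferred`` = experiments in which it was the most preferred
    prey.  Only taxa whose counts were printed are included; the full review
    covered additional taxa (e.g. Trichoptera, Isopoda) whose exact counts
    were given only in a supplementary table.
    """
    rows = [
        ("Cladocera", 27, 21),
        ("Diptera", 29, 19),
        ("Culicidae", 28, 12),
        ("Chironomidae", 13, 10),
        ("Copepoda", 10, 2),
        ("Ephemeroptera", 12, 2),
        ("Rotifera", 4, 1),
        ("Heteroptera", 7, 0),
        ("Ostracoda", 6, 0),
        ("Odonata", 4, 0),
        ("Hydrachnida", 1, 0),
        ("Turbellaria", 1, 0),
    ]
    return pd.DataFrame(rows, columns=["taxon", "n_offered", "n_preferred"])


def microhabitat_contingency_published() -> np.ndarray:
    """Published 2x2 table: predator microhabitat x preferred-prey microhabitat.

    Rows: benthic predators, water-column predators; columns: benthic prey
    preferred, water-column prey preferred.
    """
    return np.array([[10, 4], [1, 3]])
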