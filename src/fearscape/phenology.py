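"""Food availability indices from phenology scores and vegetation plots.

Availability of a species group in a sampling occasion is
``F_m = sum_k F_k * D_k * S_k`` over group members k, where F_k is the mean
0-4 ripe-fruit score of the monitored individuals at that occasion's survey,
D_k the density of adult stems (stems/ha) in the vegetation plots and S_k
their mean DBH (cm).  The site-level variant recomputes D_k and S_k from the
plots inside each camera site's 200 m buffer while keeping the global F_k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ORGANS = ("new_leaves", "flowers", "unripe_fruit", "ripe_fruit")

#: Species-group presets: naturalised oil palm alone; the ten other monitored
#: wild fruits combined; cashew (matrix orchards); mango+baobab (villages and
#: abandoned villages); orange/lime/papaya (village-only); all cultivated.
DEFAULT_GROUPS: dict[str, list[str]] = {
    "palm_fruit": ["Elaeis guineensis"],
    "ten_wild_fruits": [
        "Dialium guineense", "Ceiba pentandra", "Treculia africana",
        "Parinari excelsa", "Saba senegalensis", "Spondias mombin",
        "Detarium senegalense", "Landolphia heudelotii", "Ficus sur",
        "Uvaria chamae",
    ],
    "cashew": ["Anacardium occidentale"],
    "mango_baobab": ["Mangifera indica", "Adansonia digitata"],
    "orange_lime_papaya": ["Citrus sinensis", "Citrus aurantifolia", "Carica papaya"],
    "all_cultivated": [
        "Anacardium occidentale", "Mangifera indica", "Adansonia digitata",
        "Citrus sinensis", "Citrus aurantifolia", "Carica papaya",
    ],
}


@dataclass(frozen=True)
class PhenologyScore:
    species: str
    individual_id: str
    survey_date: date
    organ: str
    score: int

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.score not in (0, 1, 2, 3, 4):
            raise ValueError("phenology score must be an integer in 0..4")


@dataclass(frozen=True)
class PlotRecord:
    """One measured stem in a 10 x 20 m vegetation plot (DBH >= 10 cm survey)."""

    plot_id: str
    site_id: str
    species: str
    dbh_cm: float
    plot_area_m2: float = 200.0

    def __post_init__(self) -> None:
        if self.dbh_cm <= 0:
            raise ValueError("dbh_cm must be positive")
        if self.plot_area_m2 <= 0:
            raise ValueError("plot_area_m2 must be positive")


def total_plot_area_m2(plots: Sequence[PlotRecord] | pd.DataFrame) -> float:
    """Total surveyed area: sum of distinct plot areas (stems share a plot)."""
    df = plots_to_frame(plots) if not isinstance(plots, pd.DataFrame) else plots
    return float(df.drop_duplicates("plot_id")["plot_area_m2"].sum())


def density_and_size(
    plots: Sequence[PlotRecord] | pd.DataFrame,
    species: str,
    min_adult_dbh: float = 10.0,
) -> tuple[float, float]:
    """Adult stem density D_k (stems/ha) and mean adult DBH S_k (cm) of a species.

    Density uses the *total* surveyed plot area, so absent species dilute to
    zero; both values are 0 when no adult stems were measured.
    """
    df = plots_to_frame(plots) if not isinstance(plots, pd.DataFrame) else plots
    area_ha = total_plot_area_m2(df) / 10_000.0
    if area_ha <= 0:
        raise ValueError("total plot area must be positive")
    adults = df[(df["species"] == species) & (df["dbh_cm"] >= min_adult_dbh)]
    if adults.empty:
        return 0.0, 0.0
    return len(adults) / area_ha, float(adults["dbh_cm"].mean())


def mean_ripe_score(
    scores: Sequence[PhenologyScore] | pd.DataFrame,
    species: str,
    survey_date: date,
) -> float:
    """F_k: mean ripe-fruit score over monitored individuals at one survey.

    Individuals missing from the survey are skipped, not imputed; a species
    with no scored individuals at that date contributes 0.
    """
    df = scores_to_frame(scores) if not isinstance(scores, pd.DataFrame) else scores
    sel = df[
        (df["species"] == species)
        & (df["organ"] == "ripe_fruit")
        & (df["survey_date"] == survey_date)
    ]
    return float(sel["score"].mean()) if len(sel) else 0.0


def availability_index(
    scores: Sequence[PhenologyScore] | pd.DataFrame,
    plots: Sequence[PlotRecord] | pd.DataFrame,
    group: Sequence[str],
    survey_date: date,
    min_adult_dbh: Mapping[str, float] | float = 10.0,
    site_id: str | None = None,
) -> float:
    """Availability index F_m of a species group at one phenology survey.

    With ``site_id`` given, D_k and S_k come from that site's own plots
    (spatial variant); F_k is always the global survey mean.  A species with
    scores but no plot presence contributes 0 (logged).
    """
    if not group:
        raise ValueError("species group must be nonempty")
    pdf = plots_to_frame(plots) if not isinstance(plots, pd.DataFrame) else plots
    sdf = scores_to_frame(scores) if not isinstance(scores, pd.DataFrame) else scores
    if site_id is not None:
        pdf = pdf[pdf["site_id"] == site_id]
        if pdf.empty:
            raise ValueError(f"no plots recorded for site {site_id!r}")
    total = 0.0
    for sp in group:
        thr = min_adult_dbh[sp] if isinstance(min_adult_dbh, Mapping) else min_adult_dbh
        f_k = mean_ripe_score(sdf, sp, survey_date)
        d_k, s_k = density_and_size(pdf, sp, thr)
        if f_k > 0 and d_k == 0:
            logger.info("species %r scored but absent from plots; contributes 0", sp)
        total += f_k * d_k * s_k
    return total


def availability_table(
    scores: Sequence[PhenologyScore] | pd.DataFrame,
    plots: Sequence[PlotRecord] | pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    survey_dates: Sequence[date],
    min_adult_dbh: Mapping[str, float] | float = 10.0,
    site_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format availability: one row per (group, occasion[, site]).

    Occasions are numbered 1..T in ``survey_dates`` order.  With ``site_ids``
    the site-level variant is used; otherwise a single global series per
    group is returned (site column empty).
    """
    rows = []
    for gname, members in groups.items():
        for occ, d in enumerate(survey_dates, start=1):
            if site_ids is None:
                val = availability_index(scores, plots, members, d, min_adult_dbh)
                rows.append((gname, occ, "", val))
            else:
                for sid in site_ids:
                    val = availability_index(
                        scores, plots, members, d, min_adult_dbh, site_id=sid
                    )
                    rows.append((gname, occ, sid, val))
    return pd.DataFrame(rows, columns=["group", "occasion", "site_id", "value"])


def normalize_series(series: Sequence[float]) -> np.ndarray:
    """Scale an availability series by its study-period total (sums to 1)."""
    x = np.asarray(series, dtype=float)
    if np.any(x < 0):
        raise ValueError("availability series must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("normalization undefined for an all-zero series")
    return x / total


def shannon_diversity(stem_counts: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i from per-species stem counts."""
    counts = np.asarray(
        list(stem_counts.values()) if isinstance(stem_counts, Mapping) else stem_counts,
        dtype=float,
    )
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("need at least one positive count")
    return float(stats.entropy(counts))


def scores_to_frame(scores: Sequence[PhenologyScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [s.species for s in scores],
            "individual_id": [s.individual_id for s in scores],
            "survey_date": [s.survey_date for s in scores],
            "organ": [s.organ for s in scores],
            "score": [s.score for s in scores],
        }
    )


def plots_to_frame(plots: Sequence[PlotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "site_id": [p.site_id for p in plots],
            "species": [p.species for p in plots],
            "dbh_cm": [p.dbh_cm for p in plots],
            "plot_area_m2": [p.plot_area_m2 for p in plots],
        }
    )
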