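"""Seeded synthetic studies with known ground truth.

No field dataset is distributed with the package, so every pipeline stage is
exercised on generated data that mimics the real survey design: 21 camera
sites at >= 500 m spacing in a ~5 km agroforest mosaic, 24 twice-monthly
occasions, 0-4 phenology scores with group-specific seasonality (village
fruits peaking when wild fruits trough), a latent AR(1) x Matern field, and
timestamped detection streams drawn from class-specific diel activity
curves.  Identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point, Polygon

from .events import DetectionRecord, OccasionGrid, build_occasions
from .landscape import Landscape
from .phenology import DEFAULT_GROUPS, PhenologyScore, PlotRecord
from .stmodel import (
    Hyperparameters,
    StDataset,
    build_dataset,
    matern1_correlation,
)

STUDY_START = date(2017, 7, 9)


# ---------------------------------------------------------------------------
# Truth containers


@dataclass(frozen=True)
class DielCurve:
    """Mixture of von Mises components on the 24-h clock (hours, not radians)."""

    mean_hours: tuple[float, ...]
    kappas: tuple[float, ...]
    weights: tuple[float, ...]

    def sample_hours(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights) / sum(self.weights))
        mu = np.asarray(self.mean_hours)[comp] * 2 * np.pi / 24.0
        kap = np.asarray(self.kappas)[comp]
        ang = rng.vonmises(mu - np.pi, kap) + np.pi  # wrap into [0, 2*pi)
        return ang % (2 * np.pi) * 24.0 / (2 * np.pi)


@dataclass(frozen=True)
class GroupSeason:
    peak_occasion: float
    amplitude: float  # 0..4 score scale


@dataclass
class SyntheticTruth:
    """Everything the generator committed to, for recovery checks."""

    beta0: float
    beta: dict[str, float]
    hp: Hyperparameters
    diel: dict[str, DielCurve]
    seasonality: dict[str, GroupSeason]
    seed: int
    field: np.ndarray | None = None  # (S, T), filled by simulate_study


#: diel curves: chimpanzees strictly diurnal and bimodal; humans late-morning
#: centred with some night activity in the forest
DEFAULT_DIEL = {
    "chimpanzee": DielCurve((8.0, 16.0), (3.0, 3.0), (0.5, 0.5)),
    "human": DielCurve((11.0, 21.0), (2.5, 4.0), (0.85, 0.15)),
}

#: seasonal peaks on the 24-occasion clock starting 9 July: wild fruits and
#: mango peak Apr-Jun (occasions ~19-23), village-only fruits Oct-Jan
#: (occasions ~6-13) — the inverse relationship the study design relies on
DEFAULT_SEASONALITY = {
    "palm_fruit": GroupSeason(18.0, 2.5),
    "ten_wild_fruits": GroupSeason(20.0, 2.0),
    "cashew": GroupSeason(21.0, 3.0),
    "mango_baobab": GroupSeason(22.0, 3.0),
    "orange_lime_papaya": GroupSeason(8.0, 3.0),
}


def default_truth(seed: int = 0) -> SyntheticTruth:
    """Preset mirroring the qualitative structure of the study system:
    space use increases away from villages, near roads, and with palm and
    village-fruit availability.  Illustrative, not a reproduction of any
    fitted values."""
    return SyntheticTruth(
        beta0=0.158,
        beta={
            "dist_village": 0.087,
            "dist_road": -0.103,
            "dist_agriculture": 0.034,
            "palm_fruit": 0.022,
            "ten_wild_fruits": 0.005,
            "mango_baobab": -0.015,
            "orange_lime_papaya": 0.012,
        },
        hp=Hyperparameters(a=0.7, rho=1500.0, sigma2_omega=0.012, sigma2_eps=0.01),
        diel=dict(DEFAULT_DIEL),
        seasonality=dict(DEFAULT_SEASONALITY),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Landscape


def generate_landscape(
    seed: int,
    n_sites: int = 21,
    extent_m: float = 5000.0,
    n_villages: int = 3,
    n_settlements: int = 5,
    n_roads: int = 2,
    min_spacing_m: float = 500.0,
) -> Landscape:
    """Random agroforest landscape: forest block, agriculture, villages,
    settlements, roads and camera sites with a minimum inter-site spacing."""
    if min(n_sites, n_villages, n_settlements, n_roads) <= 0 or extent_m <= 0:
        raise ValueError("counts and extent must be positive")
    rng = np.random.default_rng(seed)

    # rejection-sample sites with pairwise spacing
    sites: list[tuple[float, float]] = []
    for _ in range(20_000):
        if len(sites) == n_sites:
            break
        cand = tuple(rng.uniform(0.05 * extent_m, 0.95 * extent_m, 2))
        if all(np.hypot(cand[0] - x, cand[1] - y) >= min_spacing_m for x, y in sites):
            sites.append(cand)
    if len(sites) < n_sites:
        raise ValueError(
            f"cannot place {n_sites} sites with {min_spacing_m} m spacing in a "
            f"{extent_m} m extent"
        )
    site_dict = {f"S{i + 1:02d}": xy for i, xy in enumerate(sites)}

    # forest block: irregular polygon around a random centre in the west half
    cx, cy = rng.uniform(0.25, 0.45) * extent_m, rng.uniform(0.35, 0.65) * extent_m
    ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    radii = rng.uniform(0.15, 0.30, 12) * extent_m
    forest = Polygon(
        [(cx + r * np.cos(t), cy + r * np.sin(t)) for r, t in zip(radii, ang)]
    ).buffer(0)

    villages = [
        Point(rng.uniform(0.55, 0.95) * extent_m, rng.uniform(0.1, 0.9) * extent_m)
        for _ in range(n_villages)
    ]
    settlements = [
        Point(rng.uniform(0.5, 0.95) * extent_m, rng.uniform(0.05, 0.95) * extent_m)
        for _ in range(n_settlements)
    ]
    abandoned = [
        Point(rng.uniform(0.4, 0.9) * extent_m, rng.uniform(0.1, 0.9) * extent_m)
        for _ in range(4)
    ]

    roads = []
    for _ in range(n_roads):
        y0, y1 = rng.uniform(0.1, 0.9, 2) * extent_m
        mid = (extent_m / 2, rng.uniform(0.2, 0.8) * extent_m)
        roads.append(LineString([(0, y0), mid, (extent_m, y1)]))

    agriculture = []
    for v in villages:
        w = rng.uniform(0.08, 0.18) * extent_m
        agriculture.append(
            Polygon(
                [
                    (v.x - w, v.y - w), (v.x + w, v.y - w),
                    (v.x + w, v.y + w), (v.x - w, v.y + w),
                ]
            )
        )

    return Landscape(
        sites=site_dict,
        villages=villages,
        settlements=settlements,
        roads=roads,
        agriculture=agriculture,
        forest_block=forest,
        abandoned_villages=abandoned,
    )


# ---------------------------------------------------------------------------
# Phenology


def _survey_dates(T: int) -> list[date]:
    """Twice-monthly survey dates: one per 15-day occasion, on day 7."""
    return [STUDY_START + timedelta(days=15 * i + 6) for i in range(T)]


def seasonal_score(t: float, season: GroupSeason, T: int = 24) -> float:
    """Mean 0-4 score at occasion t: a raised-cosine pulse around the peak."""
    phase = 2 * np.pi * (t - season.peak_occasion) / T
    return season.amplitude * max(0.0, np.cos(phase)) ** 2


def generate_phenology(
    seed: int,
    groups: Mapping[str, Sequence[str]] | None = None,
    T: int = 24,
    site_ids: Sequence[str] | None = None,
    forest_sites: Sequence[str] | None = None,
    seasonality: Mapping[str, GroupSeason] | None = None,
    n_individuals: int = 9,
    plots_per_site: int = 25,
) -> tuple[list[PhenologyScore], list[PlotRecord]]:
    """Phenology scores and vegetation plots with group seasonality.

    Scores follow each group's raised-cosine seasonal curve discretised to
    0-4 with per-individual noise.  Plots place wild species more densely at
    ``forest_sites`` and cultivated species more densely elsewhere.
    """
    groups = dict(groups) if groups is not None else {
        k: v for k, v in DEFAULT_GROUPS.items() if k != "all_cultivated"
    }
    seasonality = dict(seasonality) if seasonality is not None else DEFAULT_SEASONALITY
    site_ids = list(site_ids) if site_ids is not None else [f"S{i + 1:02d}" for i in range(21)]
    forest_sites = set(forest_sites) if forest_sites is not None else set(site_ids[: len(site_ids) // 3])
    rng = np.random.default_rng(seed)
    dates = _survey_dates(T)

    wild_groups = {"palm_fruit", "ten_wild_fruits"}
    scores: list[PhenologyScore] = []
    for gname, members in groups.items():
        season = seasonality.get(gname, GroupSeason(12.0, 2.0))
        for sp in members:
            for ind in range(n_individuals):
                iid = f"{sp[:3].upper()}-{ind + 1}"
                for occ, dt in enumerate(dates, start=1):
                    mu = seasonal_score(occ, season, T)
                    # survey noise scales with the signal so a flat (amplitude
                    # 0) curve really produces constant scores
                    sc = int(np.clip(round(mu + rng.normal(0, 0.2 * season.amplitude)), 0, 4))
                    scores.append(PhenologyScore(sp, iid, dt, "ripe_fruit", sc))

    plots: list[PlotRecord] = []
    all_species = [(g, sp) for g, mem in groups.items() for sp in mem]
    for sid in site_ids:
        in_forest = sid in forest_sites
        for p in range(plots_per_site):
            pid = f"{sid}-P{p + 1:02d}"
            for gname, sp in all_species:
                wild = gname in wild_groups
                lam = (0.5 if wild else 0.15) if in_forest else (0.15 if wild else 0.4)
                if gname == "palm_fruit":
                    lam = 0.35  # oil palm is common on both sides of the forest edge
                for _ in range(rng.poisson(lam)):
                    dbh = float(np.clip(rng.lognormal(np.log(25.0), 0.4), 10.0, 150.0))
                    plots.append(PlotRecord(pid, sid, sp, dbh))
    return scores, plots


def availability_matrix(
    scores: Sequence[PhenologyScore],
    plots: Sequence[PlotRecord],
    group: Sequence[str],
    site_ids: Sequence[str],
    T: int = 24,
) -> np.ndarray:
    """(S, T) site-level availability of one species group.

    Vectorised equivalent of calling phenology.availability_index per
    (site, occasion) cell: F_k from a survey-date groupby, D_k and S_k from a
    per-site stem groupby (adult threshold 10 cm, the survey minimum).
    """
    from .phenology import plots_to_frame, scores_to_frame

    dates = _survey_dates(T)
    sdf = scores_to_frame(scores) if not isinstance(scores, pd.DataFrame) else scores
    pdf = plots_to_frame(plots) if not isinstance(plots, pd.DataFrame) else plots
    sdf = sdf[(sdf["organ"] == "ripe_fruit") & sdf["species"].isin(group)]
    f_k = sdf.groupby(["species", "survey_date"])["score"].mean()

    area_ha = (
        pdf.groupby("site_id")
        .apply(lambda g: g.drop_duplicates("plot_id")["plot_area_m2"].sum(), include_groups=False)
        / 10_000.0
    )
    adults = pdf[(pdf["dbh_cm"] >= 10.0) & pdf["species"].isin(group)]
    grp = adults.groupby(["site_id", "species"])["dbh_cm"]
    n_k, s_k = grp.size(), grp.mean()

    out = np.zeros((len(site_ids), T))
    for i, sid in enumerate(site_ids):
        for sp in group:
            if (sid, sp) not in n_k.index:
                continue
            d_sp = n_k[(sid, sp)] / area_ha[sid]
            s_sp = s_k[(sid, sp)]
            for j, dt in enumerate(dates):
                out[i, j] += f_k.get((sp, dt), 0.0) * d_sp * s_sp
    return out


# ---------------------------------------------------------------------------
# Latent field


def simulate_field(
    seed: int | np.random.Generator,
    coords: np.ndarray,
    T: int,
    hp: Hyperparameters,
) -> np.ndarray:
    """Draw the latent AR(1) x Matern field: (S, T) matrix.

    The first occasion comes from the stationary distribution (marginal
    variance sigma2_omega / (1 - a^2)); later occasions follow
    xi_t = a xi_{t-1} + omega_t with spatially Matern-correlated innovations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    S = len(coords)
    R = matern1_correlation(cdist(coords, coords), hp.rho) + 1e-10 * np.eye(S)
    L = np.linalg.cholesky(R)
    marg_sd = np.sqrt(hp.sigma2_omega / (1.0 - hp.a**2))
    innov_sd = np.sqrt(hp.sigma2_omega)
    out = np.empty((S, T))
    out[:, 0] = marg_sd * (L @ rng.standard_normal(S))
    for t in range(1, T):
        out[:, t] = hp.a * out[:, t - 1] + innov_sd * (L @ rng.standard_normal(S))
    return out


# ---------------------------------------------------------------------------
# Recovery-scale dataset (no detection stream)


def simulate_dataset(
    seed: int,
    n_sites: int = 21,
    T: int = 24,
    beta: Sequence[float] = (0.5, -0.3),
    beta0: float = 0.2,
    hp: Hyperparameters | None = None,
    n_null_covariates: int = 0,
    missing_frac: float = 0.0,
    extent_m: float = 5000.0,
) -> tuple[StDataset, dict]:
    """Model-scale simulation: response directly from y = z beta + xi + eps.

    Covariates are iid standard normal over cells (already on the z-scored
    scale); ``n_null_covariates`` extra columns have zero coefficient.
    Returns the dataset and a truth dict {beta0, beta, hp, xi}.
    """
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hp = hp or Hyperparameters(a=0.6, rho=1500.0, sigma2_omega=0.04, sigma2_eps=0.02)
    coords = rng.uniform(0, extent_m, (n_sites, 2))
    p = len(beta) + n_null_covariates
    z = rng.standard_normal((n_sites, T, p))
    full_beta = np.concatenate([np.asarray(beta, float), np.zeros(n_null_covariates)])
    xi = simulate_field(rng, coords, T, hp)
    eps = np.sqrt(hp.sigma2_eps) * rng.standard_normal((n_sites, T))
    y = beta0 + z @ full_beta + xi + eps
    if missing_frac > 0:
        mask = rng.random((n_sites, T)) < missing_frac
        y = np.where(mask, np.nan, y)
    names = tuple(
        [f"x{i + 1}" for i in range(len(beta))]
        + [f"null{i + 1}" for i in range(n_null_covariates)]
    )
    data = StDataset(coords, y, z, names)
    return data, {"beta0": beta0, "beta": full_beta, "hp": hp, "xi": xi}


# ---------------------------------------------------------------------------
# Full end-to-end study


def simulate_study(
    seed: int,
    landscape: Landscape | None = None,
    truth: SyntheticTruth | None = None,
    missing_frac: float = 0.1,
    T: int = 24,
    species_class: str = "chimpanzee",
) -> dict:
    """End-to-end synthetic study with a raw detection stream.

    Builds site covariates from the landscape and generated phenology, draws
    the latent field, forms y = z beta + xi + eps on the log(x+1) scale,
    converts each cell back to an integer event count
    (round((exp(y) - 1) * active_days), floored at 0) and scatters the
    events as timestamped photo bursts drawn from the class diel curve.
    ``missing_frac`` of cells get a simulated camera outage longer than
    7 days.  Returns a dict with the dataset, records, daily effort log,
    occasion grid, rates, availability matrices and the committed truth.
    """
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    landscape = landscape if landscape is not None else generate_landscape(seed)
    truth = truth if truth is not None else default_truth(seed)

    site_ids = list(landscape.sites)
    coords = landscape.site_coords()
    S = len(site_ids)

    # occasions: 15-day blocks with mid-occasion phenology surveys
    dates = _survey_dates(T)
    study_end = STUDY_START + timedelta(days=15 * T - 1)
    grid = build_occasions(dates, STUDY_START, study_end)

    # covariates
    from .landscape import covariate_table as _covtab

    cov = _covtab(landscape)
    forest_sites = [
        s for s, pt in landscape.site_points().items()
        if landscape.forest_block is not None and landscape.forest_block.contains(pt)
    ]
    scores, plots = generate_phenology(
        seed + 1, T=T, site_ids=site_ids, forest_sites=forest_sites,
        seasonality=truth.seasonality,
    )
    avail = {
        g: availability_matrix(scores, plots, DEFAULT_GROUPS[g], site_ids, T)
        for g in truth.seasonality
    }

    names = list(truth.beta)
    z_raw = np.empty((S, T, len(names)))
    for j, nm in enumerate(names):
        if nm in cov.columns:
            z_raw[:, :, j] = np.repeat(cov.loc[site_ids, nm].to_numpy()[:, None], T, axis=1)
        elif nm in avail:
            z_raw[:, :, j] = avail[nm]
        else:
            raise KeyError(f"truth covariate {nm!r} has no source")
    from .stmodel import standardize_covariates

    z, scaling = standardize_covariates(z_raw, names)

    xi = simulate_field(rng, coords, T, truth.hp)
    truth.field = xi
    eps = np.sqrt(truth.hp.sigma2_eps) * rng.standard_normal((S, T))
    beta_vec = np.array([truth.beta[n] for n in names])
    y = truth.beta0 + z @ beta_vec + xi + eps

    # effort with simulated outages
    occ_lens = np.array([grid.length_days(t + 1) for t in range(T)])
    active = np.repeat(occ_lens[None, :], S, axis=0).astype(int)
    outage = rng.random((S, T)) < missing_frac
    for s, t in zip(*np.nonzero(outage)):
        active[s, t] = int(rng.integers(0, max(occ_lens[t] - 8, 1)))

    # counts and detection streams
    counts = np.maximum(np.round(np.expm1(y) * active), 0).astype(int)

    # a second, human stream: intensity falls off with distance from villages
    # (people stay near settlements and fields), independent diel curve
    j_village = names.index("dist_village") if "dist_village" in names else 0
    y_human = 0.2 - 0.15 * z[:, :, j_village] + 0.1 * rng.standard_normal((S, T))
    counts_human = np.maximum(np.round(np.expm1(y_human) * active), 0).astype(int)

    def scatter(cls: str, cnt: np.ndarray) -> list[DetectionRecord]:
        curve = truth.diel[cls]
        recs: list[DetectionRecord] = []
        for s, sid in enumerate(site_ids):
            for t in range(T):
                start = grid.starts[t]
                act_days = [start + timedelta(days=dd) for dd in range(active[s, t])]
                if not act_days or cnt[s, t] == 0:
                    continue
                used: dict[date, list[float]] = {}
                for j in range(cnt[s, t]):
                    dday = act_days[j % len(act_days)]
                    hrs = used.setdefault(dday, [])
                    for _ in range(50):  # keep same-day events > 30 min apart
                        h = float(curve.sample_hours(1, rng)[0])
                        if all(abs(h - u) * 60 >= 35 for u in hrs):
                            break
                    else:
                        h = (max(hrs) + 1.0) % 24.0 if hrs else 12.0
                    hrs.append(h)
                    ts = datetime.combine(dday, time(0)) + timedelta(hours=h)
                    # a triggered burst of three frames seconds apart collapses
                    # to one minute-resolution photo; emit one record
                    recs.append(DetectionRecord(sid, cls, ts.replace(second=0, microsecond=0)))
        return recs

    daily_rows = []
    for s, sid in enumerate(site_ids):
        for t in range(T):
            start = grid.starts[t]
            for dd in range(occ_lens[t]):
                daily_rows.append(
                    (sid, (start + timedelta(days=dd)).isoformat(), int(dd < active[s, t]))
                )
    records = scatter(species_class, counts) + scatter("human", counts_human)

    keep_cell = (occ_lens[None, :] - active <= 7) & (active > 0)
    rates = np.where(keep_cell, counts / np.maximum(active, 1), np.nan)
    rates_human = np.where(keep_cell, counts_human / np.maximum(active, 1), np.nan)
    data = build_dataset(rates, z_raw, coords, names, site_ids=site_ids)
    effort_daily = pd.DataFrame(daily_rows, columns=["site_id", "date", "active"])

    return {
        "rates_human": rates_human,
        "dataset": data,
        "records": records,
        "effort_daily": effort_daily,
        "grid": grid,
        "rates": rates,
        "y": y,
        "counts": counts,
        "availability": avail,
        "covariates": cov,
        "scores": scores,
        "plots": plots,
        "truth": truth,
        "landscape": landscape,
        "site_ids": site_ids,
    }
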