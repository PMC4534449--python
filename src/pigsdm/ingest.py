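"""From occurrence polygons to presence and background samples.

Survey polygons describing the extent of established populations are
aggregated to watersheds under two criteria: the population must be larger
than three average home ranges (13 km²), and it must occupy more than 2.5 %
of the watershed. First-occupancy records implausibly far from the previous
year's occupied range are flagged as likely human introductions; a flagged
watershed re-enters the presence set once it is reported occupied again or a
neighbouring watershed becomes occupied. The estimation design contrasts the
presence sample with a background sample of twice its size drawn uniformly
from all watersheds (overlap with presences allowed — background points are
availability, not absence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError, SampleSizeError

SERIES_COLUMNS = ["watershed_id", "year", "present", "introduction",
                  "population_id"]


@dataclass
class SampleDesign:
    """Presence and background watershed samples for one model fit."""

    presence_ids: np.ndarray
    background_ids: np.ndarray
    multiplier: int
    seed: int

    def __post_init__(self) -> None:
        self.presence_ids = np.asarray(self.presence_ids)
        self.background_ids = np.asarray(self.background_ids)

    @property
    def record_ids(self) -> np.ndarray:
        """All record watershed ids, presences first."""
        return np.concatenate([self.presence_ids, self.background_ids])

    @property
    def labels(self) -> np.ndarray:
        """1 for presence records, 0 for background records."""
        return np.concatenate([np.ones(self.presence_ids.size, dtype=np.int64),
                               np.zeros(self.background_ids.size, dtype=np.int64)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"watershed_id": self.record_ids,
                             "label": self.labels})


def assign_presence(polygons: pd.DataFrame, watersheds: pd.DataFrame,
                    min_area_km2: float = 13.0,
                    min_prop: float = 0.025) -> pd.DataFrame:
    """Aggregate population polygons to watershed-year presence records.

    A watershed-year is marked present iff some intersecting population has
    (a) total polygon area that year greater than ``min_area_km2`` and
    (b) intersection covering more than ``min_prop`` of the watershed area.

    ``polygons`` needs columns population_id, year, geometry (shapely);
    ``watersheds`` is indexed by id with columns geometry and area_km2.
    """
    from shapely.strtree import STRtree

    for rec in polygons.itertuples():
        if rec.geometry is None or not rec.geometry.is_valid:
            raise GeometryError(
                f"invalid geometry for population {rec.population_id} "
                f"year {rec.year}")

    pop_area = polygons.assign(a=[g.area for g in polygons["geometry"]]) \
        .groupby(["population_id", "year"])["a"].sum()

    w_ids = watersheds.index.to_numpy()
    w_geoms = list(watersheds["geometry"])
    w_area = watersheds["area_km2"].to_numpy(dtype=float)
    tree = STRtree(w_geoms)

    # intersection area per (watershed, population, year)
    inter: dict = {}
    for rec in polygons.itertuples():
        for j in tree.query(rec.geometry, predicate="intersects"):
            a = rec.geometry.intersection(w_geoms[j]).area
            if a > 0:
                key = (int(j), rec.population_id, rec.year)
                inter[key] = inter.get(key, 0.0) + a

    rows = {}
    for (j, pop, year), a in inter.items():
        if pop_area[(pop, year)] > min_area_km2 and a / w_area[j] > min_prop:
            key = (int(w_ids[j]), int(year))
            # keep the qualifying population with the largest footprint
            if key not in rows or a > rows[key][1]:
                rows[key] = (pop, a)

    out = pd.DataFrame(
        [(w, y, True, False, pop) for (w, y), (pop, _a) in sorted(rows.items())],
        columns=SERIES_COLUMNS)
    return out


def _centroids(watersheds: pd.DataFrame) -> dict:
    return {int(i): (float(x), float(y)) for i, x, y in zip(
        watersheds.index, watersheds["centroid_x_km"],
        watersheds["centroid_y_km"])}


def flag_introductions(series: pd.DataFrame, watersheds: pd.DataFrame,
                       dispersal_threshold_km: float,
                       adjacency: dict | None = None) -> pd.DataFrame:
    """Flag first-occupancy records implausibly far from the prior range.

    A watershed first reported occupied in year *t* (for *t* after the first
    survey year) is flagged when its centroid is farther than
    ``dispersal_threshold_km`` from every watershed accepted as occupied in
    year *t − 1*. A flagged watershed re-enters the accepted occupancy set
    from the first later year in which it is reported occupied again or an
    adjacent watershed is accepted (``reincluded_year`` column; NaN when it
    never re-enters).
    """
    if dispersal_threshold_km <= 0:
        raise ConfigError("dispersal_threshold_km must be positive")
    cxy = _centroids(watersheds)
    adjacency = adjacency or {}

    out = series.copy().sort_values(["year", "watershed_id"],
                                    kind="stable").reset_index(drop=True)
    out["introduction"] = False
    out["reincluded_year"] = np.nan

    years = sorted(out["year"].unique())
    first_year = out.groupby("watershed_id")["year"].min()
    accepted: set = set()
    pending: set = set()
    flag_rows: dict = {}

    for t in years:
        present_t = set(out.loc[(out["year"] == t) & out["present"],
                                "watershed_id"].astype(int))
        prev_accepted = set(accepted)
        newly_accepted = set()
        # re-inclusion by repeated reporting
        for w in sorted(pending & present_t):
            if t > flag_rows[w][1]:
                out.loc[flag_rows[w][0], "reincluded_year"] = t
                pending.discard(w)
                newly_accepted.add(w)
        for w in sorted(present_t - prev_accepted - pending - newly_accepted):
            if int(first_year[w]) == years[0] or t == years[0]:
                newly_accepted.add(w)       # founding populations, never flagged
                continue
            if int(first_year[w]) < t:      # seen before and already handled
                newly_accepted.add(w)
                continue
            if not prev_accepted:
                newly_accepted.add(w)
                continue
            d = min(np.hypot(cxy[int(w)][0] - cxy[a][0],
                             cxy[int(w)][1] - cxy[a][1])
                    for a in prev_accepted)
            if d > dispersal_threshold_km:
                ridx = out.index[(out["watershed_id"] == w)
                                 & (out["year"] == t)][0]
                out.loc[ridx, "introduction"] = True
                flag_rows[int(w)] = (ridx, t)
                pending.add(int(w))
            else:
                newly_accepted.add(w)
        accepted |= {int(w) for w in newly_accepted}
        # re-inclusion by adjacency to newly accepted occupancy
        for w in sorted(pending):
            if t > flag_rows[w][1] and adjacency.get(w, set()) & accepted:
                out.loc[flag_rows[w][0], "reincluded_year"] = t
                pending.discard(w)
                accepted.add(w)
    return out


def presence_set(series: pd.DataFrame) -> np.ndarray:
    """Included presence watersheds: everything ever present, minus flagged
    introductions that never re-entered the accepted set."""
    present = series[series["present"]]
    ids = set(present["watershed_id"].astype(int))
    if "reincluded_year" in series.columns:
        flagged = series[series["introduction"]]
        for rec in flagged.itertuples():
            if np.isnan(rec.reincluded_year):
                ids.discard(int(rec.watershed_id))
    return np.array(sorted(ids), dtype=np.int64)


def build_samples(series: pd.DataFrame, watersheds: pd.DataFrame,
                  multiplier: int = 2,
                  seed: int | np.random.SeedSequence = 0) -> SampleDesign:
    """Presence sample plus a seeded uniform background draw.

    Background watersheds are drawn without replacement from *all* watersheds
    (presences included), ``multiplier`` times the presence count.
    """
    if series.empty:
        raise ConfigError("empty occurrence series")
    presence = presence_set(series)
    n_bg = multiplier * presence.size
    all_ids = watersheds.index.to_numpy()
    if n_bg > all_ids.size:
        raise SampleSizeError(
            f"background sample of {n_bg} exceeds the {all_ids.size} available "
            f"watersheds; use a smaller multiplier")
    rng = np.random.default_rng(seed)
    background = np.sort(rng.choice(all_ids, size=n_bg, replace=False))
    return SampleDesign(presence_ids=presence, background_ids=background,
                        multiplier=multiplier,
                        seed=int(seed) if np.isscalar(seed) else -1)
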