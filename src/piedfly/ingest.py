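"""Reading, validation and sufficient statistics for the three data streams.

The capture stream is reduced to release–recapture m-arrays (one
juvenile-release and one adult-release array per sex and site), the
sufficient statistics of the multinomial Cormack–Jolly–Seber likelihood.
Productivity is aggregated to brood / egg / fledgling totals per female
stage class, site and year, and the abundance stream is the annual count
of occupied nest boxes per sex and site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import FECUNDITY_STAGES, SEXES


class ValidationError(ValueError):
    """A data file violates the declared schema or an internal invariant."""


# ---------------------------------------------------------------------------
# capture histories
# ---------------------------------------------------------------------------


@dataclass
class CaptureTable:
    """Individual detection histories, one row per marked bird.

    ``detections`` is an (n_individuals, n_years) 0/1 matrix aligned with
    ``years``; the marking event itself counts as the first detection.
    """

    ids: np.ndarray          # str array, unique
    sex: np.ndarray          # "f" / "m"
    site: np.ndarray         # site labels
    first_year: np.ndarray   # int, year of marking
    stage: np.ndarray        # "juv" / "ad", stage at marking
    years: np.ndarray        # int, study years (ascending, contiguous)
    detections: np.ndarray   # (n, T) int 0/1

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def sites(self) -> tuple:
        return tuple(sorted(set(self.site.tolist())))

    def validate(self) -> None:
        years = self.years
        if np.any(np.diff(years) != 1):
            raise ValidationError("study years must be consecutive")
        year_index = {y: i for i, y in enumerate(years.tolist())}
        for row, (fy, det) in enumerate(zip(self.first_year, self.detections)):
            if fy not in year_index:
                raise ValidationError(
                    f"row {row}: first capture year {fy} outside study years "
                    f"{years[0]}-{years[-1]}"
                )
            j = year_index[fy]
            if det[j] != 1:
                raise ValidationError(f"row {row}: no detection in first-capture year {fy}")
            if det[:j].any():
                raise ValidationError(f"row {row}: detection before first capture year {fy}")
        if len(set(self.ids.tolist())) != len(self.ids):
            dup = pd.Series(self.ids).duplicated()
            raise ValidationError(f"duplicate individual id(s): {set(self.ids[dup].tolist())}")
        bad_sex = ~np.isin(self.sex, SEXES)
        if bad_sex.any():
            raise ValidationError(f"row {int(np.argmax(bad_sex))}: sex must be one of {SEXES}")
        bad_stage = ~np.isin(self.stage, ("juv", "ad"))
        if bad_stage.any():
            raise ValidationError(f"row {int(np.argmax(bad_stage))}: stage must be juv or ad")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "sex": self.sex,
                "site": self.site,
                "first_year": self.first_year,
                "stage": self.stage,
            }
        )
        for i, y in enumerate(self.years.tolist()):
            df[f"y{y}"] = self.detections[:, i]
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_captures(path) -> CaptureTable:
    """Read and validate a capture-history CSV.

    Schema: columns ``id, sex, site, first_year, stage`` followed by one
    0/1 column per study year named ``y<year>`` (4-digit years).
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "site": str, "stage": str})
    required = {"id", "sex", "site", "first_year", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    year_cols = [c for c in df.columns if c.startswith("y") and c[1:].isdigit()]
    if not year_cols:
        raise ValidationError("no detection columns (expected y<year>)")
    years = np.array(sorted(int(c[1:]) for c in year_cols))
    det = df[[f"y{y}" for y in years.tolist()]].to_numpy()
    if not np.isin(det, (0, 1)).all():
        raise ValidationError("detection indicators must be 0 or 1")
    # conflicting duplicate metadata is an error; exact duplicate ids are too
    if df["id"].duplicated().any():
        conflicts = df.groupby("id")[["sex", "site", "stage"]].nunique()
        bad = conflicts[(conflicts > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValidationError(f"duplicate id(s) with conflicting metadata: {bad}")
        raise ValidationError(
            f"duplicate id(s): {df.loc[df['id'].duplicated(), 'id'].unique().tolist()}"
        )
    table = CaptureTable(
        ids=df["id"].to_numpy(dtype=object),
        sex=df["sex"].to_numpy(dtype=object),
        site=df["site"].to_numpy(dtype=object),
        first_year=df["first_year"].to_numpy(dtype=int),
        stage=df["stage"].to_numpy(dtype=object),
        years=years,
        detections=det.astype(np.int64),
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# m-arrays
# ---------------------------------------------------------------------------


@dataclass
class MArraySet:
    """Release–recapture m-arrays per sex and site.

    For each (sex, site) there are two arrays of shape ``(T-1, T)``:
    rows are release occasions ``0 .. T-2``, columns ``0 .. T-2`` hold first
    recaptures at occasions ``1 .. T-1`` (column ``k`` = occasion ``k+1``),
    and the last column counts birds never seen again.  Birds marked as
    juveniles are released once into the juvenile array; every recapture
    re-releases the bird into the adult array.
    """

    sexes: tuple
    sites: tuple
    years: np.ndarray
    juv: dict = field(default_factory=dict)   # (sex, site) -> (T-1, T) int array
    ad: dict = field(default_factory=dict)

    @property
    def n_occasions(self) -> int:
        return len(self.years)

    def releases(self, sex, site, stage) -> np.ndarray:
        arr = (self.juv if stage == "juv" else self.ad)[(sex, site)]
        return arr.sum(axis=1)

    def total_recaptures(self) -> int:
        T = self.n_occasions
        return int(
            sum(a[:, : T - 1].sum() for a in self.juv.values())
            + sum(a[:, : T - 1].sum() for a in self.ad.values())
        )


def build_marrays(captures: CaptureTable) -> MArraySet:
    """Reduce capture histories to the CJS sufficient statistics.

    Each detection at occasion ``t < T-1`` is a release; the next detection
    (if any) is its first recapture.  The release after the marking event of
    a juvenile-marked bird goes into the juvenile array, all later releases
    (and all releases of adult-marked birds) into the adult array.
    Final-occasion releases contribute no multinomial row and are dropped.
    """
    captures.validate()
    years = captures.years
    T = len(years)
    sites = captures.sites
    mset = MArraySet(sexes=SEXES, sites=sites, years=years)
    for j in SEXES:
        for s in sites:
            mset.juv[(j, s)] = np.zeros((T - 1, T), dtype=np.int64)
            mset.ad[(j, s)] = np.zeros((T - 1, T), dtype=np.int64)
    year0 = int(years[0])
    for i in range(len(captures)):
        key = (captures.sex[i], captures.site[i])
        det_occ = np.flatnonzero(captures.detections[i])
        for k, t in enumerate(det_occ.tolist()):
            if t == T - 1:
                continue  # no interval follows the final occasion
            is_marking = k == 0
            arr = mset.juv[key] if (is_marking and captures.stage[i] == "juv") else mset.ad[key]
            if k + 1 < len(det_occ):
                arr[t, det_occ[k + 1] - 1] += 1
            else:
                arr[t, T - 1] += 1
    return mset


# ---------------------------------------------------------------------------
# productivity
# ---------------------------------------------------------------------------


@dataclass
class NestAggregate:
    """Brood, egg and fledgling totals per female stage class, site, year.

    ``b[a, s, t]`` broods, ``c[a, s, t]`` total eggs, ``f[a, s, t]`` total
    fledglings, with the fecundity-stage axis ordered ``(rec, ad, im)``.
    """

    sites: tuple
    years: np.ndarray
    b: np.ndarray  # (3, S, T) int
    c: np.ndarray
    f: np.ndarray

    def validate(self) -> None:
        if (self.f > self.c).any():
            raise ValidationError("fledglings exceed eggs in some cell")
        if (self.b < 0).any() or (self.c < 0).any() or (self.f < 0).any():
            raise ValidationError("negative productivity totals")
        if ((self.b == 0) & (self.c > 0)).any():
            raise ValidationError("eggs recorded in a cell with zero broods")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ai, a in enumerate(FECUNDITY_STAGES):
            for si, s in enumerate(self.sites):
                for ti, y in enumerate(self.years.tolist()):
                    rows.append(
                        {
                            "site": s,
                            "year": y,
                            "stage": a,
                            "broods": int(self.b[ai, si, ti]),
                            "eggs": int(self.c[ai, si, ti]),
                            "fledglings": int(self.f[ai, si, ti]),
                        }
                    )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def aggregate_nests(nests: pd.DataFrame, sites=None, years=None) -> NestAggregate:
    """Aggregate per-nest records to stage x site x year totals.

    Expects columns ``site, year, stage, clutch, fledged``; rows whose
    female stage is missing/unknown are excluded (nests where the female
    could not be recaptured cannot be assigned a stage class).
    """
    df = nests.copy()
    known = df["stage"].isin(FECUNDITY_STAGES)
    df = df[known]
    bad = df["fledged"] > df["clutch"]
    if bad.any():
        raise ValidationError(
            f"fledged > clutch in row(s) {df.index[bad].tolist()} of the nest table"
        )
    if sites is None:
        sites = tuple(sorted(df["site"].unique().tolist()))
    if years is None:
        years = np.arange(int(df["year"].min()), int(df["year"].max()) + 1)
    b = np.zeros((3, len(sites), len(years)), dtype=np.int64)
    c = np.zeros_like(b)
    f = np.zeros_like(b)
    site_ix = {s: i for i, s in enumerate(sites)}
    year_ix = {int(y): i for i, y in enumerate(np.asarray(years).tolist())}
    for (a, s, y), grp in df.groupby(["stage", "site", "year"]):
        ai = FECUNDITY_STAGES.index(a)
        b[ai, site_ix[s], year_ix[int(y)]] = len(grp)
        c[ai, site_ix[s], year_ix[int(y)]] = int(grp["clutch"].sum())
        f[ai, site_ix[s], year_ix[int(y)]] = int(grp["fledged"].sum())
    agg = NestAggregate(sites=tuple(sites), years=np.asarray(years), b=b, c=c, f=f)
    agg.validate()
    return agg


def read_nest_totals(path) -> NestAggregate:
    """Read productivity already aggregated to stage x site x year totals."""
    df = pd.read_csv(path, dtype={"site": str, "stage": str})
    sites = tuple(sorted(df["site"].unique().tolist()))
    years = np.arange(int(df["year"].min()), int(df["year"].max()) + 1)
    b = np.zeros((3, len(sites), len(years)), dtype=np.int64)
    c = np.zeros_like(b)
    f = np.zeros_like(b)
    site_ix = {s: i for i, s in enumerate(sites)}
    year_ix = {int(y): i for i, y in enumerate(years.tolist())}
    for _, row in df.iterrows():
        ai = FECUNDITY_STAGES.index(row["stage"])
        b[ai, site_ix[row["site"]], year_ix[int(row["year"])]] = int(row["broods"])
        c[ai, site_ix[row["site"]], year_ix[int(row["year"])]] = int(row["eggs"])
        f[ai, site_ix[row["site"]], year_ix[int(row["year"])]] = int(row["fledglings"])
    agg = NestAggregate(sites=sites, years=years, b=b, c=c, f=f)
    agg.validate()
    return agg


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass
class CountSeries:
    """Occupied-nest-box counts ``y[j, s, t]`` per sex, site, year.

    Missing years hold NaN and are excluded from the likelihood via
    ``observed``.  Counts must be >= 1 where observed (lognormal support).
    """

    sites: tuple
    years: np.ndarray
    y: np.ndarray         # (2, S, T) float, NaN = missing
    observed: np.ndarray  # (2, S, T) bool

    def validate(self) -> None:
        vals = self.y[self.observed]
        if (vals < 1).any():
            raise ValidationError("observed counts must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ji, j in enumerate(SEXES):
            for si, s in enumerate(self.sites):
                for ti, yy in enumerate(self.years.tolist()):
                    if self.observed[ji, si, ti]:
                        rows.append(
                            {"site": s, "year": yy, "sex": j, "count": int(self.y[ji, si, ti])}
                        )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_counts(path, years=None) -> CountSeries:
    """Read the count CSV (columns ``site, year, sex, count``)."""
    df = pd.read_csv(path, dtype={"site": str, "sex": str})
    sites = tuple(sorted(df["site"].unique().tolist()))
    if years is None:
        years = np.arange(int(df["year"].min()), int(df["year"].max()) + 1)
    y = np.full((2, len(sites), len(years)), np.nan)
    site_ix = {s: i for i, s in enumerate(sites)}
    year_ix = {int(v): i for i, v in enumerate(np.asarray(years).tolist())}
    for _, row in df.iterrows():
        ji = SEXES.index(row["sex"])
        y[ji, site_ix[row["site"]], year_ix[int(row["year"])]] = float(row["count"])
    cs = CountSeries(sites=sites, years=np.asarray(years), y=y, observed=~np.isnan(y))
    cs.validate()
    return cs


# ---------------------------------------------------------------------------
# joint container
# ---------------------------------------------------------------------------


@dataclass
class IPMData:
    """All observed streams plus the annual covariate series, aligned."""

    marrays: MArraySet
    nests: NestAggregate
    counts: CountSeries
    covariates: dict = field(default_factory=dict)  # name -> (T,) values, standardized

    @property
    def sites(self) -> tuple:
        return self.counts.sites

    @property
    def years(self) -> np.ndarray:
        return self.counts.years
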