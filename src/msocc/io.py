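"""Data containers and tabular I/O for multistate detection histories.

Detection histories record, for every site x year x monthly occasion, an
observed state: 0 = species not detected, 1 = adults detected, 2 = young
(cubs) detected.  Occasions where the camera was inactive are *missing* and
are never coerced to state 0.  Site covariates carry the proportion of
habitat within 5 km and 1 km of each site, plus a two-level ecoregion label
with ``GreatBasin`` as the reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ECOREGION_LEVELS",
    "DetectionHistory",
    "SiteCovariates",
    "standardize",
    "read_detections",
    "read_covariates",
    "write_detections",
]

#: Sentinel for an inactive (unobserved) occasion in the integer state array.
MISSING = -1

#: Ecoregion factor levels; the first is the reference (intercept) level.
ECOREGION_LEVELS = ("GreatBasin", "SierraNevada")

_MISSING_TOKENS = {"", "na", "n/a", "nan", "none", "null", "."}


class ValidationError(ValueError):
    """Raised when an input file or container violates the data contract."""


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Center and scale a covariate to mean 0, sample sd 1 (``ddof=1``).

    Returns ``(z, mean, sd)``; the constants are retained so that prediction
    inputs given on the raw scale can be transformed identically later
    (``z = (x - mean) / sd``).

    Raises
    ------
    ValidationError
        If fewer than two values are supplied or the vector is constant.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("standardize requires a 1-d vector of length >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValidationError("cannot standardize a constant covariate (zero variance)")
    return (x - mean) / sd, mean, sd


@dataclass(frozen=True)
class DetectionHistory:
    """Observed states on a (site, year, occasion) grid with missingness.

    ``observed_state`` is an integer array holding 0/1/2 where observed and
    :data:`MISSING` where the camera was inactive; ``missing_mask`` is True
    exactly at the inactive cells.
    """

    observed_state: np.ndarray  # (n_sites, n_years, n_occasions) int8
    missing_mask: np.ndarray    # same shape, bool
    site_ids: tuple = ()
    year_labels: tuple = ()

    def __post_init__(self):
        state = np.asarray(self.observed_state, dtype=np.int8)
        mask = np.asarray(self.missing_mask, dtype=bool)
        if state.shape != mask.shape or state.ndim != 3:
            raise ValidationError("observed_state and missing_mask must share a 3-d shape")
        state = state.copy()
        state[mask] = MISSING
        obs = state[~mask]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValidationError("observed states must be in {0, 1, 2}")
        object.__setattr__(self, "observed_state", state)
        object.__setattr__(self, "missing_mask", mask)
        site_ids = tuple(self.site_ids) or tuple(f"site{i + 1}" for i in range(state.shape[0]))
        years = tuple(self.year_labels) or tuple(str(j + 1) for j in range(state.shape[1]))
        if len(site_ids) != state.shape[0] or len(years) != state.shape[1]:
            raise ValidationError("site_ids / year_labels do not match array shape")
        object.__setattr__(self, "site_ids", site_ids)
        object.__setattr__(self, "year_labels", years)

    @property
    def n_sites(self) -> int:
        return self.observed_state.shape[0]

    @property
    def n_years(self) -> int:
        return self.observed_state.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.observed_state.shape[2]

    def to_long_frame(self) -> pd.DataFrame:
        """Long table with one row per (site, year, occasion); missing -> NA."""
        s, y, t = np.meshgrid(
            np.arange(self.n_sites), np.arange(self.n_years),
            np.arange(self.n_occasions), indexing="ij",
        )
        state = self.observed_state.astype(float)
        state[self.missing_mask] = np.nan
        return pd.DataFrame({
            "site": np.asarray(self.site_ids, dtype=object)[s.ravel()],
            "year": np.asarray(self.year_labels, dtype=object)[y.ravel()],
            "occasion": t.ravel() + 1,
            "state": state.ravel(),
        })

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide table with one row per (site, year) and ``occ_1..occ_T`` columns."""
        rows = []
        for i, site in enumerate(self.site_ids):
            for j, year in enumerate(self.year_labels):
                row = {"site": site, "year": year}
                for t in range(self.n_occasions):
                    v = self.observed_state[i, j, t]
                    row[f"occ_{t + 1}"] = np.nan if self.missing_mask[i, j, t] else int(v)
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SiteCovariates:
    """Per-site covariates with stored standardization constants.

    ``ecoregion_indicator`` codes ``GreatBasin`` as 0 (reference level) and
    ``SierraNevada`` as 1, matching the model's intercept parameterization.
    """

    site_ids: tuple
    habitat5km: np.ndarray
    habitat1km: np.ndarray
    ecoregion: tuple
    standardized_habitat5km: np.ndarray = field(default=None, repr=False)
    standardized_habitat1km: np.ndarray = field(default=None, repr=False)
    standardization_constants: dict = field(default=None, repr=False)

    def __post_init__(self):
        h5 = np.asarray(self.habitat5km, dtype=float)
        h1 = np.asarray(self.habitat1km, dtype=float)
        eco = tuple(self.ecoregion)
        n = len(self.site_ids)
        if h5.shape != (n,) or h1.shape != (n,) or len(eco) != n:
            raise ValidationError("covariate arrays must have one value per site")
        for name, arr in (("habitat5km", h5), ("habitat1km", h1)):
            bad = np.flatnonzero((arr < 0) | (arr > 1) | ~np.isfinite(arr))
            if bad.size:
                raise ValidationError(
                    f"{name} outside [0, 1] for site(s) "
                    f"{[self.site_ids[i] for i in bad[:5]]}"
                )
        unknown = sorted(set(eco) - set(ECOREGION_LEVELS))
        if unknown:
            raise ValidationError(f"unknown ecoregion level(s): {unknown}")
        z5, m5, s5 = standardize(h5)
        z1, m1, s1 = standardize(h1)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "habitat5km", h5)
        object.__setattr__(self, "habitat1km", h1)
        object.__setattr__(self, "ecoregion", eco)
        object.__setattr__(self, "standardized_habitat5km", z5)
        object.__setattr__(self, "standardized_habitat1km", z1)
        object.__setattr__(self, "standardization_constants", {
            "habitat5km": (m5, s5), "habitat1km": (m1, s1),
        })

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def ecoregion_indicator(self) -> np.ndarray:
        """0 for GreatBasin (reference), 1 for SierraNevada."""
        return np.asarray([ECOREGION_LEVELS.index(e) for e in self.ecoregion], dtype=float)

    @property
    def standardized(self) -> bool:
        return self.standardization_constants is not None

    def standardize_new(self, habitat5km=None, habitat1km=None):
        """Transform new raw covariate values with the *stored* constants."""
        out = []
        for name, vals in (("habitat5km", habitat5km), ("habitat1km", habitat1km)):
            if vals is None:
                out.append(None)
                continue
            mean, sd = self.standardization_constants[name]
            out.append((np.asarray(vals, dtype=float) - mean) / sd)
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site": list(self.site_ids),
            "habitat5km": self.habitat5km,
            "habitat1km": self.habitat1km,
            "ecoregion": list(self.ecoregion),
        })


def _parse_state(value, where: str) -> int:
    """Parse a state cell; returns MISSING for NA tokens, else 0/1/2."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    text = str(value).strip()
    if text.lower() in _MISSING_TOKENS:
        return MISSING
    try:
        num = float(text)
    except ValueError:
        raise ValidationError(f"unparseable state {value!r} at {where}") from None
    state = int(num)
    if state != num or state not in (0, 1, 2):
        raise ValidationError(f"unknown state code {value!r} at {where}; expected 0/1/2 or NA")
    return state


def read_detections(path, dialect: str = "long") -> DetectionHistory:
    """Read a detection-history CSV in ``long`` or ``wide`` dialect.

    Long: columns ``site, year, occasion, state``.  Wide: one row per
    site-year with ``occ_1..occ_T`` columns.  Site-year-occasion cells absent
    from the file, or carrying an NA token, become missing — never state 0.
    """
    if dialect not in ("long", "wide"):
        raise ValidationError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if dialect == "long":
        required = {"site", "year", "occasion", "state"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long dialect needs columns {sorted(required)}")
        sites = list(dict.fromkeys(df["site"]))
        years = sorted(set(df["year"]))
        occasions = sorted({int(o) for o in df["occasion"]})
        if occasions and (occasions[0] < 1):
            raise ValidationError("occasion indices must be >= 1")
        n_occ = max(occasions) if occasions else 0
        shape = (len(sites), len(years), n_occ)
        state = np.full(shape, MISSING, dtype=np.int8)
        seen = np.zeros(shape, dtype=bool)
        site_pos = {s: i for i, s in enumerate(sites)}
        year_pos = {y: j for j, y in enumerate(years)}
        for idx, row in enumerate(df.itertuples(index=False)):
            i, j, t = site_pos[row.site], year_pos[row.year], int(row.occasion) - 1
            if seen[i, j, t]:
                raise ValidationError(
                    f"duplicate (site, year, occasion) = "
                    f"({row.site}, {row.year}, {row.occasion}) at data row {idx + 1}"
                )
            seen[i, j, t] = True
            state[i, j, t] = _parse_state(row.state, f"data row {idx + 1}")
        mask = state == MISSING
        return DetectionHistory(state, mask, tuple(sites), tuple(years))
    # wide
    if not {"site", "year"}.issubset(df.columns):
        raise ValidationError("wide dialect needs columns site, year and occ_* columns")
    occ_cols = sorted(
        (c for c in df.columns if c.startswith("occ_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    if not occ_cols:
        raise ValidationError("wide dialect found no occ_* columns")
    sites = list(dict.fromkeys(df["site"]))
    years = sorted(set(df["year"]))
    shape = (len(sites), len(years), len(occ_cols))
    state = np.full(shape, MISSING, dtype=np.int8)
    seen_pair = set()
    site_pos = {s: i for i, s in enumerate(sites)}
    year_pos = {y: j for j, y in enumerate(years)}
    for idx, row in df.iterrows():
        key = (row["site"], row["year"])
        if key in seen_pair:
            raise ValidationError(f"duplicate (site, year) = {key} at data row {idx + 1}")
        seen_pair.add(key)
        i, j = site_pos[key[0]], year_pos[key[1]]
        for t, col in enumerate(occ_cols):
            state[i, j, t] = _parse_state(row[col], f"data row {idx + 1}, column {col}")
    mask = state == MISSING
    return DetectionHistory(state, mask, tuple(sites), tuple(years))


def write_detections(history: DetectionHistory, path, dialect: str = "long") -> None:
    """Write a detection history as CSV; exact round-trip with read_detections."""
    if dialect == "long":
        df = history.to_long_frame()
        df["state"] = df["state"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    elif dialect == "wide":
        df = history.to_wide_frame()
        for c in df.columns:
            if c.startswith("occ_"):
                df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False)


def read_covariates(path, site_ids=None) -> SiteCovariates:
    """Read per-site covariates (``site, habitat5km, habitat1km, ecoregion``).

    If ``site_ids`` (e.g. from a :class:`DetectionHistory`) is given, rows are
    aligned to that order and any mismatch is an error listing the sites.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"site", "habitat5km", "habitat1km", "ecoregion"}
    if not required.issubset(df.columns):
        raise ValidationError(f"covariate file needs columns {sorted(required)}")
    df["site"] = df["site"].astype(str)
    if df["site"].duplicated().any():
        dupes = sorted(df.loc[df["site"].duplicated(), "site"].unique())
        raise ValidationError(f"duplicate site rows: {dupes}")
    if site_ids is not None:
        wanted = [str(s) for s in site_ids]
        have = set(df["site"])
        missing = [s for s in wanted if s not in have]
        extra = sorted(have - set(wanted))
        if missing or extra:
            raise ValidationError(
                f"site mismatch with detection history; missing covariates for "
                f"{missing[:10]}, unmatched covariate rows {extra[:10]}"
            )
        df = df.set_index("site").loc[wanted].reset_index()
    return SiteCovariates(
        site_ids=tuple(df["site"]),
        habitat5km=df["habitat5km"].to_numpy(dtype=float),
        habitat1km=df["habitat1km"].to_numpy(dtype=float),
        ecoregion=tuple(df["ecoregion"].astype(str)),
    )
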