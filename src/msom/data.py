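"""Detection arrays and covariate tables for multispecies occupancy models.

This module assembles long-format detection records into the taxa x sites x
slots binary array the model consumes, augments it with all-zero taxa for
data augmentation, standardizes covariates, and screens covariate pairs for
collinearity.  All readers/writers use plain CSV so that datasets round-trip
through text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import LS, PM, StudyLayout

__all__ = [
    "SITE_COVARIATES",
    "SURVEY_COVARIATES",
    "REFERENCE_MOMENTS",
    "DetectionArray",
    "SiteCovariates",
    "SurveyCovariates",
    "standardize_covariate",
    "assemble_detection_array",
    "augment_detection_array",
    "correlation_screen",
    "read_detections_csv",
    "write_detections_csv",
]

SITE_COVARIATES = ("urban_dist", "garden_area")
SURVEY_COVARIATES = (
    "start_time",
    "julian_date",
    "temperature",
    "light",
    "bloom_richness",
)

#: Standardization moments (mean, SD) of the urban-garden pollinator survey
#: design the bundled presets emulate: distance to urban center (m), garden
#: area (m^2), survey start time (h after midnight), Julian date, temperature
#: (deg C), light level (lux), bloom richness (co-blooming species count).
REFERENCE_MOMENTS: dict[str, tuple[float, float]] = {
    "urban_dist": (15124.1, 12355.9),
    "garden_area": (464.7, 430.7),
    "start_time": (12.9, 1.9),
    "julian_date": (193.2, 8.8),
    "temperature": (32.4, 5.0),
    "light": (42160.6, 25340.9),
    "bloom_richness": (19.6, 8.5),
}


class DataIntegrityError(ValueError):
    """A record or table contradicts the declared survey layout."""


def standardize_covariate(values, mean: float, sd: float) -> np.ndarray:
    """Center and scale ``values`` as (x - mean) / sd.

    NaN entries (missing cells) pass through unchanged.  ``sd`` must be
    strictly positive.
    """
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"standardization SD must be > 0, got {sd}")
    arr = np.asarray(values, dtype=float)
    return (arr - mean) / sd


@dataclass(frozen=True)
class DetectionArray:
    """Binary detection/non-detection data, taxa x sites x replicate slots.

    ``y[i, j, k]`` is 1 if taxon ``i`` was detected at site ``j`` in slot
    ``k``.  The observed-cell mask comes from the layout and is identical for
    every taxon slice; augmented (all-zero) slices copy it unchanged, so the
    missing-data structure of the raw survey propagates into the data
    augmentation.
    """

    y: np.ndarray  # (M, J, K) int8
    layout: StudyLayout
    taxa: tuple[str, ...]
    n_observed_taxa: int

    def __post_init__(self) -> None:
        y = self.y
        if y.ndim != 3:
            raise ValueError("y must be 3-D (taxa, sites, slots)")
        M, J, K = y.shape
        if len(self.taxa) != M:
            raise ValueError("taxon labels do not match array")
        if J != self.layout.n_sites or K != self.layout.n_slots:
            raise ValueError("array shape does not match layout")
        if not 0 <= self.n_observed_taxa <= M:
            raise ValueError("n_observed_taxa out of range")
        mask = self.layout.observed_mask()
        vals = y[:, mask]
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("detections must be 0/1 on observed cells")
        if y[:, ~mask].any():
            raise ValueError("missing cells must carry 0 fill values")
        if y[self.n_observed_taxa:][:, mask].any():
            raise ValueError("augmented taxon slices must be all-zero")

    @property
    def n_taxa(self) -> int:
        return self.y.shape[0]

    @property
    def n_augmented(self) -> int:
        return self.n_taxa - self.n_observed_taxa

    @property
    def mask(self) -> np.ndarray:
        """(J, K) True where surveyed — shared by every taxon slice."""
        return self.layout.observed_mask()

    def detections_per_taxon(self) -> np.ndarray:
        return self.y[:, self.mask].sum(axis=1)

    def detected_sites(self) -> np.ndarray:
        """(M, J) boolean: taxon detected at least once at the site."""
        m = self.mask
        return np.array([(self.y[i] * m).any(axis=1) for i in range(self.n_taxa)])


def assemble_detection_array(
    records: pd.DataFrame | Sequence[Mapping],
    layout: StudyLayout,
    taxa: Sequence[str],
) -> DetectionArray:
    """Build a :class:`DetectionArray` from long-format detection events.

    ``records`` needs columns ``site`` (0-based site index), ``slot``
    (0-based slot index) and ``taxon``; an optional ``detected`` column
    (default 1) lets non-detections travel in the same table and is ignored
    when 0.  Records addressing a cell the layout never surveyed raise
    :class:`DataIntegrityError`; duplicate detections collapse to a single 1
    with a warning (the model is detection/non-detection).
    """
    df = pd.DataFrame(records, columns=["site", "slot", "taxon", "detected"])
    if "detected" in df and df["detected"].notna().any():
        df["detected"] = df["detected"].fillna(1).astype(int)
    else:
        df["detected"] = 1
    taxa = tuple(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    mask = layout.observed_mask()
    y = np.zeros((len(taxa), layout.n_sites, layout.n_slots), dtype=np.int8)
    seen: set[tuple[int, int, int]] = set()
    dupes = 0
    for row in df.itertuples(index=False):
        if row.taxon not in index:
            raise DataIntegrityError(f"unknown taxon {row.taxon!r}")
        j, k = int(row.site), int(row.slot)
        if not (0 <= j < layout.n_sites and 0 <= k < layout.n_slots):
            raise DataIntegrityError(f"site/slot ({j}, {k}) outside layout")
        if not mask[j, k]:
            raise DataIntegrityError(
                f"record addresses unsurveyed cell (site {j}, slot {k})"
            )
        if not row.detected:
            continue
        key = (index[row.taxon], j, k)
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        y[key] = 1
    if dupes:
        warnings.warn(
            f"{dupes} duplicate detection record(s) collapsed to single detections",
            stacklevel=2,
        )
    return DetectionArray(y=y, layout=layout, taxa=taxa, n_observed_taxa=len(taxa))


def augment_detection_array(array: DetectionArray, n_aug: int) -> DetectionArray:
    """Append ``n_aug`` all-zero taxon slices for data augmentation.

    The augmented slices copy the missing-cell pattern of the raw data
    unchanged; nothing else about the array changes.
    """
    if n_aug < 0:
        raise ValueError("n_aug must be >= 0")
    if n_aug == 0:
        return array
    extra = np.zeros((n_aug, *array.y.shape[1:]), dtype=np.int8)
    labels = array.taxa + tuple(
        f"augmented_{i + 1:02d}" for i in range(array.n_augmented, array.n_augmented + n_aug)
    )
    return replace(
        array,
        y=np.concatenate([array.y, extra], axis=0),
        taxa=labels,
    )


@dataclass(frozen=True)
class SiteCovariates:
    """Per-site covariates, raw and standardized.

    ``moments[name] = (mean, sd)`` records the standardization actually
    applied, whether estimated from the sample or injected (e.g. the bundled
    reference moments) for exact replication of a published analysis.
    """

    raw: pd.DataFrame  # one row per site, columns = covariate names
    moments: dict[str, tuple[float, float]]

    @classmethod
    def from_frame(
        cls,
        raw: pd.DataFrame,
        moments: Mapping[str, tuple[float, float]] | None = None,
    ) -> "SiteCovariates":
        raw = raw.reset_index(drop=True).astype(float)
        mom = {}
        for name in raw.columns:
            if moments is not None and name in moments:
                mom[name] = tuple(moments[name])
            else:
                mom[name] = (float(raw[name].mean()), float(raw[name].std(ddof=1)))
        return cls(raw=raw, moments=mom)

    @property
    def n_sites(self) -> int:
        return len(self.raw)

    def standardized(self, name: str) -> np.ndarray:
        mean, sd = self.moments[name]
        return standardize_covariate(self.raw[name].to_numpy(), mean, sd)

    def standardized_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: self.standardized(name) for name in self.raw.columns}
        )


@dataclass(frozen=True)
class SurveyCovariates:
    """Per-(site, slot) covariates, raw and standardized.

    Raw arrays are (J, K) floats with NaN at unsurveyed cells.  On the
    standardized scale unsurveyed cells are filled with 0 (the standardized
    mean) and flagged by the layout mask; the fill is inert because masked
    cells never enter a likelihood, but downstream numerical code needs a
    finite value in every cell.
    """

    raw: dict[str, np.ndarray]
    layout: StudyLayout
    moments: dict[str, tuple[float, float]]

    @classmethod
    def from_arrays(
        cls,
        raw: Mapping[str, np.ndarray],
        layout: StudyLayout,
        moments: Mapping[str, tuple[float, float]] | None = None,
    ) -> "SurveyCovariates":
        mask = layout.observed_mask()
        clean: dict[str, np.ndarray] = {}
        mom: dict[str, tuple[float, float]] = {}
        for name, arr in raw.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != mask.shape:
                raise DataIntegrityError(
                    f"survey covariate {name!r} shape {arr.shape} != layout {mask.shape}"
                )
            if np.isnan(arr[mask]).any():
                raise DataIntegrityError(f"covariate {name!r} missing at surveyed cells")
            arr = arr.copy()
            arr[~mask] = np.nan
            clean[name] = arr
            if moments is not None and name in moments:
                mom[name] = tuple(moments[name])
            else:
                vals = arr[mask]
                mom[name] = (float(vals.mean()), float(vals.std(ddof=1)))
        return cls(raw=clean, layout=layout, moments=mom)

    def standardized(self, name: str) -> np.ndarray:
        """(J, K) standardized values; unsurveyed cells filled with 0."""
        mean, sd = self.moments[name]
        z = standardize_covariate(self.raw[name], mean, sd)
        return np.nan_to_num(z, nan=0.0)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.raw)


def correlation_screen(
    table: pd.DataFrame, threshold: float = 0.6
) -> list[tuple[str, str, float]]:
    """Flag covariate pairs too collinear to enter the same model.

    Returns every unordered pair with |Pearson r| >= ``threshold`` (boundary
    inclusive), computed on pairwise-complete rows.  Constant covariates have
    undefined correlations; such pairs are reported via a warning but never
    excluded.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two covariates to screen")
    corr = table.corr(method="pearson", min_periods=3)
    excluded = []
    cols = list(table.columns)
    for a_idx, a in enumerate(cols):
        for b in cols[a_idx + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r):
                warnings.warn(
                    f"correlation of ({a}, {b}) undefined (constant or too few "
                    "complete rows); pair not excluded",
                    stacklevel=2,
                )
            elif abs(r) >= threshold:
                excluded.append((a, b, float(r)))
    return excluded


# ---------------------------------------------------------------------------
# CSV dialects


def write_detections_csv(array: DetectionArray, path: str | Path) -> None:
    """Long-format detection CSV: site_id, slot, plant, taxon, detected.

    Only observed (site, slot) cells appear; every observed taxon gets one
    row per surveyed cell so zeros round-trip explicitly.  Augmented slices
    are not written (they are reconstructed by ``augment_detection_array``).
    """
    mask = array.mask
    plant = array.layout.plant_indicator()
    rows = []
    for i in range(array.n_observed_taxa):
        for j, k in zip(*np.nonzero(mask)):
            rows.append(
                {
                    "site_id": j,
                    "slot": k,
                    "plant": "LS" if plant[j, k] == LS else "PM",
                    "taxon": array.taxa[i],
                    "detected": int(array.y[i, j, k]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_detections_csv(path: str | Path, layout: StudyLayout) -> DetectionArray:
    """Read the long-format CSV written by :func:`write_detections_csv`."""
    df = pd.read_csv(path, keep_default_na=True)
    taxa = tuple(pd.unique(df["taxon"]))
    plant = layout.plant_indicator()
    expect = {"PM": PM, "LS": LS}
    for row in df.itertuples(index=False):
        j, k = int(row.site_id), int(row.slot)
        if expect.get(str(row.plant)) != plant[j, k]:
            raise DataIntegrityError(
                f"plant label {row.plant!r} contradicts layout at site {j}, slot {k}"
            )
    records = df.rename(columns={"site_id": "site"})[
        ["site", "slot", "taxon", "detected"]
    ]
    return assemble_detection_array(records, layout, taxa)
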