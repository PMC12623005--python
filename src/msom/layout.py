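"""Survey layout for two-host-plant pollinator monitoring designs.

A *site* is a garden; each available host plant at a site contributes a fixed
number of replicate inflorescence surveys ("slots").  Sites fall into three
classes: both plants surveyed, *Pycnanthemum muticum* only, or *Liatris
spicata* only.  The layout fixes, for every (site, slot) cell, whether it was
actually surveyed and which plant it belongs to; the detection array inherits
this missing-cell pattern identically across all taxa, including augmented
all-zero taxa.

Slot convention: with ``r`` replicates per plant the array has ``K = 2 r``
slots.  At "both" sites slots ``0..r-1`` are *P. muticum* and ``r..2r-1`` are
*L. spicata*; single-plant sites use slots ``0..r-1`` for their plant and the
remaining ``r`` slots are missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StudyLayout", "reference_layout", "SITE_CLASSES", "PM", "LS"]

#: "unsurveyed" supports the empty (all-missing) dataset used to calibrate
#: induced priors; such sites contribute no observed cells.
SITE_CLASSES = ("both", "pm_only", "ls_only", "unsurveyed")

#: plant indicator coding: 0 = P. muticum (intercept level), 1 = L. spicata
PM, LS = 0, 1


@dataclass(frozen=True)
class StudyLayout:
    """Which (site, slot) cells were surveyed, and on which host plant.

    Parameters
    ----------
    site_classes
        Per-site plant availability, each one of ``"both"``, ``"pm_only"``,
        ``"ls_only"``.
    replicates_per_plant
        Number of replicate inflorescence surveys per available plant
        (default 5).
    """

    site_classes: tuple[str, ...]
    replicates_per_plant: int = 5

    def __post_init__(self) -> None:
        bad = sorted({c for c in self.site_classes if c not in SITE_CLASSES})
        if bad:
            raise ValueError(f"unknown site classes: {bad}")
        if self.replicates_per_plant < 1:
            raise ValueError("replicates_per_plant must be >= 1")

    @property
    def n_sites(self) -> int:
        return len(self.site_classes)

    @property
    def n_slots(self) -> int:
        """K, the fixed slot dimension of the detection array."""
        return 2 * self.replicates_per_plant

    def observed_mask(self) -> np.ndarray:
        """Boolean (J, K) array; True where the cell was surveyed."""
        r = self.replicates_per_plant
        mask = np.zeros((self.n_sites, self.n_slots), dtype=bool)
        for j, cls in enumerate(self.site_classes):
            if cls == "unsurveyed":
                continue
            mask[j, :r] = True
            if cls == "both":
                mask[j, r:] = True
        return mask

    def plant_indicator(self) -> np.ndarray:
        """Int8 (J, K) array: 0 = *P. muticum*, 1 = *L. spicata*.

        Missing cells carry 0 as an inert fill value; the observed mask, not
        this array, decides which cells enter a likelihood.
        """
        r = self.replicates_per_plant
        pt = np.zeros((self.n_sites, self.n_slots), dtype=np.int8)
        for j, cls in enumerate(self.site_classes):
            if cls == "both":
                pt[j, r:] = LS
            elif cls == "ls_only":
                pt[j, :r] = LS
        return pt

    @property
    def n_observed_slots(self) -> int:
        """Total surveyed (site, slot) cells, counting spatial replicates."""
        r = self.replicates_per_plant
        return sum(
            2 * r if c == "both" else 0 if c == "unsurveyed" else r
            for c in self.site_classes
        )

    def slot_of(self, site: int, plant: int, replicate: int) -> int:
        """Map (site, plant, replicate index within plant) to a slot index.

        ``replicate`` is 0-based within the plant.  Raises if the plant is
        not surveyed at the site.
        """
        r = self.replicates_per_plant
        if not 0 <= replicate < r:
            raise ValueError(f"replicate {replicate} outside 0..{r - 1}")
        cls = self.site_classes[site]
        if cls == "unsurveyed":
            raise ValueError(f"site {site} was not surveyed")
        if plant == PM:
            if cls == "ls_only":
                raise ValueError(f"site {site} has no P. muticum survey")
            return replicate
        if plant == LS:
            if cls == "pm_only":
                raise ValueError(f"site {site} has no L. spicata survey")
            return replicate + (r if cls == "both" else 0)
        raise ValueError(f"plant must be {PM} or {LS}, got {plant}")


def reference_layout() -> StudyLayout:
    """The urban-garden pollinator survey design bundled as a preset.

    50 garden sites: 20 surveyed on both host plants, 20 on *P. muticum*
    only, 10 on *L. spicata* only, with 5 replicate inflorescences per plant
    per visit — 350 surveyed cells in total and 150 missing cells per taxon
    slice of the 50 x 10 array.
    """
    classes = ("both",) * 20 + ("pm_only",) * 20 + ("ls_only",) * 10
    return StudyLayout(site_classes=classes, replicates_per_plant=5)
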