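"""Dataset directory format: plain-CSV serialization of a full study.

A dataset directory contains::

    layout.csv             site_id, site_class        (+ replicates in header row comment-free column)
    detections.csv         long format (site_id, slot, plant, taxon, detected)
    site_covariates.csv    site_id + one column per site covariate (raw)
    survey_covariates.csv  site_id, slot + one column per survey covariate (raw)
    moments.csv            covariate, mean, sd  (standardization actually applied)
    truth.yaml             generative truth, present only for simulated data
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    SiteCovariates,
    SurveyCovariates,
    read_detections_csv,
    write_detections_csv,
)
from .layout import StudyLayout
from .simulate import SimulatedDataset

__all__ = ["write_dataset", "read_dataset", "write_layout_csv", "read_layout_csv"]


def write_layout_csv(layout: StudyLayout, path) -> None:
    pd.DataFrame(
        {
            "site_id": np.arange(layout.n_sites),
            "site_class": layout.site_classes,
            "replicates_per_plant": layout.replicates_per_plant,
        }
    ).to_csv(path, index=False)


def read_layout_csv(path) -> StudyLayout:
    df = pd.read_csv(path)
    reps = int(df["replicates_per_plant"].iloc[0])
    return StudyLayout(
        site_classes=tuple(df.sort_values("site_id")["site_class"]),
        replicates_per_plant=reps,
    )


def write_dataset(sim: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset (including its truth) as a dataset directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = sim.detections.layout
    write_layout_csv(layout, outdir / "layout.csv")
    write_detections_csv(sim.detections, outdir / "detections.csv")

    site = sim.site_covariates.raw.copy()
    site.insert(0, "site_id", np.arange(len(site)))
    site.to_csv(outdir / "site_covariates.csv", index=False)

    mask = layout.observed_mask()
    sites, slots = np.nonzero(mask)
    surv = pd.DataFrame({"site_id": sites, "slot": slots})
    for name in sim.survey_covariates.names:
        surv[name] = sim.survey_covariates.raw[name][sites, slots]
    surv.to_csv(outdir / "survey_covariates.csv", index=False)

    moments = {**sim.site_covariates.moments, **sim.survey_covariates.moments}
    pd.DataFrame(
        [{"covariate": k, "mean": m, "sd": s} for k, (m, s) in moments.items()]
    ).to_csv(outdir / "moments.csv", index=False)

    truth = {
        "hyper": {k: float(v) for k, v in sim.truth.hyper.items()},
        "n_taxa_pool": int(sim.scenario.n_taxa_pool),
        "n_observed": int(sim.truth.n_observed),
        "supercommunity_size": int(sim.truth.w.sum()),
        "seed": int(sim.scenario.seed),
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)


def read_dataset(indir):
    """Read a dataset directory back into package objects.

    Returns ``(detections, site_covariates, survey_covariates)``; the
    standardization moments stored alongside the data are re-applied so a
    refit reproduces the original analysis exactly.
    """
    indir = Path(indir)
    for required in ("layout.csv", "detections.csv"):
        if not (indir / required).exists():
            raise FileNotFoundError(f"dataset directory lacks {required}")
    layout = read_layout_csv(indir / "layout.csv")
    detections = read_detections_csv(indir / "detections.csv", layout)

    moments = {}
    mpath = indir / "moments.csv"
    if mpath.exists():
        mdf = pd.read_csv(mpath)
        moments = {
            r.covariate: (float(r.mean), float(r.sd))
            for r in mdf.itertuples(index=False)
        }

    site_cov = None
    spath = indir / "site_covariates.csv"
    if spath.exists():
        sdf = pd.read_csv(spath).sort_values("site_id").drop(columns=["site_id"])
        site_cov = SiteCovariates.from_frame(sdf, moments=moments)

    survey_cov = None
    vpath = indir / "survey_covariates.csv"
    if vpath.exists():
        vdf = pd.read_csv(vpath)
        arrays = {}
        for name in vdf.columns:
            if name in ("site_id", "slot"):
                continue
            arr = np.full((layout.n_sites, layout.n_slots), np.nan)
            arr[vdf["site_id"], vdf["slot"]] = vdf[name]
            arrays[name] = arr
        survey_cov = SurveyCovariates.from_arrays(arrays, layout, moments=moments)
    return detections, site_cov, survey_cov
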