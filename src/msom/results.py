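"""Posterior summaries, influence classification, and derived diversity.

Conventions (fixed so outputs are bit-reproducible):

* credible intervals are central 95% intervals, i.e. the 2.5% and 97.5%
  quantiles with linear interpolation between order statistics;
* a species-specific coefficient is *influential* when its 95% CrI excludes
  0 and *well supported* when the posterior probability of its sign exceeds
  0.90;
* integer-valued derived parameters (richness, occupied-site counts,
  supercommunity size) are summarised by posterior medians, continuous
  parameters by posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import RHAT_THRESHOLD, PosteriorSamples

__all__ = [
    "summarize_parameter",
    "coefficient_influence",
    "site_richness",
    "supercommunity_size",
    "species_occurrence",
    "CommunityOccupancyResults",
]

WELL_SUPPORTED = 0.90


def summarize_parameter(draws) -> dict:
    """Mean, median, SD, and central 95% CrI of a scalar posterior trace."""
    draws = np.ravel(np.asarray(draws, dtype=float))
    if draws.size < 2:
        raise ValueError("need at least two draws to summarise")
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {
        "mean": float(draws.mean()),
        "median": float(np.median(draws)),
        "sd": float(draws.std(ddof=1)),
        "q2.5": float(lo),
        "q97.5": float(hi),
    }


def coefficient_influence(draws) -> dict:
    """Influence classification for one species-specific coefficient."""
    draws = np.ravel(np.asarray(draws, dtype=float))
    if draws.size < 100:
        raise ValueError("need at least 100 draws to classify influence")
    s = summarize_parameter(draws)
    p_pos = float(np.mean(draws > 0))
    s["p_positive"] = p_pos
    s["influential"] = bool(s["q2.5"] > 0 or s["q97.5"] < 0)
    s["well_supported"] = bool(max(p_pos, 1.0 - p_pos) > WELL_SUPPORTED)
    return s


def _int_summary(draws) -> dict:
    draws = np.ravel(np.asarray(draws))
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {
        "median": float(np.median(draws)),
        "q2.5": float(lo),
        "q97.5": float(hi),
    }


def site_richness(zcol: np.ndarray, observed_per_site=None) -> pd.DataFrame:
    """Per-site richness N_j = sum_i z_ij, summarised by median and CrI."""
    zcol = zcol.reshape(-1, zcol.shape[-1])
    rows = []
    for j in range(zcol.shape[1]):
        row = {"site": j, **_int_summary(zcol[:, j])}
        if observed_per_site is not None:
            row["observed"] = int(observed_per_site[j])
        rows.append(row)
    return pd.DataFrame(rows)


def supercommunity_size(w: np.ndarray) -> dict:
    """Posterior of the regional pool size sum_i w_i (gamma diversity)."""
    totals = w.reshape(-1, w.shape[-1]).sum(axis=1)
    return {**_int_summary(totals), "draws": totals}


def species_occurrence(
    zrow: np.ndarray,
    taxa: tuple[str, ...],
    n_observed: int,
) -> tuple[pd.DataFrame, dict]:
    """Occupied-site counts per taxon, and the taxa-present-anywhere count.

    Augmented taxa have exchangeable posteriors, so the table reports the
    observed taxa plus a single representative undetected taxon.  The second
    return value summarises, per draw, the number of taxa occurring at one
    or more sites (the richness of the sampled landscape).
    """
    flat = zrow.reshape(-1, zrow.shape[-1])
    keep = list(range(n_observed))
    labels = list(taxa[:n_observed])
    if len(taxa) > n_observed:
        keep.append(n_observed)
        labels.append(f"{taxa[n_observed]} (representative undetected)")
    rows = []
    for idx, label in zip(keep, labels):
        rows.append({"taxon": label, **_int_summary(flat[:, idx])})
    present = (flat >= 1).sum(axis=1)
    return pd.DataFrame(rows), {**_int_summary(present), "draws": present}


class CommunityOccupancyResults:
    """Posterior results of a fitted :class:`~msom.model.CommunityOccupancyModel`.

    Wraps the retained draws with summary tables (``summary()``,
    ``hyper_summary()``, ``species_summary()``), influence classification for
    covariate selection, derived diversity parameters, goodness-of-fit and
    convergence diagnostics.
    """

    def __init__(self, model, samples: PosteriorSamples) -> None:
        self.model = model
        self.samples = samples

    # -- parameter tables --------------------------------------------------

    def hyper_summary(self) -> pd.DataFrame:
        rows = []
        for label in self.samples.hyper_labels():
            tr = self.samples.hyper_trace(label)
            rows.append({"parameter": label, **summarize_parameter(tr)})
        return pd.DataFrame(rows)

    def species_summary(self, side: str = "p") -> pd.DataFrame:
        """Per-taxon parameter table for one sub-model (``"p"`` or ``"psi"``)."""
        names = self.samples.det_names if side == "p" else self.samples.occ_names
        rows = []
        for name in names:
            tr = self.samples.species_trace(side, name)
            intercept = name.startswith("(")
            for i, taxon in enumerate(self.samples.taxa):
                d = coefficient_influence(tr[:, :, i].ravel())
                if intercept:
                    d["influential"] = False  # sign of an intercept is not an effect
                rows.append({"taxon": taxon, "parameter": name, **d})
        return pd.DataFrame(rows)

    def influence_report(self) -> pd.DataFrame:
        """Coefficient influence table over both sub-models (no intercepts)."""
        frames = []
        for side in ("psi", "p"):
            df = self.species_summary(side)
            df = df[~df["parameter"].str.startswith("(")].copy()
            df.insert(0, "submodel", side)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def count_influential(self, term: str, side: str = "p") -> int:
        names = self.samples.det_names if side == "p" else self.samples.occ_names
        if term not in names:
            from .formula import ConfigurationError

            raise ConfigurationError(f"term {term!r} not in fitted {side} sub-model")
        tr = self.samples.species_trace(side, term)
        n = 0
        for i in range(self.samples.n_taxa):
            if coefficient_influence(tr[:, :, i].ravel())["influential"]:
                n += 1
        return n

    # -- derived diversity -------------------------------------------------

    def site_richness(self) -> pd.DataFrame:
        observed = self.model.detections.detected_sites()[
            : self.model.detections.n_observed_taxa
        ].sum(axis=0)
        return site_richness(self.samples.zcol, observed)

    def species_occurrence(self) -> tuple[pd.DataFrame, dict]:
        return species_occurrence(
            self.samples.zrow,
            self.samples.taxa,
            self.model.detections.n_observed_taxa,
        )

    def supercommunity_size(self) -> dict:
        return supercommunity_size(self.samples.w)

    # -- diagnostics -------------------------------------------------------

    def rhat_table(self, include_species: bool = True) -> pd.DataFrame:
        return self.samples.rhat_table(include_species)

    @property
    def converged(self) -> bool:
        return bool((self.rhat_table()["rhat"] < RHAT_THRESHOLD).all())

    def gof(self):
        from .gof import bayesian_p_value

        return bayesian_p_value(self.samples)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (hyperparameters, fit, diversity)."""
        cfg = self.samples.config
        lines = [
            "Community occupancy model (MSOM with data augmentation)",
            f"  formula: {self.model.spec.formula()}",
            f"  taxa: {self.model.detections.n_observed_taxa} observed + "
            f"{self.model.detections.n_augmented} augmented = "
            f"{self.samples.n_taxa}",
            f"  chains: {cfg.n_chains} x {cfg.n_iterations} iterations "
            f"(burn-in {cfg.burn_in}, thin {cfg.thin}) -> "
            f"{cfg.total_retained} retained draws",
            "",
            "Community hyperparameters (posterior mean [95% CrI]):",
        ]
        for _, r in self.hyper_summary().iterrows():
            lines.append(
                f"  {r['parameter']:<24s} {r['mean']:8.2f} "
                f"[{r['q2.5']:.2f}, {r['q97.5']:.2f}]"
            )
        sc = self.supercommunity_size()
        occ, present = self.species_occurrence()
        lines += [
            "",
            "Derived diversity (posterior median [95% CrI]):",
            f"  taxa at >= 1 site      {present['median']:.0f} "
            f"[{present['q2.5']:.0f}, {present['q97.5']:.0f}]",
            f"  supercommunity size    {sc['median']:.0f} "
            f"[{sc['q2.5']:.0f}, {sc['q97.5']:.0f}]",
            f"  max R-hat              {self.samples.max_rhat():.3f} "
            f"({'converged' if self.converged else 'NOT converged'})",
        ]
        if self.samples.d_obs is not None:
            g = self.gof()
            lines.append(
                f"  Bayesian p (deviance)  {g.p_value:.2f} "
                f"({'acceptable' if g.acceptable else 'UNACCEPTABLE'} fit)"
            )
        return "\n".join(lines)

    def to_csv(self, outdir) -> None:
        """Write the summary tables as CSV files into ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.hyper_summary().round(4).to_csv(outdir / "hyperparameters.csv", index=False)
        self.species_summary("p").round(4).to_csv(
            outdir / "species_detection.csv", index=False
        )
        self.species_summary("psi").round(4).to_csv(
            outdir / "species_occupancy.csv", index=False
        )
        self.site_richness().to_csv(outdir / "site_richness.csv", index=False)
        occ, present = self.species_occurrence()
        occ.to_csv(outdir / "species_occurrence.csv", index=False)
        self.rhat_table().round(4).to_csv(outdir / "rhat.csv", index=False)
        if self.samples.d_obs is not None:
            g = self.gof()
            g.to_csv(outdir)
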