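"""Posterior-predictive goodness of fit via a deviance-based Bayesian p-value.

The discrepancy is the model deviance conditional on the current latent
occupancy draw:

    D = -2 sum over observed cells with z_ij = 1 of log Bernoulli(y_ijk | p_ijk)

Cells with ``z_ij = 0`` (necessarily ``y = 0``) contribute 0; missing cells
never contribute.  At every retained draw the sampler records ``D`` for the
observed data and for one replicate dataset drawn from the same (z, p), and
the Bayesian p-value is the fraction of draws with ``D_rep >= D_obs`` (ties
count toward the p-value).  Values above 0.9 or below 0.1 flag unacceptable
fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples

__all__ = [
    "conditional_deviance",
    "replicate_dataset",
    "bayesian_p_value",
    "GofResult",
]


def conditional_deviance(y, z, p, mask) -> float:
    """Deviance of detections given occupancy: shapes (M, J, K), (M, J), (M, J, K), (J, K).

    Raises if a detection occurs where ``z = 0`` (impossible under the
    model).
    """
    y = np.asarray(y)
    z = np.asarray(z)
    p = np.asarray(p, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    live = mask[None, :, :] & (z[:, :, None] == 1)
    if ((y == 1) & mask[None, :, :] & (z[:, :, None] == 0)).any():
        raise ValueError("detection recorded at a cell with z = 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(
            live, np.where(y == 1, np.log(p), np.log1p(-p)), 0.0
        )
    return float(-2.0 * ll.sum())


def deviance_by_site(y, z, p, mask) -> np.ndarray:
    """Per-site contributions; sums exactly to :func:`conditional_deviance`."""
    y = np.asarray(y)
    z = np.asarray(z)
    p = np.asarray(p, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    live = mask[None, :, :] & (z[:, :, None] == 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(live, np.where(y == 1, np.log(p), np.log1p(-p)), 0.0)
    return -2.0 * ll.sum(axis=(0, 2))


def replicate_dataset(z, p, mask, seed=None) -> np.ndarray:
    """Draw one replicated detection array y_rep ~ Bernoulli(z * p).

    Missing cells stay 0-filled (they remain missing under ``mask``).
    """
    rng = np.random.default_rng(seed)
    z = np.asarray(z)
    p = np.asarray(p, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    y_rep = (rng.random(p.shape) < z[:, :, None] * p).astype(np.int8)
    y_rep[:, ~mask] = 0
    return y_rep


@dataclass(frozen=True)
class GofResult:
    """Bayesian p-value with its draw-level deviance pairs and decompositions."""

    p_value: float
    d_obs: np.ndarray
    d_rep: np.ndarray
    site_contributions: np.ndarray | None
    taxon_contributions: np.ndarray | None

    @property
    def acceptable(self) -> bool:
        return 0.1 <= self.p_value <= 0.9

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"d_obs": self.d_obs, "d_rep": self.d_rep}).to_csv(
            outdir / "gof_deviance.csv", index=False
        )
        meta = {"bayesian_p_value": [self.p_value], "acceptable": [self.acceptable]}
        pd.DataFrame(meta).to_csv(outdir / "gof.csv", index=False)
        if self.site_contributions is not None:
            pd.DataFrame(
                {"site": np.arange(self.site_contributions.size),
                 "mean_deviance": self.site_contributions}
            ).to_csv(outdir / "gof_by_site.csv", index=False)
        if self.taxon_contributions is not None:
            pd.DataFrame(
                {"taxon": np.arange(self.taxon_contributions.size),
                 "mean_deviance": self.taxon_contributions}
            ).to_csv(outdir / "gof_by_taxon.csv", index=False)


def bayesian_p_value(samples: PosteriorSamples) -> GofResult:
    """Assemble the posterior-predictive check from a fit's deviance traces."""
    if samples.d_obs is None or samples.d_rep is None:
        raise ValueError("fit was run without goodness-of-fit traces")
    d_obs = samples.d_obs.ravel()
    d_rep = samples.d_rep.ravel()
    return GofResult(
        p_value=float(np.mean(d_rep >= d_obs)),
        d_obs=d_obs,
        d_rep=d_rep,
        site_contributions=samples.site_deviance,
        taxon_contributions=samples.taxon_deviance,
    )
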