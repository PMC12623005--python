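"""MCMC driver, posterior-sample container, and convergence diagnostics.

The sampler is Metropolis-within-Gibbs: exact full conditionals for the
binary latent indicators (site occupancy ``z``, supercommunity membership
``w``) and for ``Omega`` (conjugate Beta), adaptive Gaussian random-walk
Metropolis for species effects and community means, and log-scale random
walks for community SDs with rejection outside their uniform prior support.
Adaptation targets 0.44 acceptance and is frozen after burn-in, so the
retained chain is a valid Markov chain with the posterior as its invariant
distribution.

Chains are reproducible: chain ``c`` of a run with seed ``s`` always uses
the same derived kernel seed, and identical inputs give bit-identical
traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ModelDesign, logit
from .priors import PriorSpec

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "run_mcmc_design",
    "gelman_rubin",
    "effective_sample_size",
    "z_full_conditional",
    "w_full_conditional",
    "omega_full_conditional",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule.  Retained draws per chain = (n_iterations - burn_in) // thin."""

    n_chains: int = 3
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be in [0, n_iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @property
    def total_retained(self) -> int:
        return self.n_chains * self.retained_per_chain

    def chain_seed(self, chain: int) -> int:
        return int((self.seed * 1_000_003 + 7_919 * chain + 12_345) % (2**31 - 1))


# ---------------------------------------------------------------------------
# closed-form full conditionals (unit-testable; mirrored inside the kernel)


def z_full_conditional(w: int, psi: float, p_slots, y_slots) -> float:
    """Pr(z = 1 | w, psi, p, y) for one (taxon, site).

    Certain 1 if any detection; certain 0 if ``w = 0``; otherwise the Bayes
    weight of an occupied-but-undetected site against an unoccupied one.
    """
    y_slots = np.asarray(y_slots)
    p_slots = np.asarray(p_slots, dtype=float)
    if y_slots.size and y_slots.any():
        return 1.0
    if w == 0:
        return 0.0
    q = float(np.prod(1.0 - p_slots))
    return psi * q / (psi * q + 1.0 - psi)


def w_full_conditional(omega: float, psi_sites, z_sites) -> float:
    """Pr(w = 1 | Omega, psi, z) for one taxon."""
    z_sites = np.asarray(z_sites)
    if z_sites.size and z_sites.any():
        return 1.0
    q = float(np.prod(1.0 - np.asarray(psi_sites, dtype=float)))
    return omega * q / (omega * q + 1.0 - omega)


def omega_full_conditional(w, a: float, b: float) -> tuple[float, float]:
    """Beta posterior parameters for Omega given the membership vector."""
    w = np.asarray(w)
    return a + float(w.sum()), b + float(w.size - w.sum())


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(traces) -> float:
    """Potential scale reduction factor (PSRF) for one scalar parameter.

    ``traces`` is (n_chains, n_draws).  Degenerate traces (zero within- and
    between-chain variance) return exactly 1.0 with a warning; zero within-
    chain variance with distinct chains returns ``inf``.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need (n_chains >= 2, n_draws) traces")
    n = traces.shape[1]
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    within = traces.var(axis=1, ddof=1).mean()
    b_over_n = traces.mean(axis=1).var(ddof=1)
    if within == 0.0:
        if b_over_n == 0.0:
            warnings.warn("degenerate (constant) traces; R-hat set to 1", stacklevel=2)
            return 1.0
        return np.inf
    var_hat = (n - 1) / n * within + b_over_n
    return float(np.sqrt(var_hat / within))


def effective_sample_size(traces) -> float:
    """Multi-chain effective sample size via Geyer's initial monotone sequence."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_chains, n = traces.shape
    if n < 4:
        return float(n_chains * n)
    centered = traces - traces.mean(axis=1, keepdims=True)
    fsize = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=fsize, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), n=fsize, axis=1)[:, :n].real
    acov /= n
    var = acov[:, 0].mean()
    if var == 0.0:
        return float(n_chains * n)
    rho = acov.mean(axis=0) / var
    # pair sums; truncate at first negative pair, enforce monotonicity
    tau = 1.0
    prev = np.inf
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += 2.0 * pair
    return float(n_chains * n / max(tau, 1.0))


def mc_standard_error(traces) -> float:
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    ess = effective_sample_size(traces)
    return float(traces.std(ddof=1) / np.sqrt(max(ess, 1.0)))


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Retained draws for one model fit, organised chain-major.

    Hyper traces are (chains, draws[, column]); species traces are
    (chains, draws, taxa, column).  ``zrow``/``zcol`` are the per-draw
    occupied-site count per taxon and richness per site — sufficient
    statistics for every derived diversity quantity.  ``z`` is the full
    latent occupancy trace when requested at fit time.
    """

    config: MCMCConfig
    taxa: tuple[str, ...]
    det_names: tuple[str, ...]
    occ_names: tuple[str, ...]
    omega: np.ndarray
    mu_det: np.ndarray
    sd_det: np.ndarray
    mu_occ: np.ndarray
    sd_occ: np.ndarray
    species_det: np.ndarray
    species_occ: np.ndarray
    w: np.ndarray
    zrow: np.ndarray
    zcol: np.ndarray
    z: np.ndarray | None = None
    d_obs: np.ndarray | None = None
    d_rep: np.ndarray | None = None
    site_deviance: np.ndarray | None = None
    taxon_deviance: np.ndarray | None = None
    acceptance: dict = field(default_factory=dict)
    hyper_fixed: bool = False

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_retained(self) -> int:
        return int(self.omega.shape[0] * self.omega.shape[1])

    def hyper_labels(self) -> list[str]:
        labels = ["omega"]
        if not self.hyper_fixed:
            for name in self.occ_names:
                labels += [f"mu_psi[{name}]", f"sd_psi[{name}]"]
            for name in self.det_names:
                labels += [f"mu_p[{name}]", f"sd_p[{name}]"]
        return labels

    def hyper_trace(self, label: str) -> np.ndarray:
        """(chains, draws) trace for a hyperparameter label."""
        if label == "omega":
            return self.omega
        kind, _, rest = label.partition("_")
        side, name = rest.split("[", 1)
        name = name[:-1]
        if side == "psi":
            arr = self.mu_occ if kind == "mu" else self.sd_occ
            col = self.occ_names.index(name)
        else:
            arr = self.mu_det if kind == "mu" else self.sd_det
            col = self.det_names.index(name)
        return arr[:, :, col]

    def species_trace(self, side: str, name: str) -> np.ndarray:
        """(chains, draws, taxa) trace for one coefficient column."""
        if side == "psi":
            return self.species_occ[:, :, :, self.occ_names.index(name)]
        return self.species_det[:, :, :, self.det_names.index(name)]

    def stacked(self, traces: np.ndarray) -> np.ndarray:
        """Merge the chain axis into the draw axis."""
        return np.asarray(traces).reshape(-1, *np.asarray(traces).shape[2:])

    def rhat_table(self, include_species: bool = True) -> pd.DataFrame:
        rows = []
        for label in self.hyper_labels():
            rows.append((label, gelman_rubin(self.hyper_trace(label))))
        if include_species:
            for side, names in (("psi", self.occ_names), ("p", self.det_names)):
                for name in names:
                    tr = self.species_trace(side, name)
                    for i, taxon in enumerate(self.taxa):
                        rows.append((f"{side}[{name}][{taxon}]",
                                     gelman_rubin(tr[:, :, i])))
        df = pd.DataFrame(rows, columns=["parameter", "rhat"])
        df["converged"] = df["rhat"] < RHAT_THRESHOLD
        return df

    def max_rhat(self, include_species: bool = True) -> float:
        return float(self.rhat_table(include_species)["rhat"].max())

    def save(self, outdir) -> None:
        """Write per-chain parameter traces as CSV plus a registry sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        columns: list[str] = []
        for c in range(self.config.n_chains):
            cols = {"omega": self.omega[c]}
            for label in self.hyper_labels()[1:]:
                cols[label] = self.hyper_trace(label)[c]
            for side, names in (("psi", self.occ_names), ("p", self.det_names)):
                for name in names:
                    tr = self.species_trace(side, name)
                    for i, taxon in enumerate(self.taxa):
                        cols[f"{side}[{name}][{taxon}]"] = tr[c, :, i]
            pd.DataFrame(cols).to_csv(outdir / f"chain_{c}.csv", index=False)
            columns = list(cols)
        pd.DataFrame({"parameter": columns}).to_csv(
            outdir / "parameter_registry.csv", index=False
        )


# ---------------------------------------------------------------------------
# driver


def _initial_state(design: ModelDesign, rng: np.random.Generator,
                   fixed: Mapping[str, np.ndarray] | None, priors: PriorSpec):
    M, C = design.y_cells.shape
    J = design.n_sites
    Td = design.X_det.shape[1]
    To = design.X_occ.shape[1]

    det_any = np.zeros((M, J), dtype=bool)
    for j in range(J):
        lo, hi = design.site_ptr[j], design.site_ptr[j + 1]
        if hi > lo:
            det_any[:, j] = design.y_cells[:, lo:hi].any(axis=1)
    observed = det_any.any(axis=1)

    w0 = np.where(observed, 1, rng.integers(0, 2, size=M)).astype(np.int8)
    z0 = np.where(
        det_any, 1, (rng.random((M, J)) < 0.5) & (w0[:, None] == 1)
    ).astype(np.int8)

    eps = 1e-3
    if C:
        det_rate = np.clip(design.y_cells.mean(axis=1), eps, 1 - eps)
    else:
        det_rate = np.full(M, 0.5)
    occ_rate = np.clip(det_any.mean(axis=1), eps, 1 - eps)

    Adet0 = np.zeros((M, Td))
    Adet0[:, 0] = np.clip(logit(det_rate), -3.0, 3.0)
    Aocc0 = np.zeros((M, To))
    Aocc0[:, 0] = np.clip(logit(occ_rate), -3.0, 3.0)

    if fixed is not None:
        mu_det0 = np.asarray(fixed["mu_det"], dtype=float).copy()
        sd_det0 = np.asarray(fixed["sd_det"], dtype=float).copy()
        mu_occ0 = np.asarray(fixed["mu_occ"], dtype=float).copy()
        sd_occ0 = np.asarray(fixed["sd_occ"], dtype=float).copy()
    else:
        mu_det0 = np.zeros(Td)
        mu_det0[0] = Adet0[:, 0].mean()
        sd_det0 = np.ones(Td)
        mu_occ0 = np.zeros(To)
        mu_occ0[0] = Aocc0[:, 0].mean()
        sd_occ0 = np.ones(To)
    omega0 = float((w0.sum() + 0.5) / (M + 1))
    return w0, z0, Adet0, Aocc0, mu_det0, sd_det0, mu_occ0, sd_occ0, omega0


def run_mcmc_design(
    design: ModelDesign,
    priors: PriorSpec,
    config: MCMCConfig,
    fixed_hyperparams: Mapping[str, np.ndarray] | None = None,
    store_z: bool = False,
    compute_gof: bool = True,
    taxa: tuple[str, ...] | None = None,
) -> PosteriorSamples:
    """Run all chains of the Metropolis-within-Gibbs sampler on a design."""
    from ._kernel import run_chain

    if taxa is None:
        taxa = tuple(f"taxon_{i}" for i in range(design.n_taxa))
    R = config.retained_per_chain
    if R < 1:
        raise ValueError("schedule retains no draws")

    chains = []
    for c in range(config.n_chains):
        seed = config.chain_seed(c)
        rng = np.random.default_rng(seed)
        state = _initial_state(design, rng, fixed_hyperparams, priors)
        out = run_chain(
            design.y_groups,
            design.n_trials,
            design.group_site,
            design.group_ptr,
            design.Xg_det,
            design.X_occ,
            design.det_kind,
            design.occ_kind,
            design.det_sd_bound,
            design.occ_sd_bound,
            float(priors.coef_mean_sd**2),
            float(priors.omega_a),
            float(priors.omega_b),
            fixed_hyperparams is not None,
            config.n_iterations,
            config.burn_in,
            config.thin,
            seed,
            store_z,
            compute_gof,
            *state,
        )
        chains.append(out)

    def stack(idx):
        return np.stack([ch[idx] for ch in chains])

    # hyper means/SDs use slice updates (no acceptance rate to report)
    acceptance = {
        "species_det": stack(15),
        "species_occ": stack(16),
    }
    return PosteriorSamples(
        config=config,
        taxa=tuple(taxa),
        det_names=design.det_names,
        occ_names=design.occ_names,
        omega=stack(0),
        mu_det=stack(1),
        sd_det=stack(2),
        mu_occ=stack(3),
        sd_occ=stack(4),
        species_det=stack(5),
        species_occ=stack(6),
        w=stack(7),
        zrow=stack(8),
        zcol=stack(9),
        z=stack(10) if store_z else None,
        d_obs=stack(11) if compute_gof else None,
        d_rep=stack(12) if compute_gof else None,
        site_deviance=stack(13).mean(axis=0) if compute_gof else None,
        taxon_deviance=stack(14).mean(axis=0) if compute_gof else None,
        acceptance=acceptance,
        hyper_fixed=fixed_hyperparams is not None,
    )
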