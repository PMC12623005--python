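"""The hierarchical multispecies occupancy model (MSOM) with data augmentation.

Model
-----
For taxon ``i``, site ``j``, replicate slot ``k``::

    w_i            ~ Bernoulli(Omega)                 (supercommunity membership)
    z_ij | w_i     ~ Bernoulli(w_i * psi_ij)          (site occupancy)
    y_ijk | z_ij   ~ Bernoulli(z_ij * p_ijk)          (detection)

    logit psi_ij = lpsi_i + sum_t betalpsi_t,i * x_occ[j, t]
    logit p_ijk  = lp_i   + betalp.f_i * ptcov_jk + sum_t betalp_t,i * x_det[j, k, t]

Species-specific intercepts and coefficients are exchangeable draws from
community-level normal distributions whose means and SDs carry the
hyperpriors in :mod:`msom.priors`.  Missing (unsurveyed) cells contribute
nothing to any likelihood.  Interactions enter as products of standardized
main-effect columns and quadratics as squares of standardized columns, so a
covariate value of 0 is the covariate's mean.

:class:`CommunityOccupancyModel` is the statsmodels-style entry point: build
it from a :class:`~msom.data.DetectionArray` plus covariate tables and a
:class:`~msom.formula.ModelSpec`, call :meth:`fit` to run the MCMC, and work
with the returned :class:`~msom.results.CommunityOccupancyResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
from scipy.special import expit as _expit
from scipy.stats import beta as _beta_dist

from .data import (
    SITE_COVARIATES,
    DetectionArray,
    SiteCovariates,
    SurveyCovariates,
)
from .formula import ConfigurationError, ModelSpec, Term, parse_formula
from .priors import PriorSpec

if TYPE_CHECKING:  # pragma: no cover
    from .results import CommunityOccupancyResults
    from .sampler import MCMCConfig

__all__ = [
    "inv_logit",
    "logit",
    "ModelDesign",
    "build_design",
    "occupancy_probability",
    "detection_probability",
    "latent_data_log_density",
    "CommunityOccupancyModel",
]

# prior-kind codes shared with the sampler kernel
KIND_INTERCEPT, KIND_COEF = 0, 1


def inv_logit(x):
    """Inverse logit (logistic) link: ``1 / (1 + exp(-x))``."""
    return _expit(x)


def logit(p):
    return np.log(p) - np.log1p(-np.asarray(p, dtype=float))


def _softplus(x):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, 0.0) + np.log1p(np.exp(-np.abs(x)))


@dataclass(frozen=True)
class ModelDesign:
    """Flattened design arrays consumed by the sampler kernel.

    Detection covariates are stored per observed cell (cells sorted by site,
    then slot); occupancy covariates per site.  Column 0 of each matrix is
    the intercept.  ``*_kind`` codes the hyperprior family of each column
    (0 = intercept, 1 = coefficient) and ``*_sd_bound`` the Uniform upper
    bound of the column's community-SD hyperprior.
    """

    y_cells: np.ndarray        # (M, C) int8
    cell_site: np.ndarray      # (C,) int64
    cell_slot: np.ndarray      # (C,) int64
    site_ptr: np.ndarray       # (J + 1,) int64
    X_det: np.ndarray          # (C, Td)
    X_occ: np.ndarray          # (J, To)
    det_names: tuple[str, ...]
    occ_names: tuple[str, ...]
    det_kind: np.ndarray       # (Td,) int8
    occ_kind: np.ndarray       # (To,) int8
    det_sd_bound: np.ndarray   # (Td,)
    occ_sd_bound: np.ndarray   # (To,)
    # Binomial collapse: cells of one site sharing a detection-covariate row
    # form a group (e.g. the replicate slots of one visit).  The Bernoulli
    # product over a group equals a Binomial likelihood in its success
    # count, which is what the sampler kernel evaluates.
    Xg_det: np.ndarray = None        # (G, Td)
    group_site: np.ndarray = None    # (G,) int64
    group_ptr: np.ndarray = None     # (J + 1,) int64
    n_trials: np.ndarray = None      # (G,) int16
    y_groups: np.ndarray = None      # (M, G) int16

    @property
    def n_taxa(self) -> int:
        return self.y_cells.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.site_ptr) - 1

    @property
    def n_cells(self) -> int:
        return self.y_cells.shape[1]


def _term_values_detection(
    term: Term,
    layout,
    site_cov: SiteCovariates | None,
    survey_cov: SurveyCovariates | None,
) -> np.ndarray:
    """(J, K) standardized covariate values for one detection term."""
    J, K = layout.n_sites, layout.n_slots

    def main(var: str) -> np.ndarray:
        if var == "plant":
            return layout.plant_indicator().astype(float)
        if var in SITE_COVARIATES:
            if site_cov is None or var not in site_cov.raw.columns:
                raise ConfigurationError(f"site covariate {var!r} not supplied")
            return np.repeat(site_cov.standardized(var)[:, None], K, axis=1)
        if survey_cov is None or var not in survey_cov.names:
            raise ConfigurationError(f"survey covariate {var!r} not supplied")
        return survey_cov.standardized(var)

    vals = main(term.vars[0])
    if len(term.vars) == 2:
        vals = vals * main(term.vars[1])
    return vals


def _term_values_occupancy(term: Term, site_cov: SiteCovariates | None) -> np.ndarray:
    def main(var: str) -> np.ndarray:
        if site_cov is None or var not in site_cov.raw.columns:
            raise ConfigurationError(f"site covariate {var!r} not supplied")
        return site_cov.standardized(var)

    vals = main(term.vars[0])
    if len(term.vars) == 2:
        vals = vals * main(term.vars[1])
    return vals


def build_design(
    detections: DetectionArray,
    spec: ModelSpec,
    site_cov: SiteCovariates | None = None,
    survey_cov: SurveyCovariates | None = None,
    priors: PriorSpec | None = None,
) -> ModelDesign:
    """Assemble the flattened per-cell design matrices for a model spec."""
    priors = priors or PriorSpec()
    layout = detections.layout
    mask = detections.mask
    sites, slots = np.nonzero(mask)  # row-major: sorted by site then slot
    C = sites.size
    y_cells = detections.y[:, sites, slots].astype(np.int8)

    site_ptr = np.zeros(layout.n_sites + 1, dtype=np.int64)
    np.add.at(site_ptr[1:], sites, 1)
    site_ptr = np.cumsum(site_ptr)

    det_cols = [np.ones(C)]
    det_names = ["(p intercept)"]
    det_kind = [KIND_INTERCEPT]
    det_bound = [priors.intercept_sd_bound]
    for term in spec.detection:
        vals = _term_values_detection(term, layout, site_cov, survey_cov)
        det_cols.append(vals[sites, slots])
        det_names.append(term.name)
        det_kind.append(KIND_COEF)
        det_bound.append(
            priors.plant_sd_bound if term.vars == ("plant",) else priors.coef_sd_bound
        )

    occ_cols = [np.ones(layout.n_sites)]
    occ_names = ["(psi intercept)"]
    occ_kind = [KIND_INTERCEPT]
    occ_bound = [priors.intercept_sd_bound]
    for term in spec.occupancy:
        occ_cols.append(_term_values_occupancy(term, site_cov))
        occ_names.append(term.name)
        occ_kind.append(KIND_COEF)
        occ_bound.append(priors.coef_sd_bound)

    X_det = np.column_stack(det_cols)

    # collapse identical covariate rows within a site into binomial groups
    group_of_cell = np.empty(C, dtype=np.int64)
    g_site: list[int] = []
    g_rows: list[np.ndarray] = []
    g_trials: list[int] = []
    for j in range(layout.n_sites):
        lo, hi = site_ptr[j], site_ptr[j + 1]
        seen: dict[bytes, int] = {}
        for c in range(lo, hi):
            key = X_det[c].tobytes()
            if key not in seen:
                seen[key] = len(g_site)
                g_site.append(j)
                g_rows.append(X_det[c])
                g_trials.append(0)
            g = seen[key]
            group_of_cell[c] = g
            g_trials[g] += 1
    G = len(g_site)
    y_groups = np.zeros((y_cells.shape[0], G), dtype=np.int16)
    for c in range(C):
        y_groups[:, group_of_cell[c]] += y_cells[:, c]
    group_site = np.array(g_site, dtype=np.int64)
    group_ptr = np.zeros(layout.n_sites + 1, dtype=np.int64)
    np.add.at(group_ptr[1:], group_site, 1)
    group_ptr = np.cumsum(group_ptr)

    return ModelDesign(
        y_cells=y_cells,
        cell_site=sites.astype(np.int64),
        cell_slot=slots.astype(np.int64),
        site_ptr=site_ptr,
        X_det=X_det,
        X_occ=np.column_stack(occ_cols),
        det_names=tuple(det_names),
        occ_names=tuple(occ_names),
        det_kind=np.array(det_kind, dtype=np.int8),
        occ_kind=np.array(occ_kind, dtype=np.int8),
        det_sd_bound=np.array(det_bound, dtype=float),
        occ_sd_bound=np.array(occ_bound, dtype=float),
        Xg_det=np.vstack(g_rows) if G else np.zeros((0, X_det.shape[1])),
        group_site=group_site,
        group_ptr=group_ptr,
        n_trials=np.array(g_trials, dtype=np.int16),
        y_groups=y_groups,
    )


def occupancy_probability(coefs: np.ndarray, X_occ: np.ndarray) -> np.ndarray:
    """psi per site from species coefficients (column 0 = intercept).

    ``coefs`` may be one species' vector (To,) giving a (J,) result, or a
    matrix (M, To) giving (M, J).
    """
    return inv_logit(np.asarray(coefs, dtype=float) @ X_occ.T)


def detection_probability(coefs: np.ndarray, X_det: np.ndarray) -> np.ndarray:
    """p per observed cell from species coefficients; shapes as above."""
    return inv_logit(np.asarray(coefs, dtype=float) @ X_det.T)


def latent_data_log_density(
    y_cells: np.ndarray,
    cell_site: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    omega: float,
    psi: np.ndarray,
    p_cells: np.ndarray,
) -> float:
    """log p(y, z, w | Omega, psi, p), Bernoulli terms over observed cells only.

    ``psi`` is (M, J), ``p_cells`` (M, C).  Returns ``-inf`` for impossible
    configurations (a detection where ``z = 0``, or ``z = 1`` where
    ``w = 0``).  Missing cells never appear in ``y_cells`` and therefore
    contribute exactly 0.
    """
    w = np.asarray(w)
    z = np.asarray(z)
    if ((z == 1) & (w[:, None] == 0)).any():
        return -np.inf
    z_cells = z[:, cell_site]
    if ((y_cells == 1) & (z_cells == 0)).any():
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        total = float(
            np.sum(np.where(w == 1, np.log(omega), np.log1p(-omega)))
        )
        occ = np.where(
            w[:, None] == 1,
            np.where(z == 1, np.log(psi), np.log1p(-psi)),
            0.0,
        )
    total += float(occ.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        det = np.where(
            z_cells == 1,
            np.where(y_cells == 1, np.log(p_cells), np.log1p(-p_cells)),
            0.0,
        )
    total += float(det.sum())
    return total


class CommunityOccupancyModel:
    """Bayesian MSOM with data augmentation, fitted by MCMC.

    Parameters
    ----------
    detections
        Detection/non-detection array, typically after
        :func:`~msom.data.augment_detection_array`.
    site_covariates, survey_covariates
        Covariate tables; only the covariates named by the model terms are required.
    spec
        Occupancy/detection term specification (default: intercept-only
        occupancy, detection with the host-plant term).
    priors
        Hyperprior settings (default: the minimally informative set).

    Examples
    --------
    >>> model = CommunityOccupancyModel.from_formula(
    ...     "psi ~ 1, p ~ plant", detections)      # doctest: +SKIP
    >>> res = model.fit(MCMCConfig(n_chains=3, n_iterations=20_000,
    ...                            burn_in=5_000, thin=5, seed=1))  # doctest: +SKIP
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(
        self,
        detections: DetectionArray,
        site_covariates: SiteCovariates | None = None,
        survey_covariates: SurveyCovariates | None = None,
        spec: ModelSpec | None = None,
        priors: PriorSpec | None = None,
    ) -> None:
        self.detections = detections
        self.site_covariates = site_covariates
        self.survey_covariates = survey_covariates
        self.spec = spec if spec is not None else ModelSpec()
        self.priors = priors or PriorSpec()
        self.design = build_design(
            detections, self.spec, site_covariates, survey_covariates, self.priors
        )

    @classmethod
    def from_formula(
        cls,
        formula: str,
        detections: DetectionArray,
        site_covariates: SiteCovariates | None = None,
        survey_covariates: SurveyCovariates | None = None,
        priors: PriorSpec | None = None,
    ) -> "CommunityOccupancyModel":
        return cls(
            detections,
            site_covariates,
            survey_covariates,
            spec=parse_formula(formula),
            priors=priors,
        )

    # -- probabilities ----------------------------------------------------

    def psi(self, occ_coefs: np.ndarray) -> np.ndarray:
        """Occupancy probability per site for coefficient rows (M, To)."""
        return inv_logit(np.atleast_2d(occ_coefs) @ self.design.X_occ.T)

    def p(self, det_coefs: np.ndarray) -> np.ndarray:
        """Detection probability per observed cell for rows (M, Td)."""
        return inv_logit(np.atleast_2d(det_coefs) @ self.design.X_det.T)

    # -- densities ---------------------------------------------------------

    def joint_log_density(
        self,
        w: np.ndarray,
        z: np.ndarray,
        occ_coefs: np.ndarray,
        det_coefs: np.ndarray,
        omega: float,
        hyper: Mapping[str, np.ndarray] | None = None,
        include_priors: bool = True,
    ) -> float:
        """log joint density of data, latent states and parameters.

        ``hyper`` maps ``mu_occ, sd_occ, mu_det, sd_det`` to per-column
        arrays; required when ``include_priors``.  Non-finite parameters
        raise; impossible latent configurations return ``-inf``.
        """
        occ_coefs = np.atleast_2d(occ_coefs)
        det_coefs = np.atleast_2d(det_coefs)
        for arr in (occ_coefs, det_coefs):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite species parameter")
        total = latent_data_log_density(
            self.design.y_cells,
            self.design.cell_site,
            w,
            z,
            omega,
            self.psi(occ_coefs),
            self.p(det_coefs),
        )
        if not include_priors or not np.isfinite(total):
            return total
        if hyper is None:
            raise ValueError("hyper parameters required when include_priors")
        pr = self.priors
        total += float(_beta_dist.logpdf(omega, pr.omega_a, pr.omega_b))
        for coefs, kinds, bounds, mu_key, sd_key in (
            (occ_coefs, self.design.occ_kind, self.design.occ_sd_bound, "mu_occ", "sd_occ"),
            (det_coefs, self.design.det_kind, self.design.det_sd_bound, "mu_det", "sd_det"),
        ):
            mu = np.asarray(hyper[mu_key], dtype=float)
            sd = np.asarray(hyper[sd_key], dtype=float)
            if np.any(sd <= 0) or np.any(sd > bounds):
                return -np.inf
            # species-level normal densities
            total += float(
                np.sum(
                    -0.5 * np.log(2 * np.pi)
                    - np.log(sd)
                    - 0.5 * ((coefs - mu) / sd) ** 2
                )
            )
            # hyperpriors: logistic for intercept means, Normal(0, 10) for
            # coefficient means, Uniform(0, bound) for SDs
            for c, kind in enumerate(kinds):
                if kind == KIND_INTERCEPT:
                    total += float(-mu[c] - 2.0 * _softplus(-mu[c]))
                else:
                    v = pr.coef_mean_sd**2
                    total += float(
                        -0.5 * np.log(2 * np.pi * v) - mu[c] ** 2 / (2 * v)
                    )
                total += -np.log(bounds[c])
        return total

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        config: "MCMCConfig | None" = None,
        fixed_hyperparams: Mapping[str, np.ndarray] | None = None,
        store_z: bool = False,
        compute_gof: bool = True,
    ) -> "CommunityOccupancyResults":
        """Draw from the posterior and wrap the samples in a results object.

        ``fixed_hyperparams`` pins community means/SDs (``mu_occ``,
        ``sd_occ``, ``mu_det``, ``sd_det``) instead of sampling them — used
        for validation against the exact tiny-instance oracle.  ``store_z``
        keeps the full per-draw occupancy matrix (memory permitting);
        reduced richness traces are always kept.
        """
        from .results import CommunityOccupancyResults
        from .sampler import MCMCConfig, run_mcmc_design

        config = config or MCMCConfig()
        samples = run_mcmc_design(
            self.design,
            self.priors,
            config,
            fixed_hyperparams=fixed_hyperparams,
            store_z=store_z,
            compute_gof=compute_gof,
            taxa=self.detections.taxa,
        )
        return CommunityOccupancyResults(self, samples)
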