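"""Heuristic forward-stepwise covariate selection by influence counts.

Information criteria (DIC, WAIC, BIC) are contested for hierarchical
occupancy models, so selection here follows the credible-interval screening
heuristic: a covariate earns its place when its species-specific coefficient
CrIs exclude zero for *multiple* taxa (operationalised as >= 2; covariates
dropped in practice had at most one such taxon).  Candidates are tested one
at a time on top of the current base model, the candidate with the most
influential coefficients advances, and previously retained main effects are
re-checked each round and dropped once other covariates absorb their signal.
Site covariates are tested on the occupancy side first, then on detection;
the host-plant term stays in every detection model.  Interactions are only
eligible once both mains are in the base; collinear pairs (|Pearson r| >=
0.6) never co-occur.

The procedure is deterministic given the fit summaries: ties break in favour
of main effects over interactions, then by candidate-pool order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Sequence

import pandas as pd

from .formula import ConfigurationError, ModelSpec, Term
from .priors import PriorSpec

__all__ = [
    "CandidatePool",
    "SelectionRound",
    "SelectionTrace",
    "count_influential",
    "forward_step",
    "select_model",
    "make_fitter",
]

MIN_INFLUENTIAL_TAXA = 2


def count_influential(summary: pd.DataFrame, term: str) -> int:
    """Number of taxa whose 95% CrI for ``term`` excludes 0.

    ``summary`` is an influence table with columns ``parameter``, ``taxon``
    and ``influential`` (e.g. ``CommunityOccupancyResults.influence_report``).
    """
    rows = summary[summary["parameter"] == term]
    if rows.empty:
        raise ConfigurationError(f"term {term!r} absent from the fit summary")
    return int(rows["influential"].sum())


@dataclass(frozen=True)
class SelectionRound:
    stage: str                 # "occupancy" or "detection"
    base: str                  # base-model formula
    candidate: str
    n_influential: int | None  # None when screened out without fitting
    decision: str              # "advance", "drop", "screened", "kept", "removed"


@dataclass
class SelectionTrace:
    rounds: list[SelectionRound] = field(default_factory=list)
    final: ModelSpec | None = None

    def log(self, **kw) -> None:
        self.rounds.append(SelectionRound(**kw))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rounds])

    def to_csv(self, path) -> None:
        df = self.to_frame()
        if self.final is not None:
            df.attrs["final"] = self.final.formula()
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class CandidatePool:
    """Terms eligible for selection, in deterministic priority order."""

    occupancy: tuple[str, ...] = ("urban_dist", "garden_area")
    detection: tuple[str, ...] = (
        "start_time",
        "julian_date",
        "temperature",
        "light",
        "bloom_richness",
        "urban_dist",
        "garden_area",
    )
    interactions: bool = True   # consider x:y between retained/tested mains
    quadratics: bool = False


def _candidate_spec(base: ModelSpec, candidate: str, stage: str) -> ModelSpec:
    """Base spec plus one candidate term (adding mains an interaction needs)."""
    if stage == "occupancy":
        spec = base
        if ":" in candidate:
            for v in candidate.split(":"):
                if v not in [t.name for t in spec.occupancy]:
                    spec = spec.with_occupancy(v)
        return spec.with_occupancy(candidate)
    spec = base
    if ":" in candidate:
        for v in candidate.split(":"):
            if v not in [t.name for t in spec.detection]:
                spec = spec.with_detection(v)
    return spec.with_detection(candidate)


def _violates_screen(spec: ModelSpec, excluded_pairs) -> bool:
    try:
        spec.check_screen(excluded_pairs)
    except ConfigurationError:
        return True
    return False


def forward_step(
    base: ModelSpec,
    candidates: Sequence[str],
    fit_summary: Callable[[ModelSpec], pd.DataFrame],
    stage: str,
    excluded_pairs=(),
    min_taxa: int = MIN_INFLUENTIAL_TAXA,
    trace: SelectionTrace | None = None,
) -> tuple[ModelSpec, str | None, dict[str, int], pd.DataFrame | None]:
    """Fit base+candidate for every candidate; advance the strongest.

    ``fit_summary`` maps a spec to an influence table (see
    :func:`count_influential`); injecting it keeps the stepping logic a pure
    function of fit summaries.  Returns the chosen spec, the advanced
    candidate (None = stop), the per-candidate influential counts, and the
    winner's influence table (None when stopping).
    """
    trace = trace if trace is not None else SelectionTrace()
    counts: dict[str, int] = {}
    specs: dict[str, ModelSpec] = {}
    summaries: dict[str, pd.DataFrame] = {}
    for cand in candidates:
        try:
            spec = _candidate_spec(base, cand, stage)
        except ConfigurationError:
            trace.log(stage=stage, base=base.formula(), candidate=cand,
                      n_influential=None, decision="screened")
            continue
        if _violates_screen(spec, excluded_pairs):
            trace.log(stage=stage, base=base.formula(), candidate=cand,
                      n_influential=None, decision="screened")
            continue
        summary = fit_summary(spec)
        counts[cand] = count_influential(summary, _canonical_name(cand))
        specs[cand] = spec
        summaries[cand] = summary
    if not counts:
        return base, None, counts, None
    # argmax with deterministic tie-break: mains before interactions, then
    # candidate order
    def rank(cand: str):
        return (-counts[cand], ":" in cand, candidates.index(cand))

    best = min(counts, key=rank)
    for cand in candidates:
        if cand not in counts:
            continue
        if counts[cand] < min_taxa:
            decision = "drop"
        elif cand == best:
            decision = "advance"
        else:
            decision = "retest"
        trace.log(stage=stage, base=base.formula(), candidate=cand,
                  n_influential=counts[cand], decision=decision)
    if counts[best] < min_taxa:
        return base, None, counts, None
    return specs[best], best, counts, summaries[best]


def _canonical_name(cand: str) -> str:
    from .formula import ALIASES

    if ":" in cand:
        a, b = (ALIASES.get(v.strip(), v.strip()) for v in cand.split(":"))
        return f"{a}:{b}"
    if cand.endswith("^2"):
        v = ALIASES.get(cand[:-2].strip(), cand[:-2].strip())
        return f"{v}^2"
    return ALIASES.get(cand.strip(), cand.strip())


def make_fitter(
    detections,
    site_covariates,
    survey_covariates,
    priors: PriorSpec | None,
    config,
    rhat_threshold: float = 1.05,
):
    """Default fit function: fit a spec, retry once longer on non-convergence.

    Returns a callable spec -> influence table; candidate fits may use a
    reduced schedule since only CrI-versus-zero decisions are consumed.
    """
    from .model import CommunityOccupancyModel

    def fit_summary(spec: ModelSpec) -> pd.DataFrame:
        cfg = config
        for attempt in range(2):
            model = CommunityOccupancyModel(
                detections, site_covariates, survey_covariates,
                spec=spec, priors=priors,
            )
            res = model.fit(cfg, compute_gof=False)
            if res.samples.max_rhat(include_species=False) < rhat_threshold:
                break
            cfg = dc_replace(
                cfg,
                n_iterations=cfg.n_iterations * 2,
                burn_in=cfg.burn_in * 2,
                seed=cfg.seed + 101,
            )
        return res.influence_report()

    return fit_summary


def select_model(
    detections,
    site_covariates,
    survey_covariates,
    pool: CandidatePool | None = None,
    priors: PriorSpec | None = None,
    config=None,
    fit_summary: Callable[[ModelSpec], pd.DataFrame] | None = None,
    excluded_pairs=(),
    min_taxa: int = MIN_INFLUENTIAL_TAXA,
    max_rounds: int = 8,
) -> tuple[ModelSpec, SelectionTrace]:
    """Full forward-stepwise selection over occupancy then detection terms.

    Occupancy candidates (site covariates) are stepped first; with none
    influential the occupancy sub-model stays intercept-only.  Detection
    selection starts from the plant-only base, considers interactions with
    retained mains as they become eligible, and re-checks retained mains
    after each advance, removing any that drop below ``min_taxa``.
    """
    from .sampler import MCMCConfig

    pool = pool or CandidatePool()
    config = config or MCMCConfig()
    if fit_summary is None:
        fit_summary = make_fitter(
            detections, site_covariates, survey_covariates, priors, config
        )
    trace = SelectionTrace()

    # -- stage 1: occupancy ------------------------------------------------
    spec = ModelSpec(occupancy=(), detection=(Term(("plant",)),))
    remaining = list(pool.occupancy)
    if pool.quadratics:
        remaining += [f"{c}^2" for c in pool.occupancy]
    for _ in range(max_rounds):
        if not remaining:
            break
        spec, chosen, counts, _ = forward_step(
            spec, remaining, fit_summary, "occupancy", excluded_pairs,
            min_taxa, trace,
        )
        if chosen is None:
            break
        remaining = [c for c in remaining if c != chosen and counts.get(c, 0) >= min_taxa]

    # -- stage 2: detection ------------------------------------------------
    remaining = list(pool.detection)
    if pool.quadratics:
        remaining += [f"{c}^2" for c in pool.detection]
    retained: list[str] = []
    for _ in range(max_rounds):
        cands = list(remaining)
        if pool.interactions:
            for m in retained:
                cands.append(f"plant:{m}")
                for other in retained:
                    if other != m and f"{other}:{m}" not in cands:
                        cands.append(f"{m}:{other}")
        cands = [c for c in cands if _canonical_name(c)
                 not in [t.name for t in spec.detection]]
        if not cands:
            break
        spec, chosen, counts, winner_summary = forward_step(
            spec, cands, fit_summary, "detection", excluded_pairs,
            min_taxa, trace,
        )
        if chosen is None:
            break
        if ":" not in chosen and not chosen.endswith("^2"):
            retained.append(_canonical_name(chosen))
        remaining = [
            c for c in remaining
            if _canonical_name(c) != _canonical_name(chosen)
            and counts.get(c, min_taxa) >= min_taxa
        ]
        # re-check retained mains using the winning fit's summary
        summary = winner_summary
        for m in list(retained):
            in_interaction = any(
                (t.is_interaction or t.is_quadratic) and m in t.vars
                for t in spec.detection
            )
            if in_interaction:
                continue
            n = count_influential(summary, m)
            if n < min_taxa:
                spec = spec.drop_detection(m)
                retained.remove(m)
                trace.log(stage="detection", base=spec.formula(), candidate=m,
                          n_influential=n, decision="removed")

    trace.final = spec
    return spec, trace
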