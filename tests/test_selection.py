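"""Forward-stepwise covariate selection driven by influence counts."""

import pandas as pd
import pytest

from msom.formula import ConfigurationError, ModelSpec, Term
from msom.selection import (
    CandidatePool,
    SelectionTrace,
    count_influential,
    forward_step,
    select_model,
)


def _summary(counts: dict[str, int], n_taxa: int = 20) -> pd.DataFrame:
    """Influence table where ``counts[term]`` taxa have CrIs excluding 0."""
    rows = []
    for term, n in counts.items():
        for i in range(n_taxa):
            rows.append(
                {"taxon": f"t{i}", "parameter": term, "influential": i < n}
            )
    return pd.DataFrame(rows)


def _stub_fitter(counts: dict[str, int]):
    """fit_summary stub reporting preset influence counts for any spec."""

    def fit(spec: ModelSpec) -> pd.DataFrame:
        terms = {t.name for t in spec.detection} | {t.name for t in spec.occupancy}
        return _summary({t: counts.get(t, 0) for t in terms})

    return fit


class TestCountInfluential:
    def test_counts_taxa_with_excluding_cris(self):
        assert count_influential(_summary({"start_time": 4}), "start_time") == 4

    def test_zero_count_droppable(self):
        assert count_influential(_summary({"garden_area": 0}), "garden_area") == 0

    def test_single_taxon_below_multiple_species_rule(self):
        n = count_influential(_summary({"urban_dist": 1}), "urban_dist")
        assert n == 1 and n < 2

    def test_absent_term_rejected(self):
        with pytest.raises(ConfigurationError, match="absent"):
            count_influential(_summary({"light": 2}), "temperature")


class TestForwardStep:
    BASE = ModelSpec(detection=(Term(("plant",)),))

    def test_argmax_advances_strongest_candidate(self):
        fit = _stub_fitter({"start_time": 11, "temperature": 3})
        spec, chosen, counts, summary = forward_step(
            self.BASE, ["temperature", "start_time"], fit, "detection"
        )
        assert chosen == "start_time"
        assert counts == {"temperature": 3, "start_time": 11}
        assert "start_time" in {t.name for t in spec.detection}
        assert summary is not None

    def test_all_below_threshold_stops(self):
        fit = _stub_fitter({"start_time": 1, "temperature": 0})
        spec, chosen, _, _ = forward_step(
            self.BASE, ["start_time", "temperature"], fit, "detection"
        )
        assert chosen is None and spec == self.BASE

    def test_tie_break_prefers_main_over_interaction(self):
        base = ModelSpec(
            detection=(Term(("plant",)), Term(("start_time",)))
        )
        fit = _stub_fitter({"light": 5, "plant:start_time": 5})
        _, chosen, _, _ = forward_step(
            base, ["plant:start_time", "light"], fit, "detection"
        )
        assert chosen == "light"

    def test_screened_candidates_never_fitted(self):
        trace = SelectionTrace()
        fit = _stub_fitter({"urban_dist": 9, "garden_area": 9})
        base = ModelSpec(occupancy=(Term(("urban_dist",)),),
                         detection=(Term(("plant",)),))
        _, chosen, counts, _ = forward_step(
            base, ["garden_area"], fit, "occupancy",
            excluded_pairs=[("urban_dist", "garden_area", 0.71)],
            trace=trace,
        )
        assert chosen is None and counts == {}
        assert trace.rounds[0].decision == "screened"


class TestSelectModel:
    def test_pure_function_of_summaries_and_deterministic(self):
        counts = {"start_time": 9, "light": 4, "plant": 4,
                  "plant:start_time": 3, "urban_dist": 0, "garden_area": 0}
        runs = [
            select_model(None, None, None, fit_summary=_stub_fitter(counts))
            for _ in range(2)
        ]
        (spec_a, trace_a), (spec_b, trace_b) = runs
        assert spec_a == spec_b
        assert trace_a.to_frame().equals(trace_b.to_frame())
        assert spec_a.occupancy == ()
        names = {t.name for t in spec_a.detection}
        assert {"plant", "start_time", "light", "plant:start_time"} <= names

    def test_no_influential_occupancy_gives_intercept_only(self):
        counts = {"start_time": 5, "plant": 3}
        spec, _ = select_model(None, None, None,
                               fit_summary=_stub_fitter(counts))
        assert spec.occupancy == ()

    def test_retained_main_dropped_when_signal_absorbed(self):
        """A main kept early is re-checked and removed once no longer
        influential (unless an interaction still needs it)."""

        def fit(spec: ModelSpec) -> pd.DataFrame:
            terms = {t.name for t in spec.detection} | {
                t.name for t in spec.occupancy
            }
            # temperature looks influential alone, but not once start_time
            # is in the model
            counts = {"start_time": 5, "plant": 3}
            counts["temperature"] = 6 if "start_time" not in terms else 0
            return _summary({t: counts.get(t, 0) for t in terms})

        spec, trace = select_model(
            None, None, None, fit_summary=fit,
            pool=CandidatePool(
                occupancy=(), detection=("temperature", "start_time"),
                interactions=False,
            ),
        )
        names = {t.name for t in spec.detection}
        assert "temperature" not in names and "start_time" in names
        decisions = set(trace.to_frame()["decision"])
        assert "removed" in decisions

    def test_trace_never_cofits_screened_pair(self):
        counts = {"urban_dist": 5, "garden_area": 5, "plant": 3}
        spec, trace = select_model(
            None, None, None, fit_summary=_stub_fitter(counts),
            excluded_pairs=[("urban_dist", "garden_area", 0.8)],
        )
        mains = {t.vars[0] for t in spec.occupancy if len(t.vars) == 1}
        assert not {"urban_dist", "garden_area"} <= mains
        df = trace.to_frame()
        assert (df["decision"] == "screened").any()
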