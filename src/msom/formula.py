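"""Declarative model specifications for the occupancy and detection sub-models.

A :class:`ModelSpec` lists the covariate terms of the two logistic
regressions: occupancy (``psi``, site covariates only) and detection (``p``,
site or survey covariates, the host-plant indicator, two-way interactions and
quadratics).  Specs can be written directly or parsed from a compact formula
string such as::

    psi ~ 1, p ~ (plant * time) + (urban_dist * jday) + light

``*`` expands to both main effects plus their interaction, ``:`` is the
interaction alone, and ``^2`` is a quadratic.  Intercepts are implicit and
always present; the plant indicator is an ordinary detection term named
``plant``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import SITE_COVARIATES, SURVEY_COVARIATES

__all__ = ["Term", "ModelSpec", "parse_formula", "ConfigurationError"]


class ConfigurationError(ValueError):
    """A model specification is internally inconsistent."""


ALIASES = {
    "time": "start_time",
    "jday": "julian_date",
    "temp": "temperature",
    "light_level": "light",
    "bloom": "bloom_richness",
    "urban": "urban_dist",
    "area": "garden_area",
}

DETECTION_VARS = ("plant",) + SITE_COVARIATES + SURVEY_COVARIATES
OCCUPANCY_VARS = SITE_COVARIATES

#: BUGS-style coefficient symbols conventional for this model family.
COEFFICIENT_SYMBOLS = {
    "plant": ("", "betalp.f"),
    "start_time": ("", "betalp1"),
    "julian_date": ("", "betalp2"),
    "temperature": ("", "betalp3"),
    "light": ("", "betalp4"),
    "bloom_richness": ("", "betalp5"),
    "urban_dist": ("betalpsi1", "betalp6"),
    "garden_area": ("betalpsi2", "betalp7"),
}


@dataclass(frozen=True)
class Term:
    """One regression term: a main effect, an interaction, or a quadratic."""

    vars: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.vars) <= 2:
            raise ConfigurationError("terms are mains, pairs, or quadratics")

    @property
    def is_interaction(self) -> bool:
        return len(self.vars) == 2 and self.vars[0] != self.vars[1]

    @property
    def is_quadratic(self) -> bool:
        return len(self.vars) == 2 and self.vars[0] == self.vars[1]

    @property
    def name(self) -> str:
        if self.is_quadratic:
            return f"{self.vars[0]}^2"
        return ":".join(self.vars)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


def _term(spec: str | tuple | Term) -> Term:
    if isinstance(spec, Term):
        return spec
    if isinstance(spec, tuple):
        return Term(tuple(ALIASES.get(v, v) for v in spec))
    s = spec.strip()
    if s.endswith("^2"):
        v = ALIASES.get(s[:-2].strip(), s[:-2].strip())
        return Term((v, v))
    if ":" in s:
        a, b = (ALIASES.get(x.strip(), x.strip()) for x in s.split(":"))
        return Term((a, b))
    return Term((ALIASES.get(s, s),))


@dataclass(frozen=True)
class ModelSpec:
    """Covariate terms of the occupancy and detection sub-models.

    Parameters
    ----------
    occupancy
        Terms of the occupancy linear predictor (empty = intercept-only).
    detection
        Terms of the detection linear predictor.  ``plant`` is an ordinary
        term here; presets include it because detection is expected to differ
        between the two host plants.
    """

    occupancy: tuple[Term, ...] = ()
    detection: tuple[Term, ...] = (Term(("plant",)),)

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupancy", tuple(_term(t) for t in self.occupancy))
        object.__setattr__(self, "detection", tuple(_term(t) for t in self.detection))
        self._check_side(self.occupancy, OCCUPANCY_VARS, "occupancy")
        self._check_side(self.detection, DETECTION_VARS, "detection")

    @staticmethod
    def _check_side(terms: tuple[Term, ...], allowed, side: str) -> None:
        names = [t.name for t in terms]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate terms in {side} sub-model")
        mains = {t.vars[0] for t in terms if len(t.vars) == 1}
        for t in terms:
            for v in t.vars:
                if v not in allowed:
                    raise ConfigurationError(
                        f"{v!r} is not a valid {side} covariate"
                    )
            if t.is_interaction and not set(t.vars) <= mains:
                raise ConfigurationError(
                    f"interaction {t.name} requires both main effects in the model"
                )
            if t.is_quadratic and t.vars[0] not in mains:
                raise ConfigurationError(
                    f"quadratic {t.name} requires its linear term in the model"
                )

    def check_screen(self, excluded_pairs) -> None:
        """Reject specs whose detection/occupancy terms co-fit a screened pair."""
        for side in (self.occupancy, self.detection):
            mains = {t.vars[0] for t in side if len(t.vars) == 1}
            for a, b, r in excluded_pairs:
                if a in mains and b in mains:
                    raise ConfigurationError(
                        f"{a} and {b} are collinear (r = {r:.2f}) and cannot "
                        "enter the same model"
                    )

    def with_detection(self, term) -> "ModelSpec":
        return ModelSpec(self.occupancy, self.detection + (_term(term),))

    def with_occupancy(self, term) -> "ModelSpec":
        return ModelSpec(self.occupancy + (_term(term),), self.detection)

    def drop_detection(self, term) -> "ModelSpec":
        t = _term(term)
        return ModelSpec(
            self.occupancy, tuple(x for x in self.detection if x != t)
        )

    def symbols(self) -> dict[str, str]:
        """Map term names to the BUGS-style symbols used in the literature."""
        out = {"(psi intercept)": "lpsi", "(p intercept)": "lp"}
        for side, idx in ((self.occupancy, 0), (self.detection, 1)):
            for t in side:
                parts = [COEFFICIENT_SYMBOLS[v][idx] or COEFFICIENT_SYMBOLS[v][1] for v in t.vars]
                if t.is_quadratic:
                    out[t.name] = parts[0] + ".sq"
                elif t.is_interaction:
                    out[t.name] = "x".join(parts)
                else:
                    out[t.name] = parts[0]
        return out

    def formula(self) -> str:
        occ = " + ".join(t.name for t in self.occupancy) or "1"
        det = " + ".join(t.name for t in self.detection) or "1"
        return f"psi ~ {occ}, p ~ {det}"


def parse_formula(formula: str) -> ModelSpec:
    """Parse ``"psi ~ ..., p ~ ..."`` into a :class:`ModelSpec`.

    Within each side, ``+`` joins terms, ``a * b`` expands to
    ``a + b + a:b``, ``a : b`` is the bare interaction, ``x^2`` a quadratic
    and ``1`` the intercept alone.  Parentheses are cosmetic.
    """
    sides: dict[str, tuple[Term, ...]] = {}
    for part in formula.split(","):
        if "~" not in part:
            raise ConfigurationError(f"expected 'lhs ~ rhs' in {part!r}")
        lhs, rhs = (s.strip() for s in part.split("~", maxsplit=1))
        if lhs not in ("psi", "p"):
            raise ConfigurationError(f"unknown sub-model {lhs!r} (use psi or p)")
        terms: list[Term] = []
        for tok in rhs.replace("(", " ").replace(")", " ").split("+"):
            tok = tok.strip()
            if tok in ("", "1"):
                continue
            if "*" in tok:
                a, b = (x.strip() for x in tok.split("*"))
                for sub in (_term(a), _term(b), _term(f"{a}:{b}")):
                    if sub not in terms:
                        terms.append(sub)
            else:
                t = _term(tok)
                if t not in terms:
                    terms.append(t)
        sides[lhs] = tuple(terms)
    return ModelSpec(
        occupancy=sides.get("psi", ()),
        detection=sides.get("p", (Term(("plant",)),)),
    )
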