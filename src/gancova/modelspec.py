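"""Model specifications for sex-interaction ANCOVA.

A model is described by, per covariate, one of three states — absent,
a single ("common") slope shared by both sexes, or a pair of sex-specific
slopes ("sex_split", coded as main effect + sex interaction) — plus a flag
for the sex main effect.  The hierarchy rule is enforced throughout: any
sex-split covariate forces the sex main effect into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

COMMON = "common"
SEX_SPLIT = "sex_split"
_KINDS = (COMMON, SEX_SPLIT)


@dataclass(frozen=True)
class ModelSpec:
    """A covariate subset with per-covariate term kinds.

    Parameters
    ----------
    terms : mapping of covariate name -> "common" | "sex_split"
    sex_main : whether the sex main effect is included.  Forced to True
        whenever any covariate is sex-split (model hierarchy).
    response : optional label of the modelled response.
    """

    terms: tuple = ()
    sex_main: bool = False
    response: str = ""

    def __post_init__(self):
        items = self.terms
        if isinstance(items, Mapping):
            items = tuple(sorted(items.items()))
        else:
            items = tuple(sorted(dict(items).items()))
        for name, kind in items:
            if kind not in _KINDS:
                raise ValueError(f"unknown term kind {kind!r} for {name!r}")
        object.__setattr__(self, "terms", items)
        if any(kind == SEX_SPLIT for _, kind in items):
            object.__setattr__(self, "sex_main", True)

    # -- queries ---------------------------------------------------------
    @property
    def covariates(self) -> tuple:
        return tuple(name for name, _ in self.terms)

    def kind(self, name: str) -> str | None:
        return dict(self.terms).get(name)

    @property
    def n_covariates(self) -> int:
        return len(self.terms)

    @property
    def n_columns(self) -> int:
        """Number of design columns including the intercept."""
        return (
            1
            + int(self.sex_main)
            + sum(1 if kind == COMMON else 2 for _, kind in self.terms)
        )

    def key(self) -> tuple:
        """Canonical hashable identity (response label excluded)."""
        return (self.terms, self.sex_main)

    # -- string grammar --------------------------------------------------
    def to_string(self) -> str:
        """Compact formula, e.g. ``"age + sex*MC + sex"``."""
        parts = []
        for name, kind in self.terms:
            parts.append(name)
            if kind == SEX_SPLIT:
                parts.append(f"sex*{name}")
        if self.sex_main:
            parts.append("sex")
        return " + ".join(parts) if parts else "1"

    @classmethod
    def from_string(cls, text: str, response: str = "") -> "ModelSpec":
        terms: dict = {}
        sex_main = False
        text = text.strip()
        if text in ("", "1"):
            return cls((), False, response)
        for raw in text.split("+"):
            tok = raw.strip()
            if not tok or tok == "1":
                continue
            if tok == "sex":
                sex_main = True
            elif "*" in tok:
                a, b = (s.strip() for s in tok.split("*", 1))
                name = b if a == "sex" else a
                if (a != "sex") == (b != "sex"):
                    raise ValueError(f"cannot parse term {tok!r}")
                terms[name] = SEX_SPLIT
            else:
                terms.setdefault(tok, COMMON)
        return cls(tuple(sorted(terms.items())), sex_main, response)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def make_spec(terms: Mapping[str, str] | Iterable = (), sex_main: bool = False,
              response: str = "") -> ModelSpec:
    """Build a :class:`ModelSpec`, applying hierarchy repair."""
    return ModelSpec(tuple(dict(terms).items()) if not isinstance(terms, tuple)
                     else terms, sex_main, response)


# ---------------------------------------------------------------------------
# chromosome coding for the genetic algorithm

ABSENT_CODE, COMMON_CODE, SPLIT_CODE = 0, 1, 2


def decode_chromosome(genes: np.ndarray, candidates: list,
                      max_terms: int | None = None) -> ModelSpec:
    """Decode a ternary+binary chromosome into a valid :class:`ModelSpec`.

    ``genes[:-1]`` hold one allele per candidate covariate (0 absent,
    1 common, 2 sex-split); ``genes[-1]`` is the sex main-effect bit.
    Repairs applied: hierarchy (any split forces sex on) and the
    ``max_terms`` cap (surplus covariates dropped from the tail of the
    candidate list, deterministically).
    """
    genes = np.asarray(genes, dtype=int)
    if genes.shape != (len(candidates) + 1,):
        raise ValueError("chromosome length must be n_candidates + 1")
    alleles = genes[:-1].copy()
    if max_terms is not None:
        active = np.flatnonzero(alleles)
        if active.size > max_terms:
            alleles[active[max_terms:]] = ABSENT_CODE
    terms = {}
    for name, allele in zip(candidates, alleles):
        if allele == COMMON_CODE:
            terms[name] = COMMON
        elif allele == SPLIT_CODE:
            terms[name] = SEX_SPLIT
    sex_main = bool(genes[-1]) or any(v == SEX_SPLIT for v in terms.values())
    return ModelSpec(tuple(sorted(terms.items())), sex_main)


def encode_spec(spec: ModelSpec, candidates: list) -> np.ndarray:
    """Inverse of :func:`decode_chromosome` for specs over ``candidates``."""
    genes = np.zeros(len(candidates) + 1, dtype=int)
    lookup = dict(spec.terms)
    for i, name in enumerate(candidates):
        kind = lookup.pop(name, None)
        if kind == COMMON:
            genes[i] = COMMON_CODE
        elif kind == SEX_SPLIT:
            genes[i] = SPLIT_CODE
    if lookup:
        raise ValueError(f"spec covariates {sorted(lookup)} not in candidates")
    genes[-1] = int(spec.sex_main)
    return genes
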