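"""Synthetic labelled citation corpora with realistic screening structure.

Real screening datasets from large reviews are proprietary, so every stage
of the pipeline is exercised on generated corpora that reproduce their
shape: a few thousand citations, a small abstract-inclusion rate (1.7% to
13.8% across the five reference profiles), roughly a fifth to a third of
abstract includes surviving full text, and a PICOS reason attached to
every exclude.

Abstract text is a bag-of-words draw from a two-component mixture: a
shared background vocabulary (Zipf-weighted, mass ``1 − signature_strength``)
plus a class-specific signature vocabulary (uniform, mass
``signature_strength``) — one signature per exclusion reason and one for
includes. Citations included at abstract level but excluded at full text
draw their signature from a blend of the include signature and their
reason's signature, emulating reviewers pushing borderline abstracts
forward for further investigation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .corpus import Citation, ExclusionReason, HIERARCHY, ValidationError

__all__ = ["CorpusSpec", "generate_corpus", "default_specs", "DEFAULT_REASON_DISTRIBUTION"]

# Synthetic assumption: per-reason exclusion frequencies are not published
# for the reference reviews; this leans toward study design and population,
# the dominant reasons in practice.
DEFAULT_REASON_DISTRIBUTION: dict[ExclusionReason, float] = {
    ExclusionReason.STUDY_DESIGN: 0.25,
    ExclusionReason.POPULATION: 0.25,
    ExclusionReason.INTERVENTION: 0.15,
    ExclusionReason.COMPARATOR: 0.05,
    ExclusionReason.OUTCOMES: 0.15,
    ExclusionReason.OTHER: 0.10,
    ExclusionReason.TIME: 0.05,
}

_SIG_PREFIX = {
    "include": "inc",
    ExclusionReason.STUDY_DESIGN: "des",
    ExclusionReason.POPULATION: "pop",
    ExclusionReason.INTERVENTION: "ivn",
    ExclusionReason.COMPARATOR: "cmp",
    ExclusionReason.OUTCOMES: "ouc",
    ExclusionReason.OTHER: "oth",
    ExclusionReason.TIME: "tim",
}


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic screening corpus."""

    n_citations: int = 2000
    abstract_include_rate: float = 0.138
    fulltext_retention_rate: float = 0.279
    reason_distribution: Optional[dict] = None
    background_vocab: int = 500
    signature_vocab_per_class: int = 30
    signature_strength: float = 0.35
    over_inclusion_blend: float = 0.5
    mean_abstract_length: float = 120.0
    seed: int = 0
    tag: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_citations < 0:
            raise ValidationError("n_citations must be >= 0")
        for name in ("abstract_include_rate", "fulltext_retention_rate",
                     "signature_strength", "over_inclusion_blend"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.mean_abstract_length <= 0:
            raise ValidationError("mean_abstract_length must be positive")
        dist = self.resolved_reason_distribution()
        if set(dist) != set(ExclusionReason):
            raise ValidationError("reason_distribution must cover exactly the seven reasons")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValidationError("reason_distribution must sum to 1")

    def resolved_reason_distribution(self) -> dict:
        return dict(self.reason_distribution or DEFAULT_REASON_DISTRIBUTION)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _make_terms(prefix: str, n: int) -> list[str]:
    letters = string.ascii_lowercase
    out = []
    for i in range(n):
        suffix = ""
        k = i
        while True:
            suffix = letters[k % 26] + suffix
            k = k // 26 - 1
            if k < 0:
                break
        out.append(prefix + suffix)
    return out


def _draw_text(
    rng: np.random.Generator,
    n_tokens: int,
    background: np.ndarray,
    bg_weights: np.ndarray,
    signatures: list[np.ndarray],
    sig_weights: list[float],
    signature_strength: float,
) -> str:
    """One abstract: mixture of background and (possibly blended) signatures."""
    tokens = []
    u = rng.random(n_tokens)
    n_sig = int((u < signature_strength).sum()) if signatures else 0
    n_bg = n_tokens - n_sig
    if n_bg > 0:
        tokens.extend(rng.choice(background, size=n_bg, p=bg_weights))
    if n_sig > 0:
        which = rng.choice(len(signatures), size=n_sig, p=sig_weights)
        for k in range(len(signatures)):
            m = int((which == k).sum())
            if m:
                tokens.extend(rng.choice(signatures[k], size=m))
    rng.shuffle(tokens)
    return " ".join(tokens)


def generate_corpus(spec: CorpusSpec) -> list[Citation]:
    """Generate one corpus, fully reproducible from ``spec.seed``.

    Class counts are deterministic (round-half-up of the configured rates);
    which citations land in which class is randomized. Abstract lengths are
    Poisson around ``mean_abstract_length`` with a floor of 10 tokens.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_citations
    if n == 0:
        return []
    n_abs_inc = _round_half_up(n * spec.abstract_include_rate)
    n_ft_inc = _round_half_up(n_abs_inc * spec.fulltext_retention_rate)

    dist = spec.resolved_reason_distribution()
    reasons = list(HIERARCHY)
    reason_p = np.array([dist[r] for r in reasons])

    background = np.array(_make_terms("bg", spec.background_vocab))
    # Zipf-like background weights: common words dominate, as in real text
    bg_weights = 1.0 / np.arange(1, spec.background_vocab + 1)
    bg_weights /= bg_weights.sum()
    sig: dict[object, np.ndarray] = {
        key: np.array(_make_terms(pref, spec.signature_vocab_per_class))
        for key, pref in _SIG_PREFIX.items()
    }

    order = rng.permutation(n)
    abs_inc_idx = set(order[:n_abs_inc].tolist())
    ft_inc_idx = set(order[:n_ft_inc].tolist())  # subset of abstract includes

    citations = []
    width = len(str(n))
    for i in range(n):
        length = max(10, int(rng.poisson(spec.mean_abstract_length)))
        if i in ft_inc_idx:
            abstract = _draw_text(
                rng, length, background, bg_weights, [sig["include"]], [1.0],
                spec.signature_strength,
            )
            c = Citation(
                id=f"{spec.tag}-{i:0{width}d}",
                title="",
                abstract=abstract,
                abstract_decision="include",
                fulltext_decision="include",
                dataset_tag=spec.tag,
            )
        elif i in abs_inc_idx:
            r = reasons[int(rng.choice(len(reasons), p=reason_p))]
            b = spec.over_inclusion_blend
            abstract = _draw_text(
                rng, length, background, bg_weights,
                [sig["include"], sig[r]], [b, 1.0 - b],
                spec.signature_strength,
            )
            c = Citation(
                id=f"{spec.tag}-{i:0{width}d}",
                title="",
                abstract=abstract,
                abstract_decision="include",
                fulltext_decision="exclude",
                fulltext_reason=r,
                dataset_tag=spec.tag,
            )
        else:
            r = reasons[int(rng.choice(len(reasons), p=reason_p))]
            abstract = _draw_text(
                rng, length, background, bg_weights, [sig[r]], [1.0],
                spec.signature_strength,
            )
            c = Citation(
                id=f"{spec.tag}-{i:0{width}d}",
                title="",
                abstract=abstract,
                abstract_decision="exclude",
                abstract_reason=r,
                fulltext_decision="not_screened",
                dataset_tag=spec.tag,
            )
        citations.append(c)
    return citations


def default_specs(**overrides) -> dict[str, CorpusSpec]:
    """The five reference corpus profiles (size, inclusion and retention
    rates of the psoriasis, lung-cancer, liver-cancer, melanoma and obesity
    reviews). Keyword overrides apply to every profile — e.g.
    ``default_specs(n_citations=2000)`` keeps the rates but shrinks each
    corpus."""
    profiles = {
        "psoriasis": (4442, 0.138, 0.279),
        "lung_cancer": (12769, 0.017, 0.307),
        "liver_cancer": (8507, 0.134, 0.258),
        "melanoma": (3089, 0.040, 0.331),
        "obesity": (5187, 0.044, 0.206),
    }
    specs = {}
    for tag, (n, inc, ret) in profiles.items():
        spec = CorpusSpec(
            n_citations=n,
            abstract_include_rate=inc,
            fulltext_retention_rate=ret,
            tag=tag,
        )
        if overrides:
            spec = replace(spec, **overrides)
        specs[tag] = spec
    return specs
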