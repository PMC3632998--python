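"""Deterministic fixtures: synthetic compound libraries and demo knowledge bases.

Three self-contained setups exercise every other module without any
downloads:

* :func:`gen_compound_library` draws a synthetic screening library whose
  hidden activity surface is a smooth sum of Gaussian bumps over the unit
  feature cube plus additive noise — a desk-scale stand-in for a large
  anticancer screen with pGI50-like responses.
* :func:`aaa_fixture` builds the gene-deletion hypothesis set for the yeast
  aromatic amino acid pathway example: 8 candidate deleted genes at uniform
  prior 1/8, plus a scripted sequence of elimination cycles whose replay
  leaves one hypothesis at posterior 1.
* :func:`sirtuin_fixture` builds the sirtuin-lifespan knowledge base: the
  human hypothesis h1 ("SIRT1 regulates human life span"), its model-organism
  homologs h2 (nematode) and h3 (yeast), the evidence timeline, and the
  homological updates that move P(h1) down after the 2011 refutation and up
  after the 2012 supporting report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .active import CompoundLibrary
from .errors import ValidationError
from .evidence import (
    EstimationMethod,
    EvidenceItem,
    EvidenceRelation,
    EvidenceSourceType,
    HomologyLink,
    KnowledgeBase,
    ProbabilityKind,
    ProbabilityRecord,
)
from .hypotheses import HypothesisSet, eliminate, uniform_set
from .statements import Entity, ResearchStatement, StatementRole, make_atomic

__all__ = [
    "LibrarySpec",
    "gen_compound_library",
    "latent_activity",
    "aaa_fixture",
    "replay_aaa",
    "sirtuin_fixture",
]

# Default activity surface: three bumps of distinct heights on [0,1]^2, on a
# pGI50-like baseline of 5.  The single global optimum sits on the tallest
# bump; widths are broad enough that ~10 random bootstrap points give a GP
# with length scale 0.2 something to interpolate.
_DEFAULT_CENTERS = ((0.25, 0.70), (0.75, 0.30), (0.60, 0.85))
_DEFAULT_WIDTHS = (0.18, 0.15, 0.12)
_DEFAULT_HEIGHTS = (1.5, 2.5, 1.0)


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for a synthetic compound library.

    The latent activity is ``baseline + Σ_j height_j ·
    exp(−‖x − center_j‖² / (2·width_j²))`` and observed activities add
    N(0, noise_sd²) noise.  Identical spec + seed reproduce the library
    bit-exactly.
    """

    n_compounds: int = 500
    n_features: int = 2
    centers: Tuple[Tuple[float, ...], ...] = _DEFAULT_CENTERS
    widths: Tuple[float, ...] = _DEFAULT_WIDTHS
    heights: Tuple[float, ...] = _DEFAULT_HEIGHTS
    baseline: float = 5.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not (len(self.centers) == len(self.widths) == len(self.heights)):
            raise ValidationError("centers, widths and heights must align")
        for c in self.centers:
            if len(c) != self.n_features:
                raise ValidationError("bump centers must match n_features")
        if any(w <= 0 for w in self.widths):
            raise ValidationError("bump widths must be positive")


def latent_activity(X: np.ndarray, spec: LibrarySpec) -> np.ndarray:
    """Noise-free activity surface of a spec, evaluated at feature rows X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.full(X.shape[0], spec.baseline, dtype=float)
    for center, width, height in zip(spec.centers, spec.widths, spec.heights):
        sq = ((X - np.asarray(center)) ** 2).sum(axis=1)
        out += height * np.exp(-sq / (2.0 * width**2))
    return out


def gen_compound_library(spec: LibrarySpec = LibrarySpec()) -> CompoundLibrary:
    """Draw a seeded synthetic library from a :class:`LibrarySpec`."""
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(0.0, 1.0, size=(spec.n_compounds, spec.n_features))
    activity = latent_activity(X, spec)
    if spec.noise_sd > 0:
        activity = activity + rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)
    width = len(str(spec.n_compounds))
    ids = [f"C{i:0{width}d}" for i in range(spec.n_compounds)]
    return CompoundLibrary(compound_ids=ids, features=X, true_activity=activity)


# ---------------------------------------------------------------------------
# Aromatic amino acid pathway: gene-deletion hypothesis elimination
# ---------------------------------------------------------------------------

_AAA_GENES = ("ARO3", "ARO4", "ARO7", "ARO2", "TRP2", "TRP3", "TYR1", "PHA2")
_AAA_PRIOR_DATE = "2009-02-23"

#: (cycle date, hypothesis ids rejected by that cycle's auxotrophic growth
#: outcome).  The per-cycle schedule is illustrative; what matters is that a
#: replay strictly shrinks the set until a single hypothesis holds mass 1.
_AAA_CYCLES: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("2009-03-02", ("hyp_TRP3", "hyp_PHA2")),
    ("2009-03-09", ("hyp_ARO2", "hyp_TYR1")),
    ("2009-03-16", ("hyp_TRP2",)),
    ("2009-03-23", ("hyp_ARO7",)),
    ("2009-03-30", ("hyp_ARO4",)),
)


def aaa_fixture() -> Tuple[KnowledgeBase, HypothesisSet, Tuple]:
    """Gene-deletion hypotheses for a yeast AAA-pathway auxotroph.

    Returns ``(kb, hypothesis_set, cycles)``: a knowledge base holding the 8
    candidate-gene hypotheses (each with a prior record of 1/8, method
    abduction), the uniform hypothesis set, and the scripted elimination
    cycles for :func:`replay_aaa`.
    """
    kb = KnowledgeBase()
    strain = kb.add_entity(
        Entity("strain_X", "uncharacterized auxotrophic deletant strain")
    )
    ids: List[str] = []
    for gene in _AAA_GENES:
        g = kb.add_entity(Entity(gene, f"S. cerevisiae gene {gene}", "SGD"))
        sid = f"hyp_{gene}"
        kb.add_statement(
            ResearchStatement(
                id=sid,
                expression=make_atomic("is_deleted_in", g, strain),
                role=StatementRole.research_hypothesis,
                free_text=f"The deleted gene in strain_X is {gene}",
            )
        )
        kb.attach_probability(
            sid,
            ProbabilityRecord(
                value=1.0 / len(_AAA_GENES),
                kind=ProbabilityKind.prior,
                method=EstimationMethod.abduction,
                timestamp=_AAA_PRIOR_DATE,
                procedure="uniform prior over abduced candidates",
            ),
        )
        ids.append(sid)
    return kb, uniform_set(ids), _AAA_CYCLES


def replay_aaa(
    kb: KnowledgeBase, hset: HypothesisSet, cycles=_AAA_CYCLES
) -> List[HypothesisSet]:
    """Replay the scripted elimination cycles, recording posteriors in ``kb``.

    Returns the hypothesis set after each cycle; the last one has a single
    member at probability 1.  Replaying from a fresh fixture is
    deterministic.
    """
    states = []
    for date, rejected in cycles:
        hset = eliminate(hset, list(rejected), kb=kb, timestamp=date)
        states.append(hset)
    return states


# ---------------------------------------------------------------------------
# Sirtuins: evidence-driven probability trajectory with homological inference
# ---------------------------------------------------------------------------

SIRTUIN_H1 = "h1"
SIRTUIN_H2 = "h2"
SIRTUIN_H3 = "h3"


def sirtuin_fixture() -> KnowledgeBase:
    """Knowledge base for the sirtuin-lifespan hypothesis timeline.

    h1: "SIRT1 regulates human life span"; h2: its nematode homolog sir-2.1
    regulates C. elegans life span; h3: SIR2 regulates yeast life span.
    Direct testing of h1 is impractical, so evidence arrives through the
    model organisms and reaches h1 via weighted homological updates
    (links h2→h1 and h3→h1).

    Timeline encoded (publication years as ISO dates):

    * 2001: increased sirtuin dosage extends nematode lifespan (supporting
      publication).  h2 rises to 0.9; an expert pegs P(h1) at 0.8.
    * corpus evidence: the yeast hypothesis h3 is extremely well attested in
      the text-mining literature; it carries a statistical estimate of 0.95.
      (The narrative source labels the near-1.0 estimate as belonging to the
      nematode hypothesis immediately after discussing the yeast corpus
      counts; this fixture attaches it to the yeast hypothesis h3 as the
      internally consistent reading.)
    * 2011: overexpression fails to extend lifespan in nematode and fly
      (refuting publication).  h2 drops to 0.4 and the homological update
      pulls P(h1) down.
    * 2012: a sirtuin extends lifespan in male mice (supporting
      publication); routed through the model-organism channel, h2 recovers
      to 0.65 and P(h1) moves back up.

    The 2011/2012 magnitudes are illustrative; only the post-2001 value of
    0.8 and the down-then-up direction are load-bearing.
    """
    kb = KnowledgeBase()
    sirt1 = kb.add_entity(Entity("SIRT1", "human sirtuin gene SIRT1", "HGNC"))
    sir21 = kb.add_entity(
        Entity("sir-2.1", "C. elegans SIRT1 homolog sir-2.1", "WormBase",
               parent_id=None)
    )
    sir2 = kb.add_entity(Entity("SIR2", "S. cerevisiae SIRT1 homolog SIR2", "SGD"))
    human_ls = kb.add_entity(Entity("human_life_span", "human life span"))
    worm_ls = kb.add_entity(Entity("celegans_life_span", "C. elegans life span"))
    yeast_ls = kb.add_entity(Entity("yeast_life_span", "S. cerevisiae life span"))

    kb.add_statement(
        ResearchStatement(
            SIRTUIN_H1,
            make_atomic("regulates", sirt1, human_ls),
            StatementRole.research_hypothesis,
            free_text="SIRT1 regulates human life span",
        )
    )
    kb.add_statement(
        ResearchStatement(
            SIRTUIN_H2,
            make_atomic("regulates", sir21, worm_ls),
            StatementRole.research_hypothesis,
            free_text="sir-2.1 regulates C. elegans life span",
        )
    )
    kb.add_statement(
        ResearchStatement(
            SIRTUIN_H3,
            make_atomic("regulates", sir2, yeast_ls),
            StatementRole.research_hypothesis,
            free_text="SIR2 regulates yeast life span",
        )
    )

    link_h2 = kb.add_homology_link(HomologyLink(SIRTUIN_H2, SIRTUIN_H1, weight=0.5))
    kb.add_homology_link(HomologyLink(SIRTUIN_H3, SIRTUIN_H1, weight=0.5))

    ev_2001 = kb.add_evidence(
        EvidenceItem(
            "ev_tissenbaum_guarente_2001",
            "Increased dosage of the SIRT1 homolog extends lifespan in "
            "C. elegans",
            EvidenceSourceType.publication,
            "2001-01-01",
        )
    )
    ev_corpus = kb.add_evidence(
        EvidenceItem(
            "ev_yeast_corpus",
            "Text-mining corpus: yeast aging sentences overwhelmingly "
            "implicate SIR2",
            EvidenceSourceType.database,
            "2001-06-01",
        )
    )
    ev_2011 = kb.add_evidence(
        EvidenceItem(
            "ev_burnett_2011",
            "Sirtuin overexpression did not boost longevity in C. elegans "
            "or D. melanogaster",
            EvidenceSourceType.publication,
            "2011-01-01",
        )
    )
    ev_2012 = kb.add_evidence(
        EvidenceItem(
            "ev_kanfi_2012",
            "SIRT6 regulates lifespan in male mice",
            EvidenceSourceType.publication,
            "2012-01-01",
        )
    )

    kb.link_evidence(SIRTUIN_H2, ev_2001.id, EvidenceRelation.supports)
    kb.link_evidence(SIRTUIN_H1, ev_2001.id, EvidenceRelation.supports)
    kb.link_evidence(SIRTUIN_H3, ev_corpus.id, EvidenceRelation.supports)
    kb.link_evidence(SIRTUIN_H2, ev_2011.id, EvidenceRelation.refutes)
    kb.link_evidence(SIRTUIN_H1, ev_2011.id, EvidenceRelation.refutes)
    kb.link_evidence(SIRTUIN_H1, ev_2012.id, EvidenceRelation.supports)

    # Seed priors so later homological updates have reference values.
    for sid in (SIRTUIN_H1, SIRTUIN_H2, SIRTUIN_H3):
        kb.attach_probability(
            sid,
            ProbabilityRecord(0.5, ProbabilityKind.prior,
                              EstimationMethod.expert_estimation, "2000-01-01"),
        )
    # 2001: nematode result lifts h2; expert pegs h1 at 0.8.
    kb.attach_probability(
        SIRTUIN_H2,
        ProbabilityRecord(0.9, ProbabilityKind.posterior,
                          EstimationMethod.bayesian_inference, "2001-01-01",
                          source=ev_2001.id),
    )
    kb.attach_probability(
        SIRTUIN_H1,
        ProbabilityRecord(0.8, ProbabilityKind.posterior,
                          EstimationMethod.expert_estimation, "2001-01-02",
                          source=ev_2001.id),
    )
    # Corpus estimate for the yeast hypothesis: close to 1.
    kb.attach_probability(
        SIRTUIN_H3,
        ProbabilityRecord(0.95, ProbabilityKind.posterior,
                          EstimationMethod.statistical_calculation, "2001-06-01",
                          source=ev_corpus.id),
    )
    # 2011 refutation drops h2 to 0.4 -> h1: 0.8 + 0.5*(0.4-0.9) = 0.55.
    kb.homological_update(link_h2, 0.4, "2011-01-01", evidence_id=ev_2011.id)
    # 2012 support recovers the model-organism channel to 0.65
    # -> h1: 0.55 + 0.5*(0.65-0.4) = 0.675.
    kb.homological_update(link_h2, 0.65, "2012-01-01", evidence_id=ev_2012.id)
    return kb
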