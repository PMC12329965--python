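"""Gene-hit filtering and progressive organelle-type assignment.

Components are scored by per-gene best hits, sorted by score, and labeled
progressively.  A plastid-labeled component is demoted to mitochondrion
when a plastid component already exists and its mitochondrial score is at
least a third of its plastid score (plastid-to-mitochondrion transfers are
common and plastid genes score high).  A component is only accepted when it
brings enough new per-gene best scores (3 for plastid, 1 for mitochondrion),
which filters NUMT/NUPT and error debris.

Also houses the HMM-database sequence-selection utility (length filter and
12-mer-completeness ranking).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .io_formats import HmmHit

logger = logging.getLogger(__name__)

ORGANELLES = ("plastid", "mitochondrion")

__all__ = [
    "AnnotationParams",
    "ComponentGeneTable",
    "ComponentLabel",
    "filter_hits",
    "build_component_tables",
    "assign_organelle_types",
    "select_representative_sequences",
]


@dataclass(frozen=True)
class AnnotationParams:
    max_evalue: float = 1e-6
    min_score: float = 300.0
    mito_vs_plastid_ratio: float = 1 / 3
    min_new_best_plastid: int = 3
    min_new_best_mito: int = 1


@dataclass
class ComponentGeneTable:
    component: int
    best: dict[str, dict[str, HmmHit]] = field(default_factory=dict)

    def score(self, organelle: str) -> float:
        return sum(h.score for h in self.best.get(organelle, {}).values())

    @property
    def plastid_score(self) -> float:
        return self.score("plastid")

    @property
    def mito_score(self) -> float:
        return self.score("mitochondrion")


@dataclass
class ComponentLabel:
    component: int
    label: str  # "plastid" | "mitochondrion" | "unassigned"


def filter_hits(hits, params: AnnotationParams = AnnotationParams()):
    """Keep significant hits only (e-value and bit-score thresholds)."""
    return [
        h for h in hits if h.evalue <= params.max_evalue and h.score >= params.min_score
    ]


def build_component_tables(
    components: list[list[str]], hits
) -> list[ComponentGeneTable]:
    """Per-component tables of the best hit of each gene, per organelle.

    ``components`` lists the sequence (unitig) names belonging to each
    component, in component order.
    """
    seq2comp = {}
    for ci, names in enumerate(components):
        for name in names:
            seq2comp[name] = ci
    tables = [ComponentGeneTable(ci) for ci in range(len(components))]
    for h in sorted(hits, key=lambda h: (-h.score, h.gene, h.target_id, h.start)):
        ci = seq2comp.get(h.target_id)
        if ci is None:
            continue
        genes = tables[ci].best.setdefault(h.organelle, {})
        if h.gene not in genes:  # hits are score-sorted: first seen is best
            genes[h.gene] = h
    return tables


def assign_organelle_types(
    components: list[list[str]],
    hits,
    params: AnnotationParams = AnnotationParams(),
) -> list[ComponentLabel]:
    """Progressive organelle-type assignment of graph components.

    Deterministic in the input: hit order never affects labels (tables use
    best-per-gene hits; component order is by score, ties broken by id).
    """
    hits = filter_hits(hits, params)
    tables = build_component_tables(components, hits)
    order = sorted(
        range(len(tables)),
        key=lambda ci: (-max(tables[ci].plastid_score, tables[ci].mito_score), ci),
    )
    labels = {ci: "unassigned" for ci in range(len(tables))}
    best_scores: dict[tuple[str, str], float] = {}
    have_plastid = False
    for ci in order:
        t = tables[ci]
        ps, ms = t.plastid_score, t.mito_score
        if ps == 0 and ms == 0:
            continue
        label = "plastid" if ps >= ms else "mitochondrion"
        if label == "plastid" and have_plastid and ms >= ps * params.mito_vs_plastid_ratio:
            label = "mitochondrion"
        need = (
            params.min_new_best_plastid
            if label == "plastid"
            else params.min_new_best_mito
        )
        new_best = [
            (gene, h)
            for gene, h in t.best.get(label, {}).items()
            if h.score > best_scores.get((label, gene), 0.0)
        ]
        if len(new_best) < need:
            logger.debug(
                "component %d fails the %s new-best gate (%d < %d)",
                ci, label, len(new_best), need,
            )
            continue
        labels[ci] = label
        if label == "plastid":
            have_plastid = True
        for org in ORGANELLES:
            for gene, h in t.best.get(org, {}).items():
                key = (org, gene)
                if h.score > best_scores.get(key, 0.0):
                    best_scores[key] = h.score
    return [ComponentLabel(ci, labels[ci]) for ci in range(len(tables))]


# ---------------------------------------------------------------------------
# HMM-database sequence selection


def select_representative_sequences(seqs, cap: int = 10_000):
    """Length/character cleaning plus 12-mer-completeness capping.

    Sequences with non-ACGT characters, or shorter than a third / longer
    than three times the average length, are dropped.  If more than ``cap``
    survive, each is scored by the sum of counts of its unique 12-mers
    (computed over survivors, excluding the 1% most and least frequent
    12-mers) and the top ``cap`` are kept.
    """
    seqs = list(seqs)
    valid = [r for r in seqs if set(r.sequence) <= set("ACGT") and len(r.sequence) > 0]
    if not valid:
        raise ValueError("no sequences left after character filtering")
    avg = sum(len(r.sequence) for r in valid) / len(valid)
    kept = [r for r in valid if avg / 3 <= len(r.sequence) <= 3 * avg]
    if not kept:
        raise ValueError("no sequences left after length filtering")
    if len(kept) <= cap:
        return kept
    kmers = Counter()
    per_seq = []
    for r in kept:
        s = r.sequence
        uniq = {s[i : i + 12] for i in range(len(s) - 11)}
        per_seq.append(uniq)
        kmers.update(uniq)
    by_freq = sorted(kmers, key=lambda k: (kmers[k], k))
    ncut = int(len(by_freq) * 0.01)
    excluded = set(by_freq[:ncut]) | set(by_freq[len(by_freq) - ncut :]) if ncut else set()
    scores = [
        sum(kmers[k] for k in uniq if k not in excluded) for uniq in per_seq
    ]
    ranked = sorted(range(len(kept)), key=lambda i: (-scores[i], kept[i].id))
    chosen = sorted(ranked[:cap])
    return [kept[i] for i in chosen]
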