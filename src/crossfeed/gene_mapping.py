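"""From changed reactions to genes, operons, regulons, and expression checks.

The gene-protein-reaction (GPR) map links each reaction to the genes whose
products catalyze it.  Translating a changed-reaction set into gene, operon
and regulon counts summarizes the regulatory breadth of a predicted flux
rearrangement; comparing predicted flux-direction changes against observed
expression changes (up / down / unchanged per gene and strain) gives a
Fisher-exact concordance test per category.

The reaction-to-gene direction vote used by
:func:`expression_concordance` (|e| vs |a| per associated reaction, majority
across reactions, ties -> unchanged) is this package's own explicit rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import fisher_exact

from .exceptions import ContractError
from .fba_core import FluxDistribution
from .model_io import AnnotationTables, MetabolicModel
from .room_methods import DEFAULT_BETA, ChangeClassification

CATEGORIES = ("up", "down", "unchanged")


@dataclass
class GeneImpact:
    """Gene/operon/regulon summary of a changed-reaction set."""

    genes: frozenset[str]
    n_genes: int
    n_operons: int
    n_regulons: int
    unmapped_reactions: frozenset[str]
    annotations_missing: bool = False
    provenance: dict = field(default_factory=dict)


def genes_for_reactions(model: MetabolicModel,
                        reactions: frozenset[str] | set[str]
                        ) -> tuple[frozenset[str], frozenset[str]]:
    """Union of GPR leaf genes over a reaction set.

    Returns ``(genes, unmapped)`` where ``unmapped`` lists the reactions with
    an empty GPR.  Unknown reaction ids raise :class:`ContractError`.
    """
    genes: set[str] = set()
    unmapped: set[str] = set()
    for rid in reactions:
        rule = model.gpr[model.rxn_index(rid)]
        if rule.is_empty:
            unmapped.add(rid)
        else:
            genes |= rule.genes
    return frozenset(genes), frozenset(unmapped)


def aggregate_gene_impact(genes: frozenset[str] | set[str],
                          tables: AnnotationTables,
                          unmapped_reactions: frozenset[str] = frozenset()
                          ) -> GeneImpact:
    """Count distinct operons and regulons covered by a gene set.

    Genes without an annotation contribute to ``n_genes`` only.  With empty
    tables both structured counts are 0 and ``annotations_missing`` is set.
    """
    genes = frozenset(genes)
    operons = {tables.operon(g) for g in genes} - {None}
    regulons: set[str] = set()
    for g in genes:
        regulons |= tables.regulons(g)
    return GeneImpact(
        genes=genes, n_genes=len(genes), n_operons=len(operons),
        n_regulons=len(regulons), unmapped_reactions=frozenset(unmapped_reactions),
        annotations_missing=tables.empty,
        provenance={"operon_table_size": len(tables.gene_to_operon),
                    "regulon_table_size": len(tables.gene_to_regulons)})


def gene_impact_for_reactions(model: MetabolicModel,
                              reactions: frozenset[str] | set[str],
                              tables: AnnotationTables) -> GeneImpact:
    """Convenience: reaction set -> GeneImpact in one step."""
    genes, unmapped = genes_for_reactions(model, reactions)
    return aggregate_gene_impact(genes, tables, unmapped)


def predict_gene_directions(model: MetabolicModel,
                            a: FluxDistribution,
                            e: FluxDistribution,
                            beta: float = DEFAULT_BETA) -> dict[str, str]:
    """Predict up/down/unchanged per gene from its reactions' |flux| changes.

    Per associated reaction: |e| > |a| + beta -> up, |e| < |a| - beta -> down,
    else unchanged; genes vote over their reactions by majority with ties
    (including up-vs-down conflicts) resolved to unchanged.
    """
    votes: dict[str, dict[str, int]] = {}
    for j, rid in enumerate(model.reaction_ids):
        rule = model.gpr[j]
        if rule.is_empty:
            continue
        da = abs(e[rid]) - abs(a[rid])
        direction = "up" if da > beta else ("down" if da < -beta else "unchanged")
        for gene in rule.genes:
            tally = votes.setdefault(gene, {c: 0 for c in CATEGORIES})
            tally[direction] += 1
    out = {}
    for gene, tally in votes.items():
        best = max(tally.values())
        winners = [c for c in CATEGORIES if tally[c] == best]
        out[gene] = winners[0] if len(winners) == 1 else "unchanged"
    return out


@dataclass
class ConcordanceResult:
    """Per-category predicted-vs-observed agreement with Fisher exact tests."""

    strain: str
    counts: dict[str, dict[str, int]]  # category -> {tp, fp, fn, tn}
    p_values: dict[str, float]
    n_genes: int

    def significance(self, category: str) -> str:
        p = self.p_values[category]
        return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def expression_concordance(
    model: MetabolicModel,
    classification: ChangeClassification,
    a: FluxDistribution,
    e: FluxDistribution,
    tables: AnnotationTables,
    strain: str,
    beta: float = DEFAULT_BETA,
) -> ConcordanceResult:
    """Compare predicted gene direction changes against observed expression.

    For each category c in {up, down, unchanged} a 2x2 table
    (predicted-in-c x observed-in-c) over the genes present in the expression
    table is tested with a two-sided Fisher exact test.  Degenerate tables
    (zero margin) give p = 1.
    """
    observed = {gene: change for (gene, s), change in tables.expression.items()
                if s == strain}
    if not observed:
        raise ContractError(
            f"expression table has no entries for strain {strain!r}")
    predicted = predict_gene_directions(model, a, e, beta=beta)
    # genes observed but absent from the model's GPRs carry no flux signal and
    # are predicted unchanged, so the whole observed gene set is compared
    genes = sorted(observed)
    counts: dict[str, dict[str, int]] = {}
    p_values: dict[str, float] = {}
    for cat in CATEGORIES:
        tp = sum(1 for g in genes if predicted.get(g, "unchanged") == cat
                 and observed[g] == cat)
        fp = sum(1 for g in genes if predicted.get(g, "unchanged") == cat
                 and observed[g] != cat)
        fn = sum(1 for g in genes if predicted.get(g, "unchanged") != cat
                 and observed[g] == cat)
        tn = len(genes) - tp - fp - fn
        counts[cat] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        _, p = fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")
        p_values[cat] = float(p)
    return ConcordanceResult(strain=strain, counts=counts, p_values=p_values,
                             n_genes=len(genes))
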