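"""Parsimonious protein inference by greedy set cover.

Shared peptides make the protein list ambiguous: many database proteins
can explain the same observations.  The classic remedy (as in IDPicker)
is a minimal explanatory set approximated greedily — repeatedly pick the
protein covering the most still-unexplained peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import QuantTable
from .mapping import PeptideProteinMap

__all__ = ["ParsimonyResult", "greedy_set_cover", "restrict_to_parsimony"]

_NORMALISED = {"NSAF", "DNSAF", "EMPAI"}


@dataclass
class ParsimonyResult:
    """Greedy cover: proteins in selection order, and who covers what."""

    selected: list
    covered: dict  # peptide -> selecting protein

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in set(self.selected)


def greedy_set_cover(pmap: PeptideProteinMap, observed: Iterable) -> ParsimonyResult:
    """Cover all observed peptides with greedily chosen proteins.

    Each round selects the protein whose peptide set covers the most
    still-uncovered observed peptides, ties broken by ascending protein
    identifier.  Raises if some observed peptide maps to no protein.
    """
    observed = set(observed)
    uncoverable = [p for p in observed if p not in pmap.peptide_to_proteins]
    if uncoverable:
        raise ValueError(
            f"peptide {sorted(uncoverable)[0]!r} maps to no protein and cannot be covered"
        )
    candidate_peps = {
        prot: peps & observed for prot, peps in pmap.protein_to_peptides.items()
    }
    uncovered = set(observed)
    selected: list = []
    covered: dict = {}
    while uncovered:
        best = min(
            candidate_peps,
            key=lambda prot: (-len(candidate_peps[prot] & uncovered), prot),
        )
        gain = candidate_peps[best] & uncovered
        if not gain:  # unreachable given the uncoverable check, kept defensive
            raise ValueError("greedy cover stalled with uncovered peptides")
        selected.append(best)
        for pep in gain:
            covered[pep] = best
        uncovered -= gain
        del candidate_peps[best]
    return ParsimonyResult(selected, covered)


def restrict_to_parsimony(
    table: QuantTable, result: ParsimonyResult, renormalize: bool = False
) -> QuantTable:
    """Drop proteins outside the parsimonious set.

    With ``renormalize`` set, NSAF/dNSAF/emPAI scores are rescaled so the
    surviving proteins again sum to 1; RAW and SI_N scores are never
    rescaled.
    """
    if table.level != "protein":
        raise ValueError("parsimony restriction applies to protein-level tables")
    keep = set(result.selected)
    scores = {n: s for n, s in table.scores.items() if n in keep}
    if renormalize and table.metric_name in _NORMALISED and scores:
        total = sum(scores.values())
        if total > 0:
            scores = {n: s / total for n, s in scores.items()}
    return QuantTable(table.metric_name, table.level, scores)
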