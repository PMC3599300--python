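"""Peptide-protein mapping, confidence filtering and in-silico digestion.

A peptide is *unique* if its sequence occurs in exactly one database
protein and *degenerate* (shared) if it occurs in two or more.  The
split drives the distributed NSAF metric: spectra of shared peptides are
apportioned among the sharing proteins in proportion to their unique
spectral counts.  In-silico tryptic digestion enumerates the peptides a
protein could in principle yield, the denominator of the emPAI exponent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pyteomics import parser as _parser

from .io import PsmRecord, ProteinRecord

# cleavage rules as regexes consumed by pyteomics' cleave(); the trypsin
# rule is the plain "after K or R, not before P" convention (without the
# ExPASy WKP/MRP exception cleavages)
CLEAVAGE_RULES = {
    "trypsin": r"[KR](?!P)",
    "trypsin/p": r"[KR]",
    "lys-c": r"K(?!P)",
    "arg-c": r"R(?!P)",
    "chymotrypsin": r"[FWYL](?!P)",
}

__all__ = [
    "PeptideProteinMap",
    "DigestSpec",
    "SpectralCounts",
    "filter_psms",
    "build_map",
    "digest",
    "count_spectra",
]


@dataclass(frozen=True)
class DigestSpec:
    """Enzymatic digestion rule and observability bounds.

    Defaults: trypsin (cleave C-terminal to K or R except before P), no
    missed cleavages, peptides of 6-50 residues considered observable.
    """

    enzyme: str = "trypsin"
    missed_cleavages: int = 0
    min_length: int = 6
    max_length: int = 50

    def __post_init__(self):
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length exceeds max_length")
        if self.enzyme not in CLEAVAGE_RULES:
            raise ValueError(
                f"unknown enzyme {self.enzyme!r}; choose from {sorted(CLEAVAGE_RULES)}"
            )


@dataclass
class PeptideProteinMap:
    """Bidirectional peptide <-> protein incidence with the unique/shared split.

    ``unique_peptides[N]`` and ``degenerate_peptides[N]`` partition
    ``protein_to_peptides[N]`` for every protein N.  ``unmatched`` lists
    peptides that matched no database protein and were excluded.
    """

    peptide_to_proteins: dict
    protein_to_peptides: dict
    unmatched: frozenset = frozenset()
    unique_peptides: dict = field(init=False)
    degenerate_peptides: dict = field(init=False)

    def __post_init__(self):
        self.unique_peptides = {p: set() for p in self.protein_to_peptides}
        self.degenerate_peptides = {p: set() for p in self.protein_to_peptides}
        for pep, prots in self.peptide_to_proteins.items():
            target = self.unique_peptides if len(prots) == 1 else self.degenerate_peptides
            for prot in prots:
                target[prot].add(pep)

    def proteins_of(self, peptide: str) -> frozenset:
        return self.peptide_to_proteins[peptide]


@dataclass
class SpectralCounts:
    """Per-protein spectral counts from one filtered PSM list.

    ``total[N]`` is s_N (a shared spectrum counts once for every protein
    its peptide maps to), ``unique[N]`` is s_N^u (spectra of peptides
    unique to N), and ``shared_peptide[j]`` is the spectral count of
    degenerate peptide j, identical for every protein sharing j.
    """

    total: dict
    unique: dict
    shared_peptide: dict


def filter_psms(psms: Sequence, q_threshold: float = 0.01) -> list:
    """Keep PSMs with q-value <= ``q_threshold`` (inclusive), order preserved."""
    if not 0.0 <= q_threshold <= 1.0:
        raise ValueError(f"q-value threshold {q_threshold} outside [0, 1]")
    return [p for p in psms if p.qvalue <= q_threshold]


def build_map(peptides: Iterable, proteins: Sequence) -> PeptideProteinMap:
    """Map peptides to the proteins containing them as exact substrings.

    Peptides matching no protein are excluded from the map, recorded in
    ``unmatched``, and reported with a warning.  No I/L equivalence is
    applied.
    """
    if not proteins:
        raise ValueError("protein list is empty")
    pep_to_prot: dict = {}
    unmatched = set()
    for pep in sorted(set(peptides)):
        hits = frozenset(pr.protein_id for pr in proteins if pep in pr.sequence)
        if hits:
            pep_to_prot[pep] = hits
        else:
            unmatched.add(pep)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} peptide(s) matched no database protein and were "
            f"excluded (e.g. {sorted(unmatched)[0]!r})",
            stacklevel=2,
        )
    prot_to_pep: dict = {}
    for pep, prots in pep_to_prot.items():
        for prot in prots:
            prot_to_pep.setdefault(prot, set()).add(pep)
    return PeptideProteinMap(pep_to_prot, prot_to_pep, frozenset(unmatched))


def digest(protein: ProteinRecord, spec: DigestSpec = DigestSpec()) -> set:
    """Distinct in-bounds cleavage products of one protein.

    Allows up to ``spec.missed_cleavages`` internal missed sites and
    keeps peptides whose residue count lies in
    [``spec.min_length``, ``spec.max_length``].
    """
    return set(
        _parser.cleave(
            protein.sequence,
            CLEAVAGE_RULES[spec.enzyme],
            missed_cleavages=spec.missed_cleavages,
            min_length=spec.min_length,
            max_length=spec.max_length,
        )
    )


def count_spectra(psms: Sequence, pmap: PeptideProteinMap) -> SpectralCounts:
    """Tally spectral counts against a peptide-protein map.

    Every PSM's peptide must be present in the map (unmatched peptides
    should have been dropped when building it).
    """
    total: dict = {}
    unique: dict = {}
    shared_peptide: dict = {}
    for psm in psms:
        pep = psm.peptide
        try:
            prots = pmap.peptide_to_proteins[pep]
        except KeyError:
            raise KeyError(f"PSM peptide {pep!r} is absent from the map") from None
        for prot in prots:
            total[prot] = total.get(prot, 0) + 1
        if len(prots) == 1:
            (prot,) = prots
            unique[prot] = unique.get(prot, 0) + 1
        else:
            shared_peptide[pep] = shared_peptide.get(pep, 0) + 1
    for prot in total:
        unique.setdefault(prot, 0)
    return SpectralCounts(total, unique, shared_peptide)
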