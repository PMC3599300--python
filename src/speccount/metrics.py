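"""The four spectral-counting abundance metrics, plus raw counts.

For protein N with spectral count s_N and length L_N in a database of n
proteins:

* NSAF_N  = (s_N / L_N) / sum_i (s_i / L_i)
* dNSAF_N = [(s_N^u + sum_j d_{j,N} s_{j,N}^s) / L_N] /
            sum_i [(s_i^u + sum_j d_{j,i} s_{j,i}^s) / L_i]
  where s_N^u counts spectra of peptides unique to N, s_{j,N}^s counts
  spectra of degenerate peptide j, and the distribution factor
  d_{j,N} = s_N^u / sum over sharing proteins of s^u apportions shared
  spectra by unique evidence.
* emPAI_N = (10^(p_N^observed / p_N^observable) - 1) normalised across
  proteins, with p^observed the distinct peptides seen and p^observable
  the in-silico digest products within observability bounds.
* SI_N    = (sum of fragment-ion intensities of N's spectra) /
            (L_N * sum over proteins of the raw intensity sums).

Only proteins with at least one retained spectral count are scored, and
the normalising sums run over those scored proteins.  NSAF, dNSAF and
emPAI therefore each sum to 1 across proteins; SI_N does not (its
denominator is not the sum of the scores).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .io import ProteinRecord, PsmRecord, QuantTable, SpectrumIntensityIndex
from .mapping import (
    DigestSpec,
    PeptideProteinMap,
    SpectralCounts,
    build_map,
    count_spectra,
    digest,
)

__all__ = [
    "MetricInputs",
    "DistributionFactors",
    "score_raw",
    "score_nsaf",
    "score_dnsaf",
    "score_empai",
    "score_sin",
    "score_peptides",
    "distribution_factors",
]


@dataclass
class DistributionFactors:
    """d_{j,N} for every (degenerate peptide j, sharing protein N) pair.

    For each peptide the factors over its sharing proteins sum to 1; when
    no sharer has unique evidence the count is split equally.
    """

    factors: dict

    def __getitem__(self, key) -> float:
        return self.factors[key]


@dataclass
class MetricInputs:
    """Everything the scoring functions consume, assembled once.

    ``psms`` is the filtered, mapped PSM list; ``counts`` its tally;
    ``observed_peptides`` counts distinct peptide sequences with at least
    one retained PSM per protein; ``observable_peptides`` (emPAI only)
    counts in-silico digest products; ``intensity_index`` (SI_N only)
    gives each spectrum's total fragment-ion intensity.
    """

    psms: list
    pmap: PeptideProteinMap
    counts: SpectralCounts
    lengths: dict
    observed_peptides: dict
    observable_peptides: dict | None = None
    intensity_index: SpectrumIntensityIndex | None = None
    database_size: int = 0

    @classmethod
    def assemble(
        cls,
        psms: Sequence,
        proteins: Sequence,
        pmap: PeptideProteinMap | None = None,
        digest_spec: DigestSpec | None = None,
        intensity_index: SpectrumIntensityIndex | None = None,
    ) -> "MetricInputs":
        """Build inputs from filtered PSMs and the protein database.

        PSMs whose peptide matched no database protein are dropped here
        (``build_map`` already warned about them).  ``digest_spec``
        triggers the observable-peptide enumeration needed by emPAI.
        """
        by_id = {pr.protein_id: pr for pr in proteins}
        if pmap is None:
            pmap = build_map({p.peptide for p in psms}, proteins)
        kept = [p for p in psms if p.peptide in pmap.peptide_to_proteins]
        counts = count_spectra(kept, pmap)
        observed_peps = {p.peptide for p in kept}
        observed = {
            prot: len(peps & observed_peps)
            for prot, peps in pmap.protein_to_peptides.items()
        }
        observable = None
        if digest_spec is not None:
            observable = {
                prot: len(digest(by_id[prot], digest_spec)) for prot in counts.total
            }
        return cls(
            psms=kept,
            pmap=pmap,
            counts=counts,
            lengths={pid: pr.length for pid, pr in by_id.items()},
            observed_peptides=observed,
            observable_peptides=observable,
            intensity_index=intensity_index,
            database_size=len(proteins),
        )


def _normalise(values: dict, metric: str) -> QuantTable:
    # sum in sorted-key order so scores are bit-identical regardless of
    # the order proteins or PSMs arrived in
    total = sum(values[k] for k in sorted(values))
    if total <= 0:
        raise ValueError(f"{metric}: no scorable protein (zero normalising sum)")
    return QuantTable(metric, "protein", {k: v / total for k, v in values.items()})


def score_raw(inputs: MetricInputs) -> QuantTable:
    """Raw spectral counts s_N for every protein with s_N >= 1."""
    return QuantTable(
        "RAW", "protein", {n: float(s) for n, s in inputs.counts.total.items()}
    )


def score_nsaf(inputs: MetricInputs) -> QuantTable:
    """Normalized spectral abundance factor; scores sum to 1."""
    saf = {n: s / inputs.lengths[n] for n, s in inputs.counts.total.items()}
    return _normalise(saf, "NSAF")


def distribution_factors(
    unique_counts: dict, pmap: PeptideProteinMap
) -> DistributionFactors:
    """Apportion each degenerate peptide's spectra by unique evidence.

    d_{j,N} = s_N^u / sum of s^u over the proteins sharing j; if no
    sharer has any unique spectra the peptide is split equally.
    """
    factors: dict = {}
    for pep, prots in pmap.peptide_to_proteins.items():
        if len(prots) < 2:
            continue
        denom = sum(unique_counts.get(p, 0) for p in sorted(prots))
        for prot in prots:
            if denom > 0:
                factors[(pep, prot)] = unique_counts.get(prot, 0) / denom
            else:
                factors[(pep, prot)] = 1.0 / len(prots)
    return DistributionFactors(factors)


def score_dnsaf(
    inputs: MetricInputs, factors: DistributionFactors | None = None
) -> QuantTable:
    """Distributed NSAF: shared spectra split by d_{j,N}; scores sum to 1."""
    if factors is None:
        factors = distribution_factors(inputs.counts.unique, inputs.pmap)
    adjusted = {n: float(u) for n, u in inputs.counts.unique.items()}
    for pep in sorted(inputs.counts.shared_peptide):
        count = inputs.counts.shared_peptide[pep]
        for prot in sorted(inputs.pmap.peptide_to_proteins[pep]):
            adjusted[prot] = adjusted.get(prot, 0.0) + factors[(pep, prot)] * count
    # score only proteins with at least one (total) spectral count
    saf = {
        n: adjusted.get(n, 0.0) / inputs.lengths[n] for n in inputs.counts.total
    }
    return _normalise(saf, "DNSAF")


def score_empai(inputs: MetricInputs) -> QuantTable:
    """Exponentially modified protein abundance index, normalised to sum 1."""
    if inputs.observable_peptides is None:
        raise ValueError("emPAI requires observable peptide counts (a digest spec)")
    values: dict = {}
    for prot in inputs.counts.total:
        observable = inputs.observable_peptides.get(prot, 0)
        if observable < 1:
            raise ValueError(
                f"emPAI: protein {prot!r} has no observable peptides in bounds"
            )
        values[prot] = 10.0 ** (inputs.observed_peptides[prot] / observable) - 1.0
    return _normalise(values, "EMPAI")


def score_sin(inputs: MetricInputs) -> QuantTable:
    """Normalized spectral index SI_N.

    The raw index of a protein sums the total fragment-ion intensity of
    every spectrum matched to it (shared spectra contribute to every
    sharing protein); the score divides by protein length and by the sum
    of the raw indices over all scored proteins.
    """
    if inputs.intensity_index is None:
        raise ValueError("SI_N requires a spectrum intensity index")
    raw: dict = {}
    for psm in inputs.psms:
        key = psm.spectrum_key
        if key not in inputs.intensity_index:
            raise KeyError(f"no intensity recorded for spectrum {key!r}")
        intensity = inputs.intensity_index[key]
        for prot in inputs.pmap.peptide_to_proteins[psm.peptide]:
            raw[prot] = raw.get(prot, 0.0) + intensity
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("SI_N: total fragment-ion intensity is zero")
    return QuantTable(
        "SIN",
        "protein",
        {n: r / (inputs.lengths[n] * total) for n, r in raw.items()},
    )


def score_peptides(
    psms: Sequence,
    metric: str = "RAW",
    intensity_index: SpectrumIntensityIndex | None = None,
) -> QuantTable:
    """Peptide-level analogues: RAW PSM counts or the SI_N-style index.

    The SI_N analogue substitutes peptides for proteins: each peptide's
    summed spectrum intensity is divided by its residue count and by the
    total over peptides.
    """
    if metric == "RAW":
        return QuantTable(
            "RAW", "peptide", {p: float(c) for p, c in Counter(x.peptide for x in psms).items()}
        )
    if metric == "SIN":
        if intensity_index is None:
            raise ValueError("peptide SI_N requires a spectrum intensity index")
        raw: dict = {}
        for psm in psms:
            if psm.spectrum_key not in intensity_index:
                raise KeyError(f"no intensity recorded for spectrum {psm.spectrum_key!r}")
            raw[psm.peptide] = raw.get(psm.peptide, 0.0) + intensity_index[psm.spectrum_key]
        if not raw:
            return QuantTable("SIN", "peptide", {})
        total = sum(raw.values())
        if total <= 0:
            raise ValueError("peptide SI_N: total fragment-ion intensity is zero")
        return QuantTable(
            "SIN", "peptide", {p: r / (len(p) * total) for p, r in raw.items()}
        )
    raise ValueError(f"peptide-level scoring supports RAW and SIN, not {metric!r}")
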