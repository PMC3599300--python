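"""End-to-end quantification: filter, map, count, score, (optionally) infer.

This is the programmatic equivalent of the command line: everything
downstream of the database search, from a PSM list and a FASTA database
to a quantification table.
"""

from __future__ import annotations

from typing import Sequence

from .evaluation import DilutionRun, DilutionSeries
from .io import QuantTable, SpectrumIntensityIndex
from .mapping import DigestSpec, filter_psms
from .metrics import (
    MetricInputs,
    score_dnsaf,
    score_empai,
    score_nsaf,
    score_peptides,
    score_raw,
    score_sin,
)
from .parsimony import greedy_set_cover, restrict_to_parsimony
from .synthetic import SimulatedDilution, SimulatedRun

__all__ = ["quantify", "quantify_run", "dilution_series"]

_PROTEIN_SCORERS = {
    "RAW": score_raw,
    "NSAF": score_nsaf,
    "DNSAF": score_dnsaf,
    "EMPAI": score_empai,
    "SIN": score_sin,
}


def quantify(
    proteins: Sequence,
    psms: Sequence,
    metric: str = "NSAF",
    level: str = "protein",
    q_threshold: float = 0.01,
    digest_spec: DigestSpec | None = None,
    intensity_index: SpectrumIntensityIndex | None = None,
    parsimony: bool = False,
    parsimony_renormalize: bool = False,
) -> QuantTable:
    """Score proteins (or peptides) from raw PSMs in one call.

    PSMs are filtered at ``q_threshold`` (inclusive), mapped against the
    database, counted, and scored with ``metric``.  ``digest_spec``
    defaults to standard trypsin bounds when emPAI needs it.  With
    ``parsimony`` set, scores are restricted to the greedy set cover of
    the observed peptides.
    """
    metric = metric.upper()
    retained = filter_psms(psms, q_threshold)
    if level == "peptide":
        return score_peptides(retained, metric, intensity_index)
    if metric not in _PROTEIN_SCORERS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "EMPAI" and digest_spec is None:
        digest_spec = DigestSpec()
    inputs = MetricInputs.assemble(
        retained,
        proteins,
        digest_spec=digest_spec,
        intensity_index=intensity_index,
    )
    table = _PROTEIN_SCORERS[metric](inputs)
    if parsimony:
        observed = {p.peptide for p in inputs.psms}
        cover = greedy_set_cover(inputs.pmap, observed)
        table = restrict_to_parsimony(table, cover, parsimony_renormalize)
    return table


def quantify_run(
    proteins: Sequence, run: SimulatedRun, metric: str = "NSAF", **kwargs
) -> QuantTable:
    """Quantify one simulated run, wiring in its own intensity index."""
    kwargs.setdefault("intensity_index", run.intensity_index)
    return quantify(proteins, run.psms, metric=metric, **kwargs)


def dilution_series(
    proteins: Sequence, sim: SimulatedDilution, metric: str = "NSAF", **kwargs
) -> DilutionSeries:
    """Quantify every standard of a simulated dilution curve."""
    runs = [
        DilutionRun(run.label, quantify_run(proteins, run, metric, **kwargs), amounts)
        for run, amounts in zip(sim.runs, sim.amounts)
    ]
    return DilutionSeries(runs)
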