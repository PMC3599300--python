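"""Synthetic proteomes, PSM tables, spectra, replicates and dilution curves.

The generator emulates the statistical structure of a shotgun-proteomics
experiment at the level the counting metrics see: a protein database
with a known shared-peptide structure, spectral counts drawn with
probability proportional to abundance x protein length (the regime in
which length-normalised counting recovers relative abundance),
log-normal fragment-ion intensities, multiplicative between-replicate
abundance noise, and a two-fold dilution series of spiked proteins on a
constant background.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import ProteinRecord, PsmRecord, SpectrumIntensityIndex, write_psm_table
from .mapping import DigestSpec, digest

__all__ = [
    "SimSpec",
    "SimulatedRun",
    "SimulatedDilution",
    "make_proteome",
    "simulate_psms",
    "simulate_replicates",
    "make_dilution_series",
]

# tryptic building blocks: interior residues avoid K/R (cleavage) and P
# (cleavage suppression); peptides terminate in K or R
_INTERIOR = np.array(list("ACDEFGHILMNQSTVWY"))
_TERMINAL = np.array(list("KR"))


@dataclass(frozen=True)
class SimSpec:
    """Ground-truth description of a simulated experiment.

    ``abundances`` are relative (any positive scale); when omitted they
    are drawn log-uniformly over one decade.  ``replicate_cv`` is the
    coefficient of variation of the multiplicative log-normal abundance
    noise between biological replicates (``replicate_cv_tech`` the
    smaller one between technical replicates).  ``decoy_fraction`` adds
    that fraction of extra PSM rows with q-values above any sensible
    threshold, emulating search-engine false positives.
    """

    n_proteins: int = 20
    length_range: tuple = (150, 400)
    n_shared_peptides: int = 4
    abundances: tuple | None = None
    total_psms: int = 5000
    replicate_cv: float = 0.30
    replicate_cv_tech: float = 0.10
    decoy_fraction: float = 0.0
    sampling: str = "multinomial"  # or "expected": noise-free allocation
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.total_psms < 1:
            raise ValueError("total_psms must be >= 1")
        if self.replicate_cv < 0 or self.replicate_cv_tech < 0:
            raise ValueError("replicate CVs must be >= 0")
        if self.abundances is not None:
            if len(self.abundances) != self.n_proteins:
                raise ValueError("abundances length must equal n_proteins")
            if any(a <= 0 for a in self.abundances):
                raise ValueError("abundances must be positive")
        if self.sampling not in ("multinomial", "expected"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


@dataclass
class SimulatedRun:
    """One simulated LC-MS/MS run with its ground truth."""

    label: str
    psms: list
    intensity_index: SpectrumIntensityIndex
    true_counts: dict  # protein -> spectra drawn from it (before mapping)
    abundances: dict  # protein -> abundance used in this run
    psm_path: Path | None = None
    mgf_path: Path | None = None


@dataclass
class SimulatedDilution:
    """A simulated dilution curve: runs plus the known spiked amounts."""

    runs: list
    amounts: list = field(default_factory=list)  # per run: {spiked protein: fmol}


def _rng(spec: SimSpec, *tags: str) -> np.random.Generator:
    # stable per-purpose streams: label hashes are CRCs, not Python hash()
    entropy = [spec.seed & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _random_peptide(rng: np.random.Generator, min_len: int, max_len: int) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(_INTERIOR, size=n - 1))
    return body + str(rng.choice(_TERMINAL))


def make_proteome(spec: SimSpec) -> list:
    """Generate a protein database with known shared-peptide structure.

    Each protein is a concatenation of tryptic peptides (6-18 residues,
    so at least three fall inside the default observability bounds);
    ``n_shared_peptides`` extra peptides are inserted verbatim into two
    proteins each, making them degenerate.
    """
    rng = _rng(spec, "proteome")
    lo, hi = spec.length_range
    if hi < 3 * 6:
        raise ValueError("length_range upper bound too small for 3 tryptic peptides")
    peptide_lists: list = []
    for _ in range(spec.n_proteins):
        target = int(rng.integers(lo, hi + 1))
        peps: list = []
        while len(peps) < 3 or sum(map(len, peps)) < target:
            peps.append(_random_peptide(rng, 6, 18))
        peptide_lists.append(peps)
    if spec.n_shared_peptides > 0 and spec.n_proteins < 2:
        raise ValueError("shared peptides require at least 2 proteins")
    for _ in range(spec.n_shared_peptides):
        shared = _random_peptide(rng, 8, 14)
        hosts = rng.choice(spec.n_proteins, size=2, replace=False)
        for h in hosts:
            pos = int(rng.integers(0, len(peptide_lists[h]) + 1))
            peptide_lists[h].insert(pos, shared)
    return [
        ProteinRecord(f"SIM{i:04d}", f"synthetic protein {i}", "".join(peps))
        for i, peps in enumerate(peptide_lists)
    ]


def _default_abundances(spec: SimSpec) -> np.ndarray:
    if spec.abundances is not None:
        return np.asarray(spec.abundances, dtype=float)
    rng = _rng(spec, "abundances")
    # two decades of dynamic range, log-uniform
    return 10.0 ** rng.uniform(0.0, 2.0, size=spec.n_proteins)


def _allocate(probs: np.ndarray, depth: int, rng, mode: str) -> np.ndarray:
    if mode == "multinomial":
        return rng.multinomial(depth, probs)
    # expected: largest-remainder rounding of the expected counts
    expected = probs * depth
    counts = np.floor(expected).astype(int)
    short = depth - counts.sum()
    order = np.argsort(-(expected - counts))
    counts[order[:short]] += 1
    return counts


def simulate_psms(
    proteome: list,
    spec: SimSpec,
    run_label: str,
    abundances: np.ndarray | None = None,
    out_dir=None,
) -> SimulatedRun:
    """Draw one run's PSMs (and spectra) from the generative model.

    ``spec.total_psms`` spectra are allocated to proteins with
    probability proportional to abundance x length, then uniformly over
    each protein's in-bounds tryptic peptides.  True PSMs get q-values
    below 0.01; ``spec.decoy_fraction`` extra rows get q-values above it
    and peptides absent from the database.  Each spectrum's total
    fragment-ion intensity is log-normal.  With ``out_dir`` set, the PSM
    table and an MGF file are written there as ``<run_label>.txt/.mgf``.
    """
    rng = _rng(spec, "run", run_label)
    if abundances is None:
        abundances = _default_abundances(spec)
    abundances = np.asarray(abundances, dtype=float)
    lengths = np.array([p.length for p in proteome], dtype=float)
    probs = abundances * lengths
    probs = probs / probs.sum()
    counts = _allocate(probs, spec.total_psms, rng, spec.sampling)

    bounds = DigestSpec()
    peptide_pools = [sorted(digest(p, bounds)) for p in proteome]
    scan = 0
    psms: list = []
    intensities: dict = {}
    for i, protein in enumerate(proteome):
        pool = peptide_pools[i]
        if counts[i] == 0:
            continue
        if not pool:
            raise ValueError(f"protein {protein.protein_id} has no in-bounds peptides")
        per_pep = rng.multinomial(counts[i], np.full(len(pool), 1.0 / len(pool)))
        for pep, c in zip(pool, per_pep):
            for _ in range(int(c)):
                scan += 1
                charge = int(rng.choice([2, 3]))
                key = (run_label, scan, charge)
                psms.append(
                    PsmRecord(key, pep, float(rng.uniform(0.0, 0.009)))
                )
                intensities[key] = float(rng.lognormal(mean=10.0, sigma=1.0))
    n_decoys = int(round(spec.decoy_fraction * spec.total_psms))
    for _ in range(n_decoys):
        scan += 1
        charge = int(rng.choice([2, 3]))
        key = (run_label, scan, charge)
        psms.append(
            PsmRecord(key, _random_peptide(rng, 8, 12), float(rng.uniform(0.02, 0.5)))
        )
        intensities[key] = float(rng.lognormal(mean=10.0, sigma=1.0))
    true_counts = {
        proteome[i].protein_id: int(counts[i]) for i in range(len(proteome))
    }
    run = SimulatedRun(
        label=run_label,
        psms=psms,
        intensity_index=SpectrumIntensityIndex(intensities),
        true_counts=true_counts,
        abundances={
            proteome[i].protein_id: float(abundances[i]) for i in range(len(proteome))
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        run.psm_path = out_dir / f"{run_label}.txt"
        run.mgf_path = out_dir / f"{run_label}.mgf"
        write_psm_table(psms, run.psm_path)
        _write_mgf(run, run.mgf_path, _rng(spec, "peaks", run_label))
    return run


def _write_mgf(run: SimulatedRun, path: Path, rng: np.random.Generator) -> None:
    """Write placeholder fragment spectra whose peaks sum to each i_k."""
    with open(path, "w") as fh:
        for psm in run.psms:
            label, scan, charge = psm.spectrum_key
            total = run.intensity_index[psm.spectrum_key]
            n_peaks = int(rng.integers(5, 11))
            fractions = rng.dirichlet(np.ones(n_peaks))
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={label}.{scan}.{scan}.{charge}\n")
            fh.write(f"SCANS={scan}\n")
            fh.write(f"CHARGE={charge}+\n")
            fh.write("PEPMASS=500.0\n")
            for j, frac in enumerate(fractions):
                fh.write(f"{100.0 + 10.0 * j:.4f} {total * frac:.8e}\n")
            fh.write("END IONS\n")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def simulate_replicates(
    proteome: list,
    spec: SimSpec,
    n_replicates: int = 2,
    kind: str = "biological",
    label_prefix: str = "rep",
    out_dir=None,
) -> list:
    """Replicate runs with abundances perturbed by log-normal noise.

    Technical replicates (``kind="technical"``) use the smaller
    ``replicate_cv_tech``; biological replicates use ``replicate_cv``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if kind not in ("biological", "technical"):
        raise ValueError(f"unknown replicate kind {kind!r}")
    cv = spec.replicate_cv if kind == "biological" else spec.replicate_cv_tech
    base = _default_abundances(spec)
    runs: list = []
    for r in range(n_replicates):
        label = f"{label_prefix}{r + 1}"
        noise = _lognormal_noise(_rng(spec, "repnoise", label, kind), cv, base.size)
        runs.append(
            simulate_psms(proteome, spec, label, abundances=base * noise, out_dir=out_dir)
        )
    return runs


def make_dilution_series(
    proteome: list,
    background_ids: set,
    spiked_ids: set,
    top_amount: float = 870.0,
    n_steps: int = 8,
    fold: float = 2.0,
    background_amount: float = 1000.0,
    spec: SimSpec | None = None,
    out_dir=None,
) -> SimulatedDilution:
    """A dilution curve: constant background, spikes diluted ``fold``-x per step.

    Standard 1 carries ``top_amount`` (fmol) of every spiked protein;
    standard i carries ``top_amount / fold**(i-1)``.  Background proteins
    keep a fixed abundance across runs, averaging ``background_amount``
    per protein (with the spec's relative protein-to-protein variation),
    so that — as in a spike-in experiment on a whole-lysate background —
    the background dominates the total signal and the normalising sums of
    the relative metrics stay nearly constant across standards.  A
    ``fold`` of 1 leaves the amounts constant and the downstream
    regression degenerate, so it is rejected here.
    """
    if spec is None:
        spec = SimSpec(n_proteins=len(proteome))
    if n_steps < 3:
        raise ValueError("a dilution series needs at least 3 steps")
    if fold <= 1.0:
        raise ValueError("dilution fold must exceed 1 (fold=1 gives a flat, degenerate series)")
    background_ids = set(background_ids)
    spiked_ids = set(spiked_ids)
    if background_ids & spiked_ids:
        raise ValueError("background and spiked protein sets must be disjoint")
    ids = [p.protein_id for p in proteome]
    unknown = (background_ids | spiked_ids) - set(ids)
    if unknown:
        raise ValueError(f"unknown protein id(s): {sorted(unknown)}")
    base = _default_abundances(spec)
    background = background_amount * base / base.mean()
    runs: list = []
    amounts: list = []
    for step in range(1, n_steps + 1):
        amount = top_amount / fold ** (step - 1)
        ab = background.copy()
        for i, pid in enumerate(ids):
            if pid in spiked_ids:
                ab[i] = amount
        run = simulate_psms(
            proteome, spec, f"std{step}", abundances=ab, out_dir=out_dir
        )
        runs.append(run)
        amounts.append({pid: amount for pid in sorted(spiked_ids)})
    return SimulatedDilution(runs, amounts)
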