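"""Reading and writing of external formats.

Handles the four formats a spectral-counting run touches: a protein
database in FASTA, a tab-delimited table of peptide-spectrum matches
(PSMs), fragmentation spectra in MGF or MS2 (needed only for the
intensity-weighted SI_N metric), and the tab-delimited quantification
output sorted by score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics import ms2 as _ms2

__all__ = [
    "ProteinRecord",
    "PsmRecord",
    "SpectrumIntensityIndex",
    "QuantTable",
    "SpectrumKey",
    "read_fasta",
    "read_psm_table",
    "read_spectrum_intensities",
    "write_quant_table",
    "read_quant_table",
    "strip_modifications",
    "FormatError",
]

#: Residue alphabet accepted in database sequences: the 20 standard amino
#: acids plus the ambiguity/rare codes B, J, O, U, X, Z and the stop '*'.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "BJOUXZ*")

METRICS = ("RAW", "NSAF", "DNSAF", "EMPAI", "SIN")
LEVELS = ("protein", "peptide")

#: (source file stem, scan number, charge) — the identity of one spectrum.
SpectrumKey = tuple


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, free-text description and sequence."""

    protein_id: str
    description: str
    sequence: str

    @property
    def length(self) -> int:
        """Residue count, the L_N of the length-normalised metrics."""
        return len(self.sequence)


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``spectrum_key`` is (file stem, scan, charge); the same scan searched
    at two charge states is two distinct PSMs.  ``peptide`` is the plain
    residue string with modification annotations stripped.
    """

    spectrum_key: SpectrumKey
    peptide: str
    qvalue: float
    claimed_proteins: frozenset = frozenset()

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("PSM peptide sequence is empty")
        if not 0.0 <= self.qvalue <= 1.0:
            raise ValueError(f"q-value {self.qvalue!r} outside [0, 1]")
        if self.spectrum_key[1] < 0:
            raise ValueError(f"negative scan number in {self.spectrum_key!r}")


@dataclass
class SpectrumIntensityIndex:
    """Total fragment-ion intensity per spectrum (the i_k of SI_N)."""

    intensities: dict = field(default_factory=dict)

    def __getitem__(self, key: SpectrumKey) -> float:
        return self.intensities[key]

    def __contains__(self, key: SpectrumKey) -> bool:
        return key in self.intensities

    def __len__(self) -> int:
        return len(self.intensities)

    def total(self) -> float:
        return float(sum(self.intensities.values()))


@dataclass
class QuantTable:
    """One run's quantification: identifier -> non-negative score.

    ``metric_name`` is one of RAW/NSAF/DNSAF/EMPAI/SIN; ``level`` is
    'protein' or 'peptide'.
    """

    metric_name: str
    level: str
    scores: dict

    def __post_init__(self):
        if self.metric_name not in METRICS:
            raise ValueError(f"unknown metric {self.metric_name!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        for ident, score in self.scores.items():
            if score < 0:
                raise ValueError(f"negative score for {ident!r}: {score}")

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        """Rows sorted by score descending, ties by identifier ascending."""
        rows = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["id", self.metric_name])


def read_fasta(path) -> list:
    """Read a FASTA protein database into a list of :class:`ProteinRecord`.

    The protein identifier is the first whitespace-delimited token of the
    header line.  Sequences wrapped over multiple lines are concatenated
    and uppercased.  Raises :class:`FormatError` on an empty file, a
    duplicate identifier, or a residue outside the accepted alphabet
    (naming the offending line).
    """
    path = Path(path)
    records: list = []
    seen: set = set()
    header: tuple | None = None  # (protein_id, description)
    chunks: list = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: entry {header[0]!r} has an empty sequence")
        records.append(ProteinRecord(header[0], header[1], seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError(f"{path}:{lineno}: header with no identifier")
                pid = parts[0]
                if pid in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate protein id {pid!r}")
                seen.add(pid)
                header = (pid, parts[1] if len(parts) > 1 else "")
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before any header")
                seq = line.upper()
                bad = set(seq) - VALID_RESIDUES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid residue(s) "
                        f"{''.join(sorted(bad))!r} in sequence"
                    )
                chunks.append(seq)
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


_BRACKET_RE = re.compile(r"\[[^\]]*\]")
_NONLETTER_RE = re.compile(r"[^A-Za-z]")


def strip_modifications(raw: str) -> str:
    """Reduce a search-engine peptide string to its plain sequence.

    Removes bracketed modification masses (``PEPT[79.97]IDEK``), single
    flanking residues around dots (``K.PEPTIDEK.R``), and any remaining
    non-letter symbols; the result is uppercased.
    """
    s = _BRACKET_RE.sub("", raw.strip())
    parts = s.split(".")
    if len(parts) == 3 and len(parts[0]) <= 1 and len(parts[2]) <= 1:
        s = parts[1]
    s = _NONLETTER_RE.sub("", s)
    return s.upper()


REQUIRED_PSM_COLUMNS = ("file", "scan", "charge", "sequence", "q-value")


def read_psm_table(path) -> list:
    """Read a tab-delimited PSM table into a list of :class:`PsmRecord`.

    The header must contain the columns ``file``, ``scan``, ``charge``,
    ``sequence`` and ``q-value``; an optional ``protein id`` column holds
    a comma-separated list of claimed protein identifiers (retained on
    the record but re-derived downstream by mapping against the FASTA).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    protein_col = "protein id" if "protein id" in df.columns else None

    records: list = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            qvalue = float(row["q-value"])
        except ValueError:
            raise FormatError(
                f"{path}: row {i}: unparseable q-value {row['q-value']!r}"
            ) from None
        try:
            scan = int(row["scan"])
            charge = int(row["charge"])
        except ValueError:
            raise FormatError(f"{path}: row {i}: unparseable scan/charge") from None
        claimed = frozenset(
            p.strip() for p in row[protein_col].split(",") if p.strip()
        ) if protein_col else frozenset()
        records.append(
            PsmRecord(
                spectrum_key=(Path(row["file"].strip()).stem, scan, charge),
                peptide=strip_modifications(row["sequence"]),
                qvalue=qvalue,
                claimed_proteins=claimed,
            )
        )
    return records


def write_psm_table(psms: Iterable, path) -> None:
    """Write PSMs back to the tab-delimited dialect of :func:`read_psm_table`."""
    rows = [
        {
            "file": f"{k[0]}.mgf",
            "scan": k[1],
            "charge": k[2],
            "sequence": p.peptide,
            "q-value": repr(p.qvalue),
        }
        for p in psms
        for k in (p.spectrum_key,)
    ]
    pd.DataFrame(rows, columns=["file", "scan", "charge", "sequence", "q-value"]).to_csv(
        path, sep="\t", index=False
    )


def _mgf_scan(params: Mapping, path: Path) -> int:
    if "scans" in params:
        return int(str(params["scans"]).split("-")[0])
    title = str(params.get("title", ""))
    m = re.search(r"scan[=\s:]*(\d+)", title, flags=re.IGNORECASE)
    if m:
        return int(m.group(1))
    # Crux-style title run.scan.scan.charge
    m = re.match(r".*?\.(\d+)\.\d+\.\d+$", title)
    if m:
        return int(m.group(1))
    raise FormatError(f"{path}: spectrum without a scan number (title {title!r})")


def read_spectrum_intensities(path, format: str | None = None) -> SpectrumIntensityIndex:
    """Sum peak intensities per spectrum from an MGF or MS2 file.

    ``format`` is ``"MGF"`` or ``"MS2"``; when omitted it is inferred
    from the file extension.  Keys are (file stem, scan, charge); spectra
    with no peaks map to 0.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper()
    fmt = format.upper()
    stem = path.stem
    index: dict = {}
    if fmt == "MGF":
        with _mgf.read(str(path)) as reader:
            for spec in reader:
                params = spec["params"]
                scan = _mgf_scan(params, path)
                charges = params.get("charge", [0])
                charge = int(charges[0])
                key = (stem, scan, charge)
                index[key] = float(spec["intensity array"].sum())
    elif fmt == "MS2":
        with _ms2.read(str(path)) as reader:
            for spec in reader:
                params = spec["params"]
                scan = int(params["scan"][0])
                charges = params.get("charge", [0])
                charge = int(charges[0]) if charges else 0
                key = (stem, scan, charge)
                index[key] = float(spec["intensity array"].sum())
    else:
        raise FormatError(f"unknown spectrum format {format!r} (expected MGF or MS2)")
    return SpectrumIntensityIndex(index)


def write_quant_table(table: QuantTable, path) -> None:
    """Write a quantification table, highest score first.

    Rows are sorted by score descending with ties broken by identifier
    ascending; scores are rendered with 6 significant digits.
    """
    df = table.to_frame()
    df[table.metric_name] = df[table.metric_name].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def read_quant_table(path, level: str = "protein") -> QuantTable:
    """Read back a table written by :func:`write_quant_table`."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] != 2 or df.columns[0] != "id":
        raise FormatError(f"{path}: expected columns 'id' and a metric name")
    metric = df.columns[1]
    return QuantTable(metric, level, dict(zip(df["id"], df[metric].astype(float))))
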