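import random

import pytest
from hypothesis import HealthCheck, settings

from speccount import ProteinRecord, PsmRecord

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def psm(peptide, q=0.001, scan=None, charge=2, run="run1", _counter=[0]):
    """Shorthand PSM with an auto-incrementing scan number."""
    if scan is None:
        _counter[0] += 1
        scan = _counter[0]
    return PsmRecord((run, scan, charge), peptide, q)


@pytest.fixture
def tiny_proteins():
    """Two proteins sharing the peptide ELVISLIVESK."""
    return [
        ProteinRecord("A", "first", "MPEPKAAELVISLIVESKTTTR"),
        ProteinRecord("B", "second", "QQELVISLIVESKWWWK"),
    ]


def random_instance(rng: random.Random, max_proteins=8, max_psms=30, with_intensities=True):
    """A small random quantification problem for oracle comparisons.

    Proteins are random sequences; peptides are random substrings of the
    proteins, so shared peptides arise whenever a substring occurs in two
    sequences.  Returns (proteins, psms, intensities).
    """
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n_prot = rng.randint(2, max_proteins)
    seqs = [
        "".join(rng.choice(alphabet) for _ in range(rng.randint(20, 60)))
        for _ in range(n_prot)
    ]
    # splice shared segments between proteins so degenerate peptides occur
    shared_segments = []
    for _ in range(rng.randint(0, 2)):
        donor = rng.randrange(n_prot)
        seg_len = rng.randint(5, 8)
        start = rng.randint(0, len(seqs[donor]) - seg_len)
        seg = seqs[donor][start : start + seg_len]
        host = rng.choice([i for i in range(n_prot) if i != donor])
        pos = rng.randint(0, len(seqs[host]))
        seqs[host] = seqs[host][:pos] + seg + seqs[host][pos:]
        shared_segments.append(seg)
    proteins = [ProteinRecord(f"P{i}", "", s) for i, s in enumerate(seqs)]
    n_psms = rng.randint(1, max_psms)
    psms = []
    intensities = {}
    for s in range(n_psms):
        if shared_segments and rng.random() < 0.3:
            pep = rng.choice(shared_segments)
        else:
            src = rng.choice(proteins)
            plen = rng.randint(4, 10)
            start = rng.randint(0, src.length - plen)
            pep = src.sequence[start : start + plen]
        key = ("run1", s + 1, rng.choice([2, 3]))
        psms.append(PsmRecord(key, pep, rng.uniform(0.0, 0.009)))
        intensities[key] = rng.uniform(0.1, 1000.0)
    return proteins, psms, (intensities if with_intensities else None)
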