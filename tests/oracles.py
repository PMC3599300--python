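"""Naive, self-contained reference implementations of the scoring formulas.

Deliberately written as direct transcriptions — plain loops over plain
dicts, no shared code with the package — so that agreement with the
package is a genuine two-route check.
"""


def naive_mapping(proteins, peptides):
    """peptide -> sorted list of protein ids containing it as a substring."""
    out = {}
    for pep in peptides:
        hits = [p.protein_id for p in proteins if pep in p.sequence]
        if hits:
            out[pep] = sorted(hits)
    return out


def naive_counts(proteins, psms):
    """(s_N, s_N^u, shared peptide counts) by exhaustive scanning."""
    mapping = naive_mapping(proteins, {p.peptide for p in psms})
    total, unique, shared = {}, {}, {}
    for psm in psms:
        owners = mapping.get(psm.peptide, [])
        for prot in owners:
            total[prot] = total.get(prot, 0) + 1
        if len(owners) == 1:
            unique[owners[0]] = unique.get(owners[0], 0) + 1
        elif len(owners) > 1:
            shared[psm.peptide] = shared.get(psm.peptide, 0) + 1
    return total, unique, shared, mapping


def naive_nsaf(proteins, psms):
    total, _, _, _ = naive_counts(proteins, psms)
    lengths = {p.protein_id: len(p.sequence) for p in proteins}
    saf = {n: s / lengths[n] for n, s in total.items()}
    z = sum(saf.values())
    return {n: v / z for n, v in saf.items()}


def naive_dnsaf(proteins, psms):
    total, unique, shared, mapping = naive_counts(proteins, psms)
    lengths = {p.protein_id: len(p.sequence) for p in proteins}
    adjusted = {n: float(unique.get(n, 0)) for n in total}
    for pep, count in shared.items():
        owners = mapping[pep]
        denom = sum(unique.get(o, 0) for o in owners)
        for prot in owners:
            d = (unique.get(prot, 0) / denom) if denom > 0 else 1.0 / len(owners)
            adjusted[prot] += d * count
    saf = {n: adjusted[n] / lengths[n] for n in total}
    z = sum(saf.values())
    return {n: v / z for n, v in saf.items()}


def naive_tryptic_digest(sequence, missed=0, min_len=6, max_len=50):
    """Cleave after K/R except before P; up to ``missed`` missed sites."""
    sites = [0]
    for i, aa in enumerate(sequence):
        if aa in "KR" and i + 1 < len(sequence) and sequence[i + 1] == "P":
            continue
        if aa in "KR":
            sites.append(i + 1)
    if sites[-1] != len(sequence):
        sites.append(len(sequence))
    out = set()
    for a in range(len(sites) - 1):
        for b in range(a + 1, min(a + 2 + missed, len(sites))):
            pep = sequence[sites[a] : sites[b]]
            if min_len <= len(pep) <= max_len:
                out.add(pep)
    return out


def naive_empai(proteins, psms, min_len=6, max_len=50):
    total, _, _, mapping = naive_counts(proteins, psms)
    observed = {}
    for pep, owners in mapping.items():
        for prot in owners:
            observed.setdefault(prot, set()).add(pep)
    values = {}
    for prot in total:
        seq = next(p.sequence for p in proteins if p.protein_id == prot)
        observable = len(naive_tryptic_digest(seq, 0, min_len, max_len))
        values[prot] = 10.0 ** (len(observed[prot]) / observable) - 1.0
    z = sum(values.values())
    return {n: v / z for n, v in values.items()}


def naive_sin(proteins, psms, intensities):
    _, _, _, mapping = naive_counts(proteins, psms)
    lengths = {p.protein_id: len(p.sequence) for p in proteins}
    raw = {}
    for psm in psms:
        for prot in mapping.get(psm.peptide, []):
            raw[prot] = raw.get(prot, 0.0) + intensities[psm.spectrum_key]
    z = sum(raw.values())
    return {n: r / (lengths[n] * z) for n, r in raw.items()}


def exhaustive_min_cover(sets_by_protein, observed):
    """Smallest protein subset covering all observed peptides, by enumeration."""
    from itertools import combinations

    proteins = sorted(sets_by_protein)
    observed = set(observed)
    for k in range(1, len(proteins) + 1):
        for combo in combinations(proteins, k):
            covered = set()
            for prot in combo:
                covered |= sets_by_protein[prot] & observed
            if covered == observed:
                return list(combo)
    return None
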