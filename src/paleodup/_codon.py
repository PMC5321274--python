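"""Genetic-code helpers shared by the codon simulator and the Ka/Ks estimator.

Everything here is precomputed once at import time for the standard nuclear
code: per-codon synonymous site fractions, mutational neighbour lists, and a
cache of averaged substitution-pathway counts between codon pairs.
"""

from __future__ import annotations

from itertools import permutations, product

from Bio.Data import CodonTable

_NT = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, stop codons mapped to "*"
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


def _one_step_changes(codon):
    """All nine single-nucleotide neighbours of a codon as (pos, nt, new)."""
    for pos in range(3):
        for nt in _NT:
            if nt != codon[pos]:
                yield pos, nt, codon[:pos] + nt + codon[pos + 1 :]


def _syn_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes producing a stop codon count as
    nonsynonymous, so S + N = 3 holds exactly per codon.
    """
    s = 0.0
    aa = GENETIC_CODE[codon]
    for _pos, _nt, new in _one_step_changes(codon):
        if not is_stop(new) and GENETIC_CODE[new] == aa:
            s += 1.0 / 3.0
    return s


#: codon -> synonymous site count (nonsynonymous sites = 3 - value)
SYN_SITES: dict[str, float] = {c: _syn_sites(c) for c in SENSE_CODONS}

#: codon -> list of (pos, nt, new codon) synonymous single-nt substitutions
SYN_NEIGHBOURS: dict[str, list[tuple[int, str, str]]] = {
    c: [
        (p, n, new)
        for p, n, new in _one_step_changes(c)
        if not is_stop(new) and GENETIC_CODE[new] == GENETIC_CODE[c]
    ]
    for c in SENSE_CODONS
}

#: codon -> list of nonsynonymous single-nt substitutions (stops excluded)
NONSYN_NEIGHBOURS: dict[str, list[tuple[int, str, str]]] = {
    c: [
        (p, n, new)
        for p, n, new in _one_step_changes(c)
        if not is_stop(new) and GENETIC_CODE[new] != GENETIC_CODE[c]
    ]
    for c in SENSE_CODONS
}


def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between codons.

    All minimal mutational pathways (orderings of the differing positions)
    are enumerated; pathways passing through a stop codon are excluded and
    the step counts are averaged over the remaining ones.  In the degenerate
    case where every pathway is blocked by a stop, all pathways are used.
    Results are cached.
    """
    key = (codon_a, codon_b)
    hit = _PATH_CACHE.get(key)
    if hit is not None:
        return hit

    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        _PATH_CACHE[key] = (0.0, 0.0)
        return 0.0, 0.0

    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            new = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(new) and new != codon_b:
                through_stop = True
            if (
                not is_stop(cur)
                and not is_stop(new)
                and GENETIC_CODE[cur] == GENETIC_CODE[new]
            ):
                sd += 1
            else:
                nd += 1
            cur = new
        (blocked if through_stop else valid).append((sd, nd))

    paths = valid if valid else blocked
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    _PATH_CACHE[key] = (s, n)
    return s, n


_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def random_codons(rng, n: int) -> list[str]:
    """Draw *n* sense codons uniformly (a flat codon background)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]
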