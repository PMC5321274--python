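"""Pairwise Ks, Ka and Ka/Ks estimation from paired transcripts.

The estimator is the counting method of Nei & Gojobori (1986) on the
standard nuclear code: per-codon synonymous/nonsynonymous site fractions
are averaged over the two sequences, observed differences are apportioned
by averaging over all minimal mutational pathways between differing codons
(pathways through stop codons excluded), and the raw proportions are
corrected for multiple hits with the Jukes--Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``.

Coding regions are inferred with a six-frame longest-ORF scan (the ORF need
not start with ATG unless ``require_atg``), and codon alignments are built
by globally aligning the translated proteins (BLOSUM62, gap open 10 /
extend 0.5) and back-translating; gap-containing codon columns are removed
by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._codon import GENETIC_CODE, SYN_SITES, is_stop, pathway_counts

__all__ = [
    "CodingRegion",
    "CodonAlignment",
    "RateEstimate",
    "infer_cds",
    "codon_align_pair",
    "ng86_rates",
    "batch_rates",
]

MIN_CODONS = 50


@dataclass(frozen=True)
class CodingRegion:
    gene_id: str
    frame: int  # 0..2
    strand: int  # +1 / -1
    cds: str

    def __post_init__(self):
        if len(self.cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if len(self.cds) < 150:
            raise ValueError("CDS shorter than 150 nt")


@dataclass(frozen=True)
class CodonAlignment:
    pair_id: str
    columns: tuple  # of (codon_a, codon_b)

    @property
    def n_codons(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class RateEstimate:
    ks: float
    ka: float
    omega: float  # nan when undefined
    s_sites: float
    n_sites: float
    sd: float  # observed synonymous differences
    nd: float  # observed nonsynonymous differences
    n_codons: int
    status: str = "ok"  # ok | saturated_ks | saturated_ka


class CdsNotFound(ValueError):
    pass


class AlignmentTooShort(ValueError):
    pass


def _orf_candidates(seq: str, require_atg: bool):
    """Stop-free stretches (trimmed to whole codons) in one reading frame."""
    n = len(seq)
    segments = []
    start = 0
    for i in range(0, n - 2, 3):
        codon = seq[i : i + 3]
        if is_stop(codon):
            segments.append((start, i))
            start = i + 3
    segments.append((start, n - (n - start) % 3))
    for s, e in segments:
        if require_atg:
            frag = seq[s:e]
            at = frag.find("ATG")
            while at != -1 and at % 3 != 0:
                at = frag.find("ATG", at + 1)
            if at == -1:
                continue
            s = s + at
        if e - s >= 3:
            yield s, e


def infer_cds(
    gene_id: str, transcript: str, min_length: int = 150, require_atg: bool = False
) -> CodingRegion:
    """Longest open reading frame across all six frames.

    Ties prefer the forward strand, then the lower frame offset.  Raises
    :class:`CdsNotFound` when no stop-free stretch reaches ``min_length``.
    """
    transcript = transcript.upper().replace("U", "T")
    best = None  # (length, strand_rank, frame, cds)
    for strand, seq in ((1, transcript), (-1, str(Seq(transcript).reverse_complement()))):
        for frame in range(3):
            sub = seq[frame:]
            for s, e in _orf_candidates(sub, require_atg):
                length = e - s
                cand = (length, -(0 if strand == 1 else 1), -frame, sub[s:e], strand, frame)
                if best is None or cand[:3] > best[:3]:
                    best = cand
    if best is None or best[0] < min_length:
        raise CdsNotFound(
            f"{gene_id}: no open reading frame of at least {min_length} nt"
        )
    return CodingRegion(gene_id=gene_id, frame=best[5], strand=best[4], cds=best[3])


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _protein_aligner()


def codon_align_pair(
    cds_a: CodingRegion | str,
    cds_b: CodingRegion | str,
    pair_id: str = "",
    gap_policy: str = "drop-columns",
    min_codons: int = MIN_CODONS,
) -> CodonAlignment:
    """Gap-free codon alignment of two coding regions.

    The proteins are aligned globally and the alignment is back-translated
    to codons.  Under the default ``drop-columns`` policy, gap-containing
    columns are removed; under ``drop-pairs`` any gapped alignment raises.
    Fails if fewer than ``min_codons`` ungapped columns remain.
    """
    a = cds_a.cds if isinstance(cds_a, CodingRegion) else cds_a
    b = cds_b.cds if isinstance(cds_b, CodingRegion) else cds_b
    if len(a) % 3 or len(b) % 3:
        raise ValueError("coding sequences must be whole codons")
    prot_a = str(Seq(a).translate())
    prot_b = str(Seq(b).translate())
    aln = _ALIGNER.align(prot_a, prot_b)[0]
    pa, pb = str(aln[0]), str(aln[1])

    cols = []
    ia = ib = 0
    gapped = False
    for ca, cb in zip(pa, pb):
        if ca == "-" or cb == "-":
            gapped = True
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
            continue
        cols.append((a[3 * ia : 3 * ia + 3], b[3 * ib : 3 * ib + 3]))
        ia += 1
        ib += 1
    if gap_policy == "drop-pairs" and gapped:
        raise AlignmentTooShort(f"{pair_id}: gapped alignment under drop-pairs policy")
    if gap_policy not in ("drop-columns", "drop-pairs"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    # columns with a stop codon (possible off-frame noise) are unusable
    cols = [c for c in cols if not is_stop(c[0]) and not is_stop(c[1])]
    if len(cols) < min_codons:
        raise AlignmentTooShort(
            f"{pair_id}: only {len(cols)} ungapped codons (< {min_codons})"
        )
    return CodonAlignment(pair_id=pair_id, columns=tuple(cols))


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_rates(alignment: CodonAlignment) -> RateEstimate:
    """Nei--Gojobori (1986) counting estimate of Ks, Ka and omega."""
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in alignment.columns:
        if ca not in GENETIC_CODE or cb not in GENETIC_CODE:
            raise ValueError(f"invalid codon pair {ca}/{cb}")
        s_a += SYN_SITES[ca]
        s_b += SYN_SITES[cb]
        d_s, d_n = pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    n_codons = alignment.n_codons
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 3.0 * n_codons - s_sites

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    status = "ok"
    if math.isnan(ks):
        status = "saturated_ks"
    elif math.isnan(ka):
        status = "saturated_ka"
    omega = ka / ks if status == "ok" and ks > 0 else math.nan
    return RateEstimate(
        ks=ks,
        ka=ka,
        omega=omega,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        n_codons=n_codons,
        status=status,
    )


def batch_rates(
    pairs,
    sequences: dict,
    gap_policy: str = "drop-columns",
    require_atg: bool = False,
    infer_orf: bool = True,
) -> pd.DataFrame:
    """Per-pair rate table with drop bookkeeping.

    ``pairs`` is an iterable of HomologPair (or any object with gene_a /
    gene_b / kind); ``sequences`` maps gene id -> transcript.  Duplicate
    unordered pairs are collapsed.  The result has one row per input pair
    with Ks/Ka/omega or a drop reason in ``status``.
    """
    rows = []
    seen = set()
    cds_cache: dict[str, CodingRegion | None] = {}

    def get_cds(gid: str):
        if gid not in cds_cache:
            try:
                cds_cache[gid] = infer_cds(gid, sequences[gid], require_atg=require_atg)
            except CdsNotFound:
                cds_cache[gid] = None
        return cds_cache[gid]

    for p in pairs:
        key = frozenset((p.gene_a, p.gene_b))
        if key in seen:
            continue
        seen.add(key)
        row = {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "kind": getattr(p, "kind", ""),
            "species_a": getattr(p, "species_a", ""),
            "species_b": getattr(p, "species_b", ""),
            "n_codons": 0,
            "S": math.nan,
            "N": math.nan,
            "Ks": math.nan,
            "Ka": math.nan,
            "omega": math.nan,
            "status": "",
        }
        missing = [g for g in (p.gene_a, p.gene_b) if g not in sequences]
        if missing:
            raise KeyError(f"missing sequence for {missing}")
        if infer_orf:
            ca, cb = get_cds(p.gene_a), get_cds(p.gene_b)
            if ca is None or cb is None:
                row["status"] = "no_orf"
                rows.append(row)
                continue
            seq_a, seq_b = ca.cds, cb.cds
        else:
            seq_a, seq_b = sequences[p.gene_a], sequences[p.gene_b]
        try:
            aln = codon_align_pair(
                seq_a, seq_b, pair_id=f"{p.gene_a}|{p.gene_b}", gap_policy=gap_policy
            )
        except AlignmentTooShort:
            row["status"] = "too_short"
            rows.append(row)
            continue
        est = ng86_rates(aln)
        row.update(
            {
                "n_codons": est.n_codons,
                "S": est.s_sites,
                "N": est.n_sites,
                "Ks": est.ks,
                "Ka": est.ka,
                "omega": est.omega,
                "status": est.status,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
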