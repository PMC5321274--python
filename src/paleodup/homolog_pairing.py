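"""Best-match ortholog / paralog pair identification from similarity hits.

Within-species best matches are treated as paralog pairs and between-species
best matches as ortholog pairs.  The filters follow the transcriptome
protocol: hits below an e-value of 1e-6 or 40% identity are never
considered; isoforms of the same parent gene (same contig) are excluded
before ranking; when several hits connect the same two genes only the one
with the longest alignment is kept; and retained pairs must reach 150 bp of
alignment at 60% identity (a minimum of 50 codons for rate estimation).

"Best match" ranks candidate partners by bitscore, breaking ties by longer
alignment and then lexicographic partner id.  By default a pair is emitted
only when the two genes are each other's best match (reciprocal best hit);
one-directional best matches can be admitted with
``require_reciprocal=False``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align

__all__ = [
    "HitRecord",
    "HomologPair",
    "read_tabular_hits",
    "all_vs_all_local_align",
    "best_match_pairs",
    "filter_pairs",
    "parent_gene",
]

#: Trinity-style isoform suffix; everything before it is the parent gene
DEFAULT_PARENT_PATTERN = r"_i\d+$"


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular similarity search."""

    query_id: str
    subject_id: str
    identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.align_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


@dataclass(frozen=True)
class HomologPair:
    """An unordered best-match gene pair with its alignment statistics."""

    kind: str  # "ortholog" | "paralog"
    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    align_length: int
    identity: float
    parent_gene_a: str = ""
    parent_gene_b: str = ""

    def __post_init__(self):
        if self.kind not in ("ortholog", "paralog"):
            raise ValueError(f"unknown pair kind {self.kind!r}")
        if self.kind == "paralog" and self.species_a != self.species_b:
            raise ValueError("paralog pair must be within one species")
        if self.kind == "ortholog" and self.species_a == self.species_b:
            raise ValueError("ortholog pair must span two species")

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


class HitParseError(ValueError):
    pass


def read_tabular_hits(path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit file (outfmt-6 dialect).

    Malformed lines raise :class:`HitParseError` naming the line number.
    """
    records: list[HitRecord] = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}"
                )
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity=float(fields[2]),
                    align_length=int(float(fields[3])),
                    mismatches=int(float(fields[4])),
                    gap_opens=int(float(fields[5])),
                    query_start=int(float(fields[6])),
                    query_end=int(float(fields[7])),
                    subject_start=int(float(fields[8])),
                    subject_end=int(float(fields[9])),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise HitParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


# Karlin-Altschul parameters for the default +1/-2 nucleotide scoring
_KA_LAMBDA = 1.33
_KA_K = 0.621


def all_vs_all_local_align(
    sequences: dict,
    min_evalue: float = 1e-6,
    min_identity: float = 40.0,
    match: float = 1.0,
    mismatch: float = -2.0,
    open_gap: float = -2.5,
    extend_gap: float = -0.5,
) -> list[HitRecord]:
    """Desk-scale all-vs-all local alignment standing in for BLASTN.

    Aligns every unordered sequence pair (both orientations emitted as two
    hits), scores with simple match/mismatch/gap parameters, converts raw
    scores to approximate bitscores and e-values with Karlin--Altschul
    statistics, and keeps hits passing both thresholds.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap

    ids = sorted(sequences)
    total_len = sum(len(s) for s in sequences.values())
    hits: list[HitRecord] = []
    for i, qid in enumerate(ids):
        for sid in ids[i + 1 :]:
            q, s = sequences[qid], sequences[sid]
            try:
                aln = aligner.align(q, s)[0]
            except IndexError:
                continue
            score = aln.score
            if score <= 0:
                continue
            qa, sa = aln[0], aln[1]
            matched = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
            length = len(qa)
            if length == 0:
                continue
            identity = matched / length * 100.0
            bitscore = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
            evalue = _KA_K * len(q) * total_len * math.exp(-_KA_LAMBDA * score)
            if evalue > min_evalue or identity < min_identity:
                continue
            (qs, qe), (ss, se) = aln.aligned[0][[0, -1], [0, 1]], aln.aligned[1][
                [0, -1], [0, 1]
            ]
            gaps = sum(
                1
                for k in range(1, length)
                if (qa[k] == "-") != (qa[k - 1] == "-")
                or (sa[k] == "-") != (sa[k - 1] == "-")
            )
            rec = HitRecord(
                query_id=qid,
                subject_id=sid,
                identity=identity,
                align_length=length,
                mismatches=length - matched - qa.count("-") - sa.count("-"),
                gap_opens=gaps // 2,
                query_start=int(qs) + 1,
                query_end=int(qe),
                subject_start=int(ss) + 1,
                subject_end=int(se),
                evalue=float(evalue),
                bitscore=float(bitscore),
            )
            hits.append(rec)
            hits.append(
                HitRecord(
                    query_id=sid,
                    subject_id=qid,
                    identity=identity,
                    align_length=length,
                    mismatches=rec.mismatches,
                    gap_opens=rec.gap_opens,
                    query_start=int(ss) + 1,
                    query_end=int(se),
                    subject_start=int(qs) + 1,
                    subject_end=int(qe),
                    evalue=float(evalue),
                    bitscore=float(bitscore),
                )
            )
    return hits


def parent_gene(gene_id: str, pattern: str = DEFAULT_PARENT_PATTERN) -> str:
    """Contig/parent-gene identifier obtained by stripping an isoform suffix."""
    return re.sub(pattern, "", gene_id)


def best_match_pairs(
    hits,
    mode: str,
    species_map: dict,
    require_reciprocal: bool = True,
    parent_pattern: str = DEFAULT_PARENT_PATTERN,
) -> list[HomologPair]:
    """Identify best-match gene pairs within ("within") or between
    ("between") species.

    Self hits are always discarded; in within mode, hits joining two
    isoforms of one parent gene are excluded before ranking.  Multiple hits
    between the same two genes are collapsed to the longest alignment.
    The output is deduplicated as unordered pairs and sorted, so it does not
    depend on input hit order.
    """
    if mode not in ("within", "between"):
        raise ValueError("mode must be 'within' or 'between'")

    # collapse to one record per ordered gene pair, preferring the longest
    # alignment (ties: higher bitscore)
    per_pair: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        a, b = h.query_id, h.subject_id
        if a == b:
            continue
        for g in (a, b):
            if g not in species_map:
                raise KeyError(f"gene {g!r} missing from species map")
        same_species = species_map[a] == species_map[b]
        if mode == "within":
            if not same_species:
                continue
            if parent_gene(a, parent_pattern) == parent_gene(b, parent_pattern):
                continue
        else:
            if same_species:
                continue
        cur = per_pair.get((a, b))
        if cur is None or (h.align_length, h.bitscore) > (
            cur.align_length,
            cur.bitscore,
        ):
            per_pair[(a, b)] = h

    # symmetrise: a hit supports both directions
    directed: dict[tuple[str, str], HitRecord] = {}
    for (a, b), h in per_pair.items():
        for key in ((a, b), (b, a)):
            cur = directed.get(key)
            if cur is None or (h.align_length, h.bitscore) > (
                cur.align_length,
                cur.bitscore,
            ):
                directed[key] = h

    best: dict[str, str] = {}
    for (a, b), h in sorted(directed.items()):
        cur = best.get(a)
        if cur is None:
            best[a] = b
            continue
        cur_hit = directed[(a, cur)]
        # rank: bitscore desc, then alignment length desc, then partner id asc
        if (h.bitscore, h.align_length) > (cur_hit.bitscore, cur_hit.align_length) or (
            (h.bitscore, h.align_length) == (cur_hit.bitscore, cur_hit.align_length)
            and b < cur
        ):
            best[a] = b

    pairs: dict[frozenset, HomologPair] = {}
    for a, b in sorted(best.items()):
        if require_reciprocal and best.get(b) != a:
            continue
        key = frozenset((a, b))
        if key in pairs:
            continue
        h = directed[(a, b)]
        ga, gb = sorted((a, b))
        kind = "paralog" if mode == "within" else "ortholog"
        pairs[key] = HomologPair(
            kind=kind,
            gene_a=ga,
            gene_b=gb,
            species_a=species_map[ga],
            species_b=species_map[gb],
            align_length=h.align_length,
            identity=h.identity,
            parent_gene_a=parent_gene(ga, parent_pattern),
            parent_gene_b=parent_gene(gb, parent_pattern),
        )
    return [pairs[k] for k in sorted(pairs, key=sorted)]


def filter_pairs(
    pairs, min_align: int = 150, min_identity: float = 60.0
) -> list[HomologPair]:
    """Retain pairs meeting both alignment-length and identity thresholds
    (closed boundaries: 150 bp at 60.0% passes)."""
    return [
        p
        for p in pairs
        if p.align_length >= min_align and p.identity >= min_identity
    ]


def pairs_to_frame(pairs):
    """Tabular view of homolog pairs (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "kind": p.kind,
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "species_a": p.species_a,
                "species_b": p.species_b,
                "length": p.align_length,
                "identity": p.identity,
            }
            for p in pairs
        ]
    )
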