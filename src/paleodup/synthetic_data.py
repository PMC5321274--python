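"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator plants known signal so every downstream stage can be tested
end-to-end without any external sequence download:

* paralog Ks values: an L-shaped small-scale-duplication (SSD) background,
  modelled as a single exponential decay, plus truncated-normal WGD
  components centred at ``2 C_Ks age`` for each planted event;
* ortholog Ks values concentrated around ``2 C_Ks T_div`` for known
  divergence times, used to exercise the clock calibration;
* codon sequence pairs with Poisson-placed synonymous and nonsynonymous
  substitutions (truth recorded), the oracle input for the Ka/Ks estimator;
* gene-count matrices evolved by a linear birth--death process along a dated
  species tree with an optional WGD doubling event retained with
  probability q;
* dated gene trees containing a duplication node at a focal ancestor, with
  per-species dropout emulating unexpressed copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import cornus
from ._codon import NONSYN_NEIGHBOURS, SYN_NEIGHBOURS, random_codons

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_paralog_ks",
    "simulate_ortholog_ks",
    "simulate_codon_pair",
    "simulate_gene_counts",
    "simulate_gene_trees",
    "build_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``wgd_events`` are (age myr, proportion of pairs, sd myr) triples;
    proportions are the mixing weights of the planted WGD components, the
    remainder of pairs coming from the exponential SSD background with
    decay constant ``ssd_rate`` (1/myr).
    """

    species_clocks: dict = field(
        default_factory=lambda: dict(cornus.REFERENCE_CLOCKS)
    )
    wgd_events: tuple = ((74.0, 0.35, 8.0), (22.0, 0.18, 4.0), (7.0, 0.17, 2.5))
    ssd_rate: float = 0.05
    n_pairs: int = 2000
    divergence_times: dict = field(default_factory=cornus.default_divergence_times)
    ortholog_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        # YAML-friendly form: {species: {outgroup: myr}} -> {(sp, og): myr}
        flat = {}
        for key, val in self.divergence_times.items():
            if isinstance(val, dict):
                for og, t in val.items():
                    flat[(key, og)] = float(t)
            else:
                flat[tuple(key)] = float(val)
        object.__setattr__(self, "divergence_times", flat)
        self.wgd_events and object.__setattr__(
            self, "wgd_events", tuple(tuple(e) for e in self.wgd_events)
        )
        for sp, c in self.species_clocks.items():
            if c <= 0:
                raise ValueError(f"clock for {sp} must be positive")
        total = 0.0
        for age, prop, sd in self.wgd_events:
            if age < 0 or sd <= 0:
                raise ValueError("WGD event ages must be >= 0 and sds > 0")
            if not 0 < prop < 1:
                raise ValueError("WGD proportions must lie in (0, 1)")
            total += prop
        if total > 1:
            raise ValueError("WGD proportions must sum to at most 1")
        if self.ssd_rate <= 0:
            raise ValueError("ssd_rate must be positive")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) conditioned on being >= 0, by resampling."""
    out = rng.normal(mean, sd, size=size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 0
    return out


def simulate_paralog_ks(config: SimulationConfig, species: str, seed: int | None = None):
    """Draw paralog Ks values with per-draw truth labels.

    Returns (ks values, labels) where each label is ``"SSD"`` or ``"WGD_i"``
    for the i-th planted event.  WGD component i is Normal(2 C age_i,
    2 C sd_i) truncated at zero; the background is exponential with rate
    ``ssd_rate`` per myr expressed in Ks units.
    """
    clock = config.species_clocks.get(species)
    if clock is None:
        raise KeyError(f"no clock configured for species {species!r}")
    if clock <= 0:
        raise ValueError("clock must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_pairs
    if n == 0:
        return np.empty(0), []

    probs = [p for _a, p, _s in config.wgd_events]
    probs.append(1.0 - sum(probs))
    comp = rng.choice(len(probs), size=n, p=probs)
    ks = np.empty(n)
    labels = []
    two_c = 2.0 * clock
    for i, (age, _p, sd) in enumerate(config.wgd_events):
        mask = comp == i
        ks[mask] = _truncated_normal(rng, two_c * age, two_c * sd, int(mask.sum()))
    ssd = comp == len(config.wgd_events)
    # Exp(rate/myr) in age maps to Exp(rate / 2C) in Ks
    ks[ssd] = rng.exponential(scale=two_c / config.ssd_rate, size=int(ssd.sum()))
    labels = ["SSD" if c == len(config.wgd_events) else f"WGD_{c}" for c in comp]
    return ks, labels


def simulate_ortholog_ks(
    config: SimulationConfig,
    species: str,
    outgroup: str,
    n: int | None = None,
    seed: int | None = None,
):
    """Ortholog Ks sample centred on 2 C_Ks T_div with configurable scatter."""
    key = (species, outgroup)
    if key not in config.divergence_times:
        raise KeyError(f"no divergence time configured for {key}")
    clock = config.species_clocks[species]
    t_div = config.divergence_times[key]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_pairs if n is None else n
    mean = 2.0 * clock * t_div
    if mean == 0:
        return np.zeros(n)
    return _truncated_normal(rng, mean, config.ortholog_sigma, n)


def simulate_codon_pair(
    target_ks: float,
    target_ka: float,
    n_codons: int,
    seed: int,
    saturation_guard: float = 3.0,
):
    """Generate a coding-sequence pair with controlled divergence.

    A uniform sense-codon ancestor is copied and Poisson-distributed
    synonymous / nonsynonymous single-nucleotide substitutions (expected
    counts target * sites) are placed on the copy, never creating a stop
    codon.  Returns (seq_a, seq_b, truth) where truth records the realised
    substitutions per site.
    """
    if target_ks < 0 or target_ka < 0:
        raise ValueError("divergence targets must be non-negative")
    if n_codons < 50:
        raise ValueError("n_codons must be at least 50")
    if target_ks > saturation_guard or target_ka > saturation_guard:
        raise ValueError(
            "target divergence beyond the saturation guard; the corrected "
            "distance would be undefined"
        )
    rng = np.random.default_rng(seed)
    codons_a = random_codons(rng, n_codons)
    codons_b = list(codons_a)

    # a position's synonymous-site fraction is the share of its three changes
    # that are synonymous, so per-codon sites = #synonymous neighbours / 3
    s0 = sum(len(SYN_NEIGHBOURS[c]) / 3.0 for c in codons_a)
    n0 = 3.0 * n_codons - s0

    n_syn = rng.poisson(target_ks * s0)
    n_non = rng.poisson(target_ka * n0)

    def apply_events(n_events, neighbours):
        applied = 0
        for _ in range(n_events):
            counts = np.array([len(neighbours[c]) for c in codons_b])
            total = counts.sum()
            if total == 0:
                break
            j = int(np.searchsorted(np.cumsum(counts), rng.integers(total), side="right"))
            opts = neighbours[codons_b[j]]
            _pos, _nt, new = opts[rng.integers(len(opts))]
            codons_b[j] = new
            applied += 1
        return applied

    applied_syn = apply_events(n_syn, SYN_NEIGHBOURS)
    applied_non = apply_events(n_non, NONSYN_NEIGHBOURS)
    truth = {
        "ks_true": applied_syn / s0 if s0 else 0.0,
        "ka_true": applied_non / n0 if n0 else 0.0,
        "syn_events": applied_syn,
        "nonsyn_events": applied_non,
        "s_sites": s0,
        "n_sites": n0,
    }
    return "".join(codons_a), "".join(codons_b), truth


# ---------------------------------------------------------------------------
# gene counts under a linear birth--death process


def _bd_alpha_beta(lam: float, mu: float, t: float):
    """Extinction and geometric parameters of the single-lineage BD process."""
    if t == 0 or (lam == 0 and mu == 0):
        return 0.0, 0.0
    if lam == mu:
        a = lam * t / (1.0 + lam * t)
        return a, a
    g = np.expm1((lam - mu) * t)
    denom = (lam - mu) + lam * g
    return float(mu * g / denom), float(lam * g / denom)


def _bd_sample_offspring(rng, counts: np.ndarray, lam, mu, t) -> np.ndarray:
    """Evolve per-family copy numbers along one branch of length t."""
    alpha, beta = _bd_alpha_beta(lam, mu, t)
    total = int(counts.sum())
    if total == 0 or t == 0 or (lam == 0 and mu == 0):
        return counts.copy()
    u = rng.random(total)
    surviving = u >= alpha
    kids = np.zeros(total, dtype=np.int64)
    if beta > 0:
        kids[surviving] = rng.geometric(1.0 - beta, size=int(surviving.sum()))
    else:
        kids[surviving] = 1
    fam = np.repeat(np.arange(counts.size), counts)
    out = np.zeros(counts.size, dtype=np.int64)
    np.add.at(out, fam, kids)
    return out


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def _clade_of(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def simulate_gene_counts(
    tree,
    birth: float,
    death: float,
    wgd=None,
    n_families: int = 1000,
    seed: int = 0,
    wgd_position: float = 0.5,
) -> pd.DataFrame:
    """Evolve gene-family copy numbers along a dated species tree.

    Every family starts with a single copy at the root node.  ``wgd`` is an
    iterable of (clade, q) events: on the stem branch of ``clade`` (a set of
    species codes) each extant copy duplicates and the new copy survives
    with probability ``q``.  Returns a families x species DataFrame.
    """
    if birth < 0 or death < 0:
        raise ValueError("rates must be non-negative")
    events = list(wgd or [])
    for clade, q in events:
        if not 0 <= q <= 1:
            raise ValueError("retention rate q must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = _load_tree(tree)
    event_map = {frozenset(clade): q for clade, q in events}

    root_counts = np.ones(n_families, dtype=np.int64)
    root_clade = _clade_of(t.seed_node)
    if root_clade in event_map:
        # event on the root stem: applied before any branch evolution
        root_counts += rng.binomial(root_counts, event_map.pop(root_clade))
    t.seed_node.counts = root_counts
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        clade = _clade_of(node)
        start = node.parent_node.counts
        if clade in event_map:
            q = event_map[clade]
            pre = _bd_sample_offspring(rng, start, birth, death, length * wgd_position)
            extra = rng.binomial(pre, q)
            post = pre + extra
            node.counts = _bd_sample_offspring(
                rng, post, birth, death, length * (1.0 - wgd_position)
            )
        else:
            node.counts = _bd_sample_offspring(rng, start, birth, death, length)

    data = {}
    for leaf in t.leaf_node_iter():
        data[leaf.taxon.label] = leaf.counts
    df = pd.DataFrame(data, index=[f"fam{i:05d}" for i in range(n_families)])
    return df[sorted(df.columns)]


# ---------------------------------------------------------------------------
# gene trees with a planted duplication node


def _subtree_newick(species_tree: dendropy.Tree, species, suffix: str,
                    scale: float = 1.0):
    """Ultrametric newick (no trailing ;) of the species tree restricted to
    ``species``, node ages multiplied by ``scale``, leaf labels tagged by
    ``suffix``; returns (newick, scaled crown age)."""
    species = sorted(species)
    if len(species) == 1:
        return f"{species[0]}{suffix}:0", 0.0

    tns = species_tree.taxon_namespace
    keep = [t for t in tns if t.label in species]
    sub = species_tree.extract_tree_with_taxa(taxa=keep)
    sub.suppress_unifurcations()

    def node_age(node):
        if node.is_leaf():
            return 0.0
        child = node.child_nodes()[0]
        return node_age(child) + (child.edge.length or 0.0)

    def render(node):
        if node.is_leaf():
            return f"{node.taxon.label}{suffix}", 0.0
        parts = []
        age = node_age(node) * scale
        for ch in node.child_nodes():
            s, a = render(ch)
            parts.append(f"{s}:{age - a:.10g}")
        return "(" + ",".join(parts) + ")", age

    s, age = render(sub.seed_node)
    return s, age


def simulate_gene_trees(
    species_tree,
    dup_age: float,
    n_trees: int,
    seed: int = 0,
    age_sd: float = 0.0,
    dropout: float = 0.0,
    species_subsets=None,
    outgroup: str = "ACH",
    far_outgroup: str = "DFE",
    outgroup_age: float | None = None,
    root_age: float | None = None,
    ingroup=None,
):
    """Dated gene trees whose two ingroup paralog subclades join at dup_age.

    Each tree joins two copies of the (possibly down-sampled) ingroup
    subtree at an age drawn from Normal(dup_age, age_sd), truncated only at
    the fossil minimum ``min_dup_age`` of 68 myr.  Dated gene trees estimate
    their own node ages, so when a drawn duplication age falls at or below
    the species-tree crown the copy subtrees are compressed to sit just
    under the duplication node, and the outgroup attachment floats above it
    (capped at the root).  ``dropout`` removes each species from each copy
    independently, emulating unexpressed copies.  Returns a list of newick
    strings with branch lengths in myr.
    """
    min_dup_age = 68.0
    rng = np.random.default_rng(seed)
    st = _load_tree(species_tree)
    ingroup = sorted(ingroup or cornus.CORNUS_SPECIES)
    t_a = cornus.T_A if outgroup_age is None else outgroup_age
    t_d = cornus.T_D if root_age is None else root_age
    pools = species_subsets or (ingroup, ingroup)

    crown = max(
        (_subtree_newick(st, pool, "")[1] for pool in pools if len(pool) > 1),
        default=0.0,
    )
    if dup_age <= min(crown, min_dup_age):
        raise ValueError("dup_age must be older than the ingroup crown age")

    trees = []
    for i in range(n_trees):
        d = float(np.clip(rng.normal(dup_age, age_sd), min_dup_age, t_d - 1.0))
        out_age = min(max(t_a, d + 0.5), t_d - 0.5)
        copies = []
        for copy_idx, pool in enumerate(pools[:2]):
            kept = [sp for sp in pool if rng.random() >= dropout]
            if not kept:
                continue
            suffix = f"_t{i}{'ab'[copy_idx]}"
            pool_crown = _subtree_newick(st, kept, "")[1]
            scale = min(1.0, (d - 0.5) / pool_crown) if pool_crown > 0 else 1.0
            nwk, age = _subtree_newick(st, kept, suffix, scale=scale)
            copies.append((nwk, age))
        if not copies:
            continue
        if len(copies) == 2:
            core = "(" + ",".join(f"{n}:{d - a:.10g}" for n, a in copies) + ")"
            core_age = d
        else:
            # the surviving copy attaches directly under the outgroup node
            core, core_age = copies[0]
        nwk = (
            f"({far_outgroup}_t{i}:{t_d:.10g},({outgroup}_t{i}:{out_age:.10g},"
            f"{core}:{out_age - core_age:.10g}):{t_d - out_age:.10g});"
        )
        trees.append(nwk)
    return trees


def leaf_species(label: str) -> str:
    """Species code of a synthetic gene-tree or transcript label."""
    return label.split("_")[0]


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SyntheticCohort:
    """All synthetic inputs for one end-to-end pipeline run."""

    config: SimulationConfig
    transcripts: dict  # species -> list of (gene id, sequence)
    paralog_truth: pd.DataFrame
    ortholog_truth: pd.DataFrame
    hits: pd.DataFrame
    gene_counts: pd.DataFrame | None = None
    gene_trees: list | None = None

    @property
    def species_map(self) -> dict:
        out = {}
        for sp, recs in self.transcripts.items():
            for gid, _seq in recs:
                out[gid] = sp
        return out


def _hit_row(qid, sid, seq_a, seq_b):
    """A tabular hit for an ungapped equal-length pair."""
    n = min(len(seq_a), len(seq_b))
    ident = sum(a == b for a, b in zip(seq_a[:n], seq_b[:n])) / n * 100.0
    return {
        "qseqid": qid,
        "sseqid": sid,
        "pident": round(ident, 2),
        "length": n,
        "mismatch": int(round((100.0 - ident) / 100.0 * n)),
        "gapopen": 0,
        "qstart": 1,
        "qend": n,
        "sstart": 1,
        "send": n,
        "evalue": 0.0,
        "bitscore": round(2.0 * n * ident / 100.0, 1),
    }


def build_cohort(
    config: SimulationConfig,
    species=None,
    outgroups=cornus.OUTGROUPS,
    n_codons: int = 200,
    n_ortholog_pairs: int = 40,
    target_omega: float = 0.2,
    isoform_decoys: int = 0,
    gene_counts: bool = False,
    gene_trees: int = 0,
    dup_age: float = 74.0,
) -> SyntheticCohort:
    """Assemble transcripts, hits and truth tables for a pipeline run.

    Each planted paralog pair becomes two coding sequences generated at its
    true Ks (with Ka = omega * Ks); ortholog pairs are generated against
    both outgroups at the configured divergence times.  The hit table lists
    one tabular record per generated pair, plus optional same-parent isoform
    decoys that the pairing stage must exclude.
    """
    species = list(species or config.species_clocks)
    species = [sp for sp in species if sp not in outgroups]
    rng = np.random.default_rng(config.seed)
    transcripts: dict[str, list] = {sp: [] for sp in species}
    for og in outgroups:
        transcripts[og] = []
    rows_par, rows_ort, hit_rows = [], [], []

    for sp in species:
        ks, labels = simulate_paralog_ks(config, sp, seed=int(rng.integers(2**31)))
        for j, (k, lab) in enumerate(zip(ks, labels)):
            k = float(min(k, 2.5))
            a_id = f"{sp}_g{2 * j}_i1"
            b_id = f"{sp}_g{2 * j + 1}_i1"
            seq_a, seq_b, truth = simulate_codon_pair(
                k, target_omega * k, n_codons, seed=int(rng.integers(2**31))
            )
            transcripts[sp].append((a_id, seq_a))
            transcripts[sp].append((b_id, seq_b))
            rows_par.append(
                {
                    "species": sp,
                    "gene_a": a_id,
                    "gene_b": b_id,
                    "ks_target": k,
                    "ks_true": truth["ks_true"],
                    "label": lab,
                }
            )
            hit_rows.append(_hit_row(a_id, b_id, seq_a, seq_b))
            if isoform_decoys > 0 and j < isoform_decoys:
                iso_id = f"{sp}_g{2 * j}_i2"
                transcripts[sp].append((iso_id, seq_a))
                hit_rows.append(_hit_row(a_id, iso_id, seq_a, seq_a))

        for og in outgroups:
            t_div = config.divergence_times[(sp, og)]
            mean_ks = 2.0 * config.species_clocks[sp] * t_div
            for j in range(n_ortholog_pairs):
                k = float(
                    max(0.0, rng.normal(mean_ks, config.ortholog_sigma))
                )
                a_id = f"{sp}_o{og}{j}_i1"
                b_id = f"{og}_o{sp}{j}_i1"
                seq_a, seq_b, _truth = simulate_codon_pair(
                    min(k, 2.5), target_omega * min(k, 2.5), n_codons,
                    seed=int(rng.integers(2**31)),
                )
                transcripts[sp].append((a_id, seq_a))
                transcripts[og].append((b_id, seq_b))
                rows_ort.append(
                    {
                        "species_a": sp,
                        "species_b": og,
                        "gene_a": a_id,
                        "gene_b": b_id,
                        "ks_target": k,
                    }
                )
                hit_rows.append(_hit_row(a_id, b_id, seq_a, seq_b))

    counts = None
    if gene_counts:
        counts = simulate_gene_counts(
            cornus.SPECIES_TREE_NEWICK,
            birth=0.002,
            death=0.002,
            wgd=[(frozenset(cornus.CORNUS_SPECIES), 0.1)],
            n_families=1000,
            seed=int(rng.integers(2**31)),
        )
    trees = None
    if gene_trees:
        trees = simulate_gene_trees(
            cornus.SPECIES_TREE_NEWICK,
            dup_age=dup_age,
            n_trees=gene_trees,
            seed=int(rng.integers(2**31)),
            age_sd=2.7,
            dropout=0.2,
        )
    return SyntheticCohort(
        config=config,
        transcripts=transcripts,
        paralog_truth=pd.DataFrame(rows_par),
        ortholog_truth=pd.DataFrame(rows_ort),
        hits=pd.DataFrame(hit_rows),
        gene_counts=counts,
        gene_trees=trees,
    )


def write_cohort(cohort: SyntheticCohort, outdir):
    """Write a cohort to disk (FASTA, hits TSV, truth TSVs, newick)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_dir = outdir / "fasta"
    fasta_dir.mkdir(exist_ok=True)
    for sp, recs in cohort.transcripts.items():
        with open(fasta_dir / f"{sp}.fasta", "w") as fh:
            for gid, seq in recs:
                fh.write(f">{gid}\n{seq}\n")
    cohort.hits.to_csv(outdir / "hits.tsv", sep="\t", header=False, index=False)
    cohort.paralog_truth.to_csv(outdir / "paralog_truth.tsv", sep="\t", index=False)
    cohort.ortholog_truth.to_csv(outdir / "ortholog_truth.tsv", sep="\t", index=False)
    with open(outdir / "species_map.tsv", "w") as fh:
        for gid, sp in sorted(cohort.species_map.items()):
            fh.write(f"{gid}\t{sp}\n")
    if cohort.gene_counts is not None:
        cohort.gene_counts.to_csv(outdir / "gene_counts.tsv", sep="\t")
    if cohort.gene_trees:
        with open(outdir / "gene_trees.nwk", "w") as fh:
            fh.write("\n".join(cohort.gene_trees) + "\n")
    return outdir
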