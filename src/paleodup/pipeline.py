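"""End-to-end orchestration: pair -> rates -> calibrate -> detect -> profile,
with optional gene-count placement and gene-tree screening stages.

A run is driven by a :class:`RunConfig` (typically loaded from YAML); every
stage writes TSV outputs into the run directory and records row counts and
SHA-256 hashes in a JSON manifest, so a run with a fixed seed is
reproducible file-by-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    clock_calibration,
    cornus,
    genetree_screen,
    homolog_pairing,
    rate_estimation,
    selection_profile,
    wgd_mixture,
    wgd_placement,
)

log = logging.getLogger("paleodup")

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    outdir: str
    fasta_dir: str
    species: list
    outgroups: list = field(default_factory=lambda: list(cornus.OUTGROUPS))
    hits: str | None = None
    species_map: str | None = None
    t_a: float = cornus.T_A
    t_d: float = cornus.T_D
    t_max: float = 200.0
    min_evalue: float = 1e-6
    min_hit_identity: float = 40.0
    min_align: int = 150
    min_identity: float = 60.0
    require_reciprocal: bool = True
    gap_policy: str = "drop-columns"
    k_range: tuple = (2, 5)
    min_proportion: float = 0.20
    bin_width: float = 5.0
    gene_counts: str | None = None
    species_tree: str | None = None
    gene_trees: str | None = None
    bw_group: list = field(default_factory=lambda: list(cornus.BW_GROUP))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta_dir(fasta_dir: Path, species):
    seqs: dict[str, str] = {}
    by_species: dict[str, list] = {}
    for sp in species:
        path = fasta_dir / f"{sp}.fasta"
        if not path.exists():
            raise FileNotFoundError(f"missing FASTA for species {sp}: {path}")
        from Bio import SeqIO

        ids = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq)
            ids.append(rec.id)
        by_species[sp] = ids
    return seqs, by_species


def run_full(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest."""
    import Bio
    import dendropy as _dendropy
    import scipy

    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "paleodup": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "biopython": Bio.__version__,
            "dendropy": _dendropy.__version__,
        },
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, path: Path, **info):
        manifest["stages"].setdefault(stage, {}).update(info)
        if path is not None:
            manifest["outputs"][str(path.name)] = _sha256(path)

    all_species = list(config.species) + [
        og for og in config.outgroups if og not in config.species
    ]
    seqs, by_species = _read_fasta_dir(Path(config.fasta_dir), all_species)
    species_map = {}
    if config.species_map:
        with open(config.species_map) as fh:
            for line in fh:
                gid, sp = line.split()
                species_map[gid] = sp
    else:
        for sp, ids in by_species.items():
            for gid in ids:
                species_map[gid] = sp

    # --- pair -------------------------------------------------------------
    if config.hits:
        hits = homolog_pairing.read_tabular_hits(config.hits)
    else:
        hits = homolog_pairing.all_vs_all_local_align(
            seqs, min_evalue=config.min_evalue, min_identity=config.min_hit_identity
        )
    paralogs = homolog_pairing.best_match_pairs(
        hits, "within", species_map, require_reciprocal=config.require_reciprocal
    )
    orthologs = homolog_pairing.best_match_pairs(
        hits, "between", species_map, require_reciprocal=config.require_reciprocal
    )
    n_before = (len(paralogs), len(orthologs))
    paralogs = homolog_pairing.filter_pairs(
        paralogs, config.min_align, config.min_identity
    )
    orthologs = homolog_pairing.filter_pairs(
        orthologs, config.min_align, config.min_identity
    )
    pairs_df = homolog_pairing.pairs_to_frame(list(paralogs) + list(orthologs))
    pairs_path = outdir / "pairs.tsv"
    pairs_df.to_csv(pairs_path, sep="\t", index=False)
    record(
        "pair",
        pairs_path,
        n_hits=len(hits),
        n_paralogs_raw=n_before[0],
        n_orthologs_raw=n_before[1],
        n_paralogs=len(paralogs),
        n_orthologs=len(orthologs),
    )
    log.info("pair: %d paralog and %d ortholog pairs", len(paralogs), len(orthologs))

    # --- rates ------------------------------------------------------------
    rates = rate_estimation.batch_rates(
        list(paralogs) + list(orthologs), seqs, gap_policy=config.gap_policy
    )
    rates_path = outdir / "rates.tsv"
    rates.to_csv(rates_path, sep="\t", index=False)
    record(
        "rates",
        rates_path,
        n_rows=len(rates),
        n_ok=int((rates["status"] == "ok").sum()),
        drop_reasons=rates.loc[rates["status"] != "ok", "status"]
        .value_counts()
        .to_dict(),
    )

    # --- calibrate --------------------------------------------------------
    near_og, far_og = config.outgroups[0], config.outgroups[-1]
    ok = rates[rates["status"] == "ok"]
    clocks: dict[str, clock_calibration.ClockCalibration] = {}
    cal_rows = []
    ages_by_species: dict[str, list] = {}
    omega_rows = []
    for sp in config.species:
        ort = ok[(ok["kind"] == "ortholog")]
        ks_a_vals = ort[
            ((ort["species_a"] == sp) & (ort["species_b"] == near_og))
            | ((ort["species_b"] == sp) & (ort["species_a"] == near_og))
        ]["Ks"].to_numpy()
        ks_d_vals = ort[
            ((ort["species_a"] == sp) & (ort["species_b"] == far_og))
            | ((ort["species_b"] == sp) & (ort["species_a"] == far_og))
        ]["Ks"].to_numpy()
        if len(ks_a_vals) < 10 or len(ks_d_vals) < 10:
            log.warning("calibrate: too few ortholog pairs for %s; skipped", sp)
            continue
        ks_a = clock_calibration.kde_peak(ks_a_vals)
        ks_d = clock_calibration.kde_peak(ks_d_vals)
        clock = clock_calibration.calibrate_clock(
            ks_a, ks_d, config.t_a, config.t_d, species=sp
        )
        clocks[sp] = clock
        max_ks = clock_calibration.max_ks_for_window(clock, config.t_max)
        cal_rows.append(
            {
                "species": sp,
                "Ks_A": ks_a,
                "Ks_D": ks_d,
                "T_A": config.t_a,
                "T_D": config.t_d,
                "C_Ks": clock.c_ks,
                "max_Ks": max_ks,
            }
        )
        par = ok[(ok["kind"] == "paralog") & (ok["species_a"] == sp)]
        samples = clock_calibration.ages_from_rate_table(
            par["Ks"].to_numpy(),
            (par["gene_a"] + "|" + par["gene_b"]).tolist(),
            clock,
            config.t_max,
        )
        ages_by_species[sp] = samples
        kept = {s.pair_id for s in samples}
        for _, row in par.iterrows():
            pid = f"{row['gene_a']}|{row['gene_b']}"
            if pid in kept and np.isfinite(row["omega"]):
                omega_rows.append(
                    {
                        "species": sp,
                        "pair": pid,
                        "age": row["Ks"] / (2 * clock.c_ks),
                        "omega": row["omega"],
                    }
                )
    cal_path = outdir / "calibration.tsv"
    pd.DataFrame(cal_rows).to_csv(cal_path, sep="\t", index=False)
    record("calibrate", cal_path, n_species=len(cal_rows))

    ages_path = outdir / "paralog_ages.tsv"
    pd.DataFrame(
        [
            {"species": sp, "pair": s.pair_id, "Ks": s.ks, "age": s.age}
            for sp, samples in ages_by_species.items()
            for s in samples
        ]
    ).to_csv(ages_path, sep="\t", index=False)
    record("calibrate_ages", ages_path)

    # --- detect -----------------------------------------------------------
    detect_info = {}
    if ages_by_species:
        pooled_fit = wgd_mixture.pooled_analysis(
            {sp: [s.age for s in v] for sp, v in ages_by_species.items()},
            k_range=tuple(config.k_range),
            seed=config.seed,
        )
        retained = wgd_mixture.retain_components(pooled_fit, config.min_proportion)
        comp_path = outdir / "pooled_components.tsv"
        pd.DataFrame(
            [
                {
                    "mean_age": c.mean,
                    "sd": c.sd,
                    "proportion": c.proportion,
                    "label": c.label,
                    "retained": c.proportion > config.min_proportion,
                }
                for c in pooled_fit.components
            ]
        ).to_csv(comp_path, sep="\t", index=False)
        record(
            "detect",
            comp_path,
            k=pooled_fit.k,
            bic_table={str(k): v for k, v in pooled_fit.bic_table.items()},
            n_retained=len(retained),
        )
        detect_info["pooled_fit"] = pooled_fit
        detect_info["retained"] = retained

    # --- profile ----------------------------------------------------------
    if omega_rows:
        odf = pd.DataFrame(omega_rows)
        bins, excluded = selection_profile.bin_omega(
            odf["age"], odf["omega"], window=(0.0, config.t_max), width=config.bin_width
        )
        bins_path = outdir / "omega_bins.tsv"
        selection_profile.bins_to_frame(bins).to_csv(bins_path, sep="\t", index=False)
        record("profile", bins_path, n_excluded=excluded)

    # --- place (optional) -------------------------------------------------
    if config.gene_counts:
        tree = wgd_placement.SpeciesTree(
            config.species_tree or cornus.SPECIES_TREE_NEWICK
        )
        counts = pd.read_csv(config.gene_counts, sep="\t", index_col=0)
        counts, n_removed = wgd_placement.filter_gene_counts(counts)
        results = wgd_placement.test_hypotheses(tree, counts)
        place_path = outdir / "placement.tsv"
        wgd_placement.placement_frame(results).to_csv(
            place_path, sep="\t", index=False
        )
        record(
            "place",
            place_path,
            n_families=len(counts),
            n_removed=n_removed,
            best=results[0].hypothesis,
        )

    # --- screen (optional) ------------------------------------------------
    if config.gene_trees:
        calls = []
        with open(config.gene_trees) as fh:
            newicks = [ln.strip() for ln in fh if ln.strip()]
        for i, nwk in enumerate(newicks):
            rec = genetree_screen.GeneTreeRecord.from_newick(f"gt{i}", nwk)
            rec = genetree_screen.outgroup_branch_filter(rec, config.outgroups[-1])
            calls.append(
                genetree_screen.screen_tree(rec, deep_group=config.bw_group)
            )
        calls_path = outdir / "duplication_calls.tsv"
        pd.DataFrame(
            [
                {"tree": c.tree_id, "passes": c.passes, "age": c.age,
                 "flags": ";".join(c.flags)}
                for c in calls
            ]
        ).to_csv(calls_path, sep="\t", index=False)
        n_pass = sum(c.passes for c in calls)
        info = {"n_trees": len(calls), "n_pass": n_pass}
        if n_pass >= 10:
            fit = genetree_screen.collect_and_fit_dates(calls, seed=config.seed)
            dom = genetree_screen.dominant_component(fit)
            info["dup_age_mean"] = dom.mean
            info["dup_age_sd"] = dom.sd
        record("screen", calls_path, **info)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
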