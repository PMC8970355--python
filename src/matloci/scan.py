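"""Genome-wide balancing-selection outlier scan and pipeline orchestration.

A gene is a balancing-selection candidate when it falls in the extreme 1%
tail (direction-aware: high pi/dxy, high Tajima's D, high within-species
dS, high partial HKA, low Fst) of at least ``min_flags`` statistics,
mirroring the "top 1% in at least two statistics" outlier rule.  Thresholds
are empirical nearest-rank quantiles over all non-null gene values (mating
genes included in the background by default); genes strictly beyond the
threshold are flagged, so ties at the threshold are never flagged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
import warnings

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allelic import aai_cluster, clade_concordance, pairwise_aai
from .errors import ValidationError
from .hka import hka_table
from .io import GenePanel, read_gene_panel, read_strain_table, species_map, write_fasta
from .mating import MATING_GENES, assign_genotypes, enumerate_types
from .popgen import gene_summary
from .simulate import SimConfig, plant_pheromone_fixture, simulate_panel

#: statistic column -> tail direction for the default flag set; dN is
#: reported in the stats table but not flagged by default.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "pi_over_dxy_a": "high",
    "pi_over_dxy_b": "high",
    "tajima_a": "high",
    "tajima_b": "high",
    "ds_within_a": "high",
    "ds_within_b": "high",
    "partial_hka": "high",
    "fst": "low",
}


def nearest_rank_threshold(values: np.ndarray, q: float, direction: str) -> float:
    """Empirical tail threshold by rank.

    For the high tail the threshold is the floor((1-q)*m)-th smallest of the
    m non-null values and genes strictly above it are flagged, so the flag
    set is the top ceil(q*m) values (ties at the threshold never flagged);
    the low tail is the mirror image.  With 200 genes and q = 0.01 exactly
    the top 2 are flagged.
    """
    v = np.sort(values)
    m = len(v)
    k = max(1, min(m, math.floor((1.0 - q) * m)))
    if direction == "high":
        return float(v[k - 1])
    return float(v[m - k])


def outlier_scan(
    stats: pd.DataFrame,
    directions: dict[str, str] | None = None,
    q: float = 0.01,
    min_flags: int = 2,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag per-statistic tail outliers and call candidates.

    Returns the table with added ``flag_*`` columns, ``n_flags`` and
    ``candidate``, plus the per-statistic thresholds used.
    """
    if len(stats) < 10:
        raise ValidationError("outlier_scan requires at least 10 genes")
    if not (0.0 < q < 0.5):
        raise ValidationError("q must be in (0, 0.5)")
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    out = stats.copy()
    thresholds: dict[str, float] = {}
    flag_cols = []
    for col, direction in directions.items():
        if direction not in ("high", "low"):
            raise ValidationError(f"direction for {col!r} must be high or low")
        if col not in out.columns:
            warnings.warn(f"statistic column {col!r} absent; skipped")
            continue
        vals = pd.to_numeric(out[col], errors="coerce")
        ok = vals.notna()
        if not ok.any():
            warnings.warn(f"statistic column {col!r} is all-null; skipped")
            continue
        thr = nearest_rank_threshold(vals[ok].to_numpy(float), q, direction)
        thresholds[col] = thr
        if direction == "high":
            flags = ok & (vals > thr)
        else:
            flags = ok & (vals < thr)
        out[f"flag_{col}"] = flags
        flag_cols.append(f"flag_{col}")
    out["n_flags"] = out[flag_cols].sum(axis=1).astype(int) if flag_cols else 0
    out["candidate"] = out["n_flags"] >= min_flags
    return out, thresholds


# ---------------------------------------------------------------------------
# Pipeline


class PipelineError(ValidationError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def demo_config() -> dict:
    """A self-contained demo: a simulated 106-gene panel (100 neutral
    background genes plus the six mating genes) analysed end to end."""
    return {
        "seed": 1,
        "species": ["speciesA", "speciesB"],
        "tau": 86.0,
        "q": 0.01,
        "min_flags": 2,
        "codon_stats": True,
        "simulate": {
            "n_neutral": 100,
            "n_balanced": 6,
            "n_a": 10,
            "n_b": 10,
            "t_split": 5.0,
            "theta": 5.0,
            "L": 300,
            "mode": "codon",
            "k": 3,
            "d_bal": 0.3,
            "theta_within": 0.5,
        },
        "mating_roles": {
            "aHD1": "mat01",
            "aHD2": "mat02",
            "bHD1": "mat03",
            "bHD2": "mat04",
            "STE3.2": "mat05",
            "STE3.4": "mat06",
        },
        "pheromone": True,
    }


def _validate_config(config: dict) -> dict:
    cfg = dict(config)
    if "species" not in cfg or len(cfg["species"]) != 2:
        raise ValidationError("config must name exactly two species")
    tau = float(cfg.get("tau", 86.0))
    if not (0.0 < tau <= 100.0):
        raise ValidationError(f"tau must be in (0, 100], got {tau}")
    q = float(cfg.get("q", 0.01))
    if not (0.0 < q < 0.5):
        raise ValidationError(f"q must be in (0, 0.5), got {q}")
    if "simulate" not in cfg and "panel" not in cfg:
        raise ValidationError("config needs a 'simulate' or 'panel' section")
    cfg["tau"], cfg["q"] = tau, q
    cfg.setdefault("seed", 0)
    cfg.setdefault("min_flags", 2)
    cfg.setdefault("codon_stats", False)
    return cfg


def _na(x) -> str:
    return "NA" if x is None else str(x)


def run_pipeline(config: dict, outdir: str) -> str:
    """Execute simulate (optional) -> stats -> hka -> classify -> mating ->
    pheromone (optional) -> outlier scan, writing every intermediate TSV, a
    machine-readable run manifest and a human-readable log."""
    cfg = _validate_config(config)
    os.makedirs(outdir, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    sp_a, sp_b = cfg["species"]
    seed = int(cfg["seed"])
    log(f"matloci {__version__} run; master seed {seed}")

    # --- stage: panel -----------------------------------------------------
    try:
        if "simulate" in cfg:
            sim = dict(cfg["simulate"])
            n_neutral = int(sim.pop("n_neutral"))
            n_balanced = int(sim.pop("n_balanced"))
            base = SimConfig(species_a=sp_a, species_b=sp_b, **sim)
            cfg_bal = dataclasses.replace(base)
            panel, loci = simulate_panel(
                n_neutral, n_balanced, base, cfg_bal, seed=seed
            )
            aln_dir = os.path.join(outdir, "alignments")
            os.makedirs(aln_dir, exist_ok=True)
            rows = []
            for gid, aln in panel.genes.items():
                fpath = os.path.join(aln_dir, f"{gid}.fasta")
                write_fasta(fpath, aln.seqs)
                npath = os.path.join(aln_dir, f"{gid}.nwk")
                with open(npath, "w") as fh:
                    fh.write(panel.tree_of[gid] + "\n")
                rows.append(
                    {
                        "gene_id": gid,
                        "fasta_path": os.path.relpath(fpath, outdir),
                        "category": panel.category_of[gid],
                        "newick_path": os.path.relpath(npath, outdir),
                    }
                )
            pd.DataFrame(rows).to_csv(
                os.path.join(outdir, "manifest.tsv"), sep="\t", index=False
            )
            truth = pd.DataFrame(
                [
                    {
                        "gene_id": gid,
                        "is_balanced": locus.is_balanced,
                        "lineages": _na(
                            None
                            if locus.truth_class_of is None
                            else len(set(locus.truth_class_of.values()))
                        ),
                    }
                    for gid, locus in loci.items()
                ]
            )
            truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
            log(f"simulated panel: {len(panel.genes)} genes")
        else:
            pcfg = cfg["panel"]
            panel = read_gene_panel(pcfg["manifest"], pcfg["strains"])
            log(f"loaded panel: {len(panel.genes)} genes")
    except ValidationError as exc:
        raise PipelineError("panel", str(exc)) from exc

    # --- stage: stats -----------------------------------------------------
    try:
        stats = gene_summary(panel, sp_a, sp_b, codon_stats=cfg["codon_stats"])
        stats.to_csv(
            os.path.join(outdir, "stats.tsv"), sep="\t", index=False, na_rep="NA"
        )
        log(f"stats: {len(stats)} gene records")
    except ValidationError as exc:
        raise PipelineError("stats", str(exc)) from exc

    # --- stage: hka -------------------------------------------------------
    try:
        hka_df, model = hka_table(panel, sp_a, sp_b)
        with open(os.path.join(outdir, "hka.tsv"), "w") as fh:
            fh.write(f"# X2={model.X2:.6g} df={model.df} ")
            fh.write(f"p={model.p_value:.6g} T_hat={model.T_hat:.6g}\n")
            hka_df.to_csv(fh, sep="\t", index=False, na_rep="NA")
        stats = stats.merge(
            hka_df[["locus_id", "partial_hka"]].rename(
                columns={"locus_id": "gene_id"}
            ),
            on="gene_id",
            how="left",
        )
        log(f"hka: X2={model.X2:.4g} df={model.df} p={model.p_value:.4g}")
    except ValidationError as exc:
        raise PipelineError("hka", str(exc)) from exc

    # --- stage: classify + mating ----------------------------------------
    roles = cfg.get("mating_roles") or {}
    genotypes = None
    if roles:
        try:
            classifications = {}
            class_rows = []
            for role, gid in roles.items():
                if role not in MATING_GENES:
                    raise ValidationError(f"unknown mating role {role!r}")
                if gid not in panel.genes:
                    raise ValidationError(f"mating role {role}: no gene {gid!r}")
                prot = panel.genes[gid].translated()
                cls = aai_cluster(pairwise_aai(prot), tau=cfg["tau"], gene_id=gid)
                if gid in panel.tree_of:
                    clade_concordance(cls, panel.tree_of[gid])
                classifications[role] = cls
                for s, c in cls.class_of.items():
                    class_rows.append(
                        {
                            "gene_id": gid,
                            "role": role,
                            "strain_id": s,
                            "allelic_class": c,
                            "concordant": _na(
                                None
                                if cls.concordant_with_tree is None
                                else cls.concordant_with_tree[c]
                            ),
                        }
                    )
            pd.DataFrame(class_rows).to_csv(
                os.path.join(outdir, "classes.tsv"), sep="\t", index=False
            )
            sp_of = {}
            for aln in panel.genes.values():
                sp_of.update(aln.species_of)
            genotypes = assign_genotypes(classifications, sp_of)
            census_rows = []
            for scope in (sp_a, sp_b, "pooled"):
                c = enumerate_types(genotypes, scope=scope)
                census_rows.append(
                    {
                        "scope": scope,
                        "n_strains": c.n_strains,
                        "n_alpha": c.n_alpha,
                        "n_beta": c.n_beta,
                        "n_MATA": c.n_mata,
                        "n_ste32": c.n_ste32,
                        "n_ste34": c.n_ste34,
                        "n_MATB": c.n_matb,
                        "n_types": c.n_types,
                        "observed_MATA": c.observed_mata,
                        "observed_MATB": c.observed_matb,
                        "observed_types": c.observed_types,
                    }
                )
            pd.DataFrame(census_rows).to_csv(
                os.path.join(outdir, "census.tsv"), sep="\t", index=False
            )
            log(f"mating: {len(genotypes)} genotypes")
        except ValidationError as exc:
            raise PipelineError("mating", str(exc)) from exc

    # --- stage: pheromone (fixture demo) ----------------------------------
    if cfg.get("pheromone"):
        try:
            from .pheromone import scan_contig

            contig, features, truths = plant_pheromone_fixture(seed)
            hits = scan_contig(contig, "contig1", features)
            pd.DataFrame(
                [
                    {
                        "contig": h.contig,
                        "start": h.orf_start,
                        "end": h.orf_end,
                        "strand": h.strand,
                        "len_bp": h.orf_len_bp,
                        "motif": h.motif_kind,
                        "maturation": h.maturation_site,
                        "mature_peptide": h.mature_peptide,
                        "ste3": _na(h.nearest_ste3_id),
                        "distance": _na(h.nearest_ste3_distance),
                        "verdict": h.verdict,
                    }
                    for h in hits
                ]
            ).to_csv(os.path.join(outdir, "pheromone.tsv"), sep="\t", index=False)
            n_acc = sum(h.verdict == "accepted" for h in hits)
            log(f"pheromone: {len(hits)} candidate ORFs, {n_acc} accepted")
        except ValidationError as exc:
            raise PipelineError("pheromone", str(exc)) from exc

    # --- stage: outlier scan ----------------------------------------------
    try:
        flagged, thresholds = outlier_scan(
            stats, q=cfg["q"], min_flags=int(cfg["min_flags"])
        )
        flagged.to_csv(
            os.path.join(outdir, "outliers.tsv"),
            sep="\t",
            index=False,
            na_rep="NA",
        )
        cands = flagged.loc[flagged["candidate"], "gene_id"].tolist()
        log(f"outlier scan: {len(cands)} candidates: {', '.join(cands) or 'none'}")
    except ValidationError as exc:
        raise PipelineError("outlier_scan", str(exc)) from exc

    manifest = {
        "matloci_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg,
        "outputs": sorted(
            f for f in os.listdir(outdir) if f.endswith((".tsv", ".json"))
        ),
    }
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return outdir
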