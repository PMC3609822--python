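"""Config-driven end-to-end run: from input files to the full table set.

``run_pipeline`` reads an aligned FASTA, sample metadata, a river map and an
optional population->cohort table, then emits (in order): the haplotype
table, NJ tree + collapsed tree + clade partition, clade distance summary,
per-population diversity, pairwise F_ST with permutation p-values, AMOVA
over populations and cohorts, the UPGMA population tree on net distances,
the geographic index table, per-site correlation profiles, and the GLM/AIC
model comparison — plus a machine-readable run log. Each artifact is
written as soon as its stage completes, so partial output survives a
failure; failures carry the stage name.
"""

from __future__ import annotations

import json
import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .barrier import RiverineBarrierModel
from .distances import clade_distance_summary, pairwise_diff_matrix, \
    tn93_distance_matrix
from .errors import InputError, RiverhapError
from .io import collapse_haplotypes, locality_specificity, read_alignment, \
    read_metadata
from .popgen import amova, diversity_table, net_population_distance, \
    pairwise_fst
from .rivers import RiverMap, geo_index_table, site_table
from .trees import bootstrap_support, build_upgma, collapse_low_support, \
    extract_clades, to_newick


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    alignment: str
    metadata: str
    rivers: str | None = None
    cohorts: dict[str, str] | None = None
    outdir: str = "riverhap_out"
    n_boot: int = 1000
    collapse_threshold: float = 70.0
    n_perm: int = 1023
    width_threshold: str = "large"
    tree_metric: str = "tn93"
    exclude: str | None = None
    seed: int = 0
    run_barriers: bool = True

    def validate(self) -> None:
        for name in ("alignment", "metadata"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise InputError(f"config field {name!r}: file not found: {path}")
        if self.run_barriers and self.rivers is None:
            raise InputError("config field 'rivers' is required when the "
                             "barrier analysis is requested")
        if self.rivers is not None and not Path(self.rivers).exists():
            raise InputError(f"config field 'rivers': file not found: "
                             f"{self.rivers}")
        if not (0 <= self.collapse_threshold <= 100):
            raise InputError("collapse_threshold must be in [0, 100]")
        if self.n_boot < 1 or self.n_perm < 1:
            raise InputError("n_boot and n_perm must be >= 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


class StageError(RiverhapError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage; returns a mapping artifact name -> written path."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: list[dict] = []

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise StageError(f"[{name}] {exc}") from exc
        log.append({"stage": name, "ok": True})
        return result

    def emit(name: str, filename: str, writer) -> Path:
        path = outdir / filename
        writer(path)
        artifacts[name] = path
        return path

    aln = stage("read_alignment", lambda: read_alignment(cfg.alignment))
    meta = stage("read_metadata", lambda: read_metadata(cfg.metadata))

    table = stage("collapse_haplotypes", lambda: collapse_haplotypes(aln, meta))
    emit("haplotypes", "haplotypes.tsv", table.write_tsv)
    spec = stage("locality_specificity", lambda: locality_specificity(table))

    hap_aln = table.alignment()
    diffs = stage("pairwise_diff_matrix", lambda: pairwise_diff_matrix(hap_aln))
    emit("diff_matrix", "diff_matrix.tsv", diffs.write_tsv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tn93 = stage("tn93_distance_matrix",
                     lambda: tn93_distance_matrix(hap_aln))
    emit("tn93_matrix", "tn93_matrix.tsv", tn93.write_tsv)

    tree = stage("bootstrap_nj", lambda: bootstrap_support(
        hap_aln, cfg.n_boot, cfg.seed, metric=cfg.tree_metric, builder="nj"))
    emit("nj_tree", "nj_tree.nwk",
         lambda p: Path(p).write_text(to_newick(tree) + "\n"))
    collapsed = stage("collapse_low_support",
                      lambda: collapse_low_support(tree,
                                                   cfg.collapse_threshold))
    emit("nj_collapsed", "nj_collapsed.nwk",
         lambda p: Path(p).write_text(to_newick(collapsed) + "\n"))
    clades = stage("extract_clades",
                   lambda: extract_clades(collapsed, cfg.collapse_threshold))
    emit("clades", "clades.tsv", lambda p: pd.Series(clades, name="clade")
         .rename_axis("haplotype_id").to_csv(p, sep="\t"))

    summary = stage("clade_distance_summary",
                    lambda: clade_distance_summary(diffs, clades))
    def _write_clade_summary(p):
        with open(p, "w") as fh:
            fh.write(f"# between_mean\t{summary.between_mean}\n")
            fh.write(f"# between_sd\t{summary.between_sd}\n")
            fh.write(f"# within_mean\t{summary.within_mean}\n")
            fh.write(f"# within_sd\t{summary.within_sd}\n")
            out = summary.between.copy()
            for c in summary.clades:
                out.loc[c, c] = summary.within[c]
            for i, ci in enumerate(summary.clades):
                for cj in summary.clades[i + 1:]:
                    out.loc[cj, ci] = summary.net.loc[cj, ci]
            out.to_csv(fh, sep="\t")
    emit("clade_distances", "clade_distances.tsv", _write_clade_summary)

    div = stage("diversity", lambda: diversity_table(
        table, diffs, hap_aln.length, aln=hap_aln))
    emit("diversity", "diversity.tsv", lambda p: div.to_csv(p, sep="\t"))

    fst = stage("pairwise_fst", lambda: pairwise_fst(
        table, diffs, n_perm=cfg.n_perm, seed=cfg.seed))
    emit("fst", "fst.tsv",
         lambda p: fst.lower_upper_table().to_csv(p, sep="\t"))

    amova_frames = []
    am_pops = stage("amova_populations", lambda: amova(table, diffs))
    frame = am_pops.to_frame()
    frame.insert(0, "comparison", "populations")
    amova_frames.append(frame)
    if cfg.cohorts:
        am_coh = stage("amova_cohorts",
                       lambda: amova(table, diffs, grouping=cfg.cohorts))
        frame = am_coh.to_frame()
        frame.insert(0, "comparison", "cohorts")
        amova_frames.append(frame)
    emit("amova", "amova.tsv",
         lambda p: pd.concat(amova_frames).to_csv(p, sep="\t"))

    net = stage("net_population_distance",
                lambda: net_population_distance(table, diffs))
    emit("net_distances", "net_distances.tsv", net.write_tsv)
    upgma = stage("upgma_populations", lambda: build_upgma(net))
    emit("upgma_tree", "upgma_populations.nwk",
         lambda p: Path(p).write_text(to_newick(upgma) + "\n"))

    if cfg.run_barriers:
        rivers = stage("read_rivers", lambda: RiverMap.from_geojson(cfg.rivers))
        sites = stage("site_table", lambda: site_table(meta))
        geo = stage("geo_index_table", lambda: geo_index_table(
            sites, rivers, width_threshold=cfg.width_threshold))
        emit("geo_indices", "geo_indices.tsv",
             lambda p: geo.to_csv(p, sep="\t", index=False))

        model = stage("barrier_model", lambda: RiverineBarrierModel
                      .from_components(fst.fst, geo, cfg.cohorts))
        emit("pair_table", "pair_table.tsv",
             lambda p: model.table.to_csv(p, sep="\t", index=False))
        corr = stage("correlation_table", lambda: model.correlation_table())
        emit("correlations", "correlations.tsv",
             lambda p: corr.to_csv(p, sep="\t"))
        ranked = stage("model_comparison",
                       lambda: model.model_comparison())
        frames = [ranked.ranking()]
        if cfg.exclude is not None:
            ranked_ex = stage("model_comparison_excluded",
                              lambda: model.model_comparison(cfg.exclude))
            frames.append(ranked_ex.ranking())
        emit("glm_aic", "glm_aic.tsv", lambda p: pd.concat(frames)
             .to_csv(p, sep="\t", index=False))
        ks = stage("ks_normality", model.normality_check)
    else:
        ks = None

    run_log = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in asdict(cfg).items()
                       if k not in ("cohorts",)},
        "inputs": {
            "alignment": _file_hash(cfg.alignment),
            "metadata": _file_hash(cfg.metadata),
            "rivers": _file_hash(cfg.rivers) if cfg.rivers else None,
        },
        "n_samples": table.n_samples,
        "n_haplotypes": len(table.ids),
        "n_clades": len(set(clades.values())),
        "locality_specific": spec.n_specific,
        "locality_shared": spec.n_shared,
        "bootstrap_replicates_used": tree.bootstrap_reps,
        "bootstrap_replicates_skipped": tree.bootstrap_skipped,
        "ks_normality": {"D": ks[0], "p": ks[1]} if ks else None,
        "stages": log,
    }
    path = outdir / "run_log.json"
    with open(path, "w") as fh:
        json.dump(run_log, fh, indent=1)
    artifacts["run_log"] = path
    return artifacts
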