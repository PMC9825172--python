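"""End-to-end orchestration: simulate -> cluster -> tu -> enrich -> promoter.

A single flat YAML config drives the run; every stochastic stage takes
an explicit seed (stage seeds default to deterministic offsets of the
top-level seed). Outputs are plain TSV/FASTA/JSON in a fixed directory
layout so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrichment, fourier, io, promoter, simulate, tu as tu_mod
from .core import Classification

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "timeseries", "promoters", "gradients", "clustering",
    "tu", "enrichment", "promoter_analysis",
}


@dataclass
class RunConfig:
    seed: int
    timeseries: dict = field(default_factory=dict)
    promoters: dict = field(default_factory=dict)
    gradients: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    tu: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    promoter_analysis: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config must declare a seed")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def stage_seed(self, offset: int) -> int:
        return (self.seed + offset) % (2**31 - 1)


def run_all(config: RunConfig, outdir) -> Path:
    """Run the full synthetic pipeline into ``outdir``.

    Layout: inputs/ (simulated data + truth), clustering/, tu/,
    enrichment/, promoter/, logs/run.log.
    """
    out = Path(outdir)
    for sub in ("inputs", "clustering", "tu", "enrichment", "promoter", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (out / "logs" / "config.yaml").write_text(cfg_text)
    log_lines = [
        f"coilscape {__version__}",
        f"config_sha256 {hashlib.sha256(cfg_text.encode()).hexdigest()}",
        f"seed {config.seed}",
    ]

    # --- inputs -----------------------------------------------------------
    ts_kw = dict(config.timeseries)
    scenario = simulate.default_induction_scenario(
        n_genes_per_cohort=ts_kw.pop("n_genes_per_cohort", 150),
        noise_sd=ts_kw.pop("noise_sd", 0.2),
        seed=ts_kw.pop("seed", config.stage_seed(1)),
    )
    if ts_kw:
        raise ValueError(f"unknown timeseries keys: {sorted(ts_kw)}")
    matrix, cohorts = simulate.simulate_timeseries(scenario)
    io.write_expression_tsv(matrix, out / "inputs" / "expression_tpm.tsv")
    io.write_samples_table(matrix.samples, out / "inputs" / "samples.tsv")
    io.write_classification(cohorts, out / "inputs" / "truth_cohorts.tsv")

    p_kw = dict(config.promoters)
    p_kw.setdefault("seed", config.stage_seed(2))
    pscenario = simulate.PromoterScenario(**p_kw)
    genome, tus = simulate.simulate_genome(pscenario, genes_per_tu=4)
    genome, planted = simulate.plant_promoter_motifs(genome, tus, pscenario)
    # link the independent generators: TUs carry the expression genes
    tus = simulate.annotate_tus_with_genes(tus, matrix.gene_ids)
    planted = Classification(
        {t.tu_id: planted.labels[t.tu_id] for t in tus})
    io.write_fasta(genome, out / "inputs" / "genome.fasta")
    io.write_tu_table(tus, out / "inputs" / "tus.tsv")
    io.write_classification(planted, out / "inputs" / "truth_planted.tsv")

    g_kw = dict(config.gradients)
    g_kw.setdefault("seed", config.stage_seed(3))
    gscenario = simulate.GradientScenario(**g_kw)
    fc = simulate.simulate_foldchanges(tus, gscenario)
    io.write_foldchanges(fc, out / "inputs" / "foldchanges.tsv")
    log_lines.append(f"seeds timeseries={scenario.seed} promoters={pscenario.seed} "
                     f"gradients={gscenario.seed}")

    # --- clustering -------------------------------------------------------
    ckw = dict(config.clustering)
    m = ckw.pop("components", 6)
    k_range = range(ckw.pop("k_min", 2), ckw.pop("k_max", 10) + 1)
    restarts = ckw.pop("restarts", 20)
    min_signal = ckw.pop("min_total_signal", 1.0)
    cseed = ckw.pop("seed", config.stage_seed(4))
    if ckw:
        raise ValueError(f"unknown clustering keys: {sorted(ckw)}")
    features = fourier.build_features(matrix, m=m, min_total_signal=min_signal)
    result = fourier.select_k(features, k_range, n_restarts=restarts, seed=cseed)
    relabel = fourier.sort_clusters_by_reference(result.labels, cohorts)
    sorted_labels = {g: relabel[c] for g, c in result.labels.items()}
    io.write_classification(
        Classification({g: f"c{l}" for g, l in sorted_labels.items()}),
        out / "clustering" / "gene_clusters.tsv",
        item_col="gene_id",
    )
    result.bic_by_k.to_csv(out / "clustering" / "bic_by_k.tsv", sep="\t", index=False)
    model_info = {
        "chosen_k": result.chosen_k,
        "relabel_map": {str(k): v for k, v in relabel.items()},
        "weights": result.model.weights.tolist(),
        "means": result.model.means.tolist(),
        "seed": cseed,
        "n_restarts": restarts,
    }
    (out / "clustering" / "model.json").write_text(json.dumps(model_info, indent=1))
    log_lines.append(f"clustering chosen_k={result.chosen_k} "
                     f"excluded={len(features.excluded)}")

    # --- tu ---------------------------------------------------------------
    tkw = dict(config.tu)
    theta_gene = tkw.pop("theta_gene", tu_mod.THETA_GENE)
    theta_tu = tkw.pop("theta_tu", tu_mod.THETA_TU)
    min_genes = tkw.pop("min_genes", 2)
    if tkw:
        raise ValueError(f"unknown tu keys: {sorted(tkw)}")
    tu_expr, _ = tu_mod.aggregate_to_tu(matrix, tus)
    tu_feats = fourier.build_features(tu_expr, m=m, min_total_signal=min_signal)
    km = tu_mod.kmeans_seeded(tu_feats.matrix, result.model.means)
    tu_labels = {t: f"c{relabel[int(l)]}" for t, l in zip(tu_feats.gene_ids, km.labels)}
    io.write_classification(
        Classification(tu_labels), out / "tu" / "tu_clusters.tsv", item_col="tu_id"
    )
    gene_resp = tu_mod.immediate_response(matrix, theta=theta_gene)
    tu_resp = tu_mod.immediate_response(tu_expr, theta=theta_tu)
    io.write_classification(Classification(gene_resp.labels),
                            out / "tu" / "gene_response.tsv", item_col="gene_id")
    io.write_classification(Classification(tu_resp.labels),
                            out / "tu" / "tu_response.tsv", item_col="tu_id")
    grad = tu_mod.tu_gradient(fc, tus, min_genes=min_genes)
    grad.to_csv(out / "tu" / "tu_gradients.tsv", sep="\t", index=False)
    log_lines.append(f"tu response counts {tu_resp.counts()}")

    # --- enrichment -------------------------------------------------------
    ekw = dict(config.enrichment)
    p_sort = ekw.pop("p_sort", 0.01)
    p_min = ekw.pop("p_min", 1e-10)
    p_txt = ekw.pop("p_txt", 1e-5)
    if ekw:
        raise ValueError(f"unknown enrichment keys: {sorted(ekw)}")
    cluster_cls = Classification({g: f"c{l}" for g, l in sorted_labels.items()})
    table = enrichment.cross_tabulate(cluster_cls, cohorts)
    table = enrichment.sort_overlaps(table, p_sort=p_sort)
    table.counts.loc[table.row_order].to_csv(out / "enrichment" / "overlap_counts.tsv",
                                             sep="\t")
    table.p_enrich.loc[table.row_order].to_csv(
        out / "enrichment" / "overlap_p_enrich.tsv", sep="\t")
    enrichment.render_profile(table, p_min=p_min, p_txt=p_txt).to_csv(
        out / "enrichment" / "overlap_style.tsv", sep="\t", index=False)
    log_lines.append(f"enrichment cut_row={table.cut_row}")

    # --- promoter ---------------------------------------------------------
    pkw = dict(config.promoter_analysis)
    w = pkw.pop("window", 5)
    region = tuple(pkw.pop("region", (-pscenario.upstream, pscenario.downstream)))
    acf_region = tuple(pkw.pop("acf_region", (-100, -1)))
    max_lag = pkw.pop("max_lag", 30)
    B = pkw.pop("B", 200)
    jsd_seed = pkw.pop("seed", config.stage_seed(5))
    if pkw:
        raise ValueError(f"unknown promoter_analysis keys: {sorted(pkw)}")
    U, D = -region[0], region[1]
    planted_ids = [t for t, l in planted.labels.items() if l == "planted"]
    profiles = []
    for motif_name in ("GC", "AT2", "TpA", "ATRACT4"):
        motif = promoter.MOTIFS[motif_name]
        aligned = promoter.align_at_tss(genome, tus, motif, U, D)
        w_use = 66 if motif_name == "GC" else w
        prof = promoter.positional_profile(aligned, planted_ids, w=w_use)
        prof.insert(0, "motif", motif_name)
        profiles.append(prof.reset_index())
    pd.concat(profiles).to_csv(out / "promoter" / "profiles.tsv", sep="\t", index=False)

    acf, period = promoter.acf_periodicity(genome, tus, region=acf_region,
                                           max_lag=max_lag)
    pd.DataFrame({"lag": np.arange(len(acf)), "acf": acf}).to_csv(
        out / "promoter" / "acf.tsv", sep="\t", index=False)

    bg_ids = [t for t, l in planted.labels.items() if l == "background"]
    seq_by_id = {}
    for t_u in tus:
        try:
            seq_by_id[t_u.tu_id] = promoter.tss_window(genome, t_u, U, D)
        except promoter.WindowOutOfBounds:
            pass
    pos_index = np.arange(-U, D)
    jsd = promoter.jsd_permutation_test(
        [seq_by_id[t] for t in planted_ids if t in seq_by_id],
        [seq_by_id[t] for t in bg_ids if t in seq_by_id],
        B=B, seed=jsd_seed, positions=pos_index,
    )
    jsd.rename_axis("position").to_csv(out / "promoter" / "jsd.tsv", sep="\t")

    disc_all = promoter.discriminator_stats(genome, tus)
    disc_planted = promoter.discriminator_stats(
        genome, [t for t in tus if t.tu_id in set(planted_ids)])
    p_en, p_de = promoter.discriminator_enrichment(disc_planted, disc_all)
    pd.DataFrame(
        [
            {"set": "all", "n_tus": disc_all.n_tus,
             "gc_fraction": disc_all.gc_fraction,
             "t_at_minus7": disc_all.t_at_minus7_fraction,
             "p_enrich": "", "p_deplete": ""},
            {"set": "planted", "n_tus": disc_planted.n_tus,
             "gc_fraction": disc_planted.gc_fraction,
             "t_at_minus7": disc_planted.t_at_minus7_fraction,
             "p_enrich": p_en, "p_deplete": p_de},
        ]
    ).to_csv(out / "promoter" / "discriminator.tsv", sep="\t", index=False)
    log_lines.append(f"promoter acf_period={period:.3f}")

    (out / "logs" / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
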