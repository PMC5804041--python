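"""End-to-end orchestration: simulate -> normalize -> DE -> PCIT/DH -> PIF/RIF
-> modules -> integration -> targets/enrichment -> report.

Configuration is a flat ``key = value`` file (see :class:`PipelineConfig`
for the keys); every stage writes deterministic TSV outputs with a
provenance header (package version, seed, config hash) into its own
subdirectory, and a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    read_annotation,
    read_counts,
    read_fasta,
    read_phenotypes,
    summarize_phenotypes,
    compare_groups,
    write_counts,
    write_phenotypes,
)
from .diffexpr import de_test, normalize, size_factors
from .integration import module_module_correlation, module_trait_correlation
from .pcit import (
    correlation_network,
    dh_scores,
    hub_neighbors,
    pcit,
    top_dh,
    variance_filter,
    write_edges_graphml,
)
from .pif_rif import group_means, pif, rank_regulators, rif_scores
from .simulate import default_config, generate_dataset, truth_tables
from .targets import enrich, predict_targets
from .wgcna import (
    adjacency,
    detect_modules,
    module_hubs,
    module_membership,
    pick_soft_threshold,
    signed_similarity,
    tom,
)

log = logging.getLogger("imfnet")

__all__ = ["PipelineConfig", "load_config", "run", "report"]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; unspecified inputs enable the simulator."""

    outdir: str = "imfnet_out"
    seed: int = 0
    # inputs (empty string = not provided; simulate instead)
    mrna_counts: str = ""
    mirna_counts: str = ""
    phenotypes: str = ""
    mirna_fasta: str = ""
    utr_fasta: str = ""
    annotation: str = ""
    # simulated-dataset scale (used only when inputs are not provided)
    sim_genes: int = 2000
    sim_mirnas: int = 150
    # stage toggles
    do_simulate: bool = True
    do_de: bool = True
    do_pcit: bool = True
    do_rif: bool = True
    do_modules: bool = True
    do_integrate: bool = True
    do_targets: bool = True
    do_enrich: bool = True
    # thresholds (defaults follow the study design)
    de_fdr: float = 0.10
    edge_threshold: float = 0.9
    pcit_top_features: int = 500  # variance pre-filter; 0 disables the cap
    min_module_size_mrna: int = 30
    min_module_size_mirna: int = 5
    merge_height: float = 0.25
    module_pair_r: float = -0.4
    module_pair_p: float = 0.05
    trait_p: float = 0.1
    trait_column: str = "imf_percent"
    beta_override_mrna: int = 12  # fixed signed-network default; 0 = automatic selection
    beta_override_mirna: int = 12
    covariates: str = ""  # comma-separated phenotype columns
    regulators: str = "all"  # "all" | "mirna"

    def covariate_tuple(self) -> tuple[str, ...]:
        return tuple(c.strip() for c in self.covariates.split(",") if c.strip())

    def config_hash(self) -> str:
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in fields(self) if f.name != "outdir"
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_BOOL_KEYS = {f.name for f in fields(PipelineConfig) if f.type == "bool"}
_INT_KEYS = {f.name for f in fields(PipelineConfig) if f.type == "int"}
_FLOAT_KEYS = {f.name for f in fields(PipelineConfig) if f.type == "float"}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    values: dict[str, object] = {}
    known = {f.name for f in fields(PipelineConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key in _BOOL_KEYS:
            values[key] = raw.lower() in ("1", "true", "yes", "on")
        elif key in _INT_KEYS:
            values[key] = int(raw)
        elif key in _FLOAT_KEYS:
            values[key] = float(raw)
        else:
            values[key] = raw
    return PipelineConfig(**values)


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# imfnet {__version__} seed={config.seed} config={config.config_hash()}\n")
        frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _detect_layer_modules(
    values: np.ndarray,
    feature_ids: list[str],
    min_size: int,
    merge_height: float,
    beta_override: int,
) -> tuple[dict[str, str], pd.DataFrame, int]:
    report = pick_soft_threshold(
        values, beta_override=beta_override if beta_override > 0 else None
    )
    adj = adjacency(signed_similarity(values), report.beta)
    t = tom(adj)
    assign, me = detect_modules(values, feature_ids, 1.0 - t, min_size, merge_height)
    return assign, me, report.beta


def run(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Outputs are written once per stage; a stage failure raises after logging
    which stage failed, leaving earlier outputs in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")
    log.info(
        "thresholds: de_fdr=%s edge=%s min_sizes=%s/%s merge=%s pair_r<=%s pair_p<%s trait_p<%s",
        config.de_fdr, config.edge_threshold, config.min_module_size_mrna,
        config.min_module_size_mirna, config.merge_height, config.module_pair_r,
        config.module_pair_p, config.trait_p,
    )
    stage = "inputs"
    try:
        if config.do_simulate or not (config.mrna_counts and config.mirna_counts and config.phenotypes):
            stage = "simulate"
            log.info("simulating dataset (seed=%d)", config.seed)
            sim = replace(
                default_config(config.seed),
                n_genes=config.sim_genes,
                n_mirnas=config.sim_mirnas,
            )
            mrna, mirna, pheno, truth = generate_dataset(sim)
            sim_dir = out / "simulate"
            sim_dir.mkdir(exist_ok=True)
            write_counts(mrna, sim_dir / "mrna_counts.tsv")
            write_counts(mirna, sim_dir / "mirna_counts.tsv")
            write_phenotypes(pheno, sim_dir / "phenotypes.tsv")
            truth_tables(truth, sim_dir / "truth")
        else:
            mrna = read_counts(config.mrna_counts, "mRNA")
            mirna = read_counts(config.mirna_counts, "miRNA")
            pheno = read_phenotypes(config.phenotypes)

        stage = "summarize"
        rows = []
        for col in ("imf_percent", "gebv"):
            summ = summarize_phenotypes(pheno, col)
            for grp in summ.index:
                rows.append({"column": col, "group": grp, **summ.loc[grp].to_dict()})
        t_stat, t_p = compare_groups(pheno, "gebv")
        _write_tsv(pd.DataFrame(rows), out / "phenotypes" / "group_summary.tsv", config)
        _write_tsv(
            pd.DataFrame([{"column": "gebv", "welch_t": t_stat, "p": t_p}]),
            out / "phenotypes" / "group_test.tsv",
            config,
        )

        stage = "normalize"
        covs = config.covariate_tuple()
        factors_mrna = size_factors(mrna)
        factors_mirna = size_factors(mirna)
        expr_mrna = normalize(mrna, factors_mrna)
        expr_mirna = normalize(mirna, factors_mirna)
        combined_values = np.vstack([expr_mrna.values, expr_mirna.values])
        combined_ids = list(expr_mrna.feature_ids) + list(expr_mirna.feature_ids)
        from .data_model import ExpressionMatrix

        expr_all = ExpressionMatrix(
            combined_values, combined_ids, list(mrna.sample_ids),
            np.ones(mrna.n_samples), 1.0,
        )

        de_features: list[str] = []
        if config.do_de:
            stage = "de"
            log.info("differential expression (NB Wald, FDR %.0f%%)", 100 * config.de_fdr)
            de_mirna = de_test(mirna, pheno, covs, fdr=config.de_fdr, factors=factors_mirna)
            de_mrna = de_test(mrna, pheno, covs, fdr=config.de_fdr, factors=factors_mrna)
            _write_tsv(de_mirna.frame, out / "de" / "de_mirna.tsv", config)
            _write_tsv(de_mrna.frame, out / "de" / "de_mrna.tsv", config)
            de_features = de_mirna.de_features + de_mrna.de_features
            log.info("DE features at FDR %.2f: %d", config.de_fdr, len(de_features))

        samples_h = pheno.samples_in_group("H")
        samples_l = pheno.samples_in_group("L")

        if config.do_pcit:
            stage = "pcit"
            ids = (
                variance_filter(expr_all, config.pcit_top_features)
                if config.pcit_top_features
                else combined_ids
            )
            log.info("PCIT on %d features per group", len(ids))
            sub = expr_all.subset_features(sorted(ids))
            net_h = correlation_network(sub, samples_h, "H")
            net_l = correlation_network(sub, samples_l, "L")
            mask_h = pcit(net_h.r)
            mask_l = pcit(net_l.r)
            dh = dh_scores(net_h, mask_h, net_l, mask_l, config.edge_threshold)
            _write_tsv(dh, out / "pcit" / "dh.tsv", config)
            pos, neg = top_dh(dh, k=min(10, len(dh)))
            _write_tsv(pos, out / "pcit" / "dh_top_positive.tsv", config)
            _write_tsv(neg, out / "pcit" / "dh_top_negative.tsv", config)
            hubs = list(pos["feature"]) + list(neg["feature"])
            for grp, net, mask in (("H", net_h, mask_h), ("L", net_l, mask_l)):
                _, edges = hub_neighbors(net, mask, hubs, config.edge_threshold)
                _write_tsv(edges, out / "pcit" / f"hub_edges_{grp}.tsv", config)
                write_edges_graphml(edges, out / "pcit" / f"hub_edges_{grp}.graphml")

        if config.do_rif:
            stage = "rif"
            if not de_features:
                log.info("RIF skipped: no DE features available")
            else:
                regulators = (
                    list(expr_mirna.feature_ids)
                    if config.regulators == "mirna"
                    else combined_ids
                )
                means = group_means(expr_all, pheno)
                pif_all = pif(means)
                scores = rif_scores(expr_all, pheno, regulators, de_features, pif_all)
                _write_tsv(scores, out / "rif" / "regulator_scores.tsv", config)
                ranks = rank_regulators(scores, k=10)
                for name, frame in ranks.items():
                    _write_tsv(frame, out / "rif" / f"{name}.tsv", config)

        me_by_group: dict[str, dict[str, pd.DataFrame]] = {}
        assign_by_group: dict[str, dict[str, dict[str, str]]] = {}
        hubs_by_group: dict[str, dict[str, str]] = {}
        if config.do_modules:
            stage = "modules"
            for grp, samples in (("H", samples_h), ("L", samples_l)):
                me_by_group[grp] = {}
                assign_by_group[grp] = {}
                for layer, expr, min_size, override in (
                    ("mrna", expr_mrna, config.min_module_size_mrna, config.beta_override_mrna),
                    ("mirna", expr_mirna, config.min_module_size_mirna, config.beta_override_mirna),
                ):
                    sub = expr.subset_samples(samples)
                    sd = np.std(sub.values, axis=1)
                    keep = sd > 0
                    vals = sub.values[keep]
                    ids = [f for f, k in zip(sub.feature_ids, keep) if k]
                    assign, me, beta = _detect_layer_modules(
                        vals, ids, min_size, config.merge_height, override
                    )
                    log.info(
                        "group %s %s: beta=%d, %d modules",
                        grp, layer, beta, me.shape[0],
                    )
                    me.columns = samples
                    me_by_group[grp][layer] = me
                    assign_by_group[grp][layer] = assign
                    mm = module_membership(vals, ids, me)
                    _write_tsv(
                        pd.DataFrame(
                            {"feature": ids, "module": [assign[f] for f in ids]}
                        ).join(mm.reset_index(drop=True)),
                        out / "modules" / f"{grp}_{layer}_modules.tsv",
                        config,
                    )
                    _write_tsv(me, out / "modules" / f"{grp}_{layer}_eigengenes.tsv", config, index=True)
                    if layer == "mirna" and len(me):
                        hubs_by_group[grp] = module_hubs(mm, assign)

        if config.do_integrate and config.do_modules:
            stage = "integrate"
            for grp, samples in (("H", samples_h), ("L", samples_l)):
                me_mi = me_by_group[grp]["mirna"]
                me_mr = me_by_group[grp]["mrna"]
                if len(me_mi) and len(me_mr):
                    pairs = module_module_correlation(
                        me_mi, me_mr, config.module_pair_r, config.module_pair_p
                    )
                    _write_tsv(pairs, out / "integration" / f"{grp}_module_pairs.tsv", config)
                for layer in ("mrna", "mirna"):
                    me = me_by_group[grp][layer]
                    if not len(me):
                        continue
                    trait = module_trait_correlation(
                        me, pheno, config.trait_column, config.trait_p, sample_ids=samples
                    )
                    _write_tsv(
                        trait, out / "integration" / f"{grp}_{layer}_trait.tsv", config
                    )

        if config.do_targets and config.mirna_fasta and config.utr_fasta:
            stage = "targets"
            mirna_seqs = read_fasta(config.mirna_fasta)
            utr_seqs = read_fasta(config.utr_fasta)
            expressed = set(mrna.feature_ids)
            sites, tmap = predict_targets(mirna_seqs, utr_seqs, expressed)
            _write_tsv(
                pd.DataFrame(
                    [
                        {"mirna": s.mirna, "utr": s.utr, "start": s.start, "type": s.site_type}
                        for s in sites
                    ],
                    columns=["mirna", "utr", "start", "type"],
                ),
                out / "targets" / "seed_sites.tsv",
                config,
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {"mirna": m, "gene": g}
                        for m in sorted(tmap.targets)
                        for g in sorted(tmap.targets[m])
                    ],
                    columns=["mirna", "gene"],
                ),
                out / "targets" / "target_map.tsv",
                config,
            )
        elif config.do_targets:
            log.info("targets stage skipped: no miRNA/UTR FASTA provided")
            tmap = None
        else:
            log.info("targets stage disabled; miRNA-module enrichment will be skipped")
            tmap = None

        if config.do_enrich and config.annotation:
            stage = "enrich"
            annotation = read_annotation(config.annotation)
            universe = set(mrna.feature_ids)
            if de_features:
                sel = set(de_features) & universe
                if sel:
                    _write_tsv(
                        enrich(sel, universe, annotation, config.de_fdr),
                        out / "enrichment" / "de_genes.tsv",
                        config,
                    )
        stage = "report"
        report(out, config)
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise
    return out


def _read_stage_tsv(path: Path) -> pd.DataFrame | None:
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t", comment="#")


def report(outdir: str | Path, config: PipelineConfig | None = None) -> Path:
    """Assemble a markdown summary of the main result tables of a finished run."""
    out = Path(outdir)
    lines = ["# imfnet run report", ""]

    def section(title: str, frame: pd.DataFrame | None, top: int | None = None) -> None:
        lines.append(f"## {title}")
        if frame is None:
            lines.append("_not run_")
        elif len(frame) == 0:
            lines.append("_empty (zero rows)_")
        else:
            shown = frame.head(top) if top else frame
            lines.append(shown.to_markdown(index=False))
        lines.append("")

    section("Phenotype group summary", _read_stage_tsv(out / "phenotypes" / "group_summary.tsv"))
    section("GEBV group contrast (Welch t)", _read_stage_tsv(out / "phenotypes" / "group_test.tsv"))
    de = _read_stage_tsv(out / "de" / "de_mirna.tsv")
    section(
        "DE miRNAs (FDR flag set)",
        None if de is None else de[de["de_flag"]].reset_index(drop=True),
    )
    section("Top positive differential hubbing", _read_stage_tsv(out / "pcit" / "dh_top_positive.tsv"))
    section("Top negative differential hubbing", _read_stage_tsv(out / "pcit" / "dh_top_negative.tsv"))
    section("Top regulators by RIF1", _read_stage_tsv(out / "rif" / "rif1_top_positive.tsv"))
    for grp in ("H", "L"):
        pairs = _read_stage_tsv(out / "integration" / f"{grp}_module_pairs.tsv")
        if pairs is not None:
            retained = pairs[pairs["retained"]].reset_index(drop=True)
            section(f"Retained miRNA-mRNA module pairs ({grp})", retained)
        trait = _read_stage_tsv(out / "integration" / f"{grp}_mrna_trait.tsv")
        if trait is not None:
            section(
                f"mRNA modules correlated with trait ({grp})",
                trait[trait["retained"]].reset_index(drop=True),
            )
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
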