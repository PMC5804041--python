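"""Synthetic paired miRNA/mRNA count data with planted structure.

The generator emulates the design of a two-group (high vs low breeding value)
muscle transcriptome study: 15 + 15 animals, negative-binomial counts with
lognormal library-size variation, block-correlated co-expression modules
driven by shared latent factors, a handful of differentially expressed
features, one miRNA regulator that is wired to an mRNA module in only one
group, one miRNA module anti-correlated with an mRNA module through a shared
factor with opposite-sign loadings, and a continuous trait (IMF %) driven by
one module's latent factor.  Every planted element is recorded in a
:class:`SyntheticTruth` so recovery tests can score the pipeline against it.

Counts for feature *i*, sample *j* are drawn

    NB(mean = s_j * 2**(b_i + sum_m lambda_im * F_mj + beta_i * 1[group_j = L]),
       variance = mean + alpha * mean**2)

with ``s_j`` the lognormal library-size factor, ``b_i`` a per-feature
baseline log2 abundance, ``F_mj`` standard-normal latent module factors and
``beta_i`` the planted log2 fold change of the Low group relative to High.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CountMatrix, PhenotypeTable

__all__ = [
    "ModuleSpec",
    "DeSpec",
    "RegulatorSpec",
    "TraitSpec",
    "SimConfig",
    "SyntheticTruth",
    "default_config",
    "generate_dataset",
    "truth_tables",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module: ``size`` features in ``layer`` loading
    on latent factor ``factor`` with the given (signed) loading."""

    name: str
    size: int
    loading: float
    layer: str  # "mRNA" | "miRNA"
    factor: str | None = None  # shared-factor id; defaults to the module name
    factor2: str | None = None  # optional secondary factor
    loading2: float = 0.0

    def factor_id(self) -> str:
        return self.factor if self.factor is not None else self.name

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"module {self.name!r}: size must be >= 2")
        if self.layer not in ("mRNA", "miRNA"):
            raise ValueError(f"module {self.name!r}: unknown layer {self.layer!r}")


@dataclass(frozen=True)
class DeSpec:
    """Planted differential expression: log2 fold change of Low relative to High."""

    feature: str
    log2fc: float


@dataclass(frozen=True)
class RegulatorSpec:
    """A regulator miRNA wired to ``target_module``'s factor with different
    correlations in the two groups (differential wiring).

    The optional secondary wirings (``de_modules`` with ``de_r_high`` /
    ``de_r_low`` applied to each listed module's own factor) correlate the
    regulator with the DE modules, letting its hub role (strong one-group
    wiring to the target module) and its differential wiring to DE features
    live on separate factors.
    """

    regulator_id: str
    target_module: str
    r_high: float
    r_low: float
    de_modules: tuple[str, ...] = ()
    de_r_high: float = 0.0  # wiring to each DE module's own factor, High group
    de_r_low: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.de_modules)
        for r1, r2 in ((self.r_high, self.de_r_high), (self.r_low, self.de_r_low)):
            if r1**2 + k * r2**2 >= 1:
                raise ValueError("regulator correlations must satisfy sum of r^2 < 1")


@dataclass(frozen=True)
class TraitSpec:
    """Trait = baseline + group offset + slope * driver-module factor + noise."""

    driver_module: str
    slope: float
    noise_sd: float
    imf_base: float = 2.9
    imf_group_diff: float = 2.8  # High minus Low difference in IMF %
    gebv_group_half: float = 0.51
    gebv_noise_sd: float = 0.15


@dataclass(frozen=True)
class SimConfig:
    n_per_group: int = 15
    n_genes: int = 2000
    n_mirnas: int = 150
    modules: tuple[ModuleSpec, ...] = ()
    de: tuple[DeSpec, ...] = ()
    regulator: RegulatorSpec | None = None
    trait: TraitSpec | None = None
    dispersion: float = 0.1
    libsize_lognormal_sd: float = 0.3
    mrna_base_log2: tuple[float, float] = (8.0, 1.5)  # mean, sd of baseline log2 abundance
    mirna_base_log2: tuple[float, float] = (9.0, 1.5)
    cg_log2_effect: float = 0.0  # contemporary-group batch shift (log2), applied to all features
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.libsize_lognormal_sd < 0:
            raise ValueError("libsize_lognormal_sd must be non-negative")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("duplicate module names")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset, keyed by generated feature ids."""

    module_of: dict[str, str]  # feature id -> module name ("" = background)
    de_table: pd.DataFrame  # columns: feature, true_log2fc
    regulator_id: str | None
    trait: TraitSpec | None
    trait_driver_factor: np.ndarray | None  # driver-module latent factor per sample
    seed: int


def default_config(seed: int = 0) -> SimConfig:
    """The default study conditions: 2,000 genes, 150 miRNAs, 15 + 15 samples.

    Planted structure:

    * four mRNA modules (100/80/60/40 genes); the 60-gene module carries a
      strong loading (3.0) so its internal correlations stay above the 0.9
      network edge filter even when the realized factor variance runs low,
      the others load at 0.8;
    * four miRNA modules (15/10/5/5); the 15-miRNA module shares a latent
      factor with the 80-gene mRNA module at opposite sign (anti-correlated
      cross-layer pair), and the two 5-miRNA modules each load 0.45 on the
      strong mRNA module's factor plus 0.65 on a factor of their own —
      coherent enough to form modules, far enough below the 0.9 edge filter
      that their links to the strong module never masquerade as hubs;
    * the 10 miRNAs of those two modules are differentially expressed, with
      log2 fold-change magnitudes in the 1.3-1.7 range typical of muscle
      miRNA studies, all lower in the Low group so their phenotypic impact
      weights share a sign;
    * one regulator miRNA wired to the strong module's factor at 0.96 in the
      Low group only (the planted Low-group hub: its >0.9 edges exist in one
      condition), and to each DE module's own factor at -0.68 in High vs
      +0.16 in Low — a sign-switching differential wiring to the DE features
      that the regulatory-impact scores should flag;
    * IMF % driven by the 100-gene module's factor (slope 0.5, noise 0.2) on
      top of a 2.8 % High-Low group difference.
    """
    modules = (
        ModuleSpec("mod_trait", 100, 0.8, "mRNA", factor="F_trait"),
        ModuleSpec("mod_pair_mrna", 80, -0.8, "mRNA", factor="F_pair"),
        ModuleSpec("mod_hub", 60, 3.0, "mRNA", factor="F_hub"),
        ModuleSpec("mod_extra", 40, 0.8, "mRNA", factor="F_extra"),
        ModuleSpec("mod_pair_mirna", 15, 0.8, "miRNA", factor="F_pair"),
        ModuleSpec("mod_mirna_2", 10, 0.8, "miRNA", factor="F_mir2"),
        ModuleSpec("mod_de1", 5, 0.45, "miRNA", factor="F_hub", factor2="F_de1", loading2=0.65),
        ModuleSpec("mod_de2", 5, 0.45, "miRNA", factor="F_hub", factor2="F_de2", loading2=0.65),
    )
    # ids must match the deterministic layout of generate_dataset
    de = tuple(
        DeSpec(f"mir_{26 + k:04d}", fc)
        for k, fc in enumerate(
            [-1.67, -1.45, -1.55, -1.71, -1.30, -1.60, -1.40, -1.50, -1.65, -1.35]
        )
    )
    regulator = RegulatorSpec(
        "mir_0036", "mod_hub", r_high=0.0, r_low=0.96,
        de_modules=("mod_de1", "mod_de2"), de_r_high=-0.68, de_r_low=0.16,
    )
    trait = TraitSpec("mod_trait", slope=0.5, noise_sd=0.2)
    return SimConfig(modules=modules, de=de, regulator=regulator, trait=trait, seed=seed)


def _feature_layout(config: SimConfig) -> tuple[list[str], list[str], dict[str, str]]:
    """Deterministic feature ids and module membership.

    Module members occupy the leading ids of each layer, in the order the
    modules appear in the config; remaining ids are background.  The
    regulator miRNA takes the first background miRNA slot.
    """
    genes = [f"gene_{i + 1:04d}" for i in range(config.n_genes)]
    mirnas = [f"mir_{i + 1:04d}" for i in range(config.n_mirnas)]
    module_of: dict[str, str] = {}
    cursors = {"mRNA": 0, "miRNA": 0}
    pools = {"mRNA": genes, "miRNA": mirnas}
    for mod in config.modules:
        pool, start = pools[mod.layer], cursors[mod.layer]
        if start + mod.size > len(pool):
            raise ValueError(
                f"module {mod.name!r} does not fit: needs {mod.size} {mod.layer} features"
            )
        for fid in pool[start : start + mod.size]:
            module_of[fid] = mod.name
        cursors[mod.layer] = start + mod.size
    return genes, mirnas, module_of


def generate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, PhenotypeTable, SyntheticTruth]:
    """Draw one paired dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_group
    genes, mirnas, module_of = _feature_layout(config)
    module_by_name = {m.name: m for m in config.modules}

    if config.regulator is not None:
        for mod_name in (config.regulator.target_module, *config.regulator.de_modules):
            if mod_name not in module_by_name:
                raise ValueError(f"regulator targets unknown module {mod_name!r}")
        if config.regulator.regulator_id not in set(mirnas):
            raise ValueError(f"unknown regulator id {config.regulator.regulator_id!r}")
        if module_of.get(config.regulator.regulator_id):
            raise ValueError("regulator id collides with a planted miRNA module member")
    if config.trait is not None and config.trait.driver_module not in module_by_name:
        raise ValueError(f"trait driver is unknown module {config.trait.driver_module!r}")
    known = set(genes) | set(mirnas)
    for d in config.de:
        if d.feature not in known:
            raise ValueError(f"DE spec references unknown feature {d.feature!r}")

    # sample frame: first half High, second half Low; contemporary groups balanced
    group = np.array(["H"] * config.n_per_group + ["L"] * config.n_per_group)
    is_low = (group == "L").astype(float)
    sample_ids = [f"{g}{i % config.n_per_group + 1:02d}" for i, g in enumerate(group)]
    cg = np.array(["CG1", "CG2"] * (n // 2) + ["CG1"] * (n % 2))[:n]
    age = np.round(rng.normal(760.0, 25.0, size=n), 1)

    # latent factors, one standard-normal draw per sample per factor id,
    # standardized within each group block so planted loadings and wiring
    # correlations are realized at their stated magnitude (not rescaled by
    # the sampling variance of the factor)
    factor_ids = sorted(
        {m.factor_id() for m in config.modules}
        | {m.factor2 for m in config.modules if m.factor2 is not None}
    )

    def _draw_factor() -> np.ndarray:
        f = rng.standard_normal(n)
        for mask in (group == "H", group == "L"):
            blk = f[mask]
            f[mask] = (blk - blk.mean()) / blk.std()
        return f

    factors = {f: _draw_factor() for f in factor_ids}

    libsize = np.exp(rng.normal(0.0, config.libsize_lognormal_sd, size=n))
    de_of = {d.feature: d.log2fc for d in config.de}
    alpha = float(config.dispersion)

    def _layer_counts(feature_ids: list[str], base_mu_sd: tuple[float, float]) -> np.ndarray:
        base = rng.normal(base_mu_sd[0], base_mu_sd[1], size=len(feature_ids))
        log2_mean = np.tile(base[:, None], (1, n))
        for i, fid in enumerate(feature_ids):
            mod = module_of.get(fid)
            if mod:
                spec = module_by_name[mod]
                log2_mean[i] += spec.loading * factors[spec.factor_id()]
                if spec.factor2 is not None and spec.loading2:
                    log2_mean[i] += spec.loading2 * factors[spec.factor2]
            if fid in de_of:
                log2_mean[i] += de_of[fid] * is_low
        reg = config.regulator
        if reg is not None and reg.regulator_id in feature_ids:
            i = feature_ids.index(reg.regulator_id)
            f1 = factors[module_by_name[reg.target_module].factor_id()]
            f_de = []
            for name in reg.de_modules:
                de_mod = module_by_name[name]
                f_de.append(factors[de_mod.factor2 or de_mod.factor_id()])
            # loadings that realize the requested correlations with the
            # factors, given the feature's NB noise on the log2 scale
            noise_sd = np.sqrt(1.0 / 2.0 ** base[i] + alpha) / LN2
            for grp, rho1, rho2 in (
                ("H", reg.r_high, reg.de_r_high),
                ("L", reg.r_low, reg.de_r_low),
            ):
                resid = np.sqrt(1.0 - rho1**2 - len(f_de) * rho2**2)
                mask = group == grp
                contrib = np.zeros(int(mask.sum()))
                if rho1:
                    contrib += (rho1 * noise_sd / resid) * f1[mask]
                if rho2:
                    for f2 in f_de:
                        contrib += (rho2 * noise_sd / resid) * f2[mask]
                # center on the raw-count scale so group-specific wiring does
                # not masquerade as differential expression (Jensen term)
                contrib -= np.log2(np.mean(np.exp2(contrib)))
                log2_mean[i, mask] += contrib
        if config.cg_log2_effect:
            log2_mean += config.cg_log2_effect * (cg == "CG2").astype(float)[None, :]
        mu = libsize[None, :] * np.exp2(log2_mean)
        k = 1.0 / alpha
        return rng.negative_binomial(k, k / (k + mu)).astype(np.int64)

    gene_counts = _layer_counts(genes, config.mrna_base_log2)
    mirna_counts = _layer_counts(mirnas, config.mirna_base_log2)

    # trait and breeding values
    half = np.where(group == "H", 1.0, -1.0)
    if config.trait is not None:
        t = config.trait
        driver_f = factors[module_by_name[t.driver_module].factor_id()]
        imf = (
            t.imf_base
            + 0.5 * t.imf_group_diff * half
            + t.slope * driver_f
            + rng.normal(0.0, t.noise_sd, size=n)
        )
        gebv = t.gebv_group_half * half + rng.normal(0.0, t.gebv_noise_sd, size=n)
    else:
        driver_f = None
        imf = 2.9 + 1.4 * half + rng.normal(0.0, 0.5, size=n)
        gebv = 0.51 * half + rng.normal(0.0, 0.15, size=n)
    imf = np.maximum(np.round(imf, 3), 0.05)

    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "imf_percent": imf,
                "gebv": np.round(gebv, 4),
                "group": group,
                "age_days": age,
                "contemporary_group": cg,
                "mapped_reads": mirna_counts.sum(axis=0).astype(float),
            }
        )
    )
    de_table = pd.DataFrame(
        {"feature": [d.feature for d in config.de], "true_log2fc": [d.log2fc for d in config.de]}
    )
    truth = SyntheticTruth(
        module_of={f: module_of.get(f, "") for f in genes + mirnas},
        de_table=de_table,
        regulator_id=None if config.regulator is None else config.regulator.regulator_id,
        trait=config.trait,
        trait_driver_factor=driver_f,
        seed=config.seed,
    )
    mrna = CountMatrix(gene_counts, genes, sample_ids, "mRNA")
    mirna = CountMatrix(mirna_counts, mirnas, sample_ids, "miRNA")
    return mrna, mirna, pheno, truth


def truth_tables(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write module / DE / regulator / trait ground truth as TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["modules"] = outdir / "truth_modules.tsv"
    pd.DataFrame(
        {"feature": list(truth.module_of), "module": list(truth.module_of.values())}
    ).to_csv(paths["modules"], sep="\t", index=False, lineterminator="\n")

    paths["de"] = outdir / "truth_de.tsv"
    truth.de_table.to_csv(paths["de"], sep="\t", index=False, lineterminator="\n")

    paths["regulator"] = outdir / "truth_regulator.tsv"
    regs = [] if truth.regulator_id is None else [truth.regulator_id]
    pd.DataFrame({"regulator": regs}).to_csv(
        paths["regulator"], sep="\t", index=False, lineterminator="\n"
    )

    paths["trait"] = outdir / "truth_trait.tsv"
    if truth.trait is None:
        pd.DataFrame(columns=["driver_module", "slope", "noise_sd"]).to_csv(
            paths["trait"], sep="\t", index=False, lineterminator="\n"
        )
    else:
        pd.DataFrame(
            [
                {
                    "driver_module": truth.trait.driver_module,
                    "slope": truth.trait.slope,
                    "noise_sd": truth.trait.noise_sd,
                }
            ]
        ).to_csv(paths["trait"], sep="\t", index=False, lineterminator="\n")
    return paths
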