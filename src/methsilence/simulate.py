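"""Seeded synthetic data with planted ground truth.

The generator emulates the statistical structure of a multi-genotype plant
methylome/transcriptome/siRNA study:

* an annotation of non-overlapping genes and TEs on a small genome;
* per-genotype cytosine reports: site coverage ~ Poisson(lambda), methylated
  reads ~ Binomial(coverage, level), where the generating level is the
  (feature kind x context) baseline plus any planted hypo-DMR delta for the
  genotype, clamped to [0, 1];
* per-genotype expression counts: per-feature baseline abundance drawn once
  from a gamma distribution (across-feature heterogeneity, CV^2 =
  ``expression_dispersion``), then one Poisson count per sequencing library,
  with planted fold changes multiplying the mean in affected genotypes;
* per-genotype 24-nt siRNA counts with genotype scaling according to planted
  Pol IV / Pol V dependence labels, plus a small 21-23-nt background.

Every generator is a pure function of (config, annotation, truth, genotype):
the site layout, feature placement, and per-feature abundances are drawn from
seed substreams that do not depend on genotype, so all genotypes share one
genome; only read sampling differs per genotype.

Defaults describe a study-scale scenario at roughly one-tenth genome scale: 60 planted
300-bp hypo-DMRs (CHH -0.30, CHG -0.15, CG -0.10) in a suvh2/9-like genotype
of which 15 are shared with a morc6-like genotype plus 6 morc6-specific ones;
30 up-regulated TEs per mutant with 12 shared; Pol IV-dependent 24-nt siRNAs
with about half of the features Pol V-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CONTEXTS, CytosineSiteRecord, GenomicFeature
from .features import promoter_region

_CTX_CODE = {c: i for i, c in enumerate(CONTEXTS)}
_KIND_CODE = {"other": 0, "gene": 1, "TE": 2}

# rng substream tags (mixed with the seed, all well below 2**31)
_S_ANNOT, _S_PLANT, _S_SITES, _S_METH, _S_EXPR_BASE, _S_EXPR, _S_SIRNA_BASE, _S_SIRNA = (
    7, 11, 13, 17, 19, 23, 29, 31,
)


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


def _default_baseline() -> dict:
    return {
        ("TE", "CG"): 0.85, ("TE", "CHG"): 0.45, ("TE", "CHH"): 0.30,
        ("gene", "CG"): 0.05, ("gene", "CHG"): 0.02, ("gene", "CHH"): 0.02,
        ("other", "CG"): 0.04, ("other", "CHG"): 0.02, ("other", "CHH"): 0.02,
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    # probability per bp of hosting a cytosine site of each context
    site_density: dict = field(
        default_factory=lambda: {"CG": 0.05, "CHG": 0.05, "CHH": 0.15}
    )
    coverage_mean: float = 20.0
    baseline: dict = field(default_factory=_default_baseline)
    # levels assigned to promoters of planted methylated-promoter genes
    promoter_methylation: dict = field(
        default_factory=lambda: {"CG": 0.30, "CHG": 0.15, "CHH": 0.12}
    )
    promoter_len: int = 1000
    # annotation
    n_genes: int = 120
    n_tes: int = 120
    gene_length: int = 1500
    te_length: int = 800
    # genotypes carrying methylomes / expression (first entry is the reference)
    genotypes: tuple = ("WT", "suvh29", "morc6")
    # planted hypo-DMRs (placed inside TEs)
    n_dmrs_suvh29: int = 60
    n_dmrs_shared: int = 15
    n_dmrs_morc6_specific: int = 6
    dmr_width: int = 300
    dmr_deltas: dict = field(
        default_factory=lambda: {"CG": -0.10, "CHG": -0.15, "CHH": -0.30}
    )
    # planted up-regulation (disjoint from DMR-carrying TEs)
    n_up_tes: dict = field(default_factory=lambda: {"suvh29": 30, "morc6": 30})
    n_up_tes_shared: int = 12
    n_up_genes: dict = field(default_factory=lambda: {"suvh29": 19, "morc6": 25})
    n_up_genes_shared: int = 6
    up_fold: float = 4.0
    # expression model
    expression_base_mean: dict = field(default_factory=lambda: {"TE": 30.0, "gene": 100.0})
    expression_dispersion: float = 0.1
    rna_library_size: int = 1_000_000
    # methylated promoters planted on a subset of genes
    n_meth_promoter_genes: int = 40
    # siRNA model
    sirna_genotypes: tuple = ("WT", "nrpd1", "nrpe1")
    sirna_mean: dict = field(default_factory=lambda: {"TE": 200.0, "gene": 60.0})
    sirna_background_mean: float = 3.0
    sirna_library_size: int = 2_000_000
    frac_pol_v_independent: float = 0.5
    nrpd1_scale_dependent: float = 0.02
    nrpe1_scale_dependent: float = 0.05

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), *stream])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline"] = {f"{k}:{c}": v for (k, c), v in self.baseline.items()}
        return d


@dataclass(frozen=True, slots=True)
class PlantedDMR:
    chrom: str
    start: int
    end: int
    genotypes: tuple  # affected (non-reference) genotypes
    deltas: dict  # context -> additive level change


@dataclass(frozen=True)
class GroundTruth:
    dmrs: tuple  # PlantedDMR
    up_features: dict  # genotype -> {feature_id: fold}
    sirna_labels: dict  # feature_id -> (pol_iv_dependent, pol_v_dependent)
    methylated_promoters: frozenset

    def dmrs_for(self, genotype: str) -> list[PlantedDMR]:
        return [d for d in self.dmrs if genotype in d.genotypes]


def simulate_annotation(config: SimulationConfig) -> list[GenomicFeature]:
    """Place non-overlapping genes and TEs with random spacing; deterministic
    under the config seed."""
    rng = config.rng(_S_ANNOT)
    features: list[GenomicFeature] = []
    per_chrom_genes = _split(config.n_genes, config.n_chromosomes)
    per_chrom_tes = _split(config.n_tes, config.n_chromosomes)
    for ci in range(config.n_chromosomes):
        chrom = f"Chr{ci + 1}"
        lengths = [config.gene_length] * per_chrom_genes[ci] + [config.te_length] * per_chrom_tes[ci]
        kinds = ["gene"] * per_chrom_genes[ci] + ["TE"] * per_chrom_tes[ci]
        order = rng.permutation(len(lengths))
        lengths = [lengths[i] for i in order]
        kinds = [kinds[i] for i in order]
        slack = config.chromosome_length - sum(lengths)
        if slack < len(lengths) + 1:
            raise ConfigError(
                f"{chrom}: features ({sum(lengths)} bp) exceed chromosome length "
                f"{config.chromosome_length}"
            )
        w = rng.random(len(lengths) + 1)
        gaps = np.floor(w / w.sum() * slack).astype(int)
        pos = 0
        n_gene = n_te = 0
        for L, kind, gap in zip(lengths, kinds, gaps):
            pos += int(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "gene":
                n_gene += 1
                fid = f"AT{ci + 1}G{n_gene:05d}"
            else:
                n_te += 1
                fid = f"AT{ci + 1}TE{n_te:05d}"
            features.append(GenomicFeature(fid, chrom, pos, pos + L, strand, kind))
            pos += L
    return features


def _split(n: int, parts: int) -> list[int]:
    base = n // parts
    out = [base] * parts
    for i in range(n - base * parts):
        out[i] += 1
    return out


def plant_ground_truth(
    config: SimulationConfig, annotation: Sequence[GenomicFeature]
) -> GroundTruth:
    """Draw the planted effects deterministically from the config seed.

    Hypo-DMRs are placed inside randomly chosen TEs; up-regulated features are
    drawn from TEs and genes *not* carrying a planted DMR, so expression and
    methylation effects are planted independently (the construction behind the
    "silencing without methylation change" analysis).
    """
    rng = config.rng(_S_PLANT)
    tes = [f for f in annotation if f.kind == "TE"]
    genes = [f for f in annotation if f.kind == "gene"]
    n_dmr_tes = config.n_dmrs_suvh29 + config.n_dmrs_morc6_specific
    need_tes = n_dmr_tes + (
        sum(config.n_up_tes.values()) - config.n_up_tes_shared
    )
    if need_tes > len(tes):
        raise ConfigError(f"need {need_tes} TEs for planting, annotation has {len(tes)}")

    te_order = rng.permutation(len(tes))
    dmr_tes = [tes[i] for i in te_order[:n_dmr_tes]]
    free_tes = [tes[i] for i in te_order[n_dmr_tes:]]

    dmrs = []
    for i, te in enumerate(dmr_tes):
        width = min(config.dmr_width, te.length)
        off = int(rng.integers(0, te.length - width + 1))
        if i < config.n_dmrs_shared:
            genos: tuple = ("suvh29", "morc6")
        elif i < config.n_dmrs_suvh29:
            genos = ("suvh29",)
        else:
            genos = ("morc6",)
        dmrs.append(
            PlantedDMR(te.chrom, te.start + off, te.start + off + width, genos,
                       dict(config.dmr_deltas))
        )

    up: dict[str, dict[str, float]] = {g: {} for g in config.genotypes if g != config.genotypes[0]}
    _plant_up(rng, free_tes, config.n_up_tes, config.n_up_tes_shared, config.up_fold, up)
    n_up_genes_total = sum(config.n_up_genes.values()) - config.n_up_genes_shared
    if n_up_genes_total > len(genes):
        raise ConfigError("not enough genes for planted up-regulation")
    gene_order = rng.permutation(len(genes))
    up_gene_pool = [genes[i] for i in gene_order]
    _plant_up(rng, up_gene_pool, config.n_up_genes, config.n_up_genes_shared, config.up_fold, up)

    labels = {}
    for f in annotation:
        pol_v_dep = bool(rng.random() >= config.frac_pol_v_independent)
        labels[f.feature_id] = (True, pol_v_dep)

    meth_prom = rng.choice(
        [g.feature_id for g in genes],
        size=min(config.n_meth_promoter_genes, len(genes)),
        replace=False,
    )
    return GroundTruth(
        dmrs=tuple(dmrs),
        up_features=up,
        sirna_labels=labels,
        methylated_promoters=frozenset(meth_prom.tolist()),
    )


def _plant_up(rng, pool, n_by_genotype: Mapping[str, int], n_shared: int, fold: float, out):
    genotypes = list(n_by_genotype)
    total = sum(n_by_genotype.values()) - n_shared * (len(genotypes) - 1)
    if total > len(pool):
        raise ConfigError(f"not enough features to plant up-regulation ({total} > {len(pool)})")
    idx = 0
    shared = pool[idx:idx + n_shared]
    idx += n_shared
    for g in genotypes:
        for f in shared:
            out[g][f.feature_id] = fold
        n_specific = n_by_genotype[g] - n_shared
        for f in pool[idx:idx + n_specific]:
            out[g][f.feature_id] = fold
        idx += n_specific


def _site_layout(config: SimulationConfig, chrom_index: int):
    """Genotype-independent site positions, contexts and strands for one
    chromosome."""
    rng = config.rng(_S_SITES, chrom_index)
    L = config.chromosome_length
    u = rng.random(L)
    strands = rng.integers(0, 2, L)
    d = config.site_density
    edges = np.cumsum([d["CG"], d["CHG"], d["CHH"]])
    ctx_code = np.full(L, -1, dtype=np.int8)
    ctx_code[u < edges[0]] = _CTX_CODE["CG"]
    ctx_code[(u >= edges[0]) & (u < edges[1])] = _CTX_CODE["CHG"]
    ctx_code[(u >= edges[1]) & (u < edges[2])] = _CTX_CODE["CHH"]
    mask = ctx_code >= 0
    pos0 = np.nonzero(mask)[0]
    return pos0, ctx_code[mask], strands[mask]


def _site_levels(
    config: SimulationConfig,
    annotation: Sequence[GenomicFeature],
    truth: GroundTruth,
    genotype: str,
    chrom: str,
    pos0: np.ndarray,
    ctx: np.ndarray,
) -> np.ndarray:
    L = config.chromosome_length
    kind_code = np.zeros(L, dtype=np.int8)
    chrom_feats = [f for f in annotation if f.chrom == chrom]
    for f in chrom_feats:
        kind_code[f.start:f.end] = _KIND_CODE[f.kind]
    lookup = np.zeros((3, 3))
    for kind, kcode in _KIND_CODE.items():
        for c, ccode in _CTX_CODE.items():
            lookup[kcode, ccode] = config.baseline[(kind, c)]
    level_map = np.empty((L, 3))
    for ccode in range(3):
        level_map[:, ccode] = lookup[kind_code, ccode]
    # static promoter methylation (same in every genotype)
    by_id = {f.feature_id: f for f in chrom_feats}
    for gid in truth.methylated_promoters:
        g = by_id.get(gid)
        if g is None:
            continue
        prom = promoter_region(g, config.promoter_len, chrom_len=L)
        for c, ccode in _CTX_CODE.items():
            level_map[prom.start:prom.end, ccode] = config.promoter_methylation[c]
    # planted genotype-specific deltas
    for d in truth.dmrs_for(genotype):
        if d.chrom != chrom:
            continue
        for c, ccode in _CTX_CODE.items():
            level_map[d.start:d.end, ccode] += d.deltas.get(c, 0.0)
    np.clip(level_map, 0.0, 1.0, out=level_map)
    return level_map[pos0, ctx]


def simulate_methylome(
    config: SimulationConfig,
    annotation: Sequence[GenomicFeature],
    truth: GroundTruth,
    genotype: str,
) -> list[CytosineSiteRecord]:
    """Cytosine report for one genotype; sites with zero coverage are omitted."""
    if genotype not in config.genotypes:
        raise ConfigError(f"genotype {genotype!r} not in config.genotypes")
    gi = config.genotypes.index(genotype)
    records: list[CytosineSiteRecord] = []
    inv_ctx = {v: k for k, v in _CTX_CODE.items()}
    for ci in range(config.n_chromosomes):
        chrom = f"Chr{ci + 1}"
        pos0, ctx, strands = _site_layout(config, ci)
        levels = _site_levels(config, annotation, truth, genotype, chrom, pos0, ctx)
        rng = config.rng(_S_METH, gi, ci)
        cov = rng.poisson(config.coverage_mean, pos0.size)
        m = rng.binomial(cov, levels)
        u = cov - m
        keep = cov > 0
        strand_chars = np.where(strands == 0, "+", "-")
        for p, c, s, mi, ui in zip(
            pos0[keep], ctx[keep], strand_chars[keep], m[keep], u[keep]
        ):
            records.append(
                CytosineSiteRecord(chrom, int(p) + 1, str(s), inv_ctx[int(c)], int(mi), int(ui))
            )
    return records


def expression_base_means(
    config: SimulationConfig, annotation: Sequence[GenomicFeature]
) -> dict[str, float]:
    """Per-feature baseline abundance, shared by all genotypes.

    Gamma-distributed across features with CV^2 = ``expression_dispersion``,
    so a library's counts are marginally negative-binomial with that
    dispersion."""
    rng = config.rng(_S_EXPR_BASE)
    disp = config.expression_dispersion
    shape = 1.0 / disp
    means = {}
    for f in annotation:
        base = config.expression_base_mean[f.kind]
        means[f.feature_id] = float(rng.gamma(shape, base * disp))
    return means


def simulate_expression(
    config: SimulationConfig,
    annotation: Sequence[GenomicFeature],
    truth: GroundTruth,
    genotype: str,
) -> tuple[dict[str, int], int]:
    """One library of per-feature counts for one genotype; returns
    (counts, library_total)."""
    if genotype not in config.genotypes:
        raise ConfigError(f"genotype {genotype!r} not in config.genotypes")
    gi = config.genotypes.index(genotype)
    means = expression_base_means(config, annotation)
    folds = truth.up_features.get(genotype, {})
    rng = config.rng(_S_EXPR, gi)
    counts = {}
    for f in annotation:
        mu = means[f.feature_id] * folds.get(f.feature_id, 1.0)
        counts[f.feature_id] = int(rng.poisson(mu))
    return counts, config.rna_library_size


def sirna_base_means(
    config: SimulationConfig, annotation: Sequence[GenomicFeature]
) -> dict[str, float]:
    rng = config.rng(_S_SIRNA_BASE)
    means = {}
    for f in annotation:
        base = config.sirna_mean[f.kind]
        means[f.feature_id] = float(rng.gamma(10.0, base / 10.0))
    return means


def simulate_sirna(
    config: SimulationConfig,
    annotation: Sequence[GenomicFeature],
    truth: GroundTruth,
    genotype: str,
) -> tuple[pd.DataFrame, int]:
    """Per-feature small-RNA counts by read length (21-24 nt) for one genotype.

    24-nt means are scaled by the planted dependence labels: x
    ``nrpd1_scale_dependent`` in nrpd1 (all planted siRNAs are Pol
    IV-dependent), x ``nrpe1_scale_dependent`` in nrpe1 for Pol V-dependent
    features, x 1.0 for Pol V-independent ones.
    """
    if genotype not in config.sirna_genotypes:
        raise ConfigError(f"genotype {genotype!r} not in config.sirna_genotypes")
    gi = config.sirna_genotypes.index(genotype)
    means = sirna_base_means(config, annotation)
    rng = config.rng(_S_SIRNA, gi)
    rows = []
    for f in annotation:
        pol_iv_dep, pol_v_dep = truth.sirna_labels[f.feature_id]
        scale = 1.0
        if genotype == "nrpd1" and pol_iv_dep:
            scale = config.nrpd1_scale_dependent
        elif genotype == "nrpe1" and pol_v_dep:
            scale = config.nrpe1_scale_dependent
        bg = config.sirna_background_mean
        rows.append(
            {
                "feature_id": f.feature_id,
                "21": int(rng.poisson(bg)),
                "22": int(rng.poisson(bg)),
                "23": int(rng.poisson(bg)),
                "24": int(rng.poisson(means[f.feature_id] * scale)),
            }
        )
    return pd.DataFrame(rows), config.sirna_library_size


# ---------------------------------------------------------------------------
# ground-truth serialization (single TSV, one record type per row)

def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("#record_type\tchrom\tstart\tend\tfeature_id\tgenotypes\tpayload\n")
        for d in truth.dmrs:
            payload = ";".join(f"{c}={d.deltas[c]:g}" for c in sorted(d.deltas))
            fh.write(
                f"dmr\t{d.chrom}\t{d.start}\t{d.end}\t.\t{','.join(d.genotypes)}\t{payload}\n"
            )
        for g in sorted(truth.up_features):
            for fid in sorted(truth.up_features[g]):
                fh.write(f"up\t.\t0\t0\t{fid}\t{g}\tfold={truth.up_features[g][fid]:g}\n")
        for fid in sorted(truth.sirna_labels):
            iv, v = truth.sirna_labels[fid]
            fh.write(f"sirna\t.\t0\t0\t{fid}\t.\tpol_iv_dep={int(iv)};pol_v_dep={int(v)}\n")
        for fid in sorted(truth.methylated_promoters):
            fh.write(f"meth_promoter\t.\t0\t0\t{fid}\t.\t.\n")


def read_ground_truth(path) -> GroundTruth:
    dmrs = []
    up: dict[str, dict[str, float]] = {}
    labels = {}
    prom = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rtype, chrom, start, end, fid, genos, payload = line.split("\t")
            if rtype == "dmr":
                deltas = {}
                for item in payload.split(";"):
                    c, v = item.split("=")
                    deltas[c] = float(v)
                dmrs.append(PlantedDMR(chrom, int(start), int(end), tuple(genos.split(",")), deltas))
            elif rtype == "up":
                fold = float(payload.split("=")[1])
                up.setdefault(genos, {})[fid] = fold
            elif rtype == "sirna":
                parts = dict(item.split("=") for item in payload.split(";"))
                labels[fid] = (bool(int(parts["pol_iv_dep"])), bool(int(parts["pol_v_dep"])))
            elif rtype == "meth_promoter":
                prom.add(fid)
            else:
                raise ValueError(f"unknown ground-truth record type {rtype!r}")
    return GroundTruth(tuple(dmrs), up, labels, frozenset(prom))
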