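"""End-to-end orchestration: simulate -> DMRs -> comparison -> DE -> feature
methylation -> siRNA profile -> summary, with a manifest and ground-truth
evaluation.

Each stage consumes and produces only files under the run directory, so any
stage can be re-run in isolation. The summary TSV is byte-deterministic for a
fixed seed; wall-clock runtimes live only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import compare, dmr, expression, features, io, simulate, sirna


@dataclass
class PipelineParams:
    """Every threshold of the analysis in one namespace (defaults are the
    study's stated values)."""

    window_size: int = 50
    min_coverage: int = 5
    delta_min: float = 0.10
    alpha: float = 0.01
    max_gap: int = 50
    context_mode: str = "total"
    min_overlap: int = 50
    fc_min: float = 2.0
    de_alpha: float = 0.01
    de_pseudocount: float = 0.5
    promoter_len: int = 1000
    te_threshold: float = 0.20
    gene_threshold: float = 0.05
    sirna_cutoff: float = 0.5
    sirna_pseudocount: float = 1.0
    min_wt_rptm: float = 5.0
    mutants: tuple = ("suvh29", "morc6")
    reference: str = "WT"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: simulate.SimulationConfig, simdir: Path) -> None:
    simdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate.simulate_annotation(config)
    truth = simulate.plant_ground_truth(config, annotation)
    io.write_features(annotation, simdir / "annotation.bed")
    io.write_gff3(annotation, simdir / "annotation.gff3")
    simulate.write_ground_truth(truth, simdir / "ground_truth.tsv")
    with open(simdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
    for g in config.genotypes:
        sites = simulate.simulate_methylome(config, annotation, truth, g)
        io.write_cytosine_report(sites, simdir / f"meth_{g}.tsv")
    # expression: one wide table, feature x genotype
    counts = {}
    libs = {}
    for g in config.genotypes:
        counts[g], libs[g] = simulate.simulate_expression(config, annotation, truth, g)
    expr = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in annotation],
            "kind": [f.kind for f in annotation],
            **{g: [counts[g][f.feature_id] for f in annotation] for g in config.genotypes},
        }
    )
    expr.to_csv(simdir / "expression.tsv", sep="\t", index=False)
    _write_kv(simdir / "expression_libs.tsv", libs)
    # siRNA: long by genotype, wide by read length
    frames = []
    sirna_libs = {}
    for g in config.sirna_genotypes:
        df, sirna_libs[g] = simulate.simulate_sirna(config, annotation, truth, g)
        df.insert(1, "genotype", g)
        frames.append(df)
    pd.concat(frames).to_csv(simdir / "sirna_counts.tsv", sep="\t", index=False)
    _write_kv(simdir / "sirna_libs.tsv", sirna_libs)


def stage_dmrs(simdir: Path, dmrdir: Path, params: PipelineParams) -> None:
    dmrdir.mkdir(parents=True, exist_ok=True)
    ref_sites = io.read_cytosine_report(simdir / f"meth_{params.reference}.tsv")
    ref_windows = dmr.compute_window_methylation(
        ref_sites, params.window_size, params.min_coverage
    )
    for mutant in params.mutants:
        mut_sites = io.read_cytosine_report(simdir / f"meth_{mutant}.tsv")
        mut_windows = dmr.compute_window_methylation(
            mut_sites, params.window_size, params.min_coverage
        )
        n_tested = _n_tested(ref_windows, mut_windows, params.context_mode)
        diff = dmr.call_differential_windows(
            ref_windows, mut_windows, params.delta_min, params.alpha, params.context_mode
        )
        dmrs = dmr.merge_windows(diff, params.max_gap)
        io.write_dmrs(dmrs, dmrdir / f"dmrs_{mutant}.bed")
        with open(dmrdir / f"windows_{mutant}.json", "w") as fh:
            json.dump(
                {"n_windows_tested": n_tested, "n_differential_windows": len(diff)},
                fh, sort_keys=True,
            )


def _n_tested(windows_a, windows_b, context_mode: str) -> int:
    index_b = {(w.chrom, w.start): w for w in windows_b}
    n = 0
    for wa in windows_a:
        wb = index_b.get((wa.chrom, wa.start))
        if wb is None:
            continue
        if wa.level(context_mode) is not None and wb.level(context_mode) is not None:
            n += 1
    return n


def stage_compare(dmrdir: Path, simdir: Path, cmpdir: Path, params: PipelineParams) -> None:
    cmpdir.mkdir(parents=True, exist_ok=True)
    a_name, b_name = params.mutants[:2]
    hypo = {}
    for name in (a_name, b_name):
        hypo[name] = [
            d for d in io.read_dmrs(dmrdir / f"dmrs_{name}.bed") if d.direction == "hypo"
        ]
    part = compare.classify_overlap(hypo[a_name], hypo[b_name], params.min_overlap)
    rows = []
    for category, dmrs in [
        (f"shared_{a_name}", part.shared_a),
        (f"specific_{a_name}", part.specific_a),
        (f"shared_{b_name}", part.shared_b),
        (f"specific_{b_name}", part.specific_b),
    ]:
        for d in dmrs:
            rows.append({"category": category, "chrom": d.chrom, "start": d.start, "end": d.end})
    pd.DataFrame(rows, columns=["category", "chrom", "start", "end"]).to_csv(
        cmpdir / "partition.tsv", sep="\t", index=False
    )
    with open(dmrdir / f"windows_{a_name}.json") as fh:
        universe = json.load(fh)["n_windows_tested"]
    k = len(part.shared_b)
    K = len(hypo[a_name])
    n = len(hypo[b_name])
    p = compare.hypergeometric_upper_tail(min(k, min(K, n)), K, n, universe)
    with open(cmpdir / "enrichment.tsv", "w") as fh:
        fh.write("k\tK\tn\tN\tp\n")
        fh.write(f"{k}\t{K}\t{n}\t{universe}\t{p:.6g}\n")
    annotation = io.read_features(simdir / "annotation.bed", dialect="bed")
    comp_rows = []
    for name in (a_name, b_name):
        summary = compare.genomic_composition(hypo[name], annotation)
        for kind in io.FEATURE_KINDS:
            comp_rows.append(
                {
                    "set": name,
                    "kind": kind,
                    "count": summary.counts[kind],
                    "percentage": round(summary.percentages[kind], 4),
                }
            )
    pd.DataFrame(comp_rows).to_csv(cmpdir / "composition.tsv", sep="\t", index=False)


def stage_de(simdir: Path, dedir: Path, params: PipelineParams) -> None:
    dedir.mkdir(parents=True, exist_ok=True)
    expr = pd.read_csv(simdir / "expression.tsv", sep="\t")
    libs = _read_kv(simdir / "expression_libs.tsv")
    kind_of = dict(zip(expr["feature_id"], expr["kind"]))
    ref_counts = dict(zip(expr["feature_id"], expr[params.reference]))
    up_ids: dict[str, dict[str, set]] = {}
    for mutant in params.mutants:
        mut_counts = dict(zip(expr["feature_id"], expr[mutant]))
        records = expression.call_differential_expression(
            ref_counts, mut_counts,
            int(libs[params.reference]), int(libs[mutant]),
            params.fc_min, params.de_alpha, params.de_pseudocount,
        )
        frame = expression.records_to_frame(records)
        frame.insert(1, "kind", frame["feature_id"].map(kind_of))
        frame.to_csv(dedir / f"de_{mutant}.tsv", sep="\t", index=False, float_format="%.6g")
        up_ids[mutant] = {
            kind: {r.feature_id for r in records if r.call == "up" and kind_of[r.feature_id] == kind}
            for kind in ("TE", "gene")
        }
    a_name, b_name = params.mutants[:2]
    target_rows = []
    enrich_rows = []
    for kind in ("TE", "gene"):
        part = expression.partition_targets(up_ids[a_name][kind], up_ids[b_name][kind])
        for category, ids in [
            ("common", part.common),
            (f"specific_{a_name}", part.specific_a),
            (f"specific_{b_name}", part.specific_b),
        ]:
            for fid in ids:
                target_rows.append({"kind": kind, "category": category, "feature_id": fid})
        universe = int((expr["kind"] == kind).sum())
        p = expression.set_enrichment(
            len(part.common), len(up_ids[a_name][kind]), len(up_ids[b_name][kind]), universe
        )
        enrich_rows.append(
            {
                "kind": kind,
                "k": len(part.common),
                "K": len(up_ids[a_name][kind]),
                "n": len(up_ids[b_name][kind]),
                "N": universe,
                "p": f"{p:.6g}",
            }
        )
    pd.DataFrame(target_rows, columns=["kind", "category", "feature_id"]).to_csv(
        dedir / "targets.tsv", sep="\t", index=False
    )
    pd.DataFrame(enrich_rows).to_csv(dedir / "de_enrichment.tsv", sep="\t", index=False)


def stage_feature_meth(simdir: Path, dedir: Path, methdir: Path, params: PipelineParams) -> None:
    methdir.mkdir(parents=True, exist_ok=True)
    annotation = io.read_features(simdir / "annotation.bed", dialect="bed")
    with open(simdir / "config.json") as fh:
        chrom_len = json.load(fh)["chromosome_length"]
    tes = [f for f in annotation if f.kind == "TE"]
    genes = [f for f in annotation if f.kind == "gene"]
    promoters = [features.promoter_region(g, params.promoter_len, chrom_len) for g in genes]
    genotypes = (params.reference,) + tuple(params.mutants)
    te_levels = {}
    prom_levels = {}
    long_rows = []
    for g in genotypes:
        sites = io.read_cytosine_report(simdir / f"meth_{g}.tsv")
        te_levels[g] = features.feature_methylation_table(
            sites, tes, params.min_coverage, genotype=g
        )
        prom_levels[g] = features.feature_methylation_table(
            sites, promoters, params.min_coverage, genotype=g
        )
        for span, table in (("TE_body", te_levels[g]), ("promoter", prom_levels[g])):
            for fid, fm in table.items():
                for context in io.CONTEXTS + ("total",):
                    lv = fm.level(context)
                    long_rows.append(
                        {
                            "feature_id": fid, "span": span, "genotype": g,
                            "context": context,
                            "level": "NA" if lv is None else f"{lv:.6g}",
                        }
                    )
    pd.DataFrame(long_rows).to_csv(methdir / "feature_methylation.tsv", sep="\t", index=False)

    # methylation classes in the reference genotype
    ref = params.reference
    te_class = features.filter_methylated_features(
        {fid: fm.level("total") for fid, fm in te_levels[ref].items()},
        "TE", params.te_threshold,
    )
    prom_class = features.filter_methylated_features(
        {fid: fm.level("total") for fid, fm in prom_levels[ref].items()},
        "gene-promoter", params.gene_threshold,
    )
    with open(methdir / "methylation_classes.tsv", "w") as fh:
        fh.write("feature_id\tspan\tclass\n")
        for fid in sorted(te_class):
            fh.write(f"{fid}\tTE_body\tmethylated\n")
        for fid in sorted(prom_class):
            fh.write(f"{fid}\tpromoter\tmethylated\n")

    delta = features.methylation_delta_table(te_levels, ref)
    delta.to_csv(methdir / "te_deltas.tsv", sep="\t", index=False, float_format="%.6g")

    # methylation change at transcriptionally up-regulated TEs, per mutant
    targets = pd.read_csv(dedir / "targets.tsv", sep="\t")
    up_te = {
        m: set(
            targets[
                (targets["kind"] == "TE")
                & targets["category"].isin(["common", f"specific_{m}"])
            ]["feature_id"]
        )
        for m in params.mutants
    }
    rows = []
    for m in params.mutants:
        sub = delta[
            (delta["genotype"] == m)
            & (delta["context"] == "total")
            & delta["feature_id"].isin(up_te[m])
        ]
        vals = sub["delta"].dropna()
        wt_vals = sub["ref_level"].dropna()
        mut_vals = sub["level"].dropna()
        if len(wt_vals) >= 2 and len(mut_vals) >= 2:
            test = features.group_ttest(wt_vals, mut_vals)
            t_str, p_str, stars = f"{test.t:.6g}", f"{test.p:.6g}", test.stars
        else:
            t_str = p_str = stars = "NA"
        rows.append(
            {
                "class": f"up_TE_{m}", "genotype": m, "n": len(vals),
                "median_delta": f"{vals.median():.6g}" if len(vals) else "NA",
                "t": t_str, "p": p_str, "stars": stars,
            }
        )
    pd.DataFrame(rows).to_csv(methdir / "up_te_methylation.tsv", sep="\t", index=False)


def stage_sirna(simdir: Path, sirnadir: Path, params: PipelineParams) -> None:
    sirnadir.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(simdir / "sirna_counts.tsv", sep="\t")
    libs = _read_kv(simdir / "sirna_libs.tsv")
    counts_24 = {}
    for g, grp in counts.groupby("genotype"):
        counts_24[g] = {
            row["feature_id"]: sirna.count_24nt_reads(row, row["feature_id"])
            for _, row in grp.iterrows()
        }
    profiles = sirna.profile_features(
        counts_24, {g: int(v) for g, v in libs.items()},
        wt=params.reference,
        pseudocount=params.sirna_pseudocount,
        cutoff=params.sirna_cutoff,
        min_wt_rptm=params.min_wt_rptm,
    )
    sirna.profiles_to_frame(profiles).to_csv(
        sirnadir / "sirna_profile.tsv", sep="\t", index=False, float_format="%.6g"
    )


def stage_summary(outdir: Path, params: PipelineParams) -> None:
    a_name, b_name = params.mutants[:2]
    lines: list[tuple[str, str]] = []
    for m in params.mutants:
        dmrs = io.read_dmrs(outdir / "dmr" / f"dmrs_{m}.bed")
        lines.append((f"n_hypo_dmrs_{m}", str(sum(d.direction == "hypo" for d in dmrs))))
        lines.append((f"n_hyper_dmrs_{m}", str(sum(d.direction == "hyper" for d in dmrs))))
    part = pd.read_csv(outdir / "compare" / "partition.tsv", sep="\t")
    lines.append(
        (f"n_shared_hypo_{b_name}", str((part["category"] == f"shared_{b_name}").sum()))
    )
    enrich = pd.read_csv(outdir / "compare" / "enrichment.tsv", sep="\t")
    lines.append(("dmr_overlap_p", f"{float(enrich['p'].iloc[0]):.6g}"))
    targets = pd.read_csv(outdir / "de" / "targets.tsv", sep="\t")
    for m in params.mutants:
        for kind in ("TE", "gene"):
            n = (
                (targets["kind"] == kind)
                & targets["category"].isin(["common", f"specific_{m}"])
            ).sum()
            lines.append((f"n_up_{kind}_{m}", str(n)))
    for kind in ("TE", "gene"):
        n = ((targets["kind"] == kind) & (targets["category"] == "common")).sum()
        lines.append((f"n_up_{kind}_common", str(n)))
    classes = pd.read_csv(outdir / "meth" / "methylation_classes.tsv", sep="\t")
    lines.append(("n_methylated_te_bodies", str((classes["span"] == "TE_body").sum())))
    lines.append(("n_methylated_promoters", str((classes["span"] == "promoter").sum())))
    upte = pd.read_csv(outdir / "meth" / "up_te_methylation.tsv", sep="\t")
    for _, row in upte.iterrows():
        lines.append((f"median_meth_delta_{row['class']}", str(row["median_delta"])))
    prof = pd.read_csv(outdir / "sirna" / "sirna_profile.tsv", sep="\t")
    lines.append(("n_pol_iv_dependent", str((prof["pol_iv"] == "Pol IV-dependent").sum())))
    lines.append(("n_pol_v_independent", str((prof["pol_v"] == "Pol V-independent").sum())))
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in lines:
            fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------

def run_full_pipeline(
    config: simulate.SimulationConfig,
    outdir,
    params: PipelineParams | None = None,
) -> dict:
    """Run every stage under ``outdir`` and write summary.tsv + manifest.json.

    Returns the manifest dictionary. A stage failure raises
    :class:`StageError` naming the stage.
    """
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simdir = outdir / "sim"
    stages = [
        ("simulate", lambda: stage_simulate(config, simdir)),
        ("dmr_calling", lambda: stage_dmrs(simdir, outdir / "dmr", params)),
        ("dmr_comparison", lambda: stage_compare(outdir / "dmr", simdir, outdir / "compare", params)),
        ("expression", lambda: stage_de(simdir, outdir / "de", params)),
        ("feature_methylation", lambda: stage_feature_meth(simdir, outdir / "de", outdir / "meth", params)),
        ("sirna", lambda: stage_sirna(simdir, outdir / "sirna", params)),
        ("summary", lambda: stage_summary(outdir, params)),
    ]
    runtimes = {}
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(name, exc) from exc
        runtimes[name] = round(time.perf_counter() - t0, 3)
    manifest = {
        "tool": "methsilence 0.1.0",
        "seed": config.seed,
        "config": config.to_dict(),
        "params": asdict(params),
        "stage_runtimes_s": runtimes,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def evaluate_against_truth(outdir, truth_path=None, params: PipelineParams | None = None) -> dict:
    """Recovery metrics of a (simulated) run against its planted ground truth.

    DMR sensitivity/precision use the strict >``min_overlap``-bp rule; DE and
    siRNA metrics are per-feature. Undefined ratios (empty call sets) are
    reported as NaN.
    """
    params = params or PipelineParams()
    outdir = Path(outdir)
    truth = simulate.read_ground_truth(truth_path or outdir / "sim" / "ground_truth.tsv")
    metrics: dict[str, float] = {}
    for m in params.mutants:
        calls = [
            d for d in io.read_dmrs(outdir / "dmr" / f"dmrs_{m}.bed") if d.direction == "hypo"
        ]
        planted = truth.dmrs_for(m)
        sens, prec = interval_recovery(calls, planted, params.min_overlap)
        metrics[f"dmr_sensitivity_{m}"] = sens
        metrics[f"dmr_precision_{m}"] = prec
        de = pd.read_csv(outdir / "de" / f"de_{m}.tsv", sep="\t")
        called_up = set(de[de["call"] == "up"]["feature_id"])
        planted_up = set(truth.up_features.get(m, {}))
        null_ids = set(de["feature_id"]) - planted_up
        metrics[f"de_sensitivity_{m}"] = (
            len(called_up & planted_up) / len(planted_up) if planted_up else float("nan")
        )
        metrics[f"de_false_positive_rate_{m}"] = (
            len(called_up - planted_up) / len(null_ids) if null_ids else float("nan")
        )
    prof = pd.read_csv(outdir / "sirna" / "sirna_profile.tsv", sep="\t")
    correct = total = 0
    for _, row in prof.iterrows():
        true_iv, true_v = truth.sirna_labels[row["feature_id"]]
        want_iv = "Pol IV-dependent" if true_iv else "Pol IV-independent"
        want_v = "Pol V-dependent" if true_v else "Pol V-independent"
        total += 1
        if row["pol_iv"] == want_iv and row["pol_v"] == want_v:
            correct += 1
    metrics["sirna_label_accuracy"] = correct / total if total else float("nan")
    with open(outdir / "evaluation.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k in sorted(metrics):
            fh.write(f"{k}\t{metrics[k]:.6g}\n")
    return metrics


def interval_recovery(calls, planted, min_overlap: int = 50) -> tuple[float, float]:
    """(sensitivity, precision) of called intervals against planted ones at
    the strict >min_overlap-bp rule; NaN where the denominator is empty."""
    part = compare.classify_overlap(calls, planted, min_overlap)
    sens = len(part.shared_b) / len(planted) if planted else float("nan")
    prec = len(part.shared_a) / len(calls) if calls else float("nan")
    return sens, prec


def _write_kv(path, mapping) -> None:
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k in sorted(mapping):
            fh.write(f"{k}\t{mapping[k]}\n")


def _read_kv(path) -> dict:
    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            k, v = line.rstrip("\n").split("\t")
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
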