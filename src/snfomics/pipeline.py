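"""End-to-end orchestration: discovery cohort in, fused groups, signatures,
posttranscriptional statistics, enrichment, deconvolution and clinical
associations out, with a JSON manifest recording inputs, parameters, seed,
software version and per-stage wall time so any stage can be re-run in
isolation.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import SurvivalTable, categorical_association, km_curves, logrank_test
from .deconvolution import compare_fractions, estimate_fractions
from .enrichment import preranked_gsea, rank_features, ssgsea_score
from .groups import build_signature, differential_features, extend_groups_hcl
from .io import (
    align_cohort,
    read_clinical_table,
    read_gmt,
    read_omic_matrix,
    read_signature_matrix,
    write_clinical_table,
    write_omic_matrix,
)
from .preprocess import match_pairs
from .ratios import group_ratio, pair_correlations, ratio_shift_test
from .snf import SNFParams, build_affinity, estimate_num_clusters, export_network, fuse_networks, spectral_cluster
from .synthetic import CohortConfig, simulate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage, partial outputs remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Either ``synthetic`` (a :class:`CohortConfig`) or ``inputs`` (paths to
    mrna/protein[/methylation]/clinical[/signature][/genesets] files) must
    be provided. ``layers`` selects which layers enter the fusion.
    """

    synthetic: CohortConfig | None = None
    inputs: dict = field(default_factory=dict)
    layers: tuple[str, ...] = ("mrna", "protein")
    snf: SNFParams = field(default_factory=SNFParams)
    k: int | None = None  # None = eigengap selection
    k_max: int = 6
    p_thresh: float = 0.05
    fc_thresh: float = 2.0
    n_per_direction: int = 50
    gsea_permutations: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = CohortConfig(**(raw["synthetic"] or {}))
        if "inputs" in raw:
            kwargs["inputs"] = raw["inputs"]
        if "snf" in raw:
            kwargs["snf"] = SNFParams(**raw["snf"])
        for key in ("layers", "k", "k_max", "p_thresh", "fc_thresh", "n_per_direction", "gsea_permutations", "seed"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "layers" else raw[key]
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full workflow and return the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "layers": list(config.layers),
            "snf": asdict(config.snf),
            "k": config.k,
            "p_thresh": config.p_thresh,
            "fc_thresh": config.fc_thresh,
            "n_per_direction": config.n_per_direction,
        },
        "stages": [],
    }
    if config.synthetic is not None:
        manifest["parameters"]["synthetic"] = asdict(config.synthetic)
    else:
        manifest["parameters"]["inputs"] = dict(config.inputs)

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.record = {"name": name, "outputs": [], "counts": {}}
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                self_inner.record["wall_seconds"] = round(time.perf_counter() - self_inner.t0, 4)
                manifest["stages"].append(self_inner.record)
                _write_manifest()
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

            def out(self_inner, path: Path):
                self_inner.record["outputs"].append(str(path.relative_to(outdir)))

            def count(self_inner, key: str, value):
                self_inner.record["counts"][key] = int(value)

        return _Stage()

    def _write_manifest():
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)

    # ---- load or simulate -------------------------------------------------
    signature_matrix = None
    genesets = None
    with stage("load") as st:
        if config.synthetic is not None:
            cohort = simulate_cohort(config.synthetic, seed=config.seed)
            unknown = [name for name in config.layers if name not in cohort.layers]
            if unknown:
                raise ValueError(f"unknown layer(s): {', '.join(unknown)}")
            layers = {k: v for k, v in cohort.layers.items() if k in config.layers}
            clinical = cohort.clinical
            signature_matrix = cohort.signature
        else:
            layers = {}
            for name in config.layers:
                if name not in config.inputs:
                    raise ValueError(f"no input path for layer '{name}'")
                layers[name] = read_omic_matrix(config.inputs[name], name, is_log=name != "methylation")
            clinical = read_clinical_table(config.inputs["clinical"]) if "clinical" in config.inputs else None
            if "signature" in config.inputs:
                signature_matrix = read_signature_matrix(config.inputs["signature"])
            if "genesets" in config.inputs:
                genesets = read_gmt(config.inputs["genesets"])
        for name, m in layers.items():
            st.count(f"n_features_{name}", m.n_features)

    # ---- align ------------------------------------------------------------
    with stage("align") as st:
        ordered = [layers[name] for name in config.layers]
        aligned, clinical = align_cohort(ordered, clinical)
        layers = dict(zip(config.layers, aligned))
        st.count("n_samples", aligned[0].n_samples)

    sample_ids = layers[config.layers[0]].sample_ids

    # ---- fusion and clustering -------------------------------------------
    with stage("fuse") as st:
        affinities = [build_affinity(layers[name], config.snf) for name in config.layers]
        fusion = fuse_networks(affinities, config.snf)
        np.savetxt(outdir / "fused_similarity.tsv", fusion.fused, delimiter="\t")
        st.out(outdir / "fused_similarity.tsv")

    with stage("cluster") as st:
        best_k, gaps = estimate_num_clusters(fusion.fused, k_max=min(config.k_max, len(sample_ids) - 1))
        k = config.k or best_k
        raw_labels = spectral_cluster(fusion.fused, k=k, seed=config.seed)
        labels = pd.Series([f"group{i + 1}" for i in raw_labels], index=sample_ids, name="group")
        labels.rename_axis("sample_id").to_csv(outdir / "labels.tsv", sep="\t")
        pd.DataFrame({"k": np.arange(2, 2 + len(gaps)), "eigengap": gaps}).to_csv(outdir / "eigengaps.tsv", sep="\t", index=False)
        edges = export_network(fusion.fused, sample_ids, outdir / "network_edges.tsv")
        for p in ("labels.tsv", "eigengaps.tsv", "network_edges.tsv"):
            st.out(outdir / p)
        st.count("best_k", best_k)
        st.count("k_used", k)
        st.count("n_edges", len(edges))

    # ---- differential signatures ------------------------------------------
    signatures = {}
    with stage("signatures") as st:
        for name in config.layers:
            if name == "methylation":
                continue
            table = differential_features(layers[name], labels, config.p_thresh, config.fc_thresh)
            table.to_csv(outdir / f"differential_{name}.tsv", sep="\t", index=False)
            st.out(outdir / f"differential_{name}.tsv")
            sig = build_signature(table, config.n_per_direction, layer=name)
            signatures[name] = sig
            rows = [(f, "up") for f in sig.up_features] + [(f, "down") for f in sig.down_features]
            pd.DataFrame(rows, columns=["feature_id", "direction"]).to_csv(outdir / f"signature_{name}.tsv", sep="\t", index=False)
            st.out(outdir / f"signature_{name}.tsv")
            st.count(f"n_significant_{name}", table["significant"].sum())

    # ---- group extension ---------------------------------------------------
    with stage("extend") as st:
        name = config.layers[0]
        if signatures[name].features:
            extended = extend_groups_hcl(layers[name], signatures[name], labels)
            extended.rename_axis("sample_id").to_csv(outdir / "extended_labels.tsv", sep="\t")
            st.out(outdir / "extended_labels.tsv")
            st.count("n_labelled", len(extended))
        else:
            # degenerate input: nothing significant to extend with
            st.record["skipped"] = "empty signature"
            st.count("n_labelled", 0)

    # ---- posttranscriptional ----------------------------------------------
    if "mrna" in layers and "protein" in layers:
        with stage("posttranscriptional") as st:
            pairs = match_pairs(layers["mrna"], layers["protein"])
            corr, median_r = pair_correlations(pairs)
            corr.to_csv(outdir / "pair_correlations.tsv", sep="\t", index=False)
            ratios = group_ratio(pairs, labels)
            ratios.per_pair.to_csv(outdir / "group_ratios.tsv", sep="\t", index=False)
            groups = sorted(labels.unique())
            u, p = ratio_shift_test(
                ratios.per_pair[f"ratio_{groups[0]}"], ratios.per_pair[f"ratio_{groups[1]}"]
            )
            summary = {"median_pearson_r": median_r, "n_pairs": pairs.n_pairs, "ratio_shift_U": u, "ratio_shift_p": p}
            with open(outdir / "posttranscriptional_summary.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=2)
            for pth in ("pair_correlations.tsv", "group_ratios.tsv", "posttranscriptional_summary.json"):
                st.out(outdir / pth)
            st.count("n_pairs", pairs.n_pairs)

    # ---- enrichment --------------------------------------------------------
    if genesets is not None:
        with stage("gsea") as st:
            table = differential_features(layers[config.layers[0]], labels, config.p_thresh, config.fc_thresh)
            ranked = rank_features(list(table["feature_id"]), table["t"].to_numpy())
            results = preranked_gsea(
                ranked, genesets, n_permutations=config.gsea_permutations, seed=config.seed, pass_through=True
            )
            pd.DataFrame(
                [
                    {"set_name": r.set_name, "es": r.es, "nes": r.nes, "p": r.p, "q": r.q, "size": r.size}
                    for r in results
                ]
            ).to_csv(outdir / "gsea.tsv", sep="\t", index=False)
            st.out(outdir / "gsea.tsv")
            st.count("n_sets_tested", len(results))

    # ---- deconvolution -----------------------------------------------------
    if signature_matrix is not None and "mrna" in layers:
        with stage("deconvolution") as st:
            result = estimate_fractions(layers["mrna"], signature_matrix)
            result.fractions.rename_axis("sample_id").to_csv(outdir / "fractions.tsv", sep="\t")
            contrast = compare_fractions(result, labels)
            contrast.to_csv(outdir / "fraction_contrasts.tsv", sep="\t", index=False)
            # immune score: single-sample enrichment of the non-tumor marker genes
            prof = signature_matrix.profiles
            immune_types = [ct for ct in signature_matrix.cell_types if ct != "tumor"]
            immune_feats = [f for f in prof.index if prof.loc[f].idxmax() in immune_types]
            scores = ssgsea_score(layers["mrna"], immune_feats) if len(immune_feats) >= 5 else None
            if scores is not None:
                scores.rename_axis("sample_id").to_csv(outdir / "immune_scores.tsv", sep="\t")
                st.out(outdir / "immune_scores.tsv")
            for pth in ("fractions.tsv", "fraction_contrasts.tsv"):
                st.out(outdir / pth)

    # ---- clinical ----------------------------------------------------------
    if clinical is not None:
        with stage("clinical") as st:
            cdata = clinical.data.copy()
            cdata["group"] = labels.reindex(cdata["sample_id"]).to_numpy()
            groups = sorted(labels.unique())
            age1 = cdata.loc[cdata["group"] == groups[0], "age"]
            age2 = cdata.loc[cdata["group"] == groups[1], "age"]
            age_u, age_p = ratio_shift_test(age1, age2)
            loc_counts = pd.crosstab(cdata["group"], cdata["location"])
            report = {
                "age_means": {groups[0]: float(age1.mean()), groups[1]: float(age2.mean())},
                "age_mannwhitney_p": age_p,
            }
            if loc_counts.shape == (2, 2) or (loc_counts.shape[0] == 2 and loc_counts.shape[1] >= 2):
                stat, p, method = categorical_association(loc_counts.to_numpy())
                report["location_test"] = {"statistic": stat, "p": p, "method": method}
            surv = SurvivalTable(pd.DataFrame({"time": cdata["pfs_time"], "event": cdata["pfs_event"], "group": cdata["group"]}))
            if surv.data["event"].sum() > 0:
                chi2, p = logrank_test(surv)
                report["logrank"] = {"chi2": chi2, "p": p}
                curves = km_curves(surv)
                for g, df in curves.items():
                    df.to_csv(outdir / f"km_{g}.tsv", sep="\t", index=False)
                    st.out(outdir / f"km_{g}.tsv")
            with open(outdir / "clinical_report.json", "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2)
            st.out(outdir / "clinical_report.json")
            write_clinical_table(clinical, outdir / "clinical.tsv")
            st.out(outdir / "clinical.tsv")

    _write_manifest()
    return outdir
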