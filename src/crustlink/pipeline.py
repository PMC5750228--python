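"""End-to-end pipeline: simulate → filter → classify → match → correlate.

``run_pipeline`` drives a complete analysis from a wet-up scenario (or a
directory of previously written input tables): sample QC, the two-fold
dynamic-range filter, the killed-control significance filter, isolate
spent-media classification, marker-based isolate↔taxon matching,
relative-abundance estimation, pooled Spearman correlations with BH-FDR,
the exact binomial directionality test, and the foodweb edge table. All
intermediate artifacts are written as tab-separated text plus a JSON
summary and a provenance record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import concord, exoprofile, io, metabolome, taxa
from .scenario import WetupScenario, default_scenario
from .simulate import SimulatedDataset, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, significance levels and paths for one pipeline run."""

    scenario: WetupScenario | None = None
    scenario_file: str | None = None
    input_dir: str | None = None
    outdir: str | None = None
    seed: int | None = None
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    rho_threshold: float = 0.5
    fold_range_threshold: float = 2.0
    fc_consumed: float = 0.5
    fc_released: float = 2.0
    per_stage: bool = False
    tukey: bool = True
    cluster_k: int = 3

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_alpha", "rho_threshold",
                     "fold_range_threshold", "fc_consumed", "fc_released"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def resolve_scenario(self) -> WetupScenario:
        if self.scenario is not None:
            scn = self.scenario
        elif self.scenario_file is not None:
            scn = WetupScenario.from_yaml(self.scenario_file)
        else:
            scn = default_scenario()
        if self.seed is not None:
            scn = WetupScenario.from_dict({**scn.to_dict(), "seed": self.seed})
        return scn


@dataclass
class InputBundle:
    """The analysis-facing inputs, independent of their origin."""

    active: metabolome.PeakAreaTable
    killed: metabolome.PeakAreaTable
    spent_media: pd.DataFrame
    env_markers: dict[str, str]
    isolate_markers: dict[str, str]
    marker_catalog: dict[str, pd.DataFrame]
    expected_sign: dict[tuple[str, str], int] = field(default_factory=dict)

    @classmethod
    def from_dataset(cls, data: SimulatedDataset) -> "InputBundle":
        return cls(
            active=data.active,
            killed=data.killed,
            spent_media=data.spent_media,
            env_markers=data.env_markers,
            isolate_markers=data.isolate_markers,
            marker_catalog=data.marker_catalog,
            expected_sign=data.expected_sign,
        )


def analyze(inputs: InputBundle, cfg: RunConfig) -> dict:
    """Run the analysis stages on an input bundle.

    Returns a dict of all result tables plus the concordance summary.
    Raises when the spent-media and soil-water metabolite vocabularies
    do not overlap (listing the offending labels).
    """
    active = metabolome.qc_filter(inputs.active)
    killed = metabolome.qc_filter(inputs.killed)

    peak_mets = set(active.metabolites)
    exo_mets = set(inputs.spent_media["metabolite_id"])
    if not peak_mets & exo_mets:
        raise ValueError(
            "no overlap between soil-water and spent-media metabolites; "
            f"soil-water: {sorted(peak_mets)}; spent-media: {sorted(exo_mets)}"
        )

    retained, unevaluable = metabolome.fold_range_filter(
        active, cfg.fold_range_threshold
    )
    logger.info("fold-range filter: %d retained, %d unevaluable, %d excluded",
                len(retained), len(unevaluable),
                len(active.metabolites) - len(retained) - len(unevaluable))
    verdicts, tukey_table = metabolome.killed_control_test(
        active.subset_metabolites(retained), killed,
        alpha=cfg.alpha, tukey=cfg.tukey,
    )
    bc = metabolome.biologically_controlled(verdicts)

    profiles = exoprofile.build_profiles(
        inputs.spent_media, cfg.fc_consumed, cfg.fc_released
    )
    matches = taxa.match_isolates(inputs.isolate_markers, inputs.env_markers)
    iso_to_taxon = dict(
        matches[matches["is_best"]][["isolate_id", "taxon_id"]].itertuples(
            index=False
        )
    )
    predictions = exoprofile.predict_signs(profiles, iso_to_taxon)
    predictions = predictions[predictions["metabolite_id"].isin(bc)]
    logger.info("%d sign predictions on biologically controlled metabolites",
                len(predictions))

    family = taxa.select_marker_family(
        taxa.catalog_gene_counts(inputs.marker_catalog)
    )
    abundance = taxa.relative_abundance(inputs.marker_catalog[family])

    matched_taxa = sorted(set(predictions["taxon_id"]))
    correlations = concord.correlate_pairs(
        active, abundance,
        taxa=matched_taxa or None,
        metabolites=[m for m in bc if m in peak_mets],
        rho_threshold=cfg.rho_threshold,
        per_stage=cfg.per_stage,
    )
    summary, records = concord.evaluate_concordance(correlations, predictions)
    edges = concord.build_foodweb(records)

    normalized = metabolome.row_normalize(
        active.subset_metabolites(retained).cell_means()
    )
    clusters, leaf_order = metabolome.cluster_metabolites(
        normalized, k=min(cfg.cluster_k, len(retained))
    )
    scores, explained = metabolome.pca_ordinate(active)

    results = {
        "active": active,
        "killed": killed,
        "retained": retained,
        "unevaluable": unevaluable,
        "verdicts": verdicts,
        "tukey": tukey_table,
        "biologically_controlled": bc,
        "profiles": profiles,
        "matches": matches,
        "isolate_to_taxon": iso_to_taxon,
        "marker_family": family,
        "abundance": abundance,
        "predictions": predictions,
        "correlations": correlations,
        "summary": summary,
        "records": records,
        "foodweb": edges,
        "normalized": normalized,
        "clusters": clusters,
        "leaf_order": leaf_order,
        "pca_scores": scores,
        "pca_explained": explained,
    }
    if inputs.expected_sign:
        results["recovery"] = ground_truth_recovery(
            records, inputs.expected_sign
        )
    return results


def ground_truth_recovery(
    records: pd.DataFrame, expected_sign: dict[tuple[str, str], int]
) -> dict:
    """End-to-end recovery of the generator's signed pairs.

    A ground-truth pair (expected sign != 0) counts as recovered iff the
    pipeline evaluated it (classified, matched, retained) and the
    observed correlation sign equals the true sign.
    """
    truth = {k: v for k, v in expected_sign.items() if v != 0}
    by_pair = {
        (r.taxon_id, r.metabolite_id): r for r in records.itertuples(index=False)
    }
    n_recovered = 0
    for pair, sign in truth.items():
        rec = by_pair.get(pair)
        if rec is not None and rec.evaluable and rec.observed_sign == sign:
            n_recovered += 1
    n_truth = len(truth)
    return {
        "n_true_signed_pairs": n_truth,
        "n_recovered": n_recovered,
        "recovery": n_recovered / n_truth if n_truth else float("nan"),
    }


def write_dataset(data: SimulatedDataset, outdir) -> None:
    """Write a simulated study to disk as text tables + FASTA."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_peak_table(data.active, out / "active_areas.tsv",
                        out / "active_meta.tsv")
    io.write_peak_table(data.killed, out / "killed_areas.tsv",
                        out / "killed_meta.tsv")
    io.write_group_matrix(data.true_abundance, out / "true_abundance.tsv")
    io.write_group_matrix(data.true_pools_active, out / "true_pools_active.tsv")
    io.write_group_matrix(data.true_pools_killed, out / "true_pools_killed.tsv")
    for fam, counts in data.marker_catalog.items():
        io.write_group_matrix(counts, out / f"marker_counts_{fam}.tsv")
    io.write_fasta(data.env_markers, out / "markers_environment.fasta")
    io.write_fasta(data.isolate_markers, out / "markers_isolates.fasta")
    io.write_tsv(data.spent_media, out / "spent_media.tsv", index=False)
    truth = pd.DataFrame(
        [(t, m, s) for (t, m), s in data.expected_sign.items()],
        columns=["taxon_id", "metabolite_id", "expected_sign"],
    )
    io.write_tsv(truth, out / "ground_truth_signs.tsv", index=False)
    data.scenario.to_yaml(out / "scenario.yaml")


def read_inputs(indir) -> InputBundle:
    """Re-load analysis inputs from a directory written by
    :func:`write_dataset` (or assembled by hand in the same layout)."""
    ind = Path(indir)
    active = io.read_peak_table(ind / "active_areas.tsv", ind / "active_meta.tsv")
    killed = io.read_peak_table(ind / "killed_areas.tsv", ind / "killed_meta.tsv")
    catalog = {
        p.stem.replace("marker_counts_", ""): io.read_group_matrix(p)
        for p in sorted(ind.glob("marker_counts_*.tsv"))
    }
    expected = {}
    truth_path = ind / "ground_truth_signs.tsv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t")
        expected = {
            (r.taxon_id, r.metabolite_id): int(r.expected_sign)
            for r in tdf.itertuples(index=False)
        }
    return InputBundle(
        active=active,
        killed=killed,
        spent_media=pd.read_csv(ind / "spent_media.tsv", sep="\t"),
        env_markers=io.read_fasta(ind / "markers_environment.fasta"),
        isolate_markers=io.read_fasta(ind / "markers_isolates.fasta"),
        marker_catalog=catalog,
        expected_sign=expected,
    )


def summary_payload(results: dict) -> dict:
    """JSON-serializable run summary."""
    s = results["summary"]
    payload = {
        "n_evaluated": s.n_evaluated,
        "n_concordant": s.n_concordant,
        "proportion_concordant": round(s.proportion, 6),
        "p_binomial": round(s.p_binomial, 6),
        "per_class": s.per_class.assign(
            proportion=s.per_class["proportion"].round(6)
        ).to_dict(orient="records"),
        "n_retained_fold_range": len(results["retained"]),
        "n_biologically_controlled": len(results["biologically_controlled"]),
        "n_predictions": int(len(results["predictions"])),
        "marker_family": results["marker_family"],
        "pca_explained_pc1": round(float(results["pca_explained"][0]), 6),
    }
    if "recovery" in results:
        payload["recovery"] = {
            **results["recovery"],
            "recovery": round(results["recovery"]["recovery"], 6),
        }
    return payload


def write_results(results: dict, cfg: RunConfig, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_tsv(results["verdicts"], out / "killed_control_verdicts.tsv")
    if results["tukey"] is not None:
        io.write_tsv(results["tukey"], out / "tukey_hsd.tsv", index=False)
    io.write_tsv(pd.Series(results["retained"], name="metabolite_id").to_frame(),
                 out / "fold_range_retained.tsv", index=False)
    io.write_tsv(results["profiles"], out / "exo_profiles.tsv", index=False)
    io.write_tsv(results["matches"], out / "isolate_matches.tsv", index=False)
    io.write_group_matrix(results["abundance"], out / "relative_abundance.tsv")
    io.write_tsv(results["predictions"], out / "predictions.tsv", index=False)
    io.write_tsv(results["correlations"], out / "correlations.tsv", index=False)
    io.write_tsv(results["records"], out / "concordance_records.tsv", index=False)
    io.write_tsv(results["foodweb"], out / "foodweb_edges.tsv", index=False)
    io.write_group_matrix(results["normalized"], out / "normalized_profiles.tsv")
    io.write_tsv(results["clusters"].to_frame(), out / "metabolite_clusters.tsv")
    io.write_tsv(results["pca_scores"], out / "pca_scores.tsv")
    import networkx as nx

    nx.write_graphml(concord.foodweb_graph(results["foodweb"]),
                     out / "foodweb.graphml")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_payload(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def provenance(cfg: RunConfig, scenario: WetupScenario | None) -> dict:
    import crustlink

    d = asdict(cfg)
    d.pop("scenario", None)
    return {
        "crustlink_version": crustlink.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": d,
        "seed": scenario.seed if scenario is not None else cfg.seed,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and (optionally) write all artifacts.

    With ``cfg.input_dir`` set, previously written tables are re-analyzed;
    otherwise a synthetic study is generated from the scenario.
    """
    scenario = None
    if cfg.input_dir is not None:
        inputs = read_inputs(cfg.input_dir)
    else:
        scenario = cfg.resolve_scenario()
        data = simulate_dataset(scenario)
        inputs = InputBundle.from_dataset(data)
        if cfg.outdir is not None:
            write_dataset(data, Path(cfg.outdir) / "dataset")
    results = analyze(inputs, cfg)
    if cfg.outdir is not None:
        write_results(results, cfg, cfg.outdir)
        with open(Path(cfg.outdir) / "provenance.json", "w") as fh:
            json.dump(provenance(cfg, scenario), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return results
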