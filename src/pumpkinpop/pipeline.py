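"""End-to-end orchestration: QC -> diversity -> structure -> panel reports.

Reports are plain TSV/Newick/JSON with the seed recorded in a run manifest;
timestamps appear only in log lines so reruns with the same config and seeds
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import panel as ppanel
from . import popgen, qc, structure
from .datamodel import GenotypeMatrix, MarkerRecord, PopulationMap, ValidationError

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage where it occurred."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genotype_path: str | None = None        # VCF (.vcf) or genotype table
    marker_path: str | None = None          # marker metadata TSV (table input only)
    population_path: str | None = None
    output_dir: str = "pumpkinpop_out"
    filter_criteria: qc.FilterCriteria = field(default_factory=qc.FilterCriteria)
    sample_call_rate_min: float = 0.65
    panel_spec: ppanel.PanelSpec = field(default_factory=ppanel.PanelSpec)
    n_permutations: int = 10_000
    n_clusters: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "filter_criteria" in kwargs:
            kwargs["filter_criteria"] = qc.FilterCriteria(**kwargs["filter_criteria"])
        if "panel_spec" in kwargs:
            kwargs["panel_spec"] = ppanel.PanelSpec(**kwargs["panel_spec"])
        return cls(**kwargs)


def load_inputs(
    config: PipelineConfig,
) -> tuple[GenotypeMatrix, list[MarkerRecord], PopulationMap | None]:
    if config.genotype_path is None:
        raise ValidationError("no genotype input configured")
    path = Path(config.genotype_path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        matrix, markers = pio.read_vcf(path)
    else:
        if config.marker_path is None:
            raise ValidationError("genotype tables need a marker metadata file")
        markers = pio.read_marker_table(config.marker_path)
        dialect = pio.AllelePairDialect({m.marker_id: m for m in markers})
        matrix = pio.read_genotype_table(path, dialect)
    popmap = (
        pio.read_population_file(config.population_path)
        if config.population_path
        else None
    )
    return matrix, markers, popmap


def run_full_analysis(
    config: PipelineConfig,
    matrix: GenotypeMatrix | None = None,
    markers: list[MarkerRecord] | None = None,
    popmap: PopulationMap | None = None,
) -> dict[str, object]:
    """Run QC, diversity, structure and panel stages; write all reports.

    Inputs may be passed directly (e.g. from the simulator) or loaded from
    the paths in ``config``. Returns a dict of the in-memory results.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    counts: dict[str, int] = {}

    if matrix is None:
        try:
            matrix, markers, popmap = load_inputs(config)
        except Exception as e:
            raise StageError("load", e) from e
    assert markers is not None
    counts["accessions_in"] = matrix.n_accessions
    counts["markers_in"] = matrix.n_markers

    # --- QC
    try:
        matrix, excluded = qc.filter_samples_by_call_rate(
            matrix, config.sample_call_rate_min
        )
        counts["accessions_excluded"] = len(excluded)
        filtered, report = qc.filter_markers(matrix, config.filter_criteria)
        counts["markers_kept"] = filtered.n_markers
        counts["markers_dropped"] = matrix.n_markers - filtered.n_markers
        logger.info(
            "qc: %d/%d markers kept, %d accessions excluded",
            filtered.n_markers, matrix.n_markers, len(excluded),
        )
        report.to_csv(out / "qc_markers.tsv", sep="\t")
        pd.DataFrame(excluded, columns=["accession_id", "call_rate"]).to_csv(
            out / "qc_excluded_accessions.tsv", sep="\t", index=False
        )
        marker_map = {m.marker_id: m for m in markers}
        kept_markers = [marker_map[m] for m in filtered.marker_ids]
        stats = qc.marker_stats(filtered)
        freqs = popgen.allele_frequencies(filtered)
        pic_all = popgen.pic_biallelic(freqs.p_alt)
        for j, m in enumerate(kept_markers):
            m.maf = float(stats["maf"].iloc[j])
            m.missing_rate = float(stats["missing_rate"].iloc[j])
            m.pic = float(pic_all[j])
        pio.write_marker_table(out / "markers.tsv", kept_markers)
        qc.substitution_summary(kept_markers).to_csv(
            out / "substitution_types.tsv", sep="\t", index=False
        )
        matrix = filtered
        results["matrix"] = matrix
        results["markers"] = kept_markers
    except StageError:
        raise
    except Exception as e:
        raise StageError("qc", e) from e

    # --- diversity & differentiation
    if popmap is not None:
        try:
            diversity = popgen.diversity_summary(matrix, popmap)
            popgen.diversity_table(diversity).to_csv(
                out / "diversity.tsv", sep="\t", index=False, float_format="%.4f"
            )
            results["diversity"] = diversity
            if config.n_permutations == 0:
                logger.warning("permutations=0: differentiation table has no p-values")
            pairwise = popgen.fst_permutation_test(
                matrix, popmap, n_permutations=config.n_permutations, seed=config.seed
            )
            popgen.differentiation_table(pairwise).to_csv(
                out / "differentiation.tsv", sep="\t"
            )
            results["pairwise"] = pairwise
        except Exception as e:
            raise StageError("diversity", e) from e

    # --- structure
    try:
        encoded = structure.encode_genotypes(matrix)
        pca_res = structure.pca(encoded, n_components=min(10, matrix.n_accessions - 1,
                                                          matrix.n_markers))
        scores = pd.DataFrame(
            pca_res.scores,
            index=pd.Index(pca_res.accession_ids, name="accession_id"),
            columns=[f"PC{k+1}" for k in range(pca_res.scores.shape[1])],
        )
        scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6g")
        dist = structure.euclidean_distance_matrix(encoded)
        tree = structure.upgma(dist, encoded.accession_ids)
        (out / "upgma.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
        k = min(config.n_clusters, matrix.n_accessions)
        upgma_clusters = structure.cut_clusters(tree, k)
        pca_clusters = structure.pca_cluster_assignment(pca_res, k=k, seed=config.seed)
        discordant, _ = structure.compare_clusterings(upgma_clusters, pca_clusters)
        pd.DataFrame(
            {
                "accession_id": list(upgma_clusters),
                "upgma_cluster": [upgma_clusters[a] for a in upgma_clusters],
                "pca_cluster": [pca_clusters[a] for a in upgma_clusters],
                "discordant": [a in set(discordant) for a in upgma_clusters],
            }
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        results.update(
            pca=pca_res, dendrogram=tree, upgma_clusters=upgma_clusters,
            pca_clusters=pca_clusters, discordant=discordant,
        )
        logger.info("structure: %d/%d accessions discordant between UPGMA and PCA",
                    len(discordant), matrix.n_accessions)
    except Exception as e:
        raise StageError("structure", e) from e

    # --- panel
    try:
        spec = config.panel_spec
        full_report = ppanel.distinguishability(matrix, matrix.marker_ids)
        panels = {"full": full_report}
        eligible = [m for m in results["markers"] if m.pic is not None and m.pic >= spec.pic_min]
        if eligible:
            target = min(spec.target_size, len(eligible))
            nested_sizes = [s for s in spec.nested_sizes if s <= target]
            core = ppanel.select_distributed_panel(
                results["markers"],
                ppanel.PanelSpec(spec.pic_min, target, tuple(nested_sizes),
                                 spec.chromosome_lengths),
            )
            core.identification_rate = ppanel.distinguishability(
                matrix, core.marker_ids
            ).identification_rate
            panels[f"core_{core.size}"] = core
            meta = {m.marker_id: m for m in results["markers"]}
            nested = ppanel.nest_subsets([meta[mid] for mid in core.marker_ids],
                                         nested_sizes)
            for rep in nested:
                ident = ppanel.distinguishability(matrix, rep.marker_ids)
                rep.identification_rate = ident.identification_rate
                rep.n_identified = ident.n_identified
                rep.n_total = ident.n_total
                rep.indistinguishable_groups = ident.indistinguishable_groups
                panels[f"subset_{rep.size}"] = rep
        rows = []
        for name, rep in panels.items():
            rows.append(
                {"panel": name, "size": rep.size,
                 "identification_rate": rep.identification_rate,
                 "n_identified": rep.n_identified, "n_total": rep.n_total}
            )
        pd.DataFrame(rows).to_csv(out / "panels.tsv", sep="\t", index=False,
                                  float_format="%.4f")
        membership = []
        for name, rep in panels.items():
            if name == "full":
                continue
            for mid in rep.marker_ids:
                membership.append({"panel": name, "marker_id": mid})
        pd.DataFrame(membership).to_csv(out / "panel_markers.tsv", sep="\t", index=False)
        ppanel.identification_report(full_report).to_csv(
            out / "identification_groups.tsv", sep="\t", index=False
        )
        results["panels"] = panels
    except Exception as e:
        raise StageError("panel", e) from e

    counts_path = out / "run_manifest.json"
    counts_path.write_text(
        json.dumps({"seed": config.seed, "counts": counts}, indent=2) + "\n",
        encoding="utf-8",
    )
    results["counts"] = counts
    return results
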