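"""End-to-end orchestration: attribute -> correlate -> aggregate -> mask ->
cluster -> report, from a single run configuration.

Per-protein failures (too-short sequences, degenerate annotations) are
logged and excluded rather than aborting the cohort, mirroring the
restriction of population statistics to usable annotated proteins. Stage
outputs land in separate subdirectories together with a hash of the stage
inputs, so re-running with an unchanged configuration skips finished
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations as anio
from .attribution import AttributionBundle, PathSpec, attribute_all
from .cluster import cluster_separation, embed_2d, flatten_maps
from .model import ClassScoreFn, TransformerEncoderClassifier
from .stats import (
    HeadAnnotationAnalysis,
    HeadStatMatrix,
    TestConfig,
    correlate_protein,
    summed_relevance,
)

log = logging.getLogger("headig.pipeline")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; serialized into the output."""

    checkpoint: str
    fasta: str
    annotations: str
    labels: str
    out_dir: str
    annotation_type: str = "motif"
    class_choice: str = "own_label"   # "own_label" or a class index as string
    score_kind: str = "logit"
    baseline: str = "padding_embedding"
    steps: int = 64
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        for f in (self.checkpoint, self.fasta, self.annotations, self.labels):
            p = Path(f)
            if p.exists():
                blob += hashlib.sha256(p.read_bytes()).digest()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineReport:
    out_dir: Path
    n_proteins: int
    n_attributed: int
    failures: dict[str, str] = field(default_factory=dict)
    n_joint_significant: int | None = None
    silhouette: float | None = None
    summary_path: Path | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def _write_head_map_tsv(path: Path, matrix: np.ndarray, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        cols = "\t".join(f"head{h}" for h in range(matrix.shape[1]))
        fh.write(f"layer\t{cols}\n")
        for l, row in enumerate(matrix):
            fh.write(f"{l}\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def _write_grid(path_prefix: Path, matrix: HeadStatMatrix) -> None:
    _write_head_map_tsv(path_prefix.with_suffix(".tsv"), matrix.values,
                        matrix.content_kind)
    # long-format companion
    rows = []
    for l in range(matrix.shape[0]):
        for h in range(matrix.shape[1]):
            rows.append((l, h, matrix.content_kind, matrix.values[l, h]))
    pd.DataFrame(rows, columns=["layer", "head", "statistic", "value"]).to_csv(
        path_prefix.with_name(path_prefix.name + "_long.tsv"), sep="\t", index=False
    )


def _save_bundle(path: Path, bundle: AttributionBundle) -> None:
    np.savez(
        path,
        emb_values=bundle.embedding_map.values,
        special_mask=bundle.special_mask,
        layer_values=np.stack([m.values for m in bundle.layer_maps]),
        head_values=np.stack([m.values for m in bundle.head_maps]),
        scores=np.array([bundle.embedding_map.score,
                         bundle.embedding_map.baseline_score,
                         bundle.embedding_map.completeness_gap]),
    )


def _load_bundle(path: Path, sequence_id: str, class_index: int) -> AttributionBundle:
    from .attribution import AttributionMap, HeadAttributionMap

    with np.load(path) as z:
        mask = z["special_mask"]
        score, base, gap = z["scores"]
        emb_map = AttributionMap("embedding", z["emb_values"], mask,
                                 float(score), float(base), float(gap))
        layer_maps = [
            AttributionMap(l, vals, mask, float(score), float(base))
            for l, vals in enumerate(z["layer_values"])
        ]
        head_maps = [
            HeadAttributionMap(l, vals, mask)
            for l, vals in enumerate(z["head_values"])
        ]
    return AttributionBundle(sequence_id, class_index, emb_map,
                             layer_maps, head_maps, mask)


def run_pipeline(config: RunConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    run_hash = config.content_hash()
    hash_file = out / "stage_hash.json"
    stage_done: dict[str, str] = {}
    if hash_file.exists():
        stage_done = json.loads(hash_file.read_text())

    model = TransformerEncoderClassifier.load(config.checkpoint)
    records = anio.read_fasta(config.fasta)
    lengths = {r.id: len(r) for r in records}
    tracks = anio.tracks_by_protein(
        anio.read_annotations(config.annotations, lengths), config.annotation_type
    )
    labels = anio.read_labels(config.labels)
    class_names = sorted(set(labels.values()))
    class_index = {c: i for i, c in enumerate(class_names)}

    report = PipelineReport(out, n_proteins=len(records), n_attributed=0)
    path_spec = PathSpec(baseline_kind=config.baseline, steps=config.steps)

    # ---- stage 1: attribution --------------------------------------------
    attr_dir = out / "attributions"
    attr_dir.mkdir(exist_ok=True)
    bundles: dict[str, AttributionBundle] = {}
    cached = stage_done.get("attribution") == run_hash
    for rec in records:
        try:
            if config.class_choice == "own_label":
                cidx = class_index[labels[rec.id]]
            else:
                cidx = int(config.class_choice)
            cache_file = attr_dir / f"{rec.id}.npz"
            if cached and cache_file.exists():
                bundles[rec.id] = _load_bundle(cache_file, rec.id, cidx)
                continue
            fn = ClassScoreFn(cidx, config.score_kind)
            bundle = attribute_all(model, rec.residues, fn, path_spec,
                                   sequence_id=rec.id)
            bundles[rec.id] = bundle
            _save_bundle(cache_file, bundle)
            for hm in bundle.head_maps:
                _write_head_map_tsv(
                    attr_dir / f"{rec.id}_layer{hm.layer}_heads.tsv",
                    hm.residue_values,
                    f"protein={rec.id} layer={hm.layer} class={cidx} "
                    f"per-residue per-head relevance",
                )
            np.savetxt(
                attr_dir / f"{rec.id}_embedding_relevance.tsv",
                bundle.embedding_map.residue_relevance[None],
                delimiter="\t", fmt="%.8g",
                header=f"protein={rec.id} embedding per-residue relevance",
            )
        except Exception as exc:  # per-protein failure: log and continue
            log.warning("attribution failed for %s: %s", rec.id, exc)
            report.failures[rec.id] = str(exc)
    report.n_attributed = len(bundles)
    stage_done["attribution"] = run_hash

    # ---- stage 2: per-protein correlation grids --------------------------
    corr_dir = out / "correlations"
    corr_dir.mkdir(exist_ok=True)
    corr_mats: list[HeadStatMatrix] = []
    summed_mats: list[np.ndarray] = []
    usable_ids: list[str] = []
    for pid, bundle in bundles.items():
        track = tracks.get(pid)
        if track is None:
            continue
        try:
            grid = correlate_protein(bundle.head_maps, track.to_binary())
        except Exception as exc:
            log.warning("correlation failed for %s: %s", pid, exc)
            report.failures[pid] = str(exc)
            continue
        corr_mats.append(grid)
        summed_mats.append(summed_relevance(bundle.head_maps))
        usable_ids.append(pid)
        _write_head_map_tsv(corr_dir / f"{pid}_correlation.tsv", grid.values,
                            f"protein={pid} point-biserial r vs "
                            f"{config.annotation_type}")

    # ---- stage 3: aggregation + overlay ----------------------------------
    agg_dir = out / "aggregate"
    agg_dir.mkdir(exist_ok=True)
    summary_lines = [
        f"proteins: {len(records)}; attributed: {report.n_attributed}; "
        f"with usable annotations: {len(usable_ids)}",
    ]
    if len(usable_ids) >= TestConfig().min_n:
        results = HeadAnnotationAnalysis(
            corr_mats, summed_mats, TestConfig(alpha=config.alpha)
        ).fit()
        _write_grid(agg_dir / "correlation_p_adjusted", results.correlation.p_adjusted)
        _write_grid(agg_dir / "relevance_p_adjusted", results.relevance.p_adjusted)
        _write_grid(agg_dir / "overlay_neglog10", results.overlay)
        (agg_dir / "analysis_summary.txt").write_text(results.summary() + "\n")
        report.n_joint_significant = results.n_joint
        summary_lines.append(
            f"jointly significant (layer, head) cells: {results.n_joint}"
        )
        try:
            from .plotting import plot_head_grid
            plot_head_grid(results.overlay, agg_dir / "overlay.png",
                           "correlation masked by positive relevance")
        except Exception as exc:  # figures are best-effort
            log.warning("figure export failed: %s", exc)
    else:
        summary_lines.append(
            "statistics stages skipped: no testable proteins "
            f"({len(usable_ids)} usable annotations < {TestConfig().min_n})"
        )

    # ---- stage 4: summed-map clustering ----------------------------------
    if len(bundles) >= 3:
        ids = list(bundles)
        flat = flatten_maps([b.summed_matrix() for b in bundles.values()], ids)
        labs = [labels[i] for i in ids]
        try:
            emb = embed_2d(flat, labs, ids, pca_dims=50, seed=config.seed)
            df = pd.DataFrame({
                "protein_id": ids,
                "x": emb.coordinates[:, 0],
                "y": emb.coordinates[:, 1],
                "class": labs,
            })
            df.to_csv(out / "map_embedding.tsv", sep="\t", index=False)
            if len(set(labs)) >= 2:
                report.silhouette = cluster_separation(emb)
                summary_lines.append(
                    f"summed-map silhouette by class: {report.silhouette:.3f}"
                )
            from .plotting import plot_map_embedding
            plot_map_embedding(emb, out / "map_embedding.png")
        except Exception as exc:
            log.warning("clustering stage failed: %s", exc)
            summary_lines.append(f"clustering stage failed: {exc}")

    if report.failures:
        summary_lines.append(f"failed proteins: {len(report.failures)}")
        for pid, why in report.failures.items():
            summary_lines.append(f"  {pid}: {why}")
    summary = out / "summary.txt"
    summary.write_text("\n".join(summary_lines) + "\n")
    report.summary_path = summary
    hash_file.write_text(json.dumps(stage_done))
    return report
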