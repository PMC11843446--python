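"""End-to-end orchestration: classify -> cluster -> annotate -> enrich -> network.

Each stage writes a TSV into the output directory; a JSON manifest
records the config snapshot, input checksums, per-stage outputs and
timings. Stages whose optional inputs are absent (phenotypes, gene sets)
are skipped and logged. The run is deterministic given (inputs, config,
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import classify_features
from .consensus import subcluster_group
from .datatypes import (
    ExperimentDesign,
    GeneSetCollection,
    OmicsMatrix,
    PhenotypeMatrix,
    RunConfig,
)
from .enrichment import enrichment_frame, ora
from .interpret import annotate_subclusters, compute_interpretable_features
from .network import build_network

logger = logging.getLogger("enodal")


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def setup_logging(log_file: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunManifest:
    config: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    version: str = __version__
    skipped: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def run_all(
    design: ExperimentDesign,
    omics: OmicsMatrix,
    config: RunConfig,
    out_dir: str | Path,
    phenotypes: PhenotypeMatrix | None = None,
    gene_sets: GeneSetCollection | None = None,
    input_paths: dict | None = None,
) -> RunManifest:
    """Execute every applicable stage in order and write all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    for name, path in (input_paths or {}).items():
        manifest.inputs[name] = {"path": str(path), "sha256": _checksum(path)}

    omics = omics.drop_incomplete()

    t0 = time.perf_counter()
    assignment = classify_features(omics, design, config)
    path = out / "assignments.tsv"
    assignment.write(path)
    manifest.outputs["classify"] = str(path)
    manifest.timings["classify"] = round(time.perf_counter() - t0, 3)
    logger.info("classify: %s", dict(zip(*np.unique(assignment.labels, return_counts=True))))

    t0 = time.perf_counter()
    members_by_subcluster: dict[str, list[str]] = {}
    frames = []
    for group in ("NxD", "N+D", "N", "D"):
        members = assignment.members(group)
        if not members:
            continue
        result = subcluster_group(omics.subset(members), group, config)
        frames.append(result.to_frame())
        members_by_subcluster.update(result.members)
    sub_frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["feature_id", "group", "subcluster"])
    )
    path = out / "subclusters.tsv"
    sub_frame.to_csv(path, sep="\t", index=False)
    manifest.outputs["cluster"] = str(path)
    manifest.timings["cluster"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    feats = compute_interpretable_features(omics, design, config)
    feats.write(out / "interpretable_features.tsv")
    annotations = annotate_subclusters(members_by_subcluster, feats, config)
    ann_frames = [a.to_frame() for a in annotations if a.records]
    ann_frame = (
        pd.concat(ann_frames, ignore_index=True)
        if ann_frames
        else pd.DataFrame(columns=["subcluster", "set", "nutrition", "treatment",
                                   "direction", "proportion", "annotation"])
    )
    path = out / "annotations.tsv"
    ann_frame.to_csv(path, sep="\t", index=False)
    manifest.outputs["annotate"] = str(path)
    manifest.outputs["interpretable_features"] = str(out / "interpretable_features.tsv")
    manifest.timings["annotate"] = round(time.perf_counter() - t0, 3)

    if gene_sets is not None:
        t0 = time.perf_counter()
        background = frozenset(omics.feature_ids)
        rows = []
        for sc_id in sorted(members_by_subcluster):
            rows.extend(ora(members_by_subcluster[sc_id], gene_sets, background, sc_id))
        path = out / "enrichment.tsv"
        enrichment_frame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
        manifest.outputs["enrich"] = str(path)
        manifest.timings["enrich"] = round(time.perf_counter() - t0, 3)
    else:
        manifest.skipped.append("enrich (no gene sets supplied)")
        logger.info("enrichment stage skipped: no gene-set collection supplied")

    if phenotypes is not None and phenotypes.m > 0 and members_by_subcluster:
        t0 = time.perf_counter()
        net = build_network(
            omics, phenotypes, members_by_subcluster,
            p_cut=config.network_p_cut, multiset_method=config.multiset_method,
        )
        path = out / "network_edges.tsv"
        net.write_edges(path)
        manifest.outputs["network"] = str(path)
        manifest.timings["network"] = round(time.perf_counter() - t0, 3)
    elif not members_by_subcluster:
        manifest.skipped.append("network (no significant subclusters)")
        logger.info("network stage skipped: no significant subclusters")
    else:
        manifest.skipped.append("network (no phenotypes supplied)")
        logger.info("network stage skipped: no phenotype matrix supplied")

    manifest.write(out / "manifest.json")
    return manifest
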