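"""End-to-end run configuration and orchestration.

``run_pipeline`` chains: window -> quality filter -> encoding -> conserved
mask -> train/test split -> indicator vectors -> structure / diversity /
prediction matrices -> accuracy report -> NJ trees (structure- and
diversity-based) -> Klee diagrams. Every text output starts with a header
comment carrying the tool version, seed and a hash of the resolved
configuration, and a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__, alignio, indicator, kleeviz, matrices, seqspace, trees

log = logging.getLogger("kleevec")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run (JSON-serializable)."""

    window_start: int | None = None
    window_end: int | None = None
    max_ambiguous_fraction: float = 0.02
    conserved_rule: str = "strict"          # or "unambiguous"
    mask_scope: str = "all"                 # or "train"
    n_per_group: int = 3
    rng_seed: int = 0
    includes_self_pairs: bool = True
    distance_scale: str = "correlation"     # or "hamming"
    image_format: str = "png"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"kleevec {__version__}",
            f"seed={self.rng_seed}",
            f"config={self.digest()}",
        ]


def run_pipeline(fasta_path, manifest_path, config: RunConfig, outdir) -> dict:
    """Run the full analysis; returns a summary dict (also written as JSON).

    Outputs under ``outdir``: dropped-sequence report, site mask, indicator
    TSVs + sidecars, structure/diversity/prediction matrices, accuracy
    report, two Newick trees, Klee diagrams, and the resolved config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()

    log.info("stage=read fasta=%s", fasta_path)
    aln = alignio.read_fasta(fasta_path)
    if config.window_start is not None and config.window_end is not None:
        log.info("stage=window %d..%d", config.window_start, config.window_end)
        aln = alignio.extract_window(aln, config.window_start, config.window_end)

    log.info("stage=quality max_ambiguous_fraction=%g",
             config.max_ambiguous_fraction)
    aln, dropped = alignio.filter_quality(aln, config.max_ambiguous_fraction)
    alignio.write_dropped_report(dropped, outdir / "dropped_sequences.tsv")

    log.info("stage=manifest path=%s", manifest_path)
    manifest = alignio.read_manifest(manifest_path, aln)

    log.info("stage=mask rule=%s scope=%s", config.conserved_rule,
             config.mask_scope)
    cfg = indicator.TrainingConfig(config.n_per_group, config.rng_seed)
    if config.mask_scope == "all":
        mask = seqspace.find_conserved_sites(aln.rows, rule=config.conserved_rule)
        ts = indicator.split_train_test(aln, manifest, cfg, mask=mask)
    elif config.mask_scope == "train":
        # sample first on the unmasked data, then mask from training rows only
        full_mask = seqspace.SiteMask.from_dropped([], aln.n_sites)
        ts0 = indicator.split_train_test(aln, manifest, cfg, mask=full_mask)
        train_rows = [aln.row(sid) for g in ts0.group_order
                      for sid in ts0.train_ids[g]]
        mask = seqspace.find_conserved_sites(train_rows,
                                             rule=config.conserved_rule)
        ts = indicator.split_train_test(aln, manifest, cfg, mask=mask)
    else:
        raise ValueError(f"unknown mask_scope {config.mask_scope!r}")
    seqspace.save_site_list(
        mask.dropped_positions, outdir / "conserved_sites.txt",
        header="\n".join(header + ["1-based dropped positions"]),
    )
    log.info("stage=split groups=%d train=%d test=%d (excluded: %s)",
             ts.n_groups, ts.n_per_group * ts.n_groups, len(ts.test_ids),
             ts.excluded_groups or "none")

    log.info("stage=indicators")
    indicators = indicator.compute_indicators(ts)
    ind_dir = outdir / "indicators"
    ind_dir.mkdir(exist_ok=True)
    ordered = [indicators[g] for g in ts.group_order]
    for iv in ordered:
        indicator.save_indicator(iv, ts, ind_dir / f"{iv.group}.tsv")

    log.info("stage=matrices")
    sm = matrices.structure_matrix(ordered)
    dm = matrices.diversity_matrix(ts, config.includes_self_pairs)
    sm.to_tsv(outdir / "structure_matrix.tsv", header)
    dm.to_tsv(outdir / "diversity_matrix.tsv", header)

    report = {}
    if ts.test_ids:
        pm = matrices.predict(ts.test_vectors, ordered, ts.test_ids,
                              ts.test_groups)
        pm.to_tsv(outdir / "prediction_matrix.tsv", header)
        report = matrices.accuracy_report(pm)
        matrices.write_accuracy_report(report, outdir / "accuracy_report.json")
        log.info("stage=accuracy overall=%.4f", report["overall_accuracy"])

    log.info("stage=trees scale=%s", config.distance_scale)
    n_sites_for_scale = (len(ts.mask.kept_positions)
                         if config.distance_scale == "hamming" else None)
    tree_info = {}
    for name, matrix in (("structure", sm), ("diversity", dm)):
        dist = trees.correlation_to_distance(matrix, n_sites_for_scale)
        dist.to_tsv(outdir / f"{name}_distances.tsv", header)
        dist.to_phylip(outdir / f"{name}_distances.phy")
        if ts.n_groups >= 3:
            tr = trees.nj_tree(dist)
            tr.write_newick(outdir / f"{name}_tree.nwk")
            tree_info[name] = {
                "leaf_order": trees.leaf_order(tr),
                "clipped_branches": tr.clipped_branches,
            }

    log.info("stage=klee")
    fmt = config.image_format
    for name, matrix in (("structure", sm), ("diversity", dm)):
        spec = kleeviz.KleePlotSpec.from_matrix(matrix, title=f"{name} matrix")
        kleeviz.render_klee(spec, outdir / f"klee_{name}.{fmt}")
    if ts.test_ids:
        spec = kleeviz.KleePlotSpec(
            values=pm.values, row_labels=pm.test_ids,
            col_labels=list(ts.group_order), title="prediction matrix",
        )
        kleeviz.render_klee(spec, outdir / f"klee_prediction.{fmt}")

    config.to_file(outdir / "run_config.json")
    summary = {
        "version": __version__,
        "config_digest": config.digest(),
        "n_groups": ts.n_groups,
        "excluded_groups": ts.excluded_groups,
        "n_train": ts.n_per_group * ts.n_groups,
        "n_test": len(ts.test_ids),
        "n_dropped_quality": len(dropped),
        "n_conserved_sites": len(ts.mask.dropped_positions),
        "n_kept_sites": len(ts.mask.kept_positions),
        "accuracy": report.get("overall_accuracy"),
        "trees": tree_info,
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
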