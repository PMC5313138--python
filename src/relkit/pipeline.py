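"""End-to-end orchestration: seed protein -> family -> signatures ->
clades -> plasmid crosstab -> oriT/curvature report bundle.

A single seeded RNG stream is split into per-stage substreams derived
from the stage name, so stage results are reproducible independently of
stage order.  All paper-default thresholds live in :class:`RunConfig`
and are echoed verbatim into ``run.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import centroids, greedy_cluster, write_cluster_report
from .core_seq import NucSeq, SequenceSet, read_fasta, write_fasta
from .dna_features import (AAWEDGE, CDS, PARAMETER_SETS, call_peaks,
                           curvature_profile, find_repeats, gc_windows,
                           locate_nick, smooth_normalize, write_features_gff3,
                           write_peaks_bed, write_wiggle)
from .homology_search import psi_search, write_search_report
from .motifs import discover_signatures, occurrence_table, write_meme
from .phylogeny import (bootstrap_supports, build_msa, condense,
                        filter_by_length, split_two_clades, write_clades)
from .plasmid_assignment import (PlasmidRecord, clade_plasmid_crosstab,
                                 localize, write_calls, write_crosstab)

log = logging.getLogger("relkit")


@dataclass
class RunConfig:
    seed_protein: str
    protein_db: str
    plasmid_db: str | None = None
    output_dir: str = "relkit_out"
    search_evalue: float = 1e-15
    search_max_rounds: int = 10
    scan_evalue: float = 1e-6
    cluster_dedup: float = 1.00
    cluster_motif: float = 0.50
    loc_identity: float = 0.95
    loc_coverage: float = 0.80
    min_tree_len: int = 300
    bootstrap_reps: int = 1000
    smooth_window: int = 600
    max_motifs: int = 10
    motif_evalue: float = 1e-15
    motif_width_range: tuple[int, int] = (6, 50)
    curvature_params: str = "CDS"
    distance_model: str = "poisson"
    condense_support: float = 50.0
    rng_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        h = 0
        for ch in stage:
            h = (h * 131 + ord(ch)) % (2 ** 31)
        return (self.rng_seed * 7919 + h) % (2 ** 31)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns a summary dict.

    Any stage failure raises :class:`StageError`; partial outputs are
    retained next to a FAILED marker naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    current = "setup"
    try:
        seed_set = read_fasta(config.seed_protein, "protein")
        seed = seed_set[0]
        db = read_fasta(config.protein_db, "protein")

        current = "search"
        result = psi_search(seed, db, config.search_evalue,
                            config.search_max_rounds,
                            seed_rng=config.stage_seed("search"))
        members = result.members
        write_search_report(result, out / "members.tsv")
        write_fasta(members, out / "members.fasta")
        log.info("search: %d members in %d rounds", len(members),
                 len(result.rounds))
        summary["stages"]["search"] = {"members": len(members),
                                       "rounds": len(result.rounds)}

        current = "dedup"
        dedup = greedy_cluster(members, config.cluster_dedup)
        unique = centroids(dedup, members)
        log.info("dedup: %d -> %d", len(members), len(unique))

        current = "cluster"
        clusters = greedy_cluster(unique, config.cluster_motif)
        write_cluster_report(clusters, out / "clusters.tsv")
        reps = centroids(clusters, unique)
        log.info("cluster: %d centroids at %.2f", len(reps),
                 config.cluster_motif)
        summary["stages"]["cluster"] = {"dedup": len(unique),
                                        "centroids": len(reps)}

        current = "motifs"
        sigs = discover_signatures(
            reps if len(reps) >= 2 else unique,
            max_motifs=config.max_motifs, max_evalue=config.motif_evalue,
            width_range=config.motif_width_range,
            seed=config.stage_seed("motifs"))
        write_meme(sigs, out / "signatures.meme")
        log.info("motifs: %d signatures", len(sigs))
        summary["stages"]["motifs"] = {"signatures": len(sigs)}

        current = "occurrence"
        if sigs:
            table = occurrence_table({"family": sigs},
                                     {"family": unique},
                                     config.scan_evalue)
            table.to_csv(out / "occurrence.tsv", sep="\t")

        current = "tree"
        tree_in = filter_by_length(unique, config.min_tree_len)
        if len(tree_in) < 4:
            tree_in = unique
        msa = build_msa(tree_in)
        tree = bootstrap_supports(msa, config.bootstrap_reps,
                                  config.stage_seed("tree"),
                                  config.distance_model)
        condense(tree, config.condense_support)
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        partition = split_two_clades(tree)
        write_clades(partition, out / "clades.tsv")
        n1, n2 = len(partition.clade(1)), len(partition.clade(2))
        log.info("tree: clades %d/%d", n1, n2)
        summary["stages"]["tree"] = {"clade1": n1, "clade2": n2}

        current = "localize"
        if config.plasmid_db:
            pl_set = read_fasta(config.plasmid_db, "nucleotide",
                                circular=True)
            plasmids = [PlasmidRecord(r.id, r) for r in pl_set]
            tree_ids = set(partition.assignment)
            calls = localize(unique.subset(sorted(tree_ids)), plasmids,
                             config.loc_identity, config.loc_coverage)
            write_calls(calls, out / "localization.tsv")
            tab = clade_plasmid_crosstab(calls, partition)
            write_crosstab(tab, out / "crosstab.tsv")
            n_pos = sum(1 for c in calls if c.positive)
            log.info("localize: %d/%d on plasmids", n_pos, len(calls))
            summary["stages"]["localize"] = {
                "positive": n_pos,
                "counts": {f"{k[0]}_{k[1]}": v
                           for k, v in tab.counts.items()}}

            current = "curvature"
            params = PARAMETER_SETS[config.curvature_params]
            peaks_all = {}
            for rec in pl_set:
                prof = curvature_profile(rec, params)
                z = smooth_normalize(prof.curvature, config.smooth_window,
                                     circular=True)
                peaks = call_peaks(z, min_z=2.0, min_separation=1200)
                peaks_all[rec.id] = peaks
                write_wiggle(z, rec.id, out / f"curvature.{rec.id}.wig")
                write_peaks_bed(peaks, rec.id, out / f"peaks.{rec.id}.bed")
            summary["stages"]["curvature"] = {
                "peaks": {k: len(v) for k, v in peaks_all.items()}}

            current = "features"
            gff = out / "features.gff3"
            first = True
            for rec in pl_set:
                nicks = locate_nick(rec)
                repeats = []
                if nicks:
                    a = max(nicks[0].position - 200, 0)
                    b = min(nicks[0].position + 200, len(rec.bases))
                    region = NucSeq(rec.id, rec.bases[a:b])
                    repeats = find_repeats(region, min_arm=4, max_loop=20,
                                           max_mismatch=1)
                write_features_gff3(rec.id, repeats, nicks, gff,
                                    append=not first)
                first = False
            summary["stages"]["features"] = {"done": True}
        else:
            log.warning("no plasmid database: localization stage skipped")
            summary["stages"]["localize"] = {"skipped": True}

        current = "report"
        run_info = {"config": _jsonable(asdict(config)),
                    "version": __version__,
                    "seed": config.rng_seed}
        (out / "run.json").write_text(json.dumps(run_info, indent=1,
                                                 sort_keys=True))
        return summary
    except Exception as exc:  # noqa: BLE001 - stage-named abort contract
        (out / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        raise StageError(current, exc) from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
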