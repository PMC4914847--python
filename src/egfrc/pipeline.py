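"""End-to-end orchestration: fixtures -> scan -> classify -> cluster ->
ancestral reconstruction -> report, with a provenance manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import classify as classify_mod
from . import cluster as cluster_mod
from . import evolution, fixtures, io, scan

log = logging.getLogger("egfrc")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully serializable run configuration; a run is reproducible from
    (config, inputs)."""

    seed: int = 0
    out_dir: str = "egfrc_run"
    species: list | None = None  # None = all bundled species
    include_decoys: bool = True
    cluster_threshold: float = 0.5
    cluster_normalization: str = "BITS_PER_SHORTER"
    scan_overrides: dict = field(default_factory=dict)
    verbosity: int = 1

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**data)
        valid_scan = {f.name for f in dataclasses.fields(scan.ScanProfile)}
        bad = set(config.scan_overrides) - valid_scan
        if bad:
            raise ConfigError(f"unknown scan profile keys: {sorted(bad)}")
        return config

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def profile(self) -> scan.ScanProfile:
        base = dataclasses.asdict(scan.DEFAULT_PROFILE)
        base.update(self.scan_overrides)
        base["egf_spacings"] = tuple(tuple(p) for p in base["egf_spacings"])
        return scan.ScanProfile(**base)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts plus a JSON manifest.

    Returns a dict of the in-memory stage results. Output files:
    proteome.fasta, hits.gff3, calls.tsv, complements.tsv, qc.tsv,
    edges.tsv, components.tsv, node_states.tsv, events.tsv,
    annotated_tree.nwk, summary.txt, manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = config.profile()

    # --- fixtures ---------------------------------------------------------
    all_fixtures = fixtures.bundled_species_fixtures(include_decoys=config.include_decoys)
    if config.species is not None:
        wanted = set(config.species)
        missing = wanted - {f.species for f in all_fixtures}
        if missing:
            raise ConfigError(f"unknown species in config: {sorted(missing)}")
        all_fixtures = [f for f in all_fixtures if f.species in wanted]
    records = []
    for fx in all_fixtures:
        records.extend(fixtures.generate_species_set(fx, config.seed))
    io.write_fasta(records, out / "proteome.fasta")
    log.info("fixtures: %d species, %d records", len(all_fixtures), len(records))

    # --- scan -------------------------------------------------------------
    hits_by_record = {r.id: scan.scan_record(r, profile) for r in records}
    io.write_gff3(hits_by_record, out / "hits.gff3")
    log.info("scan: %d hits", sum(len(v) for v in hits_by_record.values()))

    # --- classify ---------------------------------------------------------
    calls = [classify_mod.classify_record(r, hits_by_record[r.id]) for r in records]
    species_of = {r.id: r.species for r in records}
    clade_of = {r.species: r.clade for r in records}
    matrix, qc = classify_mod.build_complement_matrix(calls, species_of, clade_of)
    _write_calls(calls, out / "calls.tsv")
    io.write_matrix_tsv(matrix, out / "complements.tsv")
    qc.to_csv(out / "qc.tsv", sep="\t", index=False)
    by_cat: dict = {}
    for c in calls:
        by_cat[c.category] = by_cat.get(c.category, 0) + 1
    log.info("classify: %s", dict(sorted(by_cat.items())))

    # --- cluster (ligand calls only, as in a ligand-family survey) --------
    ligand_ids = {
        c.record_id for c in calls if c.category in ("EGF_TYPE_LIGAND", "NRG_TYPE_LIGAND")
    }
    ligand_records = [r for r in records if r.id in ligand_ids]
    graph = None
    if len(ligand_records) >= 2:
        score_matrix = cluster_mod.pairwise_scores(ligand_records)
        graph = cluster_mod.build_graph(
            score_matrix,
            threshold=config.cluster_threshold,
            normalization=config.cluster_normalization,
        )
        _write_graph(graph, out)
        log.info(
            "cluster: %d nodes, %d edges, %d components",
            graph.graph.number_of_nodes(),
            graph.graph.number_of_edges(),
            len(graph.components),
        )

    # --- ancestral reconstruction (bundled survey matrices + tree) --------
    tree = fixtures.bundled_species_tree()
    char_matrix = evolution.matrix_from_complements(
        fixtures.bundled_complement_matrix("MERGED")
    )
    events, roots = evolution.scenario_report(tree, char_matrix)
    events.to_csv(out / "events.tsv", sep="\t", index=False)
    _write_node_states(tree, char_matrix, out / "node_states.tsv")
    _write_annotated_tree(tree, char_matrix, out / "annotated_tree.nwk")
    log.info("ancestral: %d events; roots %s", len(events), roots)

    # --- report -----------------------------------------------------------
    summary = _summary_text(matrix, qc, graph, events, roots)
    (out / "summary.txt").write_text(summary)

    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "checksums": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "records": records,
        "hits": hits_by_record,
        "calls": calls,
        "matrix": matrix,
        "qc": qc,
        "graph": graph,
        "events": events,
        "root_complement": roots,
        "manifest": manifest,
    }


def _write_calls(calls, path) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(path, sep="\t", index=False)


def _write_graph(graph, out: Path) -> None:
    edge_lines = ["a\tb\tscore\tnorm\tattraction"]
    for a, b, data in sorted(graph.graph.edges(data=True)):
        edge_lines.append(
            f"{a}\t{b}\t{data['score']:.0f}\t{data['norm']:.4f}\t{data['attraction']:.4f}"
        )
    (out / "edges.tsv").write_text("\n".join(edge_lines) + "\n")
    comp_lines = ["component\tmember"]
    for i, comp in enumerate(graph.components):
        for member in comp:
            comp_lines.append(f"{i}\t{member}")
    (out / "components.tsv").write_text("\n".join(comp_lines) + "\n")


def _write_node_states(tree, char_matrix, path) -> None:
    import pandas as pd

    sankoffs = {
        count: evolution.sankoff_counts(tree, char_matrix.df[count], character=count)
        for count in evolution.COUNT_CHARACTERS
    }
    rows = []
    for node in tree.preorder_node_iter():
        rows.append(
            {
                "node": evolution.node_name(node),
                "is_leaf": int(node.is_leaf()),
                **{c: sankoffs[c].node_counts[node] for c in evolution.COUNT_CHARACTERS},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_annotated_tree(tree, char_matrix, path) -> None:
    clone = tree.clone(depth=1)
    sankoffs = {
        count: evolution.sankoff_counts(clone, char_matrix.df[count], character=count)
        for count in evolution.COUNT_CHARACTERS
    }
    for node in clone.preorder_node_iter():
        states = "/".join(
            str(sankoffs[c].node_counts[node]) for c in evolution.COUNT_CHARACTERS
        )
        comment = f"EGFR_EGF_NRG={states}"
        node.annotations.add_new("states", comment)
    clone.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        suppress_annotations=False,
    )


def _summary_text(matrix, qc, graph, events, roots) -> str:
    lines = ["EGFR-pathway complement pipeline summary", ""]
    lines.append(f"species scanned: {len(matrix.species)}")
    lines.append(f"receptors called: {int(matrix.df['egfr_count'].sum())}")
    lines.append(
        f"ligands called: {int(matrix.df['egf_like_count'].sum() + matrix.df['nrg_like_count'].sum())}"
        f" (EGF-type {int(matrix.df['egf_like_count'].sum())},"
        f" NRG-type {int(matrix.df['nrg_like_count'].sum())})"
    )
    lines.append(f"inactive TK receptors: {int(matrix.df['inactive_tk_count'].sum())}")
    lines.append(f"rejected records: {len(qc)}")
    if graph is not None:
        lines.append(f"ligand similarity components: {len(graph.components)}")
    lines.append("")
    for name, counts in roots.items():
        lines.append(f"reconstructed {name} complement: {counts}")
    lines.append(f"reconstruction events: {len(events)}")
    return "\n".join(lines) + "\n"
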