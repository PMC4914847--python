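"""Shared fixtures and helpers for the egfrc test suite."""

from __future__ import annotations

import random
import re
import time

import dendropy
import pytest

from egfrc import (
    build_complement_matrix,
    build_graph,
    bundled_species_fixtures,
    classify_record,
    generate_species_set,
    pairwise_scores,
    scan_record,
)

#: expected classifier category by fixture spec label
LABEL_CATEGORY = [
    (re.compile(r"^egfr\d+$"), "EGFR"),
    (re.compile(r"^egf\d+$"), "EGF_TYPE_LIGAND"),
    (re.compile(r"^nrg\d+$"), "NRG_TYPE_LIGAND"),
    (re.compile(r"^decoy_"), "REJECTED"),
]


def expected_category(label: str) -> str:
    for pattern, category in LABEL_CATEGORY:
        if pattern.match(label):
            return category
    raise AssertionError(f"unrecognized fixture label {label!r}")


def label_of(record_id: str) -> str:
    return record_id.split("|")[1]


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    tree.is_rooted = True
    return tree


def random_tree(rng: random.Random, n_tips: int, allow_polytomy: bool = True) -> dendropy.Tree:
    """Random rooted tree built by repeated joins (2-3 children per join)."""
    taxa = [f"t{i}" for i in range(n_tips)]
    groups = [f"'{t}'" for t in taxa]
    while len(groups) > 1:
        k = 2
        if allow_polytomy and len(groups) >= 3 and rng.random() < 0.3:
            k = 3
        picked = [groups.pop(rng.randrange(len(groups))) for _ in range(min(k, len(groups)))]
        groups.append("(" + ",".join(picked) + ")")
    return tree_from_newick(groups[0] + ";")


@pytest.fixture(scope="session")
def all_fixtures():
    return bundled_species_fixtures(include_decoys=True)


@pytest.fixture(scope="session")
def round_trip_seed1(all_fixtures):
    """Generate, scan and classify every bundled fixture at seed 1."""
    start = time.monotonic()
    records = []
    for fx in all_fixtures:
        records.extend(generate_species_set(fx, seed=1))
    hits = {r.id: scan_record(r) for r in records}
    calls = [classify_record(r, hits[r.id]) for r in records]
    species_of = {r.id: r.species for r in records}
    clade_of = {r.species: r.clade for r in records}
    matrix, qc = build_complement_matrix(calls, species_of, clade_of)
    elapsed = time.monotonic() - start
    return {
        "records": records,
        "hits": hits,
        "calls": calls,
        "matrix": matrix,
        "qc": qc,
        "elapsed": elapsed,
    }


@pytest.fixture(scope="session")
def ligand_graph_seed1(round_trip_seed1):
    """All-vs-all similarity graph over every ligand-called record at seed 1."""
    ligand_ids = {
        c.record_id
        for c in round_trip_seed1["calls"]
        if c.category in ("EGF_TYPE_LIGAND", "NRG_TYPE_LIGAND")
    }
    ligands = [r for r in round_trip_seed1["records"] if r.id in ligand_ids]
    sm = pairwise_scores(ligands)
    return ligands, sm, build_graph(sm)
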