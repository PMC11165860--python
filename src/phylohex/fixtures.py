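"""Seedable synthetic inputs: occurrence tables, trees, endemism scenarios.

Every pipeline stage is testable without downloads: species ranges are
Gaussian clouds around random centres (a test model chosen for the analytic
tractability of planted-outlier distances, not a biological claim), trees
come from a Yule process, and the endemism scenarios plant a recently
radiated (neo) or anciently isolated (paleo) clade of narrow-range species
inside a known region so label recovery can be checked end to end.

All generators are deterministic under their seed, and occurrence
generators return a row-aligned manifest marking exactly which rows are
contamination (centroid duplicates, planted outliers, fossils).
"""

from __future__ import annotations

import random
import re

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .cleaning import EARTH_RADIUS_MEAN_KM
from .hexgrid import PresenceMatrix
from .occurrences import OccurrenceTable, ValidationReport
from .phylo import PhyloTree, tree_from_newick

_KM_PER_DEG = np.pi * EARTH_RADIUS_MEAN_KM / 180.0


def _destination(lat, lon, bearing_deg, distance_km):
    """Great-circle destination point (spherical Earth)."""
    d = distance_km / EARTH_RADIUS_MEAN_KM
    la1 = np.deg2rad(lat)
    lo1 = np.deg2rad(lon)
    th = np.deg2rad(bearing_deg)
    la2 = np.arcsin(np.sin(la1) * np.cos(d) + np.cos(la1) * np.sin(d) * np.cos(th))
    lo2 = lo1 + np.arctan2(
        np.sin(th) * np.sin(d) * np.cos(la1),
        np.cos(d) - np.sin(la1) * np.sin(la2),
    )
    return np.rad2deg(la2), (np.rad2deg(lo2) + 540.0) % 360.0 - 180.0


def gen_occurrences(
    n_species: int = 50,
    records_per_species: int = 20,
    seed: int = 0,
    bbox: tuple = (0.0, 30.0, -15.0, 15.0),
    range_sigma_km: float = 100.0,
    centroid_dupes: int = 0,
    centroid_points: pd.DataFrame | None = None,
    planted_outliers: int = 0,
    outlier_distance_km: float = 2000.0,
    fossil_fraction: float = 0.0,
    n_dataset_keys: int = 3,
    species_key_offset: int = 0,
):
    """Synthetic occurrence table plus a row-aligned ground-truth manifest.

    Species ranges are isotropic Gaussian clouds (sd ``range_sigma_km``)
    around centres drawn uniformly inside ``bbox``.  Contamination rows are
    appended after the core rows: exact duplicates of centroid reference
    points and single records displaced ``outlier_distance_km`` from their
    species centre.  The manifest column ``kind`` is one of
    ``core | centroid_dupe | outlier``.
    """
    rng = np.random.default_rng(seed)
    lon_min, lon_max, lat_min, lat_max = bbox
    pad_lon = (lon_max - lon_min) * 0.1
    pad_lat = (lat_max - lat_min) * 0.1
    keys = np.arange(1, n_species + 1) + species_key_offset
    centers_lon = rng.uniform(lon_min + pad_lon, lon_max - pad_lon, n_species)
    centers_lat = rng.uniform(lat_min + pad_lat, lat_max - pad_lat, n_species)

    rows = []
    manifest = []
    dataset_keys = [f"ds-{chr(ord('a') + i)}" for i in range(n_dataset_keys)]

    for i, key in enumerate(keys):
        n = records_per_species
        dlat = rng.normal(0.0, range_sigma_km, n) / _KM_PER_DEG
        dlon = rng.normal(0.0, range_sigma_km, n) / (
            _KM_PER_DEG * np.cos(np.deg2rad(centers_lat[i]))
        )
        lat = np.clip(centers_lat[i] + dlat, -89.9, 89.9)
        lon = centers_lon[i] + dlon
        fossil = rng.random(n) < fossil_fraction
        for j in range(n):
            rows.append(
                {
                    "species_key": int(key),
                    "species_name": f"Sp{key:04d}",
                    "latitude": float(lat[j]),
                    "longitude": float(lon[j]),
                    "year": int(rng.integers(1950, 2021)),
                    "basis_of_record": "FOSSIL_SPECIMEN" if fossil[j] else "PRESERVED_SPECIMEN",
                    "coord_uncertainty_m": float(np.round(rng.lognormal(4.0, 1.0), 1))
                    if rng.random() > 0.1
                    else None,
                    "coord_precision": rng.choice([0.0001, 0.001, 0.01, None]),
                    "country_code": "AA",
                    "dataset_key": dataset_keys[int(rng.integers(0, n_dataset_keys))],
                }
            )
            manifest.append({"kind": "core", "species_key": int(key), "fossil": bool(fossil[j])})

    if centroid_dupes:
        if centroid_points is None:
            centroid_points = pd.DataFrame(
                {
                    "latitude": rng.uniform(lat_min, lat_max, 3),
                    "longitude": rng.uniform(lon_min, lon_max, 3),
                }
            )
        for _ in range(centroid_dupes):
            p = centroid_points.iloc[int(rng.integers(0, len(centroid_points)))]
            key = int(rng.choice(keys))
            rows.append(
                {
                    "species_key": key,
                    "species_name": f"Sp{key:04d}",
                    "latitude": float(p["latitude"]),
                    "longitude": float(p["longitude"]),
                    "year": int(rng.integers(1950, 2021)),
                    "basis_of_record": "PRESERVED_SPECIMEN",
                    "coord_uncertainty_m": None,
                    "coord_precision": None,
                    "country_code": "AA",
                    "dataset_key": dataset_keys[0],
                }
            )
            manifest.append({"kind": "centroid_dupe", "species_key": key, "fossil": False})

    for _ in range(planted_outliers):
        i = int(rng.integers(0, n_species))
        lat_o, lon_o = _destination(
            centers_lat[i], centers_lon[i], float(rng.uniform(0, 360)), outlier_distance_km
        )
        rows.append(
            {
                "species_key": int(keys[i]),
                "species_name": f"Sp{keys[i]:04d}",
                "latitude": float(lat_o),
                "longitude": float(lon_o),
                "year": int(rng.integers(1950, 2021)),
                "basis_of_record": "PRESERVED_SPECIMEN",
                "coord_uncertainty_m": None,
                "coord_precision": None,
                "country_code": "AA",
                "dataset_key": dataset_keys[0],
            }
        )
        manifest.append({"kind": "outlier", "species_key": int(keys[i]), "fossil": False})

    df = pd.DataFrame(rows)
    man = pd.DataFrame(manifest)
    table = OccurrenceTable(
        df, ValidationReport(rows_read=len(df), rows_kept=len(df))
    )
    table.centroid_points = centroid_points  # ground truth for cleaning tests
    return table, man


def gen_tree(n_tips: int, seed: int = 0, model: str = "yule", birth_rate: float = 1.0) -> PhyloTree:
    """Random ultrametric tree with tips Sp0001..SpNNNN (Yule process)."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if model != "yule":
        raise ValueError(f"unknown model {model!r}")
    t = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(t.leaf_node_iter(), start=1):
        leaf.taxon.label = f"Sp{i:04d}"
    t.seed_node.edge.length = None  # no root edge: binary tree has 2n-2 branches
    return PhyloTree(t)


def _scaled_newick(tree: PhyloTree, depth: float = 1.0) -> str:
    """Newick of the tree rescaled to a given root-to-tip depth, no ';'."""
    t = tree.tree.clone(depth=1)
    maxd = max(
        leaf.distance_from_root() for leaf in t.leaf_node_iter()
    )
    for e in t.preorder_edge_iter():
        if e.length:
            e.length = e.length * depth / maxd
    s = t.as_string(schema="newick", suppress_rooting=True).strip()
    return s.rstrip(";")


# ---------------------------------------------------------------------------
# endemism scenarios
# ---------------------------------------------------------------------------

#: analysis domain and planted-endemism region of the scenarios (lon/lat bbox)
SCENARIO_DOMAIN = (0.0, 15.0, -7.5, 7.5)
SCENARIO_REGION = (9.0, 13.5, -2.25, 2.25)


def gen_endemism_scenario(kind: str, seed: int = 0):
    """Occurrences + tree with a planted endemism signal in a known region.

    kind
        ``neo``    — the region holds a recently radiated clade (terminal
        branches 5% of tree depth) of narrow-range species;
        ``paleo``  — the region holds anciently diverged, long-branch
        narrow-range species;
        ``background`` — widespread species only (for null calibration).

    Returns ``(OccurrenceTable, PhyloTree, region_bbox)`` where the region
    bbox is the ground truth for label-recovery tests.
    """
    if kind not in ("neo", "paleo", "background"):
        raise ValueError(f"unknown scenario kind {kind!r}")
    n_bg, n_end = 40, 16
    bg_table, _ = gen_occurrences(
        n_species=n_bg,
        records_per_species=50,
        seed=seed,
        bbox=SCENARIO_DOMAIN,
        range_sigma_km=600.0,
    )
    bg_tree = gen_tree(n_bg, seed=seed + 1)
    bg_sub = _scaled_newick(bg_tree, depth=1.0)

    if kind == "background":
        tree = tree_from_newick(f"({bg_sub}:0.25);")
        return bg_table, tree, SCENARIO_REGION

    end_table, _ = gen_occurrences(
        n_species=n_end,
        records_per_species=30,
        seed=seed + 2,
        bbox=SCENARIO_REGION,
        range_sigma_km=50.0,
        species_key_offset=n_bg,
    )
    labels = [f"Sp{k:04d}" for k in range(n_bg + 1, n_bg + n_end + 1)]
    if kind == "neo":
        # each endemic is a very recent split from a widespread background
        # sister, so its only range-restricted branch is a short terminal
        rng = np.random.default_rng(seed + 3)
        hosts = rng.choice(np.arange(1, n_bg + 1), size=n_end, replace=False)
        newick = bg_sub
        for host, lab in zip(hosts, labels):
            pat = re.compile(rf"\b(Sp{host:04d}):([0-9.eE+-]+)")
            m = pat.search(newick)
            assert m, f"host tip Sp{host:04d} not found"
            L = float(m.group(2))
            eps = min(0.02, 0.8 * L)
            repl = f"({m.group(1)}:{eps:.6f},{lab}:{eps:.6f}):{L - eps:.6f}"
            newick = newick[: m.start()] + repl + newick[m.end():]
        tree = tree_from_newick(f"({newick}:0.25);")
    else:
        # each endemic is an anciently isolated long pendant at the root
        pendants = ",".join(f"{lab}:1.25" for lab in labels)
        tree = tree_from_newick(f"({bg_sub}:0.25,{pendants});")

    df = pd.concat([bg_table.data, end_table.data], ignore_index=True)
    table = OccurrenceTable(df, ValidationReport(rows_read=len(df), rows_kept=len(df)))
    return table, tree, SCENARIO_REGION


def gen_null_community(
    seed: int, n_cells: int = 200, n_species: int = 30, fill: float = 0.35
) -> PresenceMatrix:
    """Random incidence matrix for null-model calibration.

    Cells are guaranteed a richness of at least 5 so the randomization null
    of the phylogenetic indices is effectively continuous (sparse cells have
    highly discrete nulls, which makes rank p-values conservative).
    """
    rng = np.random.default_rng(seed)
    A = rng.random((n_cells, n_species)) < fill
    for i in range(n_cells):
        while A[i].sum() < 5:
            A[i, rng.integers(n_species)] = True
    for j in range(n_species):
        if not A[:, j].any():
            A[rng.integers(n_cells), j] = True
    cells = np.arange(1, n_cells + 1, dtype=np.uint64)
    return PresenceMatrix(
        3, cells, np.arange(1, n_species + 1, dtype=np.int64), A, A.sum(axis=1) + 2
    )


def tip_key_map(tree: PhyloTree) -> dict:
    """Tip label -> species key for generated trees (SpNNNN -> NNNN)."""
    return {lab: int(lab.removeprefix("Sp")) for lab in tree.tip_labels}


def region_cells(matrix: PresenceMatrix, region_bbox) -> list[str]:
    """Cells of a matrix whose centre lies inside a lon/lat bbox (closed)."""
    from . import dggs

    lon_min, lon_max, lat_min, lat_max = region_bbox
    out = []
    for c in matrix.cells:
        lat, lon = dggs.cell_to_latlon(int(c))
        if lon_min <= lon <= lon_max and lat_min <= lat <= lat_max:
            out.append(dggs.cell_to_str(c))
    return out


# ---------------------------------------------------------------------------
# the worked toy example (4 tips, 3 cells)
# ---------------------------------------------------------------------------


def toy_example() -> dict:
    """The hand-checked example: tree ((A:1,B:1)E:1,(C:1,D:1)F:1) and cells
    c1={A,B} (3 records), c2={B,C} (2 records), c3={D} (1 record).

    Expected values: PD 3/4/2, PE 2.0/2.5/1.5, WE 1.5/1.5/1.0,
    redundancy of c1 = 1/3.
    """
    from . import dggs

    tree = tree_from_newick("((A:1,B:1)E:1,(C:1,D:1)F:1);")
    tip_to_key = {"A": 1, "B": 2, "C": 3, "D": 4}
    res = 4
    anchors = [(0.0, 0.0), (10.0, 10.0), (-20.0, 30.0)]  # three distinct cells
    ids = [dggs.latlon_to_cell(lat, lon, res) for lat, lon in anchors]
    assert len(set(ids)) == 3
    incidence = {ids[0]: {1, 2}, ids[1]: {2, 3}, ids[2]: {4}}
    records = {ids[0]: 3, ids[1]: 2, ids[2]: 1}
    cells = np.sort(np.array(ids, dtype=np.uint64))
    species = np.array([1, 2, 3, 4], dtype=np.int64)
    A = np.zeros((3, 4), dtype=bool)
    rec = np.zeros(3, dtype=np.int64)
    for i, c in enumerate(cells):
        for s in incidence[int(c)]:
            A[i, s - 1] = True
        rec[i] = records[int(c)]
    matrix = PresenceMatrix(res, cells, species, A, rec)
    return {
        "tree": tree,
        "tip_to_key": tip_to_key,
        "matrix": matrix,
        "cells": [dggs.cell_to_str(i) for i in ids],  # c1, c2, c3 order
    }
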