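"""Force-directed landscape clustering: graph, layout, terrain, peaks."""

import numpy as np
import pytest
from conftest import oracle_grid_ascent
from sklearn.metrics import adjusted_rand_score

import networkx as nx

from motif_landscape.landscape_clustering import (
    UNCLUSTERED,
    LayoutParams,
    cluster_genes,
    density_landscape,
    extract_peaks,
    force_layout,
    similarity_graph,
)
from motif_landscape.motif_profiling import ProfileMatrix


def _profiles(groups: list[int], n_motifs: int | None = None) -> ProfileMatrix:
    """One-hot group profiles: genes in group k count on motif k only."""
    n_motifs = n_motifs or (max(groups) + 1)
    genes = [f"g{i:02d}" for i in range(len(groups))]
    counts = np.zeros((len(groups), n_motifs * 4), dtype=int)
    for i, grp in enumerate(groups):
        if grp >= 0:
            counts[i, grp * 4] = 2
    return ProfileMatrix(genes, [f"M{k}" * 2 + "ACG" for k in range(n_motifs)],
                         4, 200, counts)


# --- similarity graph -------------------------------------------------------

def test_identical_rows_get_weight_one_edge():
    pm = _profiles([0, 0, 1, 1])
    g = similarity_graph(pm, k=1)
    assert g["g00"]["g01"]["weight"] == pytest.approx(1.0)


def test_orthogonal_rows_get_weight_zero_edge():
    pm = _profiles([0, 1])
    g = similarity_graph(pm, k=1)
    assert g["g00"]["g01"]["weight"] == pytest.approx(0.0)


def test_two_identical_triplets_form_disjoint_triangles():
    pm = _profiles([0, 0, 0, 1, 1, 1])
    g = similarity_graph(pm, k=2)
    comps = sorted(sorted(c) for c in nx.connected_components(g))
    assert comps == [["g00", "g01", "g02"], ["g03", "g04", "g05"]]
    for c in comps:
        assert g.subgraph(c).number_of_edges() == 3  # triangle


def test_k_must_be_below_n():
    with pytest.raises(ValueError):
        similarity_graph(_profiles([0, 1]), k=2)


# --- layout -----------------------------------------------------------------

def test_single_node_stays_put():
    g = nx.Graph()
    g.add_node("solo")
    coords, iters = force_layout(g, LayoutParams(seed=1))
    assert iters == 1 and "solo" in coords


def test_layout_deterministic_under_seed():
    pm = _profiles([0, 0, 1, 1, 0, 1])
    g = similarity_graph(pm, k=2)
    a, _ = force_layout(g, LayoutParams(seed=5))
    b, _ = force_layout(g, LayoutParams(seed=5))
    assert a == b
    c, _ = force_layout(g, LayoutParams(seed=6))
    assert a != c


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_disconnected_cliques_separate(seed):
    # two 20-node weight-1 cliques, no cross edges
    g = nx.Graph()
    names = [f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]
    g.add_nodes_from(names)
    for grp in ("a", "b"):
        for i in range(20):
            for j in range(i + 1, 20):
                g.add_edge(f"{grp}{i}", f"{grp}{j}", weight=1.0)
    coords, _ = force_layout(g, LayoutParams(seed=seed))
    A = np.array([coords[f"a{i}"] for i in range(20)])
    B = np.array([coords[f"b{i}"] for i in range(20)])
    between = np.linalg.norm(A.mean(0) - B.mean(0))

    def mean_pairwise(X):
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        return d[np.triu_indices(len(X), 1)].mean()

    assert between > mean_pairwise(A)
    assert between > mean_pairwise(B)


# --- density ----------------------------------------------------------------

def test_density_integrates_to_point_count():
    rng = np.random.default_rng(0)
    coords = {f"g{i}": tuple(rng.random(2)) for i in range(30)}
    grid = density_landscape(coords, bandwidth=0.1, grid_size=96)
    assert np.all(grid.values >= 0)
    total = grid.values.sum() * grid.cell_area
    assert total == pytest.approx(30, rel=0.01)


def test_single_point_peak_at_point():
    grid = density_landscape({"g": (0.3, 0.7)}, bandwidth=0.05, grid_size=64)
    iy, ix = np.unravel_index(grid.values.argmax(), grid.values.shape)
    assert grid.xs[ix] == pytest.approx(0.3, abs=0.01)
    assert grid.ys[iy] == pytest.approx(0.7, abs=0.01)


def test_two_far_groups_give_two_near_equal_maxima():
    coords = {f"a{i}": (0.0 + 0.01 * i, 0.0) for i in range(5)}
    coords |= {f"b{i}": (5.0 + 0.01 * i, 0.0) for i in range(5)}
    grid = density_landscape(coords, bandwidth=0.2, grid_size=128)
    peaks, _ = extract_peaks(grid, 0.2, coords)
    assert len(peaks) == 2
    assert peaks[0].height == pytest.approx(peaks[1].height, rel=0.1)


# --- peaks and basins -------------------------------------------------------

def _two_mode_setup():
    coords = {f"a{i}": (0.0, 0.01 * i) for i in range(6)}
    coords |= {f"b{i}": (3.0, 0.01 * i) for i in range(4)}
    grid = density_landscape(coords, bandwidth=0.25, grid_size=96)
    return coords, grid


def test_unimodal_surface_single_peak_labels_all():
    coords = {f"g{i}": (0.05 * i, 0.0) for i in range(8)}
    grid = density_landscape(coords, bandwidth=0.5, grid_size=64)
    peaks, labels = extract_peaks(grid, 0.1, coords)
    assert len(peaks) == 1
    assert set(labels.values()) == {peaks[0].peak_id}


def test_two_modes_split_matches_ascent_oracle():
    coords, grid = _two_mode_setup()
    peaks, labels = extract_peaks(grid, 0.2, coords)
    assert len(peaks) == 2
    peak_cells = {p.cell: p.peak_id for p in peaks}

    def plateau_lookup(summit):
        # summit may sit on an equal-height plateau next to the peak cell
        target = grid.values[summit]
        seen, stack = {summit}, [summit]
        while stack:
            cell = stack.pop()
            if cell in peak_cells:
                return peak_cells[cell]
            cy, cx = cell
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    nb = (cy + dy, cx + dx)
                    if (
                        0 <= nb[0] < grid.values.shape[0]
                        and 0 <= nb[1] < grid.values.shape[1]
                        and nb not in seen
                        and grid.values[nb] == target
                    ):
                        seen.add(nb)
                        stack.append(nb)
        return None

    for gene, (x, y) in coords.items():
        ix = int(np.abs(grid.xs - x).argmin())
        iy = int(np.abs(grid.ys - y).argmin())
        summit = oracle_grid_ascent(grid.values, iy, ix)
        assert labels[gene] == plateau_lookup(summit)
    assert {labels[g] for g in coords if g.startswith("a")} != {
        labels[g] for g in coords if g.startswith("b")
    }


def test_extreme_prominence_gate_leaves_one_peak():
    coords, grid = _two_mode_setup()
    peaks, _ = extract_peaks(grid, 0.999, coords)
    assert len(peaks) == 1  # the 4-point mode is lower and gets gated


def test_peak_count_monotone_in_prominence():
    coords, grid = _two_mode_setup()
    counts = [
        len(extract_peaks(grid, mp, coords)[0]) for mp in (0.05, 0.2, 0.5, 0.999)
    ]
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_prominence_bounds_validated():
    _, grid = _two_mode_setup()
    with pytest.raises(ValueError):
        extract_peaks(grid, 0.0, {})


# --- end-to-end clustering --------------------------------------------------

@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_orthogonal_groups_recovered_exactly(seed):
    # between-group cosine distance 1, within-group 0 → ARI must be 1
    groups = [0] * 8 + [1] * 8 + [2] * 8
    pm = _profiles(groups)
    res = cluster_genes(pm, LayoutParams(seed=seed, k_neighbors=5))
    assert res.n_clusters() == 3
    pred = [res.labels[g] for g in pm.genes]
    assert adjusted_rand_score(groups, pred) == pytest.approx(1.0)


def test_label_assignment_is_input_order_invariant():
    groups = [0] * 6 + [1] * 6
    pm = _profiles(groups)
    rev = ProfileMatrix(
        list(reversed(pm.genes)), pm.motifs, pm.n_bins, pm.bin_width,
        pm.counts[::-1].copy(),
    )
    r1 = cluster_genes(pm, LayoutParams(seed=2, k_neighbors=3))
    r2 = cluster_genes(rev, LayoutParams(seed=2, k_neighbors=3))
    assert r1.labels == r2.labels
    assert r1.coords == r2.coords


def test_duplicating_profiles_preserves_peak_count():
    groups = [0] * 6 + [1] * 6
    pm = _profiles(groups)
    dup = ProfileMatrix(
        pm.genes + [g + "_dup" for g in pm.genes],
        pm.motifs, pm.n_bins, pm.bin_width,
        np.vstack([pm.counts, pm.counts]),
    )
    r1 = cluster_genes(pm, LayoutParams(seed=3, k_neighbors=3))
    r2 = cluster_genes(dup, LayoutParams(seed=3, k_neighbors=3))
    assert r1.n_clusters() == r2.n_clusters()


def test_two_identical_genes_form_one_peak():
    pm = _profiles([0, 0])
    res = cluster_genes(pm, LayoutParams(seed=1, k_neighbors=1))
    assert res.n_clusters() == 1
    assert set(res.labels.values()) == {res.peaks[0].peak_id}


def test_zero_profile_genes_stay_unclustered():
    pm = _profiles([0, 0, 0, 0, -1])  # last gene all-zero
    res = cluster_genes(pm, LayoutParams(seed=4, k_neighbors=2))
    assert res.labels["g04"] == UNCLUSTERED
    assert all(res.labels[g] != UNCLUSTERED for g in pm.genes[:4])


def test_all_zero_profiles_rejected():
    pm = _profiles([-1, -1, -1])
    with pytest.raises(ValueError, match="min_sig"):
        cluster_genes(pm, LayoutParams(seed=1, k_neighbors=1))


def test_result_serialization_round_trip(tmp_path):
    pm = _profiles([0] * 5 + [1] * 5)
    res = cluster_genes(pm, LayoutParams(seed=7, k_neighbors=3))
    res.to_json(tmp_path / "landscape.json")
    res.write_labels(tmp_path / "labels.tsv")
    text = (tmp_path / "labels.tsv").read_text().splitlines()
    assert text[0] == "gene\tpeak"
    assert len(text) == 11
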