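"""Shared fixtures: tiny labelled tubes, phantom datasets, a brute-force
shortest-path oracle, and one session-scoped desk-scale cross-validation
run reused by the end-to-end tests."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from panseg import (EvalCase, NetConfig, PhantomSpec, evaluate_pipeline,
                    generate_dataset, preprocess)

MASTER_SEED = 1


# ----------------------------------------------------------------------
# independent geodesic oracle: explicit voxel graph + scipy Dijkstra
# ----------------------------------------------------------------------

def dijkstra_oracle(mask, source, spacing=(1.0, 1.0, 1.0)):
    """Single-source shortest path on the explicit 26-connected edge list.

    Built independently of the package's geodesic implementation: every
    pair of 26-adjacent mask voxels becomes an undirected edge weighted by
    its physical Euclidean step length, and scipy's sparse-graph Dijkstra
    does the rest.  Returns a grid of distances (inf off-mask/unreached).
    """
    mask = np.asarray(mask).astype(bool)
    idx = np.argwhere(mask)
    flat = {tuple(v): i for i, v in enumerate(idx)}
    sp = np.asarray(spacing, dtype=float)
    rows, cols, weights = [], [], []
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]
    for v in idx:
        vi = flat[tuple(v)]
        for off in offsets:
            w = tuple(v + np.asarray(off))
            if w in flat:
                rows.append(vi)
                cols.append(flat[w])
                weights.append(float(np.linalg.norm(np.asarray(off) * sp)))
    graph = coo_matrix((weights, (rows, cols)), shape=(len(idx), len(idx)))
    dist_flat = csgraph_dijkstra(graph, indices=flat[tuple(source)])
    out = np.full(mask.shape, np.inf)
    out[tuple(idx.T)] = dist_flat
    return out


def make_connected_mask(rng, shape=(10, 10, 10), n_voxels=40):
    """Random 26-connected mask grown by repeated neighbour accretion."""
    mask = np.zeros(shape, dtype=bool)
    pos = np.array([rng.integers(s) for s in shape])
    mask[tuple(pos)] = True
    frontier = [pos]
    while mask.sum() < n_voxels and frontier:
        base = frontier[rng.integers(len(frontier))]
        step = rng.integers(-1, 2, size=3)
        cand = base + step
        if np.all(cand >= 0) and np.all(cand < shape) and not mask[tuple(cand)]:
            mask[tuple(cand)] = True
            frontier.append(cand)
    return mask


# ----------------------------------------------------------------------
# small deterministic fixtures
# ----------------------------------------------------------------------

@pytest.fixture
def straight_tube():
    """1-voxel-thick 12-voxel tube along axis 0 with H(5)/B(4)/T(3) labels."""
    mask = np.zeros((12, 3, 3), dtype=bool)
    mask[:, 1, 1] = True
    labels = np.zeros((12, 3, 3), dtype=np.uint8)
    labels[:5, 1, 1] = 1
    labels[5:9, 1, 1] = 2
    labels[9:, 1, 1] = 3
    return mask, labels


def build_desk_cases(seed=MASTER_SEED, n=8):
    """Generate and preprocess the desk-scale phantom dataset."""
    cases_raw, manifest = generate_dataset(
        n, base_spec=PhantomSpec(preset="J"), seed=seed,
        presets=["straight", "J", "U"],
    )
    cases = []
    for i, (vol, labels, _) in enumerate(cases_raw):
        v, l, _ = preprocess(vol, labels, padding=2)
        cases.append(EvalCase(f"phantom{i:03d}", v, l))
    return cases, manifest


def run_desk_crossval(seed=MASTER_SEED, **kwargs):
    cases, _ = build_desk_cases(seed=seed)
    return evaluate_pipeline(cases, mode="crossval", folds=4, seed=seed,
                             net_config=NetConfig.desk_test(seed=seed),
                             **kwargs)


@pytest.fixture(scope="session")
def desk_cases():
    return build_desk_cases()[0]


@pytest.fixture(scope="session")
def desk_crossval(desk_cases):
    """One 4-fold cross-validation at desk scale, shared across tests."""
    return evaluate_pipeline(desk_cases, mode="crossval", folds=4,
                             seed=MASTER_SEED,
                             net_config=NetConfig.desk_test(seed=MASTER_SEED))
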