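"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results by a different route than the
package (explicit node/edge enumeration + networkx BFS for components,
all-pairs loops for STD, step-up loop for BH, projection-matrix GLM for the
ANCOVA) so that agreement is informative.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import stconnectome as st


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_sc():
    """3 regions with structural edges 0-1 and 1-2 (a path)."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return st.StructuralConnectome(w)


@pytest.fixture
def toy_raster():
    """Active cells (0,0), (1,0), (1,1), (2,1)."""
    act = np.zeros((3, 2), dtype=bool)
    act[0, 0] = act[1, 0] = act[1, 1] = act[2, 1] = True
    return st.ActivationRaster(active=act, threshold_used=2.0)


@pytest.fixture
def toy_parc():
    return st.Parcellation(
        region_names=np.array(["a", "b", "c"], dtype=object),
        systems=np.array(["VIS", "VIS", "SM"], dtype=object),
    )


@pytest.fixture(scope="session")
def small_template():
    """Shared 40-region parcellation + structural template for cohort tests."""
    labels = st.generate_parcellation(40, seed=1234)
    sc = st.generate_structural_connectome(labels, p_in=0.3, p_out=0.02, seed=1235)
    return labels, sc


def pool_from_cohort(cohort, labels, sc, min_size=2):
    """Run graph + CC extraction over a raster-mode cohort, return the pool."""
    comps = []
    for s in cohort.subjects:
        raster = st.ActivationRaster(active=s.data, threshold_used=float("nan"))
        ccset = st.extract_components(st.build_graph(raster, sc), min_size, s.subject_id)
        comps.extend(ccset.components)
    return st.CCPool(comps, labels)


def summaries_from_cohort(cohort, sc, min_size=2) -> pd.DataFrame:
    rows = []
    for s in cohort.subjects:
        raster = st.ActivationRaster(active=s.data, threshold_used=float("nan"))
        ccset = st.extract_components(st.build_graph(raster, sc), min_size, s.subject_id)
        rows.append(
            {"subject_id": s.subject_id, "group": s.group, "age": s.age, **st.cc_summary(ccset)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# oracles


def enumerate_graph(active: np.ndarray, adj: np.ndarray, temporal_self=True) -> nx.Graph:
    """Explicit O(N^2 T) enumeration of the multilayer edge rule."""
    n, t_max = active.shape
    g = nx.Graph()
    for i in range(n):
        for t in range(t_max):
            if active[i, t]:
                g.add_node((i, t))
    for (i, t), (j, u) in itertools.combinations(sorted(g.nodes), 2):
        if abs(t - u) > 1:
            continue
        if i == j:
            if temporal_self and t != u:
                g.add_edge((i, t), (j, u))
        elif adj[i, j]:
            g.add_edge((i, t), (j, u))
    return g


def oracle_components(active, adj, temporal_self=True) -> set[frozenset]:
    g = enumerate_graph(active, adj, temporal_self)
    return {frozenset(c) for c in nx.connected_components(g)}


def component_sets(ccset: st.CCSet) -> set[frozenset]:
    return {
        frozenset(zip(c.node_regions.tolist(), c.node_frames.tolist()))
        for c in ccset.components
    }


def brute_std_region_pairs(pool: st.CCPool) -> float:
    """Region-anchored STD by explicit all-pairs cosine loops."""
    vals = []
    for i in range(pool.parc.n_regions):
        members = [
            k for k, cc in enumerate(pool.components) if i in set(cc.regions.tolist())
        ]
        if len(members) < 2:
            continue
        cosines = [
            float(pool.unit_emb[a] @ pool.unit_emb[b])
            for a, b in itertools.combinations(members, 2)
        ]
        vals.append(1.0 - float(np.mean(cosines)))
    if not vals:
        raise st.InsufficientDataError("no qualifying region")
    return float(np.mean(vals))


def brute_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up, written as the textbook loop."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        k = order[rank - 1]
        running_min = min(running_min, p[k] * m / rank)
        adjusted[k] = running_min
    return adjusted


def glm_ancova_f(df: pd.DataFrame, response: str) -> dict:
    """Drop-column F tests via explicit projection matrices.

    Design: intercept, effect-coded group (+1/-1), centered age, product.
    With this coding, the drop-column test equals the Type-III test.
    """
    y = df[response].to_numpy(dtype=float)
    g = np.where(df["group"].to_numpy() == sorted(df["group"].unique())[0], 1.0, -1.0)
    a = df["age"].to_numpy(dtype=float) - df["age"].mean()
    x_full = np.column_stack([np.ones_like(y), g, a, g * a])

    def rss(x):
        proj = x @ np.linalg.pinv(x)
        resid = y - proj @ y
        return float(resid @ resid)

    rss_full = rss(x_full)
    df_den = len(y) - x_full.shape[1]
    out = {}
    for name, col in (("group", 1), ("age", 2), ("group:age", 3)):
        x_red = np.delete(x_full, col, axis=1)
        out[name] = ((rss(x_red) - rss_full) / 1.0) / (rss_full / df_den)
    return out
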