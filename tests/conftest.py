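import numpy as np
import pandas as pd
import pytest

import heteroclone as hc


@pytest.fixture
def toy_calls() -> pd.DataFrame:
    """Three tumor samples, four loci with mixed effects."""
    rows = [
        # sample chrom pos ref alt gene effect alt depth
        ("S1", "chr17", 7578190, "T", "C", "TP53", "missense", 40, 90),
        ("S2", "chr17", 7578190, "T", "C", "TP53", "missense", 35, 80),
        ("S3", "chr17", 7578190, "T", "C", "TP53", "missense", 30, 85),
        ("S1", "chr1", 100, "A", "G", "GENE1", "synonymous", 10, 50),
        ("S1", "chr2", 200, "C", "T", "GENE2", "splice", 12, 60),
        ("S3", "chr2", 200, "C", "T", "GENE2", "splice", 14, 66),
        ("S2", "chr3", 300, "G", "A", "GENE3", "nonsense", 20, 70),
    ]
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                       "gene", "effect", "alt_count", "depth"])


@pytest.fixture
def small_params() -> hc.SimParams:
    """Compact 3-cluster design for fast simulation tests."""
    return hc.SimParams(
        samples_per_cluster=(4, 3, 2),
        n_common=10,
        n_shared={("P1", "M"): 20},
        n_cluster_specific={"P1": 15, "M": 10, "P2": 15},
        n_sample_specific_per_sample=4,
        fp_locus_pool=50,
        seed=11,
    )


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds distance via dendropy (test-only reference)."""
    import dendropy
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


def random_additive_matrix(n: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive lengths; returns its leaf metric.

    Independent oracle for NJ: the returned matrix is additive by
    construction, so NJ must reproduce both the topology and the path
    lengths exactly.
    """
    import collections

    edges: dict[str, list[tuple[str, float]]] = {}

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    counter = [0]

    def new_node():
        counter[0] += 1
        return f"_I{counter[0]}"

    leaves = [chr(65 + i) for i in range(n)]
    add_edge(leaves[0], leaves[1], float(rng.uniform(0.1, 2)))
    edge_list = [(leaves[0], leaves[1])]
    for leaf in leaves[2:]:
        a, b = edge_list[int(rng.integers(len(edge_list)))]
        w = next(wt for nb, wt in edges[a] if nb == b)
        m = new_node()
        edges[a] = [(nb, wt) for nb, wt in edges[a] if nb != b]
        edges[b] = [(nb, wt) for nb, wt in edges[b] if nb != a]
        w1 = w * float(rng.uniform(0.2, 0.8))
        add_edge(a, m, w1)
        add_edge(b, m, w - w1)
        add_edge(m, leaf, float(rng.uniform(0.1, 2)))
        edge_list.remove((a, b))
        edge_list += [(a, m), (b, m), (m, leaf)]

    D = np.zeros((n, n))
    for i, s in enumerate(leaves):
        dist = {s: 0.0}
        dq = collections.deque([s])
        while dq:
            u = dq.popleft()
            for v, w in edges[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    dq.append(v)
        for j, t in enumerate(leaves):
            D[i, j] = dist[t]
    return leaves, D


def random_ultrametric_matrix(n: int, rng: np.random.Generator):
    """Random ultrametric metric built by agglomerating at increasing heights."""
    labels = [f"S{i}" for i in range(n)]
    clusters = [[l] for l in labels]
    heights = np.sort(rng.uniform(0.1, 5.0, size=n - 1))
    D = np.zeros((n, n))
    idx = {l: i for i, l in enumerate(labels)}
    for h in heights:
        a, b = rng.choice(len(clusters), size=2, replace=False)
        a, b = sorted((int(a), int(b)))
        for x in clusters[a]:
            for y in clusters[b]:
                D[idx[x], idx[y]] = D[idx[y], idx[x]] = 2 * h
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return labels, D
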