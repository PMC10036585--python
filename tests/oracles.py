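"""Independent oracles for the test suite.

These deliberately avoid the package's optimized code paths: modularity is
transcribed as a literal quadruple loop over (i, j, l, r), and the optimal
partition is found by exhaustive enumeration of set partitions (restricted
growth strings, optionally capped at a maximum block count).
"""

from __future__ import annotations

import numpy as np

from braindyn.netbuild import LayerStack


def make_stack(layers) -> LayerStack:
    layers = [np.asarray(A, dtype=float) for A in layers]
    return LayerStack(layers=layers, window_starts=list(range(len(layers))),
                      window_length_samples=1, step_samples=1,
                      region_ids=[f"n{i}" for i in range(layers[0].shape[0])])


def random_stack(rng: np.random.Generator, n_nodes: int, n_layers: int) -> LayerStack:
    layers = []
    for _ in range(n_layers):
        M = rng.random((n_nodes, n_nodes))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        layers.append(M)
    return make_stack(layers)


def brute_modularity(stack: LayerStack, labels: np.ndarray,
                     gamma: float, omega: float) -> float:
    """Literal quadruple-loop transcription of the multilayer quality function."""
    N, L = stack.n_nodes, stack.n_layers
    k = stack.layer_strengths()
    c = np.zeros((N, L))
    if L > 1 and omega:
        c[:, :] = 2 * omega
        c[:, 0] = omega
        c[:, -1] = omega
    mu = 0.5 * (k + c).sum()
    total = 0.0
    for i in range(N):
        for j in range(N):
            for l in range(L):
                for r in range(L):
                    if labels[i, l] != labels[j, r]:
                        continue
                    if l == r:
                        A = stack.layers[l]
                        m_l = A.sum() / 2
                        if m_l > 0:
                            total += A[i, j] - gamma * k[i, l] * k[j, l] / (2 * m_l)
                    if i == j and abs(l - r) == 1:
                        total += omega
    return total / (2 * mu)


def all_partitions(n: int, max_blocks: int) -> np.ndarray:
    """All set partitions of n items with at most max_blocks blocks,
    as restricted growth strings (one row per partition)."""
    out: list[tuple[int, ...]] = []
    s = [0] * n

    def rec(i: int, m: int) -> None:
        if i == n:
            out.append(tuple(s))
            return
        for v in range(min(m + 1, max_blocks - 1) + 1):
            s[i] = v
            rec(i + 1, max(m, v))

    rec(0, -1)
    return np.array(out)


def brute_optimal_Q(stack: LayerStack, gamma: float, omega: float,
                    max_blocks: int = 4) -> float:
    """Exhaustive-enumeration optimum of Q (capped community count).

    The cap can only lower the optimum, so bounds proven against this value
    are conservative.
    """
    from braindyn.community import _total_mu, modularity_matrix

    B = modularity_matrix(stack, gamma, omega).toarray()
    mu = _total_mu(stack, omega)
    n = B.shape[0]
    P = all_partitions(n, max_blocks)
    Q = np.zeros(len(P))
    for a in range(n):
        for b in range(n):
            if B[a, b]:
                Q += B[a, b] * (P[:, a] == P[:, b])
    return float(Q.max() / (2 * mu))
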