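"""Generation of the nine connection blocks of the microcircuit.

Homogeneous structure is an independent-Bernoulli digraph with the
connection-type density ``p`` (autapses excluded within a class).
Structural heterogeneity skews the in-/out-degree distributions: edge
endpoints are drawn independently from normalized truncated-exponential
index distributions

    P(j) proportional to exp(-j * k / N),   j = 0 .. N-1

for the pre (``k_out``) and post (``k_in``) side; ``k = 0`` reduces to the
uniform distribution.  Skewed blocks carry exactly floor(p * n_pre * n_post)
edges; duplicate ordered pairs and autapses are resampled, so neuron index 0
is the most-connected end of the distribution.

Weight correlations (applied when structural and synaptic heterogeneity are
combined) rescale every weight by per-pre- and per-post-neuron lognormal
factors zeta ~ logN(-c^2/2, c), whose mean is exactly 1 for any c, inducing
common-factor correlations among weights sharing an endpoint without
changing the marginal mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectionBlock",
    "truncated_exponential_pmf",
    "build_block_uniform",
    "build_block_skewed",
    "apply_weight_correlations",
]


@dataclass
class ConnectionBlock:
    """Edge list of one connection type, with parallel weight/delay arrays."""

    pre: str
    post: str
    n_pre: int
    n_post: int
    pre_idx: np.ndarray
    post_idx: np.ndarray
    weights: np.ndarray = field(default=None)
    delays: np.ndarray = field(default=None)

    def __post_init__(self):
        self.pre_idx = np.asarray(self.pre_idx, dtype=np.int64)
        self.post_idx = np.asarray(self.post_idx, dtype=np.int64)
        if len(self.pre_idx) != len(self.post_idx):
            raise ValueError("edge index arrays must have equal length")
        if len(self.pre_idx) and (self.pre_idx.min() < 0 or
                                  self.pre_idx.max() >= self.n_pre):
            raise ValueError("pre indices out of bounds")
        if len(self.post_idx) and (self.post_idx.min() < 0 or
                                   self.post_idx.max() >= self.n_post):
            raise ValueError("post indices out of bounds")
        if self.pre == self.post and np.any(self.pre_idx == self.post_idx):
            raise ValueError("autapses are not allowed within a class")
        for arr in (self.weights, self.delays):
            if arr is not None and len(arr) != self.n_edges:
                raise ValueError("weights/delays must match the edge count")

    @property
    def n_edges(self) -> int:
        return len(self.pre_idx)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.post_idx, minlength=self.n_post)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.pre_idx, minlength=self.n_pre)

    def to_coo_text(self, path):
        """Write edges as four-column text (pre, post, weight, delay)."""
        w = self.weights if self.weights is not None else np.ones(self.n_edges)
        d = self.delays if self.delays is not None else np.zeros(self.n_edges)
        np.savetxt(path, np.column_stack([self.pre_idx, self.post_idx, w, d]),
                   fmt=["%d", "%d", "%.9g", "%.9g"],
                   header=f"{self.pre}->{self.post} pre post weight delay_ms")


def truncated_exponential_pmf(n: int, k: float) -> np.ndarray:
    """Normalized pmf P(j) prop. to exp(-j k / n) on {0, ..., n-1}.

    k = 0 gives the uniform distribution.
    """
    if n <= 0:
        raise ValueError("support size must be positive")
    if k < 0:
        raise ValueError("skewness parameter must be nonnegative")
    if k == 0:
        return np.full(n, 1.0 / n)
    w = np.exp(-np.arange(n) * (k / n))
    return w / w.sum()


def build_block_uniform(n_pre: int, n_post: int, p: float, seed=None,
                        pre="pre", post="post") -> ConnectionBlock:
    """Independent-Bernoulli block: each ordered pair connected with
    probability p; autapses excluded when pre and post label the same class."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("connection probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_pre, n_post)) < p
    if pre == post:
        np.fill_diagonal(mask, False)
    pre_idx, post_idx = np.nonzero(mask)
    return ConnectionBlock(pre=pre, post=post, n_pre=n_pre, n_post=n_post,
                           pre_idx=pre_idx, post_idx=post_idx)


def build_block_skewed(n_pre: int, n_post: int, p: float,
                       k_out: float = 0.0, k_in: float = 0.0, seed=None,
                       pre="pre", post="post",
                       max_rounds: int = 10000) -> ConnectionBlock:
    """Skewed-degree block with exactly floor(p * n_pre * n_post) edges.

    Edge endpoints are drawn independently from the truncated-exponential
    index distributions; duplicate ordered pairs and autapses are resampled
    until the target count of distinct edges is reached.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("connection probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_edges = int(np.floor(p * n_pre * n_post))
    if pre == post and n_edges > n_pre * (n_post - 1):
        raise ValueError("requested edge count exceeds available pairs")
    p_pre = truncated_exponential_pmf(n_pre, k_out)
    p_post = truncated_exponential_pmf(n_post, k_in)

    codes = np.empty(0, dtype=np.int64)
    oversample = 1.3
    for _ in range(max_rounds):
        need = n_edges - len(codes)
        if need <= 0:
            break
        m = int(min(max(need * oversample + 16, need), 8 * n_edges + 64))
        i = rng.choice(n_pre, size=m, p=p_pre)
        j = rng.choice(n_post, size=m, p=p_post)
        new = i.astype(np.int64) * n_post + j
        if pre == post:
            new = new[i != j]
        before = len(codes)
        codes = np.unique(np.concatenate([codes, new]))
        gained = len(codes) - before
        # saturated regions reject most draws; widen the oversampling as the
        # acceptance rate falls
        rate = gained / m
        oversample = min(1.0 / max(rate, 1e-3), 1000.0)
    else:
        raise RuntimeError("edge resampling did not converge")
    if len(codes) > n_edges:
        codes = rng.choice(codes, size=n_edges, replace=False)
    return ConnectionBlock(pre=pre, post=post, n_pre=n_pre, n_post=n_post,
                           pre_idx=codes // n_post, post_idx=codes % n_post)


def apply_weight_correlations(block: ConnectionBlock, c_in: float = 0.0,
                              c_out: float = 0.0, seed=None) -> ConnectionBlock:
    """Rescale weights by per-endpoint lognormal factors zeta.

    zeta_i ~ logN(-c_in^2/2, c_in) per postsynaptic neuron and
    zeta_j ~ logN(-c_out^2/2, c_out) per presynaptic neuron;
    w_ij <- w_ij * zeta_i * zeta_j.  E[zeta] = 1, so the marginal mean weight
    is preserved; c = 0 leaves weights exactly unchanged.
    """
    if block.weights is None:
        raise ValueError("block has no weights assigned")
    if c_in < 0 or c_out < 0:
        raise ValueError("correlation strengths must be nonnegative")
    if c_in == 0 and c_out == 0:
        return block
    rng = np.random.default_rng(seed)
    zeta_post = (rng.lognormal(-c_in**2 / 2.0, c_in, size=block.n_post)
                 if c_in > 0 else np.ones(block.n_post))
    zeta_pre = (rng.lognormal(-c_out**2 / 2.0, c_out, size=block.n_pre)
                if c_out > 0 else np.ones(block.n_pre))
    block.weights = (block.weights * zeta_post[block.post_idx]
                     * zeta_pre[block.pre_idx])
    return block
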