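"""Posterior draw container and scalar views used by diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .design import COVARIATE_NAMES, STATUS_LABELS

__all__ = ["Posterior", "scalar_draws"]


@dataclass
class Posterior:
    """MCMC draws for every parameter, kept after burn-in, per chain.

    Array shapes (C chains, K kept draws):

    * ``beta``: (C, K, 2, 7) — status (untreated, treated) × covariate
    * ``phi``, ``sigma``: (C, K)
    * ``tau_block``, ``tau_tree``: (C, K) (NaN when the run used a flat
      intercept structure)
    * ``a``: (C, K, n_sites, 2) site × status intercepts, or (C, K, 1, 1)
      for a flat intercept
    * ``d_block``: (C, K, B); ``d_tree``: (C, K, T)
    * ``w_asw``, ``w_vpd``: (C, K, 5, 5) simplex weight matrices
    """

    beta: np.ndarray
    phi: np.ndarray
    sigma: np.ndarray
    tau_block: np.ndarray
    tau_tree: np.ndarray
    a: np.ndarray
    d_block: np.ndarray
    d_tree: np.ndarray
    w_asw: np.ndarray
    w_vpd: np.ndarray
    n_chains: int
    n_iter: int
    n_burnin: int
    seed: int
    config_hash: str
    site_labels: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("burn-in must be smaller than the iteration count")
        C, K = self.phi.shape
        if self.beta.shape[:2] != (C, K) or self.sigma.shape != (C, K):
            raise ValueError("inconsistent draw dimensions")

    @property
    def n_kept(self) -> int:
        return self.phi.shape[1]

    def pooled(self, arr: np.ndarray) -> np.ndarray:
        """Flatten the chain axis: (C, K, ...) -> (C*K, ...)."""
        return arr.reshape(-1, *arr.shape[2:])

    def to_dataframe(self):
        """Long export: one column per scalar parameter plus chain/iteration."""
        import pandas as pd

        cols = {}
        for name, d in scalar_draws(self).items():
            cols[name] = d.ravel()
        C, K = self.phi.shape
        out = pd.DataFrame(cols)
        out.insert(0, "chain", np.repeat(np.arange(C), K))
        out.insert(1, "iteration", np.tile(np.arange(K), C))
        return out


def scalar_draws(post: Posterior, include_random_effects: bool = False) -> dict[str, np.ndarray]:
    """Named scalar (C, K) views of the posterior for summaries and R-hat.

    The monitored set covers all status-specific coefficients, the AR and
    variance terms, every site × status intercept, and the per-lag totals
    of both weight matrices; block/tree deviations are included only on
    request.
    """
    out: dict[str, np.ndarray] = {}
    for s, slab in enumerate(STATUS_LABELS):
        for c, cname in enumerate(COVARIATE_NAMES):
            out[f"beta_{slab}_{cname}"] = post.beta[:, :, s, c]
    out["phi"] = post.phi
    out["sigma"] = post.sigma
    if np.all(np.isfinite(post.tau_block)):
        out["tau_block"] = post.tau_block
        out["tau_tree"] = post.tau_tree
    n_sites = post.a.shape[2]
    for si in range(n_sites):
        label = post.site_labels[si] if si < len(post.site_labels) else str(si)
        if post.a.shape[3] == 2:
            for s, slab in enumerate(STATUS_LABELS):
                out[f"a_{label}_{slab}"] = post.a[:, :, si, s]
        else:
            out[f"a_{label}"] = post.a[:, :, si, 0]
    for var, w in (("asw", post.w_asw), ("vpd", post.w_vpd)):
        totals = w.sum(axis=2)  # (C, K, 5) per-lag totals
        for lag in range(totals.shape[2]):
            out[f"w_{var}_lag{lag}_total"] = totals[:, :, lag]
    if include_random_effects:
        for j in range(post.d_block.shape[2]):
            out[f"d_block_{j}"] = post.d_block[:, :, j]
        for j in range(post.d_tree.shape[2]):
            out[f"d_tree_{j}"] = post.d_tree[:, :, j]
    return out
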